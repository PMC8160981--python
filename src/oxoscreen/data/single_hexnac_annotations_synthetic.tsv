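accession	signal_peptide	tm_domain
Q12830	0	0
Q96HC4	0	0
P51610	0	0
Q6UN15	0	0
P02545	0	0
P27816	0	0
Q8NBJ4	0	1
Q92753	0	0
P14314	1	0
P30533	1	0
Q8IYS2	1	0
Q8NBS9	1	0
P02786	0	1
Q10469	0	1
P26572	0	1
Q92520	1	0
O95994	1	0
O60502	0	0
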