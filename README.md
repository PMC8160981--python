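# oxoscreen

Oxonium-ion-guided analysis of glycopeptides in quantitative (TMT-labeled)
proteomics data.

## The problem

MS/MS spectra of glycopeptides that carry an N-acetylhexosamine (HexNAc)
are easy to recognize: they contain the [HexNAc]+ oxonium ion at m/z
204.087 and a family of related fragments in the low-mass region. What is
*not* easy is telling the two isobaric HexNAc residues apart. A single
O-linked GlcNAc (an intracellular regulatory modification) and a single
O-linked GalNAc (the Tn antigen, the start of secretory mucin-type
O-glycosylation) produce identical precursor and peptide-fragment masses,
yet they have completely different biology.

The relative intensities of two HexNAc fragment ions discriminate them:
the ratio

    r = I(m/z 144.066) / I(m/z 138.055)

is low (≲ 0.3) for O-GlcNAc peptides and high (≳ 0.7) for O-GalNAc
peptides, and this works inside ordinary TMT-labeled, non-enriched
proteome runs, so the same spectra also deliver relative quantification
across samples through their TMT reporter ions.

`oxoscreen` packages this workflow for proteomics bioinformaticians:

1. **masscalc** — theoretical masses: glycan compositions, TMT-labeled
   (glyco)peptides, precursor m/z, b/y/c/z• fragment ladders, topology-free
   glycan Y-ion ladders, and the six diagnostic oxonium ions
   (126.055, 138.055, 144.066, 168.066, 186.076, 204.087), all derived
   from elemental compositions.
2. **spectra_io** — centroided MS/MS spectra from mzML or MGF behind one
   spectrum model; MGF export of filtered subsets.
3. **oxonium_screen** — select spectra containing the 204.087 gate ion and
   register the six diagnostic ions per spectrum (tolerance 0.001 m/z,
   minimum intensity 1000 counts, peak rank ≤ 100), compute the 144/138
   ratio, and extract TMT reporter intensities.
4. **psm_integration** — read a Byonic-style glycopeptide PSM table,
   filter by score (≥ 250) and glycan composition, and merge with the
   screen output by spectrum ID.
5. **classify** — call GlcNAc / GalNAc / ambiguous from the ratio, compare
   with the localization-based prediction (signal peptide or TM domain ⇒
   GalNAc), and test group separation with a Wilcoxon rank-sum test
   (exact for small groups).
6. **site_localization** — evaluate EThcD c/z• evidence for alternative
   glycosites (presence/absence of site-discriminating ions) and annotate
   CID/MS3 spectra with glycan Y-ion ladders.
7. **synthetic_data** — a seeded generator of HCD/EThcD glycopeptide
   spectra with controllable oxonium profiles, reporters, backbone
   fragments and noise, plus matching PSM/annotation/truth tables, so the
   whole pipeline is testable without raw data.

## Worked example

The tryptic peptide `RDTTVKPGAK` of anterior gradient protein 2 (AGR2,
three TMT labels: N-terminus plus two lysines) carrying one HexNAc:

```
$ oxoscreen masscalc --peptide RDTTVKPGAK --glycan N1 --site 3 --charge 4
neutral_mass    1962.1718
precursor_mz_1+ 1963.1791
precursor_mz_2+ 982.0932
precursor_mz_3+ 655.0646
precursor_mz_4+ 491.5502
```

The 4+ precursor lands at m/z 491.550. Which threonine carries the glycan?
Simulate a clean EThcD spectrum of the Thr-4 glycoform and score the two
candidate sites (zero-based indices 2 and 3):

```python
import oxoscreen as ox

spec = ox.simulate_ethcd_spectrum("RDTTVKPGAK", ox.GlycanComposition(hexnac=1),
                                  site=3, coverage=1.0, seed=2)
hyps = ox.enumerate_hypotheses(ox.LabeledPeptide("RDTTVKPGAK"),
                               ox.GlycanComposition(hexnac=1), [2, 3])
evidence, call = ox.score_site_evidence(spec, hyps)
print(call)                      # 3  (zero-based -> Thr-4)
print([(e.hypothesis.site, e.verdict) for e in evidence])
# [(2, 'excluded'), (3, 'supported')]
```

The discriminating ions behind that call are c3 at m/z 619.372 and z7(2+)
at 673.414 (present, supporting Thr-4) versus c3+HexNAc at 822.452 and the
glycan-free z7(2+) at 571.875 (absent; they would be expected if Thr-3
were glycosylated).

Classifying the packaged 22-row single-HexNAc benchmark:

```python
df = ox.load_single_hexnac_benchmark().merge(
    ox.load_single_hexnac_annotations(), on="accession")
table, summary = ox.concordance_report(df)
print(summary["discordant_proteins"])
# ['Nuclear receptor ROR-beta', 'Protein O-GlcNAcase']
print(summary["ambiguous_proteins"])
# ['Golgi membrane protein 1']
```

All seven rows with ratio ≤ 0.24 are called GlcNAc and every row with
ratio ≥ 0.68 GalNAc; O-GlcNAcase (ratio 1.13, predicted GlcNAc from its
localization) is flagged as discordant — the known case where the ratio
contradicts the localization heuristic.

The same steps are available as CLI subcommands (`simulate`, `screen`,
`merge`, `classify`, `localize`, `masscalc`, `oxonium-table`); see
`oxoscreen --help`.

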