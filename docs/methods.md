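# Methods

## Mass model

All masses are monoisotopic. Amino-acid residue masses come from the
pyteomics element tables; glycan residue (dehydrated monosaccharide)
masses are HexNAc 203.079373, Hex 162.052824, Fuc 146.057909 and NeuAc
291.095417 Da. Fixed modifications follow the TMT10 workflow:
+229.162932 Da on the peptide N-terminus and every lysine (so a peptide
carries `Lys count + 1` labels), +57.021464 Da (carbamidomethyl) on every
cysteine. O-glycans attach to Ser/Thr only; TMT is never placed on a
glycan and glycans never carry TMT (the tag is amine-reactive).

Protonated-species m/z uses the proton mass 1.00727646688 Da. The six
diagnostic oxonium ions are computed from the elemental composition of the
[HexNAc]+ cation (C8H14NO5) minus the respective neutral loss, with one
electron mass (0.00054858 Da) subtracted because these are even-electron
cations; this reproduces all six conventional 3-decimal values
(126.055 … 204.087) exactly after rounding.

Backbone fragments are the complete b/y/c/z ladders. z ions are emitted
only in the radical z-dot (z+1) convention of ETD/EThcD:
`neutral(z•_k) = neutral(y_k) − NH3 + H`, which satisfies the conservation
identity `neutral(c_i) + neutral(z•_(n−i)) = neutral(peptide) + m(H)` at
every cleavage site. Plain (even-electron) z ions are not produced; the
EThcD ion values this package is checked against are z-dot masses.
Backbone fragments retain the intact glycan of every residue they span —
partial glycan losses appear only in the Y-ion ladder — matching how
EThcD spectra of O-glycopeptides are interpreted.

The glycan Y ladder is topology-free: every compositional sub-multiset of
the attached glycan (∏(count_i + 1) vectors before deduplication) is
paired with the labeled peptide at each requested charge. No linkage or
branching is modeled; compositional subsets are the strongest statement
the data support at the MS2/MS3 level.

## Spectrum screen

A spectrum is selected when it contains a peak within ±0.001 m/z of the
theoretical [HexNAc]+ ion. The six diagnostic ions are registered per
spectrum under three rules: match tolerance 0.001 m/z, minimum intensity
1000 counts, and intensity rank within the top 100 peaks. Registration
centers are the theoretical cation masses, not the rounded 3-decimal
conventions (the difference, ≤ 0.0006, keeps both inside the window).
Peak rank is the position in descending-intensity order with ties broken
by ascending m/z; when several peaks fall inside one window the most
intense is registered. The intensity/rank rules are also applied to the
selection gate by default (configurable off, since they are strictly
registration rules). The 144.066/138.055 ratio is defined if and only if
both ions registered.

TMT reporters are extracted at the standard TMT10 reporter masses
(126.127726 … 131.138180) with their own tolerance, default 0.003 m/z.
Reporter extraction is deliberately separate from oxonium registration:
the oxonium ion at m/z 126.055 sits only ~0.07 Th below the TMT-126
reporter, and a high-resolution but separate window prevents conflating
them. No isotope-impurity correction or cross-run normalization is done.

## PSM integration

PSM tables are delimited text with a configurable column map. Rows with
unparseable glycan strings or scores are dropped and counted. The score
filter defaults to ≥ 250 — the stringent-acceptance convention for the
search engine that produces these tables gives both "higher than 250" and
"250 and higher" readings, so the inclusive boundary is implemented and
configurable. The packaged "single HexNAc" predicate keeps glycans with
exactly one HexNAc regardless of other residues (N1, H1N1S2, H1N1F1 all
pass). Merging is an inner join on normalized spectrum IDs (by default the
digits after `scan=`, because search engines rewrite spectrum titles);
every PSM of a multiply-matched spectrum yields its own row sharing the
spectrum's oxonium data.

## Classification

The ratio classifier is a two-threshold step function: GlcNAc for
r ≤ low, GalNAc for r ≥ high, ambiguous in between, undefined when the
ratio is undefined. Defaults are low = 0.3 (the characterized upper bound
for known O-GlcNAc peptides) and high = 0.6 (below the smallest confident
GalNAc cluster in the packaged benchmark, 0.68, while leaving its 0.44
outlier ambiguous). There is no published numeric rule, so both
thresholds are explicit parameters. Glycans with more than one HexNAc mix
GlcNAc and GalNAc contributions and yield intermediate ratios (≈ 0.5 for
the extended AGR2 glycan); such rows are marked `not_classifiable` rather
than called.

The localization-based prediction is `GalNAc iff signal peptide or
transmembrane domain present`. The predictors themselves (TMHMM, SignalP)
are not executed; annotations arrive as a TSV. The packaged annotation
table for the benchmark is synthetic in exactly that sense: the 0/1 flags
are reconstructed so the rule reproduces each published prediction.

Group separation is tested with a Wilcoxon rank-sum test using midranks
for ties. For groups of ≤ 12 each, the exact null distribution is built by
dynamic programming over doubled midranks (equivalent to full enumeration
of all assignments, verified against an enumeration oracle up to n = 7 per
group); larger groups use the normal approximation with tie correction
and a 0.5 continuity correction. Two-sided p-values are
`min(1, 2·min(P(W≤w), P(W≥w)))`.

## Site localization

For k candidate Ser/Thr sites, each hypothesis places the full glycan on
one site and fragments that span some but not all candidates predict
site-dependent m/z. Predicted values per (series, ordinal, charge) are
clustered at the match tolerance (default 0.01 m/z — wider than oxonium
registration since these are larger ions quoted to 3 decimals); a
fragment is discriminating when ≥ 2 clusters remain. "Present" means a
peak within tolerance at ≥ 0.5% of the base peak (the default absence
floor); a hypothesis is *supported* when ≥ 1 of its ions is matched and no
matched ion supports only rivals, *excluded* when rivals have matched
evidence and it has none, otherwise *indeterminate*. The overall call is
the unique supported hypothesis. This is deliberately qualitative — no
site probability is computed — because the underlying argument is made
from presence/absence of specific c/z• ions.

Y-ladder annotation of CID/MS3 spectra reports ppm errors instead of
asserting exactness: observed MS3 masses routinely deviate a few mDa from
theory, so matches are evidence, not identities. Glycan rearrangement
(e.g. fucose transfer during activation) is not modeled; a matched subset
that no biosynthetic route explains should be read with that in mind.

## Synthetic data

The generator emulates the features the pipeline consumes, at the study's
conditions: 1000 spectra per dataset, three classes (O-GlcNAc-like 0.35,
O-GalNAc-like 0.35, non-glycopeptide 0.30), log-normal 144/138 ratios with
medians 0.2 (GlcNAc-like) and 0.9 (GalNAc-like) and sigma 0.2 — the
clearly separated bimodal structure reported for single-HexNAc
glycopeptides from the two compartments; medians follow the reported
central tendencies and sigma is chosen as a realistic Orbitrap
spectrum-to-spectrum spread that keeps the two populations distinct
without making them trivially separable. Oxonium intensities are anchored
at 2×10^5 counts, reporters at group means near 10^5 with log-normal
scatter, b/y ladders at 3×10^4, and 60 uniform noise peaks at 50–900
counts (below the 1000-count registration threshold). In clean mode noise
is rejected from ±0.002 of every diagnostic/reporter center, so gate
sensitivity and specificity are 100% by construction and deviations flag
implementation defects; adversarial mode removes the exclusion to exercise
false registration. One PSM is generated per glycopeptide spectrum, with
20% of scores below the 250 cutoff. EThcD simulation emits the c/z• ladder
of the true glycoform at a configurable coverage fraction and never emits
rival-site ions. Everything derives from a single seed; outputs are
byte-identical across runs.

What the simulator does *not* emulate — isotope envelopes, co-isolation
interference, chromatographic profiles, profile-mode peaks, calibration
drift, glycan rearrangement — bounds what passing tests show: they verify
the pipeline's logic (selection, registration rules, joins, thresholds,
verdicts) at known truth, not its robustness to real-instrument artifacts.

## Numerical and design choices

- 4 decimals are kept internally; user-facing comparisons round to 3.
- Duplicate m/z values within a spectrum are merged by intensity sum at
  construction so intensity ranking is deterministic; duplicate spectrum
  IDs within a file are deterministically suffixed.
- Spectra missing a charge are retained with charge unset; operations that
  need a charge skip such spectra with a warning.
- The mzML reader interprets the subset of the PSI schema the pipeline
  needs (spectrum id, ms level, precursor selected ion, activation,
  uncompressed/zlib 32/64-bit float arrays) and matches cvParams by name,
  namespace-agnostically; profile-mode data triggers a warning and is
  processed as-is (the intended inputs are centroided Orbitrap spectra).
- The extended AGR2 glycan is taken as HexNAc(3)Hex(1)Fuc(1)NeuAc(1)
  ("H1N3F1S1" in compact notation): only this composition is consistent
  with the 742.891 (4+) precursor.
- Configuration is per-command CLI options with library-level dataclass
  defaults rather than a separate config-file layer; every command logs
  the parameters it ran with.

## Limitations

Single-HexNAc ratios from sialylated glycans (H1N1S2 etc.) are classified
like bare HexNAc, which is supported by the benchmark but known to break
down for multi-HexNAc glycans. The localization heuristic itself can be
wrong (O-GlcNAcase is the packaged counterexample); discordance is
reported, never "corrected". Structural isomer reasoning (core 2 vs
core 4 and similar) is out of scope beyond composition/Y-ion level
evidence. FDR estimation, protein inference and reporter normalization
belong to upstream/downstream tools.
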