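"""Packaged reference tables.

``load_single_hexnac_benchmark`` returns the published 22-row benchmark of
single-HexNAc O-glycopeptides (protein, peptide, glycan composition,
search score, 144.066/138.055 oxonium ratio and the localization-based
HexNAc-nature prediction) used to exercise the classifier. The
``spectrum_id`` column is synthetic scaffolding added so the table can
drive the PSM-ingestion path; the measured columns are transcribed values.

``load_single_hexnac_annotations`` returns a per-accession annotation
table (signal peptide / transmembrane flags). The flags are synthetic:
they are reconstructed so that the presence/absence rule (signal peptide
or TM domain present => GalNAc) reproduces the published prediction for
every accession; they are not the output of running TMHMM or SignalP.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_single_hexnac_benchmark", "load_single_hexnac_annotations"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("oxoscreen.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_single_hexnac_benchmark() -> pd.DataFrame:
    """22 single-HexNAc O-glycopeptide PSMs with oxonium ratios."""
    return _read("single_hexnac_benchmark.tsv")


def load_single_hexnac_annotations() -> pd.DataFrame:
    """Synthetic signal-peptide / transmembrane flags per accession."""
    return _read("single_hexnac_annotations_synthetic.tsv")
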