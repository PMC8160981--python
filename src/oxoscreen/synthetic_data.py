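"""Synthetic glycopeptide HCD / EThcD spectra with known ground truth.

The generator emulates the features of TMT-labeled Orbitrap glycopeptide
spectra that the pipeline consumes: the six HexNAc oxonium ions with a
class-dependent 144.066/138.055 ratio (log-normal per class, O-GlcNAc-like
centered at 0.2 and O-GalNAc-like at 0.9, matching the bimodal split seen
between intracellular and secretory single-HexNAc glycopeptides), TMT
reporter ions at sample-group abundances, b/y backbone ladders, and
uniform noise. In "clean" mode noise peaks are excluded from small windows
around the diagnostic-ion and reporter centers so selection and
registration operate at known truth; "adversarial" mode drops that
exclusion to exercise false registration. Every draw flows from one seed,
so a fixed configuration reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .masscalc import (
    GlycanComposition,
    LabeledPeptide,
    backbone_fragments,
    precursor_mz,
)
from .oxonium_screen import TMT10_SAMPLE_GROUPS, TMT10_REPORTER_MZ, oxonium_reference_table
from .spectra_io import Spectrum, write_spectra

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_hcd_spectrum",
    "simulate_ethcd_spectrum",
    "simulate_dataset",
]

CLASS_GLCNAC = "GlcNAc"
CLASS_GALNAC = "GalNAc"
CLASS_NON_GLYCO = "non_glyco"

_OXONIUM_MZ = {f"{ion.nominal_mz:.3f}": ion.mz for ion in oxonium_reference_table()}

# (accession, protein name, tryptic peptide); all peptides carry >=1 Ser/Thr.
# Intracellular pool -> O-GlcNAc-like class, secretory pool -> O-GalNAc-like.
_INTRACELLULAR_POOL: Tuple[Tuple[str, str, str], ...] = (
    ("SIM_GLC01", "simulated nucleocytoplasmic protein 1", "SPITIITTK"),
    ("SIM_GLC02", "simulated nucleocytoplasmic protein 2", "ETALPSTK"),
    ("SIM_GLC03", "simulated nucleocytoplasmic protein 3", "TVITEVTTMTSTVATESK"),
    ("SIM_GLC04", "simulated nucleocytoplasmic protein 4", "ASPSKPASAPASR"),
)
_SECRETORY_POOL: Tuple[Tuple[str, str, str], ...] = (
    ("SIM_GAL01", "simulated secretory protein 1", "DTTVKPGAK"),
    ("SIM_GAL02", "simulated secretory protein 2", "RDTTVKPGAK"),
    ("SIM_GAL03", "simulated secretory protein 3", "LAGTESPVREEPGEDFPAAR"),
    ("SIM_GAL04", "simulated secretory protein 4", "QVTSNSLSGTQEDGLDDPRLEK"),
)
_NON_GLYCO_POOL: Tuple[str, ...] = (
    "LVNEVTEFAK",
    "AEFVEVTK",
    "GDLGIEIPAEK",
    "YLYEIAR",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Class fractions must sum to 1. Ratio distributions are log-normal per
    class; the defaults place the O-GlcNAc-like class at median 0.2 and
    the O-GalNAc-like class at median 0.9 with sigma 0.2, giving the
    clearly separated bimodal ratio structure observed for single-HexNAc
    glycopeptides from the two cellular compartments.
    """

    n_spectra: int = 1000
    seed: int = 0
    fractions: Tuple[float, float, float] = (0.35, 0.35, 0.30)  # GlcNAc, GalNAc, non-glyco
    ratio_median: Mapping[str, float] = field(
        default_factory=lambda: {CLASS_GLCNAC: 0.2, CLASS_GALNAC: 0.9}
    )
    ratio_sigma: float = 0.2
    oxonium_base_intensity: float = 2e5
    reporter_group_means: Mapping[str, float] = field(
        default_factory=lambda: {"HT29": 1.0e5, "HCT116": 0.8e5, "LS174T": 1.2e5}
    )
    reporter_sigma: float = 0.3
    backbone_intensity: float = 3e4
    noise_peaks: int = 60
    noise_intensity_range: Tuple[float, float] = (50.0, 900.0)
    clean: bool = True
    protected_halfwidth: float = 0.002
    low_score_fraction: float = 0.2
    precursor_charge: int = 3

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("class fractions must be non-negative")
        if not 0 <= self.low_score_fraction <= 1:
            raise ValueError("low_score_fraction must be in [0, 1]")


def _protected_centers(config: SimulationConfig) -> np.ndarray:
    centers = list(_OXONIUM_MZ.values()) + list(TMT10_REPORTER_MZ.values())
    return np.asarray(sorted(centers))


def _draw_noise(
    rng: np.random.Generator,
    config: SimulationConfig,
    lo: float = 120.0,
    hi: float = 1400.0,
) -> Tuple[np.ndarray, np.ndarray]:
    n = config.noise_peaks
    if n == 0:
        return np.empty(0), np.empty(0)
    centers = _protected_centers(config)
    mz = rng.uniform(lo, hi, size=n)
    if config.clean:
        for _ in range(100):
            idx = np.searchsorted(centers, mz)
            idx_lo = np.clip(idx - 1, 0, centers.size - 1)
            idx_hi = np.clip(idx, 0, centers.size - 1)
            near = np.minimum(
                np.abs(mz - centers[idx_lo]), np.abs(mz - centers[idx_hi])
            ) <= config.protected_halfwidth
            if not near.any():
                break
            mz[near] = rng.uniform(lo, hi, size=int(near.sum()))
    inten = rng.uniform(*config.noise_intensity_range, size=n)
    return mz, inten


def _reporter_truth(
    rng: np.random.Generator, config: SimulationConfig
) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for group, channels in TMT10_SAMPLE_GROUPS.items():
        mean = config.reporter_group_means.get(group, 1e5)
        for ch in channels:
            out[ch] = float(
                mean * rng.lognormal(0.0, config.reporter_sigma)
            )
    return out


def simulate_hcd_spectrum(
    peptide: LabeledPeptide,
    charge: int,
    cls: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    spectrum_id: str = "scan=1",
) -> Tuple[Spectrum, Dict[str, object]]:
    """One synthetic HCD spectrum plus its truth record.

    Glycopeptide classes carry all six oxonium ions with
    I(144.066)/I(138.055) drawn from the class ratio distribution; the
    non-glycopeptide class carries no peak near any diagnostic ion.
    """
    if cls not in (CLASS_GLCNAC, CLASS_GALNAC, CLASS_NON_GLYCO):
        raise ValueError(f"unknown class {cls!r}")
    mz_list: List[float] = []
    int_list: List[float] = []
    truth: Dict[str, object] = {
        "class": cls,
        "peptide": peptide.sequence,
        "charge": charge,
        "ratio": None,
        "site": None,
    }

    if cls != CLASS_NON_GLYCO:
        base = config.oxonium_base_intensity * rng.lognormal(0.0, 0.5)
        ratio = float(
            rng.lognormal(np.log(config.ratio_median[cls]), config.ratio_sigma)
        )
        i138 = base
        intensities = {
            "126.055": 0.4 * base * rng.lognormal(0.0, 0.3),
            "138.055": i138,
            "144.066": ratio * i138,
            "168.066": 0.3 * base * rng.lognormal(0.0, 0.3),
            "186.076": 0.5 * base * rng.lognormal(0.0, 0.3),
            "204.087": 2.0 * base * rng.lognormal(0.0, 0.3),
        }
        for label, inten in intensities.items():
            mz_list.append(_OXONIUM_MZ[label])
            int_list.append(inten)
        truth["ratio"] = ratio
        site = min(peptide.glycans) if peptide.glycans else None
        truth["site"] = site

    reporters = _reporter_truth(rng, config)
    for ch, inten in reporters.items():
        mz_list.append(TMT10_REPORTER_MZ[ch])
        int_list.append(inten)
    truth["reporters"] = reporters

    for frag in backbone_fragments(peptide, ("b", "y"), max_charge=1):
        mz_list.append(frag.mz)
        int_list.append(config.backbone_intensity * rng.lognormal(0.0, 0.7))

    noise_mz, noise_int = _draw_noise(rng, config)
    mz_list.extend(noise_mz.tolist())
    int_list.extend(noise_int.tolist())

    spectrum = Spectrum.from_peaks(
        spectrum_id,
        mz_list,
        int_list,
        precursor_mz=precursor_mz(peptide, charge),
        charge=charge,
        method="HCD",
    )
    return spectrum, truth


def simulate_ethcd_spectrum(
    peptide_sequence: str,
    glycan: GlycanComposition,
    site: int,
    coverage: float = 1.0,
    seed: int = 0,
    charge: int = 4,
    spectrum_id: str = "ethcd=1",
    rng: Optional[np.random.Generator] = None,
) -> Spectrum:
    """Synthetic EThcD spectrum of a glycopeptide with a known site.

    Emits the c/z-dot ladder of the glycoform with the glycan at ``site``,
    keeping a random ``coverage`` fraction of the ions (coverage 1.0 keeps
    all, 0.0 none); no ions supporting rival sites are generated.
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    glycopeptide = LabeledPeptide(peptide_sequence, {site: glycan})
    frags = backbone_fragments(glycopeptide, ("c", "z"), max_charge=min(2, charge))
    n_keep = int(round(coverage * len(frags)))
    keep_idx = rng.choice(len(frags), size=n_keep, replace=False) if n_keep else []
    mz_list: List[float] = []
    int_list: List[float] = []
    for i in sorted(np.asarray(keep_idx, dtype=int).tolist()):
        mz_list.append(frags[i].mz)
        int_list.append(float(5e4 * rng.lognormal(0.0, 0.5)))
    return Spectrum.from_peaks(
        spectrum_id,
        mz_list,
        int_list,
        precursor_mz=precursor_mz(glycopeptide, charge),
        charge=charge,
        method="EThcD",
    )


@dataclass
class SimulatedDataset:
    """In-memory synthetic dataset with file outputs optional."""

    spectra: List[Spectrum]
    psm_table: pd.DataFrame
    annotations: pd.DataFrame
    truth: Dict[str, Dict[str, object]]
    config: SimulationConfig

    def write(self, out_dir: str) -> Dict[str, str]:
        """Write spectra.mgf, psms.tsv, annotations.tsv and truth.json."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "spectra": os.path.join(out_dir, "spectra.mgf"),
            "psms": os.path.join(out_dir, "psms.tsv"),
            "annotations": os.path.join(out_dir, "annotations.tsv"),
            "truth": os.path.join(out_dir, "truth.json"),
        }
        write_spectra(self.spectra, paths["spectra"])
        self.psm_table.to_csv(paths["psms"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def _first_st_index(sequence: str) -> int:
    for i, aa in enumerate(sequence):
        if aa in "ST":
            return i
    raise ValueError(f"no Ser/Thr in {sequence!r}")


def simulate_dataset(config: SimulationConfig = SimulationConfig()) -> SimulatedDataset:
    """Generate a self-consistent spectrum set, PSM table, annotation table
    and truth table.

    Glycopeptide spectra get one PSM each; a ``low_score_fraction`` of PSM
    scores falls below the stringent 250 cutoff. Annotation flags are
    consistent with the class: secretory-pool proteins carry a signal
    peptide, intracellular-pool proteins carry neither flag.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_spectra
    counts = np.floor(np.asarray(config.fractions) * n).astype(int)
    # distribute the remainder deterministically
    while counts.sum() < n:
        counts[int(np.argmin(counts - np.asarray(config.fractions) * n))] += 1
    classes = (
        [CLASS_GLCNAC] * counts[0] + [CLASS_GALNAC] * counts[1] + [CLASS_NON_GLYCO] * counts[2]
    )
    rng.shuffle(classes)

    spectra: List[Spectrum] = []
    truth: Dict[str, Dict[str, object]] = {}
    psm_rows: List[Dict[str, object]] = []
    glycan = GlycanComposition(hexnac=1)

    for i, cls in enumerate(classes, start=1):
        sid = f"scan={i}"
        if cls == CLASS_GLCNAC:
            acc, name, seq = _INTRACELLULAR_POOL[rng.integers(len(_INTRACELLULAR_POOL))]
        elif cls == CLASS_GALNAC:
            acc, name, seq = _SECRETORY_POOL[rng.integers(len(_SECRETORY_POOL))]
        else:
            acc, name = "", ""
            seq = _NON_GLYCO_POOL[rng.integers(len(_NON_GLYCO_POOL))]
        if cls == CLASS_NON_GLYCO:
            peptide = LabeledPeptide(seq)
        else:
            peptide = LabeledPeptide(seq, {_first_st_index(seq): glycan})
        spectrum, t = simulate_hcd_spectrum(
            peptide, config.precursor_charge, cls, config, rng, spectrum_id=sid
        )
        spectra.append(spectrum)
        t["accession"] = acc
        truth[sid] = t
        if cls != CLASS_NON_GLYCO:
            if rng.random() < config.low_score_fraction:
                score = float(rng.uniform(100.0, 249.0))
            else:
                score = float(rng.uniform(251.0, 1200.0))
            psm_rows.append(
                {
                    "spectrum_id": sid,
                    "accession": acc,
                    "protein_name": name,
                    "peptide": seq,
                    "glycan": "N1",
                    "score": round(score, 1),
                }
            )

    ann_rows = [
        {"accession": acc, "signal_peptide": 0, "tm_domain": 0}
        for acc, _, _ in _INTRACELLULAR_POOL
    ] + [
        {"accession": acc, "signal_peptide": 1, "tm_domain": 0}
        for acc, _, _ in _SECRETORY_POOL
    ]

    return SimulatedDataset(
        spectra=spectra,
        psm_table=pd.DataFrame(
            psm_rows,
            columns=["spectrum_id", "accession", "protein_name", "peptide", "glycan", "score"],
        ),
        annotations=pd.DataFrame(ann_rows),
        truth=truth,
        config=config,
    )
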