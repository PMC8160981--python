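"""Glycosite localization from EThcD c/z-dot evidence and glycan Y-ion
annotation of CID/MS3 spectra.

For a peptide with several candidate Ser/Thr sites, alternative glycosite
hypotheses predict different m/z values for exactly those backbone
fragments that span some but not all candidate sites. Those ions are
*discriminating*: observing one supports the hypotheses that predict it
and argues against the rest. The verdict logic is deliberately
conservative and qualitative — a hypothesis is supported only when at
least one of its discriminating ions is matched and no matched ion
supports a rival — mirroring how EThcD site assignments are argued from
the presence and absence of specific c/z ions rather than from a
probabilistic localization score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .masscalc import (
    GlycanComposition,
    LabeledPeptide,
    backbone_fragments,
    glycan_y_ladder,
)
from .spectra_io import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SiteHypothesis",
    "DiscriminatingIon",
    "IonObservation",
    "SiteEvidence",
    "LocalizationParams",
    "enumerate_hypotheses",
    "discriminating_ions",
    "score_site_evidence",
    "annotate_y_ladder",
]


@dataclass(frozen=True)
class SiteHypothesis:
    """One candidate glycosylation site on a peptide."""

    peptide: LabeledPeptide
    glycan: GlycanComposition
    site: int  # zero-based residue index, Ser/Thr

    @property
    def glycopeptide(self) -> LabeledPeptide:
        return self.peptide.with_glycan(self.site, self.glycan)


@dataclass(frozen=True)
class DiscriminatingIon:
    """A fragment whose theoretical m/z separates site hypotheses.

    ``supports`` holds the candidate site indices whose hypotheses predict
    this m/z for the (series, ordinal, charge) fragment.
    """

    series: str
    ordinal: int
    charge: int
    mz: float
    supports: Tuple[int, ...]


@dataclass(frozen=True)
class IonObservation:
    """Match status of one discriminating ion in a spectrum."""

    ion: DiscriminatingIon
    matched: bool
    observed_mz: Optional[float] = None
    intensity: Optional[float] = None


@dataclass
class SiteEvidence:
    """Evidence tally for one hypothesis."""

    hypothesis: SiteHypothesis
    supporting: List[IonObservation]
    contradicting: List[IonObservation]
    verdict: str  # "supported" | "excluded" | "indeterminate"

    @property
    def n_supporting_matched(self) -> int:
        return sum(o.matched for o in self.supporting)

    @property
    def n_contradicting_matched(self) -> int:
        return sum(o.matched for o in self.contradicting)


@dataclass(frozen=True)
class LocalizationParams:
    """Fragment-evidence matching parameters.

    The tolerance is wider than the oxonium registration window because
    backbone fragments are larger ions quoted to 3 decimals. ``min_relative
    _intensity`` defines "absence": a peak below this fraction of the base
    peak does not count as a match.
    """

    tolerance: float = 0.01
    min_relative_intensity: float = 0.005
    series: Tuple[str, ...] = ("c", "z")
    max_charge: int = 2

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 <= self.min_relative_intensity < 1:
            raise ValueError("min_relative_intensity must be in [0, 1)")


def enumerate_hypotheses(
    peptide: LabeledPeptide,
    glycan: GlycanComposition,
    candidate_sites: Iterable[int],
) -> List[SiteHypothesis]:
    """One hypothesis per candidate Ser/Thr site (zero-based indices)."""
    sites = sorted(set(int(i) for i in candidate_sites))
    if not sites:
        raise ValueError("at least one candidate site is required")
    for i in sites:
        if not 0 <= i < len(peptide.sequence):
            raise ValueError(f"candidate site {i} outside peptide")
        if peptide.sequence[i] not in "ST":
            raise ValueError(
                f"candidate site {i} is {peptide.sequence[i]!r}; O-glycosites must be Ser/Thr"
            )
    base = peptide.deglycosylated()
    return [SiteHypothesis(base, glycan, i) for i in sites]


def discriminating_ions(
    hypotheses: Sequence[SiteHypothesis],
    params: LocalizationParams = LocalizationParams(),
) -> List[DiscriminatingIon]:
    """Fragments whose theoretical m/z distinguishes the hypotheses.

    For each (series, ordinal, charge), the hypotheses' predicted m/z
    values are clustered with the match tolerance; when more than one
    cluster remains the fragment is discriminating and one record per
    cluster is returned, annotated with the site indices it supports.
    Ions spanning all candidate sites or none predict identical m/z under
    every hypothesis and are never discriminating.
    """
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses to discriminate")
    tables = []
    for h in hypotheses:
        frags = backbone_fragments(h.glycopeptide, params.series, params.max_charge)
        tables.append({(f.series, f.ordinal, f.charge): f.mz for f in frags})
    keys = tables[0].keys()
    out: List[DiscriminatingIon] = []
    for key in keys:
        mzs = [t[key] for t in tables]
        if max(mzs) - min(mzs) <= params.tolerance:
            continue
        # greedy clustering on sorted m/z
        order = sorted(range(len(mzs)), key=lambda i: mzs[i])
        clusters: List[List[int]] = [[order[0]]]
        for i in order[1:]:
            if mzs[i] - mzs[clusters[-1][-1]] <= params.tolerance:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        if len(clusters) < 2:
            continue
        series, ordinal, charge = key
        for members in clusters:
            out.append(
                DiscriminatingIon(
                    series=series,
                    ordinal=ordinal,
                    charge=charge,
                    mz=float(np.mean([mzs[i] for i in members])),
                    supports=tuple(hypotheses[i].site for i in members),
                )
            )
    out.sort(key=lambda d: (d.series, d.ordinal, d.charge, d.mz))
    return out


def _match_peak(
    spectrum: Spectrum, mz: float, tolerance: float, intensity_floor: float
) -> Tuple[bool, Optional[float], Optional[float]]:
    lo, hi = spectrum.peaks_between(mz - tolerance, mz + tolerance)
    if lo.size == 0:
        return False, None, None
    idx = int(np.argmax(hi))
    if hi[idx] < intensity_floor:
        return False, None, None
    return True, float(lo[idx]), float(hi[idx])


def score_site_evidence(
    spectrum: Spectrum,
    hypotheses: Sequence[SiteHypothesis],
    params: LocalizationParams = LocalizationParams(),
) -> Tuple[List[SiteEvidence], Optional[int]]:
    """Match discriminating ions and call the glycosite.

    A hypothesis is *supported* when at least one of its discriminating
    ions is matched and no matched discriminating ion supports only rival
    hypotheses; it is *excluded* when rivals have matched evidence and it
    has none; otherwise *indeterminate*. The overall call is the site of
    the unique supported hypothesis, or None when no unique support exists.
    """
    ions = discriminating_ions(hypotheses, params)
    floor = params.min_relative_intensity * spectrum.base_peak_intensity
    observations: List[IonObservation] = []
    for ion in ions:
        matched, obs_mz, inten = _match_peak(spectrum, ion.mz, params.tolerance, floor)
        observations.append(IonObservation(ion, matched, obs_mz, inten))

    evidence: List[SiteEvidence] = []
    supported_sites: List[int] = []
    for h in hypotheses:
        supporting = [o for o in observations if h.site in o.ion.supports]
        contradicting = [o for o in observations if h.site not in o.ion.supports]
        n_sup = sum(o.matched for o in supporting)
        n_con = sum(o.matched for o in contradicting)
        if n_sup >= 1 and n_con == 0:
            verdict = "supported"
            supported_sites.append(h.site)
        elif n_con >= 1 and n_sup == 0:
            verdict = "excluded"
        else:
            verdict = "indeterminate"
        evidence.append(SiteEvidence(h, supporting, contradicting, verdict))

    call = supported_sites[0] if len(supported_sites) == 1 else None
    return evidence, call


def annotate_y_ladder(
    spectrum: Spectrum,
    peptide: LabeledPeptide,
    charges: Iterable[int] = (1, 2, 3, 4),
    tolerance: float = 0.01,
    min_relative_intensity: float = 0.0,
) -> pd.DataFrame:
    """Match the topology-free glycan Y ladder against a spectrum.

    Returns one row per matched ``peptide + glycan-subset`` ion with the
    theoretical and observed m/z, intensity and ppm error (observed MS3
    masses routinely deviate slightly from theory, so errors are reported
    rather than asserted), sorted by retained-glycan size (largest first).
    """
    ladder = glycan_y_ladder(peptide, charges)
    floor = min_relative_intensity * spectrum.base_peak_intensity
    rows = []
    for frag in ladder:
        matched, obs_mz, inten = _match_peak(spectrum, frag.mz, tolerance, floor)
        if not matched:
            continue
        rows.append(
            {
                "retained_glycan": frag.ordinal,
                "glycan_residues": frag.glycan.total_residues,
                "charge": frag.charge,
                "theoretical_mz": frag.mz,
                "observed_mz": obs_mz,
                "intensity": inten,
                "ppm_error": (obs_mz - frag.mz) / frag.mz * 1e6,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "retained_glycan",
            "glycan_residues",
            "charge",
            "theoretical_mz",
            "observed_mz",
            "intensity",
            "ppm_error",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["glycan_residues", "theoretical_mz"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
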