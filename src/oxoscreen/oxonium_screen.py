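"""Selection of HexNAc glycopeptide spectra and per-spectrum registration
of diagnostic oxonium-ion and TMT reporter intensities.

The screen mirrors the oxonium-ion filter used on Orbitrap TMT runs: a
spectrum is selected when it contains the [HexNAc]+ gate ion at m/z
204.087, and the six diagnostic oxonium ions are registered with a narrow
m/z tolerance (default 0.001), a minimum intensity (default 1000 counts)
and a maximum peak rank (default: within the 100 most intense peaks). The
144.066/138.055 intensity ratio — the O-GlcNAc vs O-GalNAc discriminator —
is defined only when both ions are registered.

TMT reporter intensities are extracted with their own (wider) tolerance
and their exact reporter masses; note that the oxonium ion at m/z 126.055
is ~0.07 Th below the TMT 126 reporter at 126.1277 and must never be
confused with it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .masscalc import oxonium_reference_table
from .spectra_io import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "OxoniumRecord",
    "ReporterConfig",
    "TMT10_REPORTER_MZ",
    "TMT10_SAMPLE_GROUPS",
    "select_hexnac_spectra",
    "register_oxonium_ions",
    "ratio_144_138",
    "extract_tmt_reporters",
    "screen_spectra",
]

# nominal-label -> theoretical m/z registration centers for the six ions
_REFERENCE_IONS: Dict[str, float] = {
    f"{ion.nominal_mz:.3f}": ion.mz for ion in oxonium_reference_table()
}
GATE_ION_MZ = _REFERENCE_IONS["204.087"]
RATIO_NUMERATOR = "144.066"
RATIO_DENOMINATOR = "138.055"

#: Monoisotopic m/z of the TMT10 reporter ions.
TMT10_REPORTER_MZ: Dict[str, float] = {
    "126": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.137790,
    "130N": 130.134825,
    "130C": 130.141145,
    "131": 131.138180,
}

#: Example 9-plex channel-to-cell-line layout for a triplicate CRC design.
TMT10_SAMPLE_GROUPS: Dict[str, Tuple[str, ...]] = {
    "HT29": ("126", "127N", "127C"),
    "HCT116": ("128N", "128C", "129N"),
    "LS174T": ("129C", "130N", "130C"),
}


@dataclass(frozen=True)
class ScreenParams:
    """Registration parameters for the oxonium screen.

    ``tolerance`` is the half-window in m/z units around each diagnostic
    ion; ``min_intensity`` and ``max_rank`` gate which peaks may register
    (rank 1 = most intense peak of the spectrum). ``gate_quality_filters``
    applies the intensity/rank rules to the 204.087 selection gate as well.
    """

    tolerance: float = 0.001
    min_intensity: float = 1000.0
    max_rank: int = 100
    gate_mz: float = GATE_ION_MZ
    gate_quality_filters: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")


@dataclass(frozen=True)
class ReporterConfig:
    """TMT reporter channel layout and extraction tolerance."""

    channels: Mapping[str, float] = field(
        default_factory=lambda: dict(TMT10_REPORTER_MZ)
    )
    tolerance: float = 0.003

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("reporter tolerance must be positive")


@dataclass
class OxoniumRecord:
    """Registered diagnostic-ion intensities for one spectrum.

    ``intensities`` maps the nominal ion label (e.g. ``"138.055"``) to the
    registered intensity, or ``None`` when no peak qualified. The
    144.066/138.055 ratio is defined iff both ions are registered.
    """

    spectrum_id: str
    intensities: Dict[str, Optional[float]]
    selected: bool

    @property
    def ratio_144_138(self) -> Optional[float]:
        return ratio_144_138(self)

    def as_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {"spectrum_id": self.spectrum_id, "selected": self.selected}
        for label in _REFERENCE_IONS:
            v = self.intensities.get(label)
            row[f"ox_{label}"] = math.nan if v is None else v
        r = self.ratio_144_138
        row["ratio_144_138"] = math.nan if r is None else r
        return row

    @classmethod
    def from_row(cls, row: Mapping[str, object]) -> "OxoniumRecord":
        intensities: Dict[str, Optional[float]] = {}
        for label in _REFERENCE_IONS:
            v = row.get(f"ox_{label}")
            v = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
            intensities[label] = v
        return cls(
            spectrum_id=str(row["spectrum_id"]),
            intensities=intensities,
            selected=bool(row.get("selected", True)),
        )


def _peak_ranks(spectrum: Spectrum) -> np.ndarray:
    """1-based intensity ranks; ties broken by ascending m/z."""
    order = np.lexsort((spectrum.mz, -spectrum.intensity))
    ranks = np.empty(spectrum.n_peaks, dtype=int)
    ranks[order] = np.arange(1, spectrum.n_peaks + 1)
    return ranks


def _best_peak(spectrum: Spectrum, center: float, tol: float) -> Optional[int]:
    """Index of the most intense peak within ±tol of center (ties: lowest m/z)."""
    i = np.searchsorted(spectrum.mz, center - tol, side="left")
    j = np.searchsorted(spectrum.mz, center + tol, side="right")
    if i == j:
        return None
    window = spectrum.intensity[i:j]
    return i + int(np.argmax(window))


def register_oxonium_ions(spectrum: Spectrum, params: ScreenParams = ScreenParams()) -> OxoniumRecord:
    """Register the six diagnostic oxonium ions in one spectrum.

    For each ion, the most intense peak within ±tolerance of the
    theoretical m/z is registered iff its intensity is at least
    ``min_intensity`` and its intensity rank is at most ``max_rank``;
    otherwise the ion is marked absent.
    """
    ranks = _peak_ranks(spectrum)
    intensities: Dict[str, Optional[float]] = {}
    for label, center in _REFERENCE_IONS.items():
        idx = _best_peak(spectrum, center, params.tolerance)
        if idx is None:
            intensities[label] = None
            continue
        inten = float(spectrum.intensity[idx])
        if inten >= params.min_intensity and ranks[idx] <= params.max_rank:
            intensities[label] = inten
        else:
            intensities[label] = None
    return OxoniumRecord(
        spectrum_id=spectrum.spectrum_id,
        intensities=intensities,
        selected=passes_gate(spectrum, params, ranks=ranks),
    )


def passes_gate(
    spectrum: Spectrum, params: ScreenParams = ScreenParams(), ranks: Optional[np.ndarray] = None
) -> bool:
    """True iff the spectrum contains a qualifying [HexNAc]+ gate peak."""
    idx = _best_peak(spectrum, params.gate_mz, params.tolerance)
    if idx is None:
        return False
    if not params.gate_quality_filters:
        return True
    if ranks is None:
        ranks = _peak_ranks(spectrum)
    return (
        float(spectrum.intensity[idx]) >= params.min_intensity
        and ranks[idx] <= params.max_rank
    )


def select_hexnac_spectra(
    spectra: Iterable[Spectrum], params: ScreenParams = ScreenParams()
) -> Tuple[List[Spectrum], Dict[str, int]]:
    """Select spectra containing the HexNAc oxonium gate ion at m/z 204.087.

    Returns the selected spectra and a log dict with counts in/out.
    """
    selected: List[Spectrum] = []
    n_in = 0
    for s in spectra:
        n_in += 1
        if passes_gate(s, params):
            selected.append(s)
    log = {"n_input": n_in, "n_selected": len(selected), "n_rejected": n_in - len(selected)}
    logger.info(
        "HexNAc gate: %d of %d spectra selected", log["n_selected"], log["n_input"]
    )
    return selected, log


def ratio_144_138(record: OxoniumRecord) -> Optional[float]:
    """Intensity ratio I(144.066)/I(138.055); None unless both registered."""
    num = record.intensities.get(RATIO_NUMERATOR)
    den = record.intensities.get(RATIO_DENOMINATOR)
    if num is None or den is None:
        return None
    return num / den


def extract_tmt_reporters(
    spectrum: Spectrum, config: ReporterConfig = ReporterConfig()
) -> Dict[str, float]:
    """Per-channel reporter intensity: most intense peak within the
    reporter tolerance of each channel m/z, 0.0 when none is present."""
    out: Dict[str, float] = {}
    for label, center in config.channels.items():
        idx = _best_peak(spectrum, center, config.tolerance)
        out[label] = float(spectrum.intensity[idx]) if idx is not None else 0.0
    return out


def screen_spectra(
    spectra: Iterable[Spectrum],
    params: ScreenParams = ScreenParams(),
    reporters: Optional[ReporterConfig] = ReporterConfig(),
    selected_only: bool = False,
) -> Tuple[pd.DataFrame, List[Spectrum]]:
    """Run the full per-spectrum screen.

    Returns a table with one row per spectrum (or per selected spectrum
    when ``selected_only``) holding the six registered intensities, the
    144/138 ratio and reporter channel intensities, plus the list of
    selected spectra for optional MGF export.
    """
    rows: List[Dict[str, object]] = []
    selected: List[Spectrum] = []
    for s in spectra:
        record = register_oxonium_ions(s, params)
        if record.selected:
            selected.append(s)
        if selected_only and not record.selected:
            continue
        row = record.as_row()
        if reporters is not None:
            for label, inten in extract_tmt_reporters(s, reporters).items():
                row[f"tmt_{label}"] = inten
        rows.append(row)
    columns = None
    if rows:
        columns = list(rows[0].keys())
    table = pd.DataFrame(rows, columns=columns)
    return table, selected
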