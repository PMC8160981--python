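"""Glycopeptide PSM table ingestion, filtering, and the spectrum-ID merge.

PSM tables are delimited text exported from a glycopeptide search engine
(Byonic-style): one row per peptide-spectrum match with a spectrum
identifier, peptide, glycan composition, score and protein fields. After
the oxonium screen, PSMs and per-spectrum oxonium/reporter records are
linked by (normalized) spectrum ID and merged into one table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .masscalc import GlycanComposition, GlycanParseError, parse_glycan_composition
from .oxonium_screen import OxoniumRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GlycoPSM",
    "MergeResult",
    "DEFAULT_COLUMN_MAP",
    "read_psm_table",
    "filter_psms",
    "single_hexnac",
    "normalize_spectrum_id",
    "merge_by_spectrum_id",
]


@dataclass(frozen=True)
class GlycoPSM:
    """One glycopeptide assignment from a search engine."""

    spectrum_id: str
    peptide: str
    glycan: GlycanComposition
    score: float
    protein_accession: str = ""
    protein_name: str = ""
    modifications: str = ""
    glyco_type: str = "O-linked"

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("PSM score must be >= 0")


#: Logical field -> expected column header. Override entries to match a
#: particular search-engine export.
DEFAULT_COLUMN_MAP: Dict[str, str] = {
    "spectrum_id": "spectrum_id",
    "peptide": "peptide",
    "glycan": "glycan",
    "score": "score",
    "protein_accession": "accession",
    "protein_name": "protein_name",
}

_REQUIRED_FIELDS = ("spectrum_id", "peptide", "glycan", "score")


def _read_delimited(path: str, sep: Optional[str]) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_psm_table(
    path: str,
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> List[GlycoPSM]:
    """Read a delimited PSM table into :class:`GlycoPSM` records.

    Rows whose glycan composition or score cannot be parsed are dropped
    with a logged count. A missing required column raises ``KeyError``.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    df = _read_delimited(path, sep)
    for fieldname in _REQUIRED_FIELDS:
        col = colmap[fieldname]
        if col not in df.columns:
            raise KeyError(f"required column {col!r} (field {fieldname!r}) missing from {path}")

    psms: List[GlycoPSM] = []
    dropped = 0
    for _, row in df.iterrows():
        try:
            glycan = parse_glycan_composition(str(row[colmap["glycan"]]))
            score = float(row[colmap["score"]])
            if score < 0:
                raise ValueError("negative score")
        except (GlycanParseError, ValueError):
            dropped += 1
            continue
        psms.append(
            GlycoPSM(
                spectrum_id=str(row[colmap["spectrum_id"]]),
                peptide=str(row[colmap["peptide"]]),
                glycan=glycan,
                score=score,
                protein_accession=str(row.get(colmap.get("protein_accession", ""), "")),
                protein_name=str(row.get(colmap.get("protein_name", ""), "")),
            )
        )
    if dropped:
        logger.warning("dropped %d unparseable PSM rows from %s", dropped, path)
    return psms


def single_hexnac(glycan: GlycanComposition) -> bool:
    """The 'single HexNAc' glycan filter: exactly one HexNAc residue,
    regardless of other monosaccharides (so N1 and H1N1S2 both pass)."""
    return glycan.hexnac == 1


def filter_psms(
    psms: Iterable[GlycoPSM],
    min_score: float = 250.0,
    glycan_predicate: Optional[Callable[[GlycanComposition], bool]] = None,
) -> List[GlycoPSM]:
    """Retain PSMs with ``score >= min_score`` and a passing glycan.

    Raising ``min_score`` is monotone: it can only remove rows.
    """
    out = []
    for p in psms:
        if p.score < min_score:
            continue
        if glycan_predicate is not None and not glycan_predicate(p.glycan):
            continue
        out.append(p)
    return out


_DEFAULT_ID_RE = re.compile(r"scan=(\d+)")


def normalize_spectrum_id(spectrum_id: str, pattern: re.Pattern = _DEFAULT_ID_RE) -> str:
    """Normalize a spectrum identifier for joining.

    Search engines rewrite spectrum titles, so by default the digits
    following ``scan=`` are extracted when present; otherwise the full ID
    is used unchanged.
    """
    m = pattern.search(spectrum_id)
    return m.group(1) if m else spectrum_id


@dataclass
class MergeResult:
    """Outcome of the spectrum-ID merge."""

    table: pd.DataFrame
    unmatched_psms: List[GlycoPSM]
    unmatched_record_ids: List[str]


def merge_by_spectrum_id(
    psms: Sequence[GlycoPSM],
    records: Sequence[OxoniumRecord],
    reporters: Optional[Mapping[str, Mapping[str, float]]] = None,
    normalizer: Callable[[str], str] = normalize_spectrum_id,
) -> MergeResult:
    """Inner-join PSMs with oxonium records on normalized spectrum ID.

    One output row per PSM: a spectrum with multiple PSMs yields multiple
    rows sharing its oxonium (and reporter) data. Unmatched PSMs and
    unmatched record IDs are reported separately. The merge is
    deterministic and independent of input order (records are keyed by
    normalized ID; PSM rows keep the PSM table order).
    """
    record_map: Dict[str, OxoniumRecord] = {}
    for r in records:
        key = normalizer(r.spectrum_id)
        if key in record_map:
            logger.warning("duplicate oxonium record for normalized ID %r", key)
        record_map[key] = r
    reporter_map: Dict[str, Mapping[str, float]] = {}
    if reporters:
        reporter_map = {normalizer(sid): vec for sid, vec in reporters.items()}

    rows: List[Dict[str, object]] = []
    unmatched: List[GlycoPSM] = []
    matched_keys = set()
    for p in psms:
        key = normalizer(p.spectrum_id)
        rec = record_map.get(key)
        if rec is None:
            unmatched.append(p)
            continue
        matched_keys.add(key)
        row: Dict[str, object] = {
            "spectrum_id": p.spectrum_id,
            "accession": p.protein_accession,
            "protein_name": p.protein_name,
            "peptide": p.peptide,
            "glycan": p.glycan.to_string(),
            "score": p.score,
        }
        rec_row = rec.as_row()
        rec_row.pop("spectrum_id")
        row.update(rec_row)
        if key in reporter_map:
            for label, inten in reporter_map[key].items():
                row[f"tmt_{label}"] = inten
        rows.append(row)

    unmatched_record_ids = sorted(
        r.spectrum_id for r in records if normalizer(r.spectrum_id) not in matched_keys
    )
    columns = list(rows[0].keys()) if rows else None
    return MergeResult(
        table=pd.DataFrame(rows, columns=columns),
        unmatched_psms=unmatched,
        unmatched_record_ids=unmatched_record_ids,
    )
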