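"""O-GlcNAc vs O-GalNAc classification from the 144.066/138.055 oxonium
ratio, concordance with localization-based predictions, and the Wilcoxon
rank-sum comparison of predicted groups.

The 144/138 ratio behaves as a step discriminator for peptides carrying a
single HexNAc: O-GlcNAc peptides sit at low ratios (known O-GlcNAc sites
fall below ~0.3) while mucin-type O-GalNAc peptides sit high. There is no
published numeric decision boundary, so the classifier uses a configurable
two-threshold rule (defaults 0.3 / 0.6) with an explicit ambiguous band in
between; glycans with more than one HexNAc mix both residue types and are
marked not classifiable rather than forced into either class.

The localization-based prediction is the secretory-pathway heuristic: a
protein with a signal peptide and/or a transmembrane domain is predicted
to carry GalNAc, otherwise GlcNAc.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .masscalc import GlycanParseError, parse_glycan_composition

logger = logging.getLogger(__name__)

__all__ = [
    "CALL_GLCNAC",
    "CALL_GALNAC",
    "CALL_AMBIGUOUS",
    "CALL_UNDEFINED",
    "CALL_NOT_CLASSIFIABLE",
    "HexNAcCall",
    "LocalizationAnnotation",
    "classify_hexnac",
    "predict_hexnac_from_annotation",
    "concordance_report",
    "RankSumResult",
    "rank_sum_test",
]

CALL_GLCNAC = "GlcNAc"
CALL_GALNAC = "GalNAc"
CALL_AMBIGUOUS = "ambiguous"
CALL_UNDEFINED = "undefined"
CALL_NOT_CLASSIFIABLE = "not_classifiable"

DEFAULT_LOW = 0.3
DEFAULT_HIGH = 0.6


@dataclass(frozen=True)
class HexNAcCall:
    """Classifier output for one ratio value."""

    ratio: Optional[float]
    call: str
    low: float
    high: float


@dataclass(frozen=True)
class LocalizationAnnotation:
    """Protein-level secretory-pathway features used for prediction."""

    accession: str
    signal_peptide: bool
    tm_domain: bool


def classify_hexnac(
    ratio: Optional[float], low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> HexNAcCall:
    """Two-threshold step classifier on the 144/138 ratio.

    GlcNAc iff ``ratio <= low``; GalNAc iff ``ratio >= high``; ambiguous in
    between; undefined when the ratio itself is undefined (one of the two
    ions was not registered).
    """
    if not (0 <= low < high):
        raise ValueError(f"thresholds must satisfy 0 <= low < high, got {low}, {high}")
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return HexNAcCall(None, CALL_UNDEFINED, low, high)
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio <= low:
        call = CALL_GLCNAC
    elif ratio >= high:
        call = CALL_GALNAC
    else:
        call = CALL_AMBIGUOUS
    return HexNAcCall(float(ratio), call, low, high)


def predict_hexnac_from_annotation(annotation: LocalizationAnnotation) -> str:
    """GalNAc iff a signal peptide or a transmembrane domain is present
    (secretory pathway); GlcNAc otherwise (nucleocytoplasmic)."""
    return CALL_GALNAC if (annotation.signal_peptide or annotation.tm_domain) else CALL_GLCNAC


def concordance_report(
    rows: pd.DataFrame,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    ratio_column: str = "ratio_144_138",
    restrict_single_hexnac: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Classify each row and compare against the localization prediction.

    ``rows`` needs a ratio column plus either a ``predicted_hexnac`` column
    or boolean/0-1 ``signal_peptide`` and ``tm_domain`` columns. When a
    ``glycan`` column is present and ``restrict_single_hexnac`` is set,
    rows whose glycan carries more than one HexNAc are marked
    ``not_classifiable`` (the ratio is not interpretable for mixed
    HexNAc content).

    Returns the annotated table (added columns ``call``, ``predicted``,
    ``concordant``) and a summary dict with counts, the discordant protein
    list, and the rank-sum p-value comparing ratios of the two predicted
    groups (when both are non-empty).
    """
    table = rows.copy()
    if "predicted_hexnac" in table.columns:
        predicted = table["predicted_hexnac"].astype(str)
    elif {"signal_peptide", "tm_domain"} <= set(table.columns):
        predicted = [
            predict_hexnac_from_annotation(
                LocalizationAnnotation("", bool(int(s)), bool(int(t)))
            )
            for s, t in zip(table["signal_peptide"], table["tm_domain"])
        ]
    else:
        raise KeyError(
            "need a 'predicted_hexnac' column or 'signal_peptide'/'tm_domain' columns"
        )
    table["predicted"] = list(predicted)

    calls: List[str] = []
    for _, row in table.iterrows():
        if restrict_single_hexnac and "glycan" in table.columns:
            try:
                g = parse_glycan_composition(str(row["glycan"]))
            except GlycanParseError:
                g = None
            if g is not None and g.hexnac != 1:
                calls.append(CALL_NOT_CLASSIFIABLE)
                continue
        ratio = row[ratio_column]
        ratio = None if pd.isna(ratio) else float(ratio)
        calls.append(classify_hexnac(ratio, low, high).call)
    table["call"] = calls
    table["concordant"] = [
        (c == p) if c in (CALL_GLCNAC, CALL_GALNAC) else None
        for c, p in zip(table["call"], table["predicted"])
    ]

    name_col = "protein_name" if "protein_name" in table.columns else None
    discordant = table[table["concordant"] == False]  # noqa: E712 (None-aware)
    ambiguous = table[table["call"] == CALL_AMBIGUOUS]
    summary: Dict[str, object] = {
        "n_rows": int(len(table)),
        "call_counts": table["call"].value_counts().to_dict(),
        "n_concordant": int((table["concordant"] == True).sum()),  # noqa: E712
        "n_discordant": int(len(discordant)),
        "discordant_proteins": sorted(
            set(discordant[name_col]) if name_col else set(discordant.index.astype(str))
        ),
        "ambiguous_proteins": sorted(
            set(ambiguous[name_col]) if name_col else set(ambiguous.index.astype(str))
        ),
        "thresholds": {"low": low, "high": high},
    }

    galnac = table.loc[table["predicted"] == CALL_GALNAC, ratio_column].dropna()
    glcnac = table.loc[table["predicted"] == CALL_GLCNAC, ratio_column].dropna()
    if len(galnac) and len(glcnac):
        result = rank_sum_test(galnac.to_numpy(float), glcnac.to_numpy(float))
        summary["rank_sum"] = {
            "statistic": result.statistic,
            "p_value": result.p_value,
            "method": result.method,
        }
    return table, summary


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum outcome: W is the rank sum of the first group."""

    statistic: float
    p_value: float
    method: str  # "exact" | "normal"


def _midranks(values: np.ndarray) -> np.ndarray:
    return _stats.rankdata(values, method="average")


def _exact_distribution(doubled_ranks: Sequence[int], n: int) -> Dict[int, int]:
    """Counts of doubled rank sums over all size-n subsets (DP subset-sum)."""
    total = sum(doubled_ranks)
    # ways[k] maps doubled-sum -> count for subsets of size k
    ways: List[Dict[int, int]] = [dict() for _ in range(n + 1)]
    ways[0][0] = 1
    for r in doubled_ranks:
        for k in range(min(n, len(doubled_ranks)) - 1, -1, -1):
            if not ways[k]:
                continue
            target = ways[k + 1]
            for s, c in ways[k].items():
                target[s + r] = target.get(s + r, 0) + c
    assert sum(ways[n].values()) == math.comb(len(doubled_ranks), n)
    return ways[n]


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> RankSumResult:
    """Wilcoxon rank-sum test with midranks for ties.

    Uses the exact null distribution (full enumeration of group
    assignments via dynamic programming) when both groups have at most 12
    observations, and the normal approximation with tie correction and
    continuity correction otherwise. ``alternative`` refers to group A:
    ``"greater"`` tests whether A tends to larger values.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one value")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())

    if n <= 12 and m <= 12:
        doubled = [int(round(2 * r)) for r in ranks]
        dist = _exact_distribution(doubled, n)
        total = sum(dist.values())
        w2 = int(round(2 * w))
        p_le = sum(c for s, c in dist.items() if s <= w2) / total
        p_ge = sum(c for s, c in dist.items() if s >= w2) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_le, p_ge))
        return RankSumResult(statistic=w, p_value=p, method="exact")

    N = n + m
    mean = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * m * (N + 1) / 12.0 - n * m * tie_term / (12.0 * N * (N - 1))
    if var <= 0:
        # all pooled values identical: no evidence either way
        return RankSumResult(statistic=w, p_value=1.0, method="normal")
    sd = math.sqrt(var)

    def _sf(z: float) -> float:
        return float(_stats.norm.sf(z))

    if alternative == "greater":
        p = _sf((w - mean - 0.5) / sd)
    elif alternative == "less":
        p = _sf((mean - w - 0.5) / sd)
    else:
        z = (abs(w - mean) - 0.5) / sd
        p = min(1.0, 2 * _sf(z))
    return RankSumResult(statistic=w, p_value=p, method="normal")
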