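"""Compositional transforms and similarity statistics for grouped
abundance tables: fourth-root transform, Bray-Curtis dissimilarity,
SIMPER decomposition, and the mean-abundance class filter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mucodyn.network_inference import AbundanceTable

__all__ = [
    "GroupedTable",
    "fourth_root",
    "bray_curtis",
    "simper",
    "SimperResult",
    "filter_classes",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupedTable:
    """Abundance table with one group label per sample (e.g. reef zone)."""

    table: AbundanceTable
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.groups) != self.table.n_samples:
            raise ValueError(
                f"{len(self.groups)} group labels for {self.table.n_samples} samples"
            )

    def group_values(self, group: str) -> np.ndarray:
        mask = np.array([g == group for g in self.groups])
        if not mask.any():
            raise KeyError(f"no samples in group {group!r}")
        return self.table.values[mask]

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen


def fourth_root(values: np.ndarray | float) -> np.ndarray | float:
    """Elementwise x**(1/4) variance-stabilizing transform (x >= 0)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("fourth_root requires non-negative values")
    out = np.power(arr, 0.25)
    return out if out.ndim else float(out)


def bray_curtis(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity ``sum|a-b| / sum(a+b)`` in [0, 1]."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("bray_curtis requires non-negative vectors")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both vectors all-zero; dissimilarity undefined")
    return float(np.abs(a - b).sum() / denom)


@dataclass
class SimperResult:
    """SIMPER output for a two-group comparison.

    ``within_similarity`` maps group -> average pairwise percent
    similarity; ``between_dissimilarity`` is the average cross-group
    percent dissimilarity; ``contributions`` lists per-taxon mean (and
    cumulative) percent contributions to the between-group
    dissimilarity, sorted descending, with the standard 90% cumulative
    cutoff flag.
    """

    within_similarity: dict[str, float]
    between_dissimilarity: float
    contributions: pd.DataFrame
    within_contributions: dict[str, pd.DataFrame]


def _pairwise_contrib_dissim(x: np.ndarray, pairs) -> np.ndarray:
    """Per-taxon percent dissimilarity contributions averaged over pairs."""
    contribs = []
    for i, j in pairs:
        denom = (x[i] + x[j]).sum()
        contribs.append(100.0 * np.abs(x[i] - x[j]) / denom)
    return np.mean(contribs, axis=0)


def _pairwise_contrib_sim(x: np.ndarray, pairs) -> np.ndarray:
    """Per-taxon percent similarity contributions (2*min / total)."""
    contribs = []
    for i, j in pairs:
        denom = (x[i] + x[j]).sum()
        contribs.append(100.0 * 2.0 * np.minimum(x[i], x[j]) / denom)
    return np.mean(contribs, axis=0)


def simper(grouped: GroupedTable, cutoff_pct: float = 90.0) -> SimperResult:
    """SIMPER decomposition of average Bray-Curtis (dis)similarity.

    The caller applies any transform (e.g. :func:`fourth_root`) first.
    Within-group similarity is ``100 * (1 - mean pairwise BC)`` over all
    sample pairs in a group; between-group dissimilarity is ``100 * mean
    BC`` over all cross-group pairs; both are decomposed exactly into
    per-taxon contributions.
    """
    names = grouped.group_names
    if len(names) != 2:
        raise ValueError(f"simper requires exactly two groups, got {names}")
    taxa = grouped.table.taxon_ids

    within_sim: dict[str, float] = {}
    within_contrib: dict[str, pd.DataFrame] = {}
    for g in names:
        vals = grouped.group_values(g)
        if vals.shape[0] < 2:
            raise ValueError(f"group {g!r} has <2 samples; within-group similarity undefined")
        pairs = list(itertools.combinations(range(vals.shape[0]), 2))
        per_taxon = _pairwise_contrib_sim(vals, pairs)
        within_sim[g] = float(per_taxon.sum())
        df = _contribution_frame(taxa, per_taxon, cutoff_pct, context=f"within:{g}")
        within_contrib[g] = df

    a = grouped.group_values(names[0])
    b = grouped.group_values(names[1])
    cross = list(itertools.product(range(a.shape[0]), range(b.shape[0])))
    stacked = np.vstack([a, b])
    cross_idx = [(i, a.shape[0] + j) for i, j in cross]
    per_taxon = _pairwise_contrib_dissim(stacked, cross_idx)
    between = float(per_taxon.sum())
    contrib = _contribution_frame(
        taxa, per_taxon, cutoff_pct, context=f"between:{names[0]}|{names[1]}"
    )
    return SimperResult(
        within_similarity=within_sim,
        between_dissimilarity=between,
        contributions=contrib,
        within_contributions=within_contrib,
    )


def _contribution_frame(
    taxa: list[str], per_taxon: np.ndarray, cutoff_pct: float, context: str
) -> pd.DataFrame:
    total = per_taxon.sum()
    order = np.argsort(-per_taxon, kind="stable")
    pct_of_total = 100.0 * per_taxon[order] / total if total > 0 else np.zeros(len(taxa))
    cum = np.cumsum(pct_of_total)
    df = pd.DataFrame(
        {
            "taxon": [taxa[i] for i in order],
            "mean_contrib_pct": per_taxon[order],
            "contrib_share_pct": pct_of_total,
            "cum_contrib_pct": cum,
            "group_context": context,
        }
    )
    # flag the taxa reported under the conventional cumulative cutoff
    df["above_cutoff"] = df["cum_contrib_pct"] <= cutoff_pct + 1e-12
    if df["above_cutoff"].any():
        first_over = int(df["above_cutoff"].sum())
        if first_over < len(df):
            df.loc[df.index[first_over], "above_cutoff"] = True  # include boundary taxon
    return df


def filter_classes(
    zone_tables: dict[str, AbundanceTable], cutoff: float = 1.0
) -> list[str]:
    """Taxa whose mean relative abundance reaches ``cutoff`` percent in at
    least one zone.

    Comparison is >= so a mean landing exactly on the cutoff is retained
    (boundary ties are logged). Input order of the first table is
    preserved.
    """
    if not zone_tables:
        raise ValueError("no zone tables supplied")
    tables = list(zone_tables.values())
    taxa = tables[0].taxon_ids
    for t in tables[1:]:
        if t.taxon_ids != taxa:
            raise ValueError("zone tables must share the same taxon namespace/order")
    retained = []
    for idx, taxon in enumerate(taxa):
        means = [t.values[:, idx].mean() for t in tables]
        if any(m >= cutoff for m in means):
            if any(abs(m - cutoff) < 1e-12 for m in means):
                logger.info("taxon %r retained at exactly the %g%% cutoff", taxon, cutoff)
            retained.append(taxon)
    return retained
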