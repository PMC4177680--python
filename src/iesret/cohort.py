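"""Cohort analyses over per-IES retention records.

Downstream, genome-wide summaries of retention-score tables: the size-group
retention bias (IES lengths follow a periodic distribution with peaks every
~10 bp starting at 26 bp, and sensitivity to silencing rises with length),
cross-sample overlaps of significantly retained sets, sequence-feature
association tests, and replicate concordance.
"""

from __future__ import annotations

import bisect
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SizeBinning",
    "DEFAULT_SIZE_BINS",
    "DEFAULT_SIZE_BIN_COUNTS",
    "GroupSummary",
    "assign_size_group",
    "group_summaries",
    "proportion_significant_by_group",
    "overlap_sets",
    "rank_correlation",
    "compare_feature",
]

# Reconstruction of the 23 genome-wide size groups: the first five bins cover
# 26-72 bp (first peak 26-32), width-10 bins continue to 212 bp, and four
# coarse bins reach past 1 kb.  Exact published edges are not recoverable, so
# these defaults are explicit and configurable.
def _default_edges() -> list[tuple[int, int | None]]:
    bins: list[tuple[int, int | None]] = [(26, 32), (33, 42), (43, 52), (53, 62), (63, 72)]
    lo = 73
    while lo <= 203:
        bins.append((lo, lo + 9))
        lo += 10
    bins.extend([(213, 332), (333, 532), (533, 1032), (1033, None)])
    return bins


# Published per-group IES tallies for the 23 size groups (genome-wide set of
# ~45,000 elements); used by the synthetic generator as default mixture
# weights over the bins above.
DEFAULT_SIZE_BIN_COUNTS: tuple[int, ...] = (
    15857, 485, 6354, 3514, 3108, 3642, 2459, 1934, 1532, 1111, 795, 594,
    410, 1176, 780, 398, 198, 89, 64, 47, 183, 63, 135,
)

# Star thresholds for adjacent-group distribution shifts.
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (2.2e-16, "***"),
    (1e-10, "**"),
    (0.05, "*"),
)


@dataclass(frozen=True)
class SizeBinning:
    """Contiguous, non-overlapping length bins; the last may be open-ended."""

    edges: tuple[tuple[int, int | None], ...]

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("at least one size bin is required")
        for (lo, hi), (nlo, _) in zip(self.edges, self.edges[1:]):
            if hi is None or nlo != hi + 1:
                raise ValueError("size bins must be contiguous and non-overlapping")
        if self.edges[0][0] < 1:
            raise ValueError("bins must cover positive lengths only")

    @property
    def n_groups(self) -> int:
        return len(self.edges)

    def labels(self) -> list[str]:
        out = []
        for lo, hi in self.edges:
            out.append(f"{lo}-{hi}" if hi is not None else f">{lo - 1}")
        return out

    def assign(self, length: int) -> int:
        """0-based group index for a length; raises below the smallest edge."""
        lows = [lo for lo, _ in self.edges]
        if length < lows[0]:
            raise ValueError(
                f"length {length} below the smallest bin edge {lows[0]}"
            )
        i = bisect.bisect_right(lows, length) - 1
        lo, hi = self.edges[i]
        if hi is not None and length > hi:
            raise ValueError(f"length {length} beyond the last bin")
        return i


DEFAULT_SIZE_BINS = SizeBinning(edges=tuple(_default_edges()))


@dataclass(frozen=True)
class GroupSummary:
    group: int
    label: str
    n: int
    median_rs: float
    q1_rs: float
    q3_rs: float
    proportion_significant: float
    p_vs_previous: float
    stars: str


def assign_size_group(length: int, binning: SizeBinning = DEFAULT_SIZE_BINS) -> int:
    return binning.assign(length)


def _stars(p: float) -> str:
    for threshold, mark in STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


def group_summaries(
    records: pd.DataFrame,
    lengths: Mapping[str, int],
    binning: SizeBinning = DEFAULT_SIZE_BINS,
) -> list[GroupSummary]:
    """Per-size-group retention summaries with adjacent-group rank tests.

    ``records`` must carry columns ``ies_id``, ``rs`` and (optionally)
    ``significant``.  IESs with missing RS are dropped.  Each group with data
    is compared with the previous non-empty group by a two-sided
    Mann-Whitney test; stars mark p<0.05 (*), p<1e-10 (**) and
    p<2.2e-16 (***).
    """
    df = records.copy()
    df["length"] = df["ies_id"].map(lengths)
    df = df.dropna(subset=["rs", "length"])
    if "significant" not in df.columns:
        df["significant"] = False
    groups: dict[int, pd.DataFrame] = {
        g: sub for g, sub in df.groupby(df["length"].map(binning.assign))
    }

    labels = binning.labels()
    out: list[GroupSummary] = []
    prev_rs: np.ndarray | None = None
    for g in range(binning.n_groups):
        sub = groups.get(g)
        if sub is None or len(sub) == 0:
            out.append(
                GroupSummary(g, labels[g], 0, np.nan, np.nan, np.nan, np.nan, np.nan, "")
            )
            continue
        rs = sub["rs"].to_numpy(dtype=float)
        if prev_rs is not None and len(prev_rs) > 0 and len(rs) > 0:
            p = float(stats.mannwhitneyu(rs, prev_rs, alternative="two-sided").pvalue)
        else:
            p = np.nan
        out.append(
            GroupSummary(
                group=g,
                label=labels[g],
                n=int(len(rs)),
                median_rs=float(np.median(rs)),
                q1_rs=float(np.percentile(rs, 25)),
                q3_rs=float(np.percentile(rs, 75)),
                proportion_significant=float(sub["significant"].mean()),
                p_vs_previous=p,
                stars=_stars(p) if np.isfinite(p) else "",
            )
        )
        prev_rs = rs
    return out


def proportion_significant_by_group(
    records: pd.DataFrame,
    lengths: Mapping[str, int],
    binning: SizeBinning = DEFAULT_SIZE_BINS,
) -> pd.DataFrame:
    """Fraction of significantly retained IESs as a function of size group."""
    df = records.copy()
    df["length"] = df["ies_id"].map(lengths)
    df = df.dropna(subset=["length"])
    df["group"] = df["length"].map(binning.assign)
    agg = (
        df.groupby("group")["significant"]
        .agg(n="size", n_significant="sum")
        .reindex(range(binning.n_groups), fill_value=0)
        .reset_index()
    )
    agg["label"] = binning.labels()
    agg["proportion"] = np.where(
        agg["n"] > 0, agg["n_significant"] / agg["n"].replace(0, np.nan), np.nan
    )
    return agg[["group", "label", "n", "n_significant", "proportion"]]


def overlap_sets(sets_by_sample: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Venn-style partition of significantly retained IES sets.

    Returns one row per membership pattern (a cell of the partition of the
    union), with the exclusive count of ids showing exactly that pattern.
    Cell counts sum to the size of the union.
    """
    names = list(sets_by_sample)
    sets = {name: frozenset(ids) for name, ids in sets_by_sample.items()}
    universe = set().union(*sets.values()) if sets else set()
    rows = []
    for combo_size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, combo_size):
            inside = set(universe)
            for name in combo:
                inside &= sets[name]
            for name in names:
                if name not in combo:
                    inside -= sets[name]
            rows.append(
                {
                    "members": "&".join(combo),
                    "n_samples": combo_size,
                    "count": len(inside),
                }
            )
    return pd.DataFrame(rows)


def rank_correlation(rs_a: Sequence[float], rs_b: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation between two replicate RS vectors.

    Pairs with a missing value on either side are dropped; ties are
    mid-ranked.  Fewer than 3 complete pairs is an error.
    """
    a = np.asarray(rs_a, dtype=float)
    b = np.asarray(rs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must be paired (same length)")
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 3:
        raise ValueError("need at least 3 complete pairs for a rank correlation")
    rho, p = stats.spearmanr(a[keep], b[keep])
    return float(rho), float(p)


def compare_feature(
    significant_values: Sequence,
    non_significant_values: Sequence,
    feature: str,
) -> dict:
    """Association of a per-IES feature with significant retention.

    ``feature`` is ``"gc_content"`` (continuous; two-sided Mann-Whitney) or
    ``"in_gene"`` (binary; chi-square on the 2x2 table, no continuity
    correction).  Returns the statistic, the p-value and the effect
    direction in the significant set relative to the non-significant one.
    """
    sig = np.asarray(significant_values)
    non = np.asarray(non_significant_values)
    if sig.size == 0 or non.size == 0:
        raise ValueError("both IES sets must be non-empty")
    if feature == "gc_content":
        res = stats.mannwhitneyu(sig.astype(float), non.astype(float),
                                 alternative="two-sided")
        delta = float(np.median(sig) - np.median(non))
        direction = "higher" if delta > 0 else ("lower" if delta < 0 else "none")
        return {
            "feature": feature,
            "test": "mann-whitney",
            "statistic": float(res.statistic),
            "pvalue": float(res.pvalue),
            "direction": direction,
            "effect": delta,
        }
    if feature == "in_gene":
        sig = sig.astype(bool)
        non = non.astype(bool)
        table = np.array(
            [[sig.sum(), (~sig).sum()], [non.sum(), (~non).sum()]], dtype=float
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        delta = float(sig.mean() - non.mean())
        direction = "higher" if delta > 0 else ("lower" if delta < 0 else "none")
        return {
            "feature": feature,
            "test": "chi-square",
            "statistic": float(chi2),
            "pvalue": float(p),
            "direction": direction,
            "effect": delta,
        }
    raise ValueError(f"unknown feature {feature!r}")
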