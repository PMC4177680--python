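"""Retention scores and significance calls against a control sample.

The retention score of an IES is RS = IES+ / (IES+ + IES-), the fraction of
boundary-classified reads supporting the unexcised form; it runs from 0 (no
retention) to 1 (complete retention).  Significant retention in an
experimental sample is called per IES by (i) taking the upper bound of the
exact two-sided (Clopper-Pearson) confidence interval of the control RS at
that IES, (ii) a one-sided binomial test of the experimental counts against
that bound, and (iii) Benjamini-Hochberg adjustment across all tested IESs,
calling adjusted p < 0.05 significant.  Testing against the control CI upper
bound, rather than the control point estimate, absorbs background signal
from sequencing biases and annotation false positives and makes the test
conservative under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestConfig",
    "retention_score",
    "clopper_pearson_upper",
    "binomial_greater_pvalue",
    "bh_adjust",
    "call_significant",
]


@dataclass(frozen=True)
class TestConfig:
    """Confidence level of the control interval and the FDR threshold."""

    __test__ = False  # not a pytest collection target

    confidence: float = 0.95
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie strictly between 0 and 1")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie strictly between 0 and 1")


def retention_score(ies_plus: int, ies_minus: int) -> float:
    """RS = IES+ / (IES+ + IES-); NaN when no read was classified."""
    if ies_plus < 0 or ies_minus < 0:
        raise ValueError("counts must be non-negative")
    n = ies_plus + ies_minus
    if n == 0:
        return float("nan")
    return ies_plus / n


def clopper_pearson_upper(k: int, n: int, confidence: float = 0.95) -> float:
    """Upper endpoint of the exact two-sided binomial confidence interval.

    The Clopper-Pearson bound inverts the binomial CDF: the upper endpoint
    is the Beta(k+1, n-k) quantile at 1 - (1-confidence)/2, with the
    convention that k = n gives 1.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if k == n:
        return 1.0
    alpha = 1.0 - confidence
    return float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))


def binomial_greater_pvalue(k: int, n: int, p0: float) -> float:
    """One-sided p-value P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    NaN entries are excluded from the number of tests and returned as NaN;
    adjusted values are monotone and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_significant(
    experiment: pd.DataFrame,
    control: pd.DataFrame,
    cfg: TestConfig | None = None,
) -> pd.DataFrame:
    """Per-IES retention records with significance against the control.

    Both inputs carry columns ``ies_id``, ``ies_plus``, ``ies_minus``.  For
    every IES with classified reads in both samples, the control counts give
    the Clopper-Pearson upper bound, the experimental counts the one-sided
    binomial p-value against it, and BH adjustment runs over all tested
    IESs.  IESs unclassifiable in either sample (n = 0, or absent from the
    control table) receive NaN and are excluded from the number of tests.

    Returns columns: ies_id, ies_plus, ies_minus, rs, control_upper,
    pvalue, padj, significant.
    """
    cfg = cfg or TestConfig()
    if experiment.empty:
        raise ValueError("experiment count table is empty")
    ctl = control.set_index("ies_id")
    missing = [i for i in experiment["ies_id"] if i not in ctl.index]
    if missing:
        import warnings

        warnings.warn(
            f"{len(missing)} IES(s) absent from the control table; "
            "their records are reported untested (NaN)",
            stacklevel=2,
        )

    rows = []
    for rec in experiment.itertuples(index=False):
        k_exp = int(rec.ies_plus)
        n_exp = k_exp + int(rec.ies_minus)
        rs = retention_score(rec.ies_plus, rec.ies_minus)
        control_upper = np.nan
        pvalue = np.nan
        if rec.ies_id in ctl.index:
            kc = int(ctl.at[rec.ies_id, "ies_plus"])
            nc = kc + int(ctl.at[rec.ies_id, "ies_minus"])
            if nc > 0 and n_exp > 0:
                control_upper = clopper_pearson_upper(kc, nc, cfg.confidence)
                pvalue = binomial_greater_pvalue(k_exp, n_exp, control_upper)
        rows.append(
            {
                "ies_id": rec.ies_id,
                "ies_plus": k_exp,
                "ies_minus": int(rec.ies_minus),
                "rs": rs,
                "control_upper": control_upper,
                "pvalue": pvalue,
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["padj"] < cfg.fdr_threshold
    out.loc[out["padj"].isna(), "significant"] = False
    return out


def write_records_tsv(records: pd.DataFrame, path) -> None:
    """TSV dump with RS and bounds rounded to 3 decimals for readability."""
    df = records.copy()
    for col in ("rs", "control_upper"):
        df[col] = df[col].round(3)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"ies_id", "ies_plus", "ies_minus"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df
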