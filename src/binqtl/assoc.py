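"""Downstream statistics: marker-group tests, expression-trait correlation,
and qPCR relative expression by the 2^-ΔΔCq method."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def marker_group_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
) -> tuple[float, float]:
    """Welch two-sided t-test between two marker genotype classes.

    Returns (difference of means, p-value); the difference is group A minus
    group B, so swapping groups negates it and leaves p unchanged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each genotype class needs at least 2 lines")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean() - b.mean()), float(res.pvalue)


def marker_group_frame_test(groups: pd.DataFrame) -> tuple[float, float]:
    """Welch t-test from a (line, genotype, blue) table with two classes."""
    classes = groups["genotype"].unique()
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 genotype classes, got {len(classes)}")
    a = groups.loc[groups["genotype"] == classes[0], "blue"].to_numpy(dtype=float)
    b = groups.loc[groups["genotype"] == classes[1], "blue"].to_numpy(dtype=float)
    return marker_group_test(a, b)


def expr_trait_correlation(
    expression: np.ndarray,
    trait: np.ndarray,
) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform) on pairwise-complete pairs."""
    x = np.asarray(expression, dtype=float)
    y = np.asarray(trait, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in expression or trait vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def candidate_gene_correlations(
    expression: pd.DataFrame,
    blue: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene correlation of expression with line BLUEs, with BH-adjusted q.

    ``expression`` is genes x lines; ``blue`` carries line/blue columns. Raw
    p-values are reported alongside Benjamini-Hochberg adjusted ones.
    """
    blue_map = blue.set_index("line")["blue"]
    shared = [ln for ln in expression.columns if ln in blue_map.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 lines shared between expression and BLUEs")
    y = blue_map[shared].to_numpy(dtype=float)
    rows = []
    for gene, expr in expression[shared].iterrows():
        try:
            r, p = expr_trait_correlation(expr.to_numpy(dtype=float), y)
        except ValueError:
            r, p = np.nan, np.nan
        rows.append((gene, r, p, len(shared)))
    df = pd.DataFrame(rows, columns=["gene", "r", "p", "n"])
    ok = df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = stats.false_discovery_control(df.loc[ok, "p"], method="bh")
    return df


@dataclass
class FoldChange:
    fold: float
    ddcq: float
    se_ddcq: float | None = None

    @property
    def fold_low(self) -> float | None:
        return 2.0 ** -(self.ddcq + self.se_ddcq) if self.se_ddcq is not None else None

    @property
    def fold_high(self) -> float | None:
        return 2.0 ** -(self.ddcq - self.se_ddcq) if self.se_ddcq is not None else None


def ddcq_relative_expression(
    cq_target_sample,
    cq_ref_sample,
    cq_target_calibrator,
    cq_ref_calibrator,
) -> FoldChange:
    """Relative expression fold change 2^-ΔΔCq.

    Each argument is a quantification-cycle value or an array of replicate
    values; replicate means are used and replicate standard errors propagated
    into an SE for ΔΔCq (reported as a fold-change range).
    """

    def _mean_se(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("Cq values must be finite")
        se = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
        return float(x.mean()), se

    mts, sts = _mean_se(cq_target_sample)
    mrs, srs = _mean_se(cq_ref_sample)
    mtc, stc = _mean_se(cq_target_calibrator)
    mrc, src = _mean_se(cq_ref_calibrator)
    ddcq = (mts - mrs) - (mtc - mrc)
    se = float(np.sqrt(sts**2 + srs**2 + stc**2 + src**2))
    return FoldChange(fold=float(2.0**-ddcq), ddcq=float(ddcq), se_ddcq=se if se > 0 else None)
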