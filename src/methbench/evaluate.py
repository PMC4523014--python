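"""Accuracy and precision evaluation of methylation estimators.

Given observed percent-methylation values labelled with their expected
panel levels, this module computes the benchmarking battery used to
compare quantification methods: Pearson correlation and ordinary
least-squares regression of observed on expected, per-level fold-bias,
barcode (MID) outlier testing, one-way ANOVA with Tukey HSD pairwise
discrimination, and a Kolmogorov-Smirnov normality check.

The module ships a transcription of the bisulfite amplicon sequencing
benchmark table (two runs over the seven-member standards panel with
within-run replicates under different MID barcodes) as a worked fixture;
see :func:`load_ngs_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "pearson_r2",
    "linear_fit",
    "fold_bias",
    "mid_outlier_summary",
    "discrimination_matrix",
    "ks_normality",
    "load_ngs_table",
    "evaluate_ngs_table",
]


def pearson_r2(x, y) -> float:
    """Squared Pearson product-moment correlation of paired values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def linear_fit(x, y) -> tuple[float, float, np.ndarray]:
    """OLS of observed on expected: returns (slope, intercept,
    residuals).  Residuals are returned so their distribution can be
    inspected — a systematic estimator bias shows up as non-random
    structure."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.var(x) == 0:
        raise ValueError("degenerate predictor; fit undefined")
    res = stats.linregress(x, y)
    residuals = y - (res.intercept + res.slope * x)
    return float(res.slope), float(res.intercept), residuals


def fold_bias(expected: float, observed_values) -> float:
    """mean(observed)/expected for one panel level; undefined at 0%."""
    if expected <= 0:
        raise ValueError("fold bias undefined for expected <= 0")
    return float(np.mean(np.asarray(observed_values, dtype=float))) / expected


def mid_outlier_summary(
    values_by_mid: dict[object, list[float]],
    candidate: object,
    alpha: float = 0.05,
) -> dict:
    """Test whether one MID barcode's replicates differ from the rest.

    Runs a two-sample t-test of the candidate MID's values against the
    pooled values of all other MIDs.  Returns per-MID means, the pooled
    non-candidate mean, the p-value and an outlier flag at ``alpha``.
    """
    if candidate not in values_by_mid:
        raise KeyError(f"candidate MID {candidate!r} not present")
    if len(values_by_mid) < 2:
        raise ValueError("need at least 2 MID groups")
    cand = np.asarray(values_by_mid[candidate], dtype=float)
    rest = np.concatenate(
        [np.asarray(v, dtype=float) for k, v in values_by_mid.items() if k != candidate]
    )
    t, p = stats.ttest_ind(cand, rest)
    return {
        "per_mid_mean": {k: float(np.mean(v)) for k, v in values_by_mid.items()},
        "candidate_mean": float(cand.mean()),
        "others_mean": float(rest.mean()),
        "t": float(t),
        "p": float(p),
        "outlier": bool(p < alpha),
    }


def discrimination_matrix(
    groups: dict[float, list[float]], alpha: float = 0.05
) -> dict:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` maps expected percent methylation to replicate observed
    values.  Groups with a single replicate are excluded (recorded in
    ``excluded``).  Returns the ANOVA p-value, a pairwise table with
    Tukey p-values and significance flags, and the minimum resolvable
    difference: the smallest |expected_i - expected_j| among significant
    pairs (NaN when nothing is significant).
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    excluded = sorted(set(groups) - set(usable))
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 replicates")
    levels = sorted(usable)
    samples = [usable[lv] for lv in levels]
    f_stat, anova_p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    pairs = []
    min_diff = np.inf
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p = float(tukey.pvalue[i, j])
            sig = p < alpha
            pairs.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "difference": abs(levels[j] - levels[i]),
                    "p": p,
                    "significant": sig,
                }
            )
            if sig:
                min_diff = min(min_diff, abs(levels[j] - levels[i]))
    return {
        "anova_f": float(f_stat),
        "anova_p": float(anova_p),
        "pairs": pairs,
        "min_resolvable_difference": float(min_diff) if np.isfinite(min_diff) else float("nan"),
        "excluded": excluded,
        "alpha": alpha,
    }


def ks_normality(values, alpha: float = 0.05) -> dict:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    Returns the statistic, p-value and a pass flag (p >= alpha).
    Constant input is degenerate and flagged rather than tested.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.std(v) == 0:
        return {"statistic": float("nan"), "p": float("nan"),
                "passed": False, "degenerate": True}
    stat, p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return {"statistic": float(stat), "p": float(p),
            "passed": bool(p >= alpha), "degenerate": False}


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy/precision summary for one estimator over the panel."""

    r_squared_means: float
    r_squared_points: float
    slope: float
    intercept: float
    fold_bias: dict[float, float]
    replicate_spread: dict[float, float]


def load_ngs_table() -> pd.DataFrame:
    """Load the shipped bisulfite-amplicon benchmark table.

    Columns: run, mid, expected_percent, intra_run_replicate,
    observed_percent.  Two sequencing runs over the standards panel; the
    25% and 50% samples carry within-run replicates under different MID
    barcodes, and the MID9 rows are the known biased barcode.
    """
    with resources.files("methbench.data").joinpath("ngs_panel_table.csv").open() as fh:
        return pd.read_csv(fh)


def evaluate_ngs_table(
    table: pd.DataFrame | None = None, exclude_mid: int | None = 9
) -> dict:
    """Run the full regression/bias battery on the NGS benchmark table.

    ``exclude_mid`` drops the named biased barcode from the correlation
    and regression (pass None to keep everything).  Per-sample means
    pool the retained replicates across both runs.
    """
    df = load_ngs_table() if table is None else table.copy()
    if exclude_mid is not None:
        kept = df[df["mid"] != exclude_mid]
    else:
        kept = df
    means = kept.groupby("expected_percent")["observed_percent"].mean()
    r2_means = pearson_r2(means.index.to_numpy(), means.to_numpy())
    r2_points = pearson_r2(
        kept["expected_percent"].to_numpy(), kept["observed_percent"].to_numpy()
    )
    slope, intercept, _ = linear_fit(means.index.to_numpy(), means.to_numpy())
    folds = {
        float(e): fold_bias(float(e), g["observed_percent"].to_numpy())
        for e, g in kept.groupby("expected_percent")
        if e > 0
    }
    fifty = df[df["expected_percent"] == 50]
    mid_groups = {
        int(m): g["observed_percent"].tolist() for m, g in fifty.groupby("mid")
    }
    mid_summary = (
        mid_outlier_summary(mid_groups, 9) if 9 in mid_groups else None
    )
    return {
        "r_squared_means": r2_means,
        "r_squared_points": r2_points,
        "slope": slope,
        "intercept": intercept,
        "fold_bias": folds,
        "mid_summary": mid_summary,
        "n_points": int(len(kept)),
    }
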