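"""Statistics linking drug promiscuity to drug and target properties.

The analysis assembles one row per promiscuous drug (>= 3 non-redundant
targets) — target count, similar-binding-site pair count, conformer cluster
count, molecular weight, logP, rotatable-bond counts, optional Pfam-family
and global-structure-similar counts — and asks which of these track the
degree of promiscuity:

* Pearson correlation with a two-sided t-test p-value (the ``cor.test``
  convention: t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom);
* pair-count axes are square-root transformed before correlating, since a
  drug with n targets has up to n(n-1)/2 target pairs — the count grows
  quadratically in the degree;
* two-sample Kolmogorov–Smirnov comparisons of property distributions
  (p > 0.05 read as "no evidence the distributions differ");
* an ordinary least squares regression of target count on all drug
  properties jointly, with R^2 and the overall F-test.

Drugs with a missing optional descriptor are excluded pairwise per
analysis, not listwise, so each panel uses the largest sample available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationReport",
    "DistributionComparison",
    "RegressionReport",
    "build_table",
    "correlate",
    "ks_compare",
    "regress_combined",
    "summarize_drugs",
    "plot_correlation",
]

REGRESSION_PREDICTORS = [
    "logp",
    "mw",
    "conformer_cluster_count",
    "rotatable_rel",
    "rotatable_abs",
]

TABLE_COLUMNS = [
    "drug",
    "target_count",
    "similar_pair_count",
    "structural_similar_pair_count",
    "conformer_cluster_count",
    "pfam_family_count",
    "mw",
    "logp",
    "rotatable_abs",
    "rotatable_rel",
]


@dataclass
class CorrelationReport:
    r: float
    p_value: float
    n: int
    y_transform: str = "none"


@dataclass
class DistributionComparison:
    statistic: float  # D = sup |ECDF_a - ECDF_b|
    p_value: float
    n_a: int
    n_b: int


@dataclass
class RegressionReport:
    coefficients: dict[str, float]
    r_squared: float
    f_pvalue: float
    n: int


def build_table(
    degrees: Mapping[str, int],
    similar_pair_counts: Mapping[str, int],
    conformer_counts: Mapping[str, int],
    descriptors: pd.DataFrame,
    pfam_counts: Mapping[str, int] | None = None,
    structural_similar_counts: Mapping[str, int] | None = None,
    min_targets: int = 3,
) -> pd.DataFrame:
    """One row per promiscuous drug (degree >= ``min_targets``).

    ``descriptors`` is indexed by drug with columns ``mw``, ``rotatable_abs``,
    ``rotatable_rel`` and optionally ``logp``.  Any drug appearing in the
    auxiliary mappings but absent from ``degrees`` is flagged as an orphan.
    """
    orphans = sorted(
        (set(similar_pair_counts) | set(conformer_counts) | set(descriptors.index))
        - set(degrees)
    )
    if orphans:
        raise ValueError(f"identifiers without a target degree: {orphans}")
    rows = []
    for drug in sorted(degrees):
        n = degrees[drug]
        if n < min_targets:
            continue
        max_pairs = n * (n - 1) // 2
        s = int(similar_pair_counts.get(drug, 0))
        if s > max_pairs:
            raise ValueError(
                f"{drug}: {s} similar pairs exceeds n(n-1)/2 = {max_pairs}"
            )
        desc = descriptors.loc[drug] if drug in descriptors.index else pd.Series(dtype=float)
        rows.append(
            {
                "drug": drug,
                "target_count": n,
                "similar_pair_count": s,
                "structural_similar_pair_count": (
                    int(structural_similar_counts.get(drug, 0))
                    if structural_similar_counts is not None
                    else np.nan
                ),
                "conformer_cluster_count": conformer_counts.get(drug, np.nan),
                "pfam_family_count": (
                    pfam_counts.get(drug, np.nan) if pfam_counts is not None else np.nan
                ),
                "mw": desc.get("mw", np.nan),
                "logp": desc.get("logp", np.nan),
                "rotatable_abs": desc.get("rotatable_abs", np.nan),
                "rotatable_rel": desc.get("rotatable_rel", np.nan),
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def correlate(
    x: Sequence[float], y: Sequence[float], y_transform: str = "none"
) -> CorrelationReport:
    """Pearson correlation with two-sided t-test p-value.

    ``y_transform='sqrt'`` takes the square root of y first (used for pair
    counts, which scale quadratically with the target count).  Pairs with a
    missing value on either side are dropped.
    """
    if y_transform not in ("none", "sqrt"):
        raise ValueError("y_transform must be 'none' or 'sqrt'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 finite (x, y) pairs")
    if y_transform == "sqrt":
        if np.any(y < 0):
            raise ValueError("sqrt transform requires nonnegative y")
        y = np.sqrt(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    res = stats.pearsonr(x, y)
    return CorrelationReport(
        r=float(res.statistic), p_value=float(res.pvalue), n=len(x), y_transform=y_transform
    )


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> DistributionComparison:
    """Two-sample Kolmogorov–Smirnov comparison (asymptotic p-value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return DistributionComparison(
        statistic=float(res.statistic), p_value=float(res.pvalue), n_a=len(a), n_b=len(b)
    )


def regress_combined(
    table: pd.DataFrame,
    predictors: Sequence[str] = tuple(REGRESSION_PREDICTORS),
    response: str = "target_count",
) -> RegressionReport:
    """OLS of the promiscuity degree on all drug properties jointly."""
    predictors = list(predictors)
    data = table[[response, *predictors]].dropna()
    n = len(data)
    if n < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} complete rows, got {n}"
        )
    X = data[predictors].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc, predictors)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(data[response].to_numpy(dtype=float), Xc).fit()
    coeffs = {"intercept": float(fit.params[0])}
    coeffs.update({p: float(c) for p, c in zip(predictors, fit.params[1:])})
    return RegressionReport(
        coefficients=coeffs,
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        n=n,
    )


def _collinear_columns(Xc: np.ndarray, predictors: Sequence[str]) -> list[str]:
    bad = []
    for k, name in enumerate(predictors):
        others = np.delete(Xc, k + 1, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(Xc):
            bad.append(name)
    return bad or list(predictors)


def summarize_drugs(
    table: pd.DataFrame, top_k: int = 10, histogram_max: int = 10
) -> dict:
    """Drug-centric summary of the binding-site similarity analysis.

    Fractions of drugs with at least one similar target pair and with all
    target pairs similar; a histogram of target counts (last bin open);
    and the ``top_k`` drugs by similar-site count.
    """
    n_drugs = len(table)
    if n_drugs == 0:
        return {
            "n_drugs": 0,
            "fraction_with_similar_pair": 0.0,
            "fraction_all_pairs_similar": 0.0,
            "target_count_histogram": {},
            "top_drugs": [],
        }
    max_pairs = table["target_count"] * (table["target_count"] - 1) // 2
    with_similar = (table["similar_pair_count"] >= 1).sum()
    all_similar = (table["similar_pair_count"] == max_pairs).sum()
    hist: dict[str, int] = {}
    for n in range(1, histogram_max):
        hist[str(n)] = int((table["target_count"] == n).sum())
    hist[f">={histogram_max}"] = int((table["target_count"] >= histogram_max).sum())
    top = (
        table.sort_values(["similar_pair_count", "drug"], ascending=[False, True])
        .head(top_k)[["drug", "target_count", "similar_pair_count"]]
        .to_dict("records")
    )
    return {
        "n_drugs": int(n_drugs),
        "fraction_with_similar_pair": float(with_similar / n_drugs),
        "fraction_all_pairs_similar": float(all_similar / n_drugs),
        "target_count_histogram": hist,
        "top_drugs": top,
    }


def plot_correlation(x, y, xlabel: str, ylabel: str, path: str) -> None:
    """Scatter plot with per-x mean overlay (presentation only)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, s=12, alpha=0.6, color="#4477aa")
    xs = np.unique(x)
    means = [np.nanmean(y[x == v]) for v in xs]
    ax.plot(xs, means, "o-", color="#228833", markersize=4, linewidth=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
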