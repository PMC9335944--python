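"""Benign-vs-malignant comparison of shape-feature distributions.

The default two-sample test is the Mann–Whitney U (the descriptors are
bounded and generally non-normal): exact null when the combined sample is
small (n ≤ 20), normal approximation with tie correction otherwise.
Welch's t is available for comparison.  No multiple-testing correction is
applied across the three descriptors by default (a Bonferroni option
exists).  Violin summaries are Gaussian KDEs (Silverman bandwidth) plus the
five-number summary, the data behind a violin plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as _sps

DESCRIPTORS = ("F", "area_convexity", "perimeter_convexity")


@dataclass
class GroupComparison:
    feature: str
    n_benign: int
    n_malignant: int
    median_benign: float
    median_malignant: float
    mean_benign: float
    mean_malignant: float
    test: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass
class ViolinSummary:
    grid: np.ndarray
    density: np.ndarray
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


def compare_feature(values_benign, values_malignant, test: str = "mann_whitney",
                    alpha: float = 0.05, feature: str = "") -> GroupComparison:
    """Two-sided two-sample comparison of one descriptor."""
    x = np.asarray(values_benign, dtype=float)
    y = np.asarray(values_malignant, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 finite values per group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("both groups are a single constant: p-value set to 1",
                      stacklevel=2)
        stat, p = float("nan"), 1.0
    elif test == "mann_whitney":
        method = "exact" if (len(x) + len(y) <= 20 and len(np.unique(pooled)) == len(pooled)) else "asymptotic"
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "welch_t":
        res = _sps.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    p = min(p, 1.0)
    return GroupComparison(
        feature=feature, n_benign=len(x), n_malignant=len(y),
        median_benign=float(np.median(x)), median_malignant=float(np.median(y)),
        mean_benign=float(np.mean(x)), mean_malignant=float(np.mean(y)),
        test=test, statistic=stat, p_value=p,
        significant=bool(p < alpha), alpha=alpha,
    )


def violin_summary(values, grid_size: int = 128) -> ViolinSummary:
    """Silverman-bandwidth KDE on a grid wide enough that the density
    trapezoid-integrates to 1 within ~1e-3, plus min/Q1/median/Q3/max."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 values for a violin summary")
    if np.ptp(v) == 0:
        raise ValueError("constant sample has no density estimate")
    kde = _sps.gaussian_kde(v, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(v.min() - 5 * bw, v.max() + 5 * bw, grid_size)
    density = kde(grid)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return ViolinSummary(grid=grid, density=density,
                         minimum=float(v.min()), q1=float(q1),
                         median=float(med), q3=float(q3), maximum=float(v.max()))


def significance_report(features: pd.DataFrame, test: str = "mann_whitney",
                        alpha: float = 0.05, bonferroni: bool = False,
                        benign_label: str = "benign",
                        malignant_label: str = "malignant") -> dict:
    """One GroupComparison per descriptor plus per-group violin data.

    Returns a JSON-serializable dict:
    ``{"comparisons": {feature: {...}}, "violins": {feature: {group: {...}}}}``.
    Descriptor columns that are absent or unusable are reported under
    ``"missing"`` while the remaining comparisons stay intact.
    """
    labels = set(features["label"])
    if benign_label not in labels or malignant_label not in labels:
        raise ValueError("both benign and malignant groups must be present")
    eff_alpha = alpha / len(DESCRIPTORS) if bonferroni else alpha
    report: dict = {"test": test, "alpha": alpha, "bonferroni": bonferroni,
                    "comparisons": {}, "violins": {}, "missing": []}
    for feat in DESCRIPTORS:
        if feat not in features.columns:
            report["missing"].append(feat)
            continue
        ben = features.loc[features["label"] == benign_label, feat].to_numpy(dtype=float)
        mal = features.loc[features["label"] == malignant_label, feat].to_numpy(dtype=float)
        try:
            cmp_res = compare_feature(ben, mal, test=test, alpha=eff_alpha, feature=feat)
        except ValueError as exc:
            warnings.warn(f"comparison failed for {feat}: {exc}", stacklevel=2)
            report["missing"].append(feat)
            continue
        report["comparisons"][feat] = asdict(cmp_res)
        report["violins"][feat] = {}
        for name, vals in (("benign", ben), ("malignant", mal)):
            try:
                vio = violin_summary(vals)
                report["violins"][feat][name] = {
                    "grid": vio.grid.tolist(), "density": vio.density.tolist(),
                    "min": vio.minimum, "q1": vio.q1, "median": vio.median,
                    "q3": vio.q3, "max": vio.maximum,
                }
            except ValueError:
                report["violins"][feat][name] = None
    return report


def render_report_text(report: dict) -> str:
    """Human-readable rendering of a significance report."""
    lines = [f"two-sample test: {report['test']} (alpha={report['alpha']}"
             f"{', Bonferroni' if report['bonferroni'] else ''})"]
    for feat, cmp_res in report["comparisons"].items():
        mark = "*" if cmp_res["significant"] else " "
        lines.append(
            f"  {feat:22s} benign median {cmp_res['median_benign']:.4f} vs "
            f"malignant {cmp_res['median_malignant']:.4f}  "
            f"p={cmp_res['p_value']:.3g} {mark}"
        )
    for feat in report.get("missing", []):
        lines.append(f"  {feat:22s} missing")
    return "\n".join(lines)
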