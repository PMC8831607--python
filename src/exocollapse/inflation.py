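"""Genomic inflation factor and QQ-plot coordinates for per-gene p-values.

The inflation factor lambda is the median of the observed association
statistics, mapped to the 1-df chi-square scale, divided by the null
median of that distribution (0.4549...). Lambda near 1 indicates no
systematic confounding; lambda below 1 is common for discrete exact
tests, whose null p-values are stochastically larger than uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

#: median of the 1-df chi-square distribution
CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def genomic_lambda(pvals, exclude_ones: bool = False) -> float:
    """Median-based genomic inflation factor of a p-value vector.

    ``exclude_ones`` drops p = 1 entries (genes without a single carrier,
    or whose observed table is the modal one) before taking the median;
    inclusion is the default and materially lowers lambda when many genes
    are empty.
    """
    p = _check_pvals(pvals)
    if exclude_ones:
        p = p[p < 1.0]
        if p.size == 0:
            raise ValueError("no p-values below 1 to evaluate")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


@dataclass
class InflationResult:
    """Lambda plus QQ coordinates with expected-percentile envelopes.

    ``qq_points`` pairs expected with observed -log10 p per rank, sorted
    by ascending expected value; the bands are the 2.5th/97.5th
    percentiles of the corresponding uniform order statistic
    (Beta(i, n - i + 1)), also on the -log10 scale.
    """

    lambda_gc: float
    qq_points: np.ndarray    # shape (n, 2): expected, observed
    band_lower: np.ndarray
    band_upper: np.ndarray


def qq_with_bands(pvals) -> InflationResult:
    """QQ coordinates with 95% pointwise order-statistic envelopes.

    The expected -log10 p for rank i of n uses the i/(n+1) plotting
    position; rank i's envelope comes from the Beta(i, n-i+1) law of the
    i-th uniform order statistic.
    """
    p = _check_pvals(pvals)
    n = p.size
    order = np.sort(p)                       # ascending p = descending -log10
    ranks = np.arange(1, n + 1)
    expected = -np.log10(ranks / (n + 1.0))
    observed = -np.log10(order)
    lo_q = beta_dist.ppf(0.025, ranks, n - ranks + 1)
    hi_q = beta_dist.ppf(0.975, ranks, n - ranks + 1)
    band_upper = -np.log10(lo_q)
    band_lower = -np.log10(hi_q)
    # sort by ascending expected -log10 p
    idx = np.argsort(expected)
    qq = np.column_stack([expected[idx], observed[idx]])
    return InflationResult(
        lambda_gc=genomic_lambda(p),
        qq_points=qq,
        band_lower=band_lower[idx],
        band_upper=band_upper[idx],
    )


def plot_qq(result: InflationResult, path, title: str | None = None) -> None:
    """Render the QQ plot to ``path`` (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    exp = result.qq_points[:, 0]
    obs = result.qq_points[:, 1]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, exp.max()], [0, exp.max()], color="tab:blue", lw=1,
            label="null")
    ax.plot(exp, result.band_lower, color="gold", lw=0.8,
            label="2.5th pct expected")
    ax.plot(exp, result.band_upper, color="green", lw=0.8,
            label="97.5th pct expected")
    ax.scatter(exp, obs, s=6, color="black", zorder=3)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.legend(frameon=False, fontsize=8)
    if title is None:
        title = f"$\\lambda$ = {result.lambda_gc:.2f}"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
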