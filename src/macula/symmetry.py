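"""Interocular agreement and two-sample comparison statistics.

Bland-Altman analysis summarises right-minus-left (OD − OS) differences
of a foveal metric by their mean (bias) and 95% limits of agreement
(bias ± 1.96·SD).  Confidence intervals use the classical large-sample
formulas: t·SD/√n for the bias and t·SD·√(3/n) for each limit.
Normality is screened with the D'Agostino-Pearson K² omnibus test and
group comparisons use the pooled-variance two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class BlandAltmanResult:
    """Agreement between paired right- and left-eye measurements."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    outliers: list

    def summary(self) -> str:
        return (
            f"Bland-Altman (OD − OS), n={self.n}\n"
            f"bias {self.bias:.5g} [{self.ci_bias[0]:.5g}, {self.ci_bias[1]:.5g}]\n"
            f"LOA  [{self.loa_low:.5g}, {self.loa_high:.5g}]\n"
            f"outliers outside LOA: {self.outliers}"
        )


@dataclass
class TTestResult:
    """Pooled-variance two-sample t-test."""

    t_stat: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def bland_altman(
    od: Sequence[float], os_: Sequence[float], ids: Sequence | None = None
) -> BlandAltmanResult:
    """Bland-Altman agreement statistics for paired OD/OS measurements.

    Differences are taken OD − OS.  ``ids`` label the pairs so subjects
    falling outside the limits of agreement can be reported.
    """
    od = np.asarray(od, dtype=float)
    os_ = np.asarray(os_, dtype=float)
    if od.shape != os_.shape:
        raise ValueError("paired vectors must have equal length")
    n = od.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if ids is None:
        ids = list(range(n))
    d = od - os_
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    outliers = [ids[i] for i in range(n) if d[i] < loa_low or d[i] > loa_high]
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        ci_loa_low=(loa_low - tcrit * se_loa, loa_low + tcrit * se_loa),
        ci_loa_high=(loa_high - tcrit * se_loa, loa_high + tcrit * se_loa),
        outliers=outliers,
    )


def dagostino_pearson(values: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson K² omnibus normality test.

    K² combines the normalising transforms of sample skewness and
    kurtosis and is referred to a χ² distribution with 2 df.  Requires
    n ≥ 20 (the transforms are unreliable below that) and non-zero
    variance.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise ValueError(f"normality test needs n ≥ 20, got {values.size}")
    if values.std() == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    k2, p = stats.normaltest(values)
    return float(k2), float(p)


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided pooled-variance t-test; df = n_a + n_b − 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n ≥ 2")
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    if sd_a == 0 and sd_b == 0:
        raise ValueError("zero pooled variance: t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t_stat=float(t),
        df=int(a.size + b.size - 2),
        p_value=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(sd_a),
        sd_b=float(sd_b),
    )


def bland_altman_plot(result: BlandAltmanResult, od, os_, path) -> None:
    """Save a standard Bland-Altman scatter (mean vs difference) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    od = np.asarray(od, dtype=float)
    os_ = np.asarray(os_, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((od + os_) / 2, od - os_, s=18)
    ax.axhline(result.bias, color="k")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("mean of OD and OS")
    ax.set_ylabel("OD − OS")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
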