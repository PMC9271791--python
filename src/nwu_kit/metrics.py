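"""Agreement statistics for validating automated against reference measures.

Dice similarity for spatial overlap of masks; single-measure two-way
random-effects absolute-agreement intraclass correlation, ICC(2,1), with
its Shrout-Fleiss 95% confidence interval; and Bland-Altman bias with
1.96-sd limits of agreement for paired continuous measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ct_io import VoxelMask
from .errors import InputError

__all__ = ["AgreementStats", "dice", "icc_2_1", "bland_altman"]


@dataclass
class AgreementStats:
    """Container for agreement results; unused fields stay None."""

    n: int
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None

    def to_dict(self) -> dict:
        d = {"n": self.n}
        if self.icc is not None:
            d["icc"] = self.icc
            d["icc_ci"] = list(self.icc_ci)
        if self.bias is not None:
            d.update(bias=self.bias, loa_low=self.loa_low, loa_high=self.loa_high)
        return d


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks agree perfectly on absence: defined as 1.0.
    """
    if not a.same_grid(b):
        raise InputError("dice requires masks on the same grid")
    av = a.voxels.astype(bool)
    bv = b.voxels.astype(bool)
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((av & bv).sum()) / denom


def icc_2_1(
    x: np.ndarray, y: np.ndarray, confidence: float = 0.95
) -> AgreementStats:
    """ICC(2,1): single-measure, absolute-agreement, two-way random effects.

    Computed from the two-way ANOVA mean squares of an n-subjects x
    2-raters table; the confidence interval uses the Shrout-Fleiss F-based
    formula with a Satterthwaite df approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("icc_2_1 requires two equal-length 1D arrays")
    n = x.size
    if n < 3:
        raise InputError("icc_2_1 requires at least 3 paired measurements")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("icc_2_1 requires finite values")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise InputError("icc_2_1 undefined for zero total variance")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise InputError("icc_2_1 undefined: zero denominator")
    icc = (msr - mse) / denom

    # Shrout-Fleiss CI for ICC(2,1)
    alpha = 1.0 - confidence
    fj = msc / mse if mse > 0 else np.inf
    a_ = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b_ = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a_) and mse > 0:
        v_num = ((k - 1.0) * (n - 1.0)
                 * (k * icc * fj + n * (1.0 + (k - 1.0) * icc) - k * icc) ** 2)
        v_den = ((n - 1.0) * k**2 * icc**2 * fj**2
                 + (n * (1.0 + (k - 1.0) * icc) - k * icc) ** 2)
        v = v_num / v_den
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        ci = (float(min(lower, icc)), float(max(upper, icc)))
    else:
        ci = (float(icc), float(icc))
    return AgreementStats(n=n, icc=float(icc), icc_ci=ci)


def bland_altman(x: np.ndarray, y: np.ndarray) -> AgreementStats:
    """Bland-Altman bias and limits of agreement for paired measurements.

    diff = x - y; bias = mean(diff); limits = bias ± 1.96 * sd(diff) with
    the n-1 sd denominator. The 1.96 multiplier is the classical normal
    quantile (not t-based).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("bland_altman requires two equal-length 1D arrays")
    if x.size < 2:
        raise InputError("bland_altman requires at least 2 paired measurements")
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementStats(
        n=x.size, bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd
    )
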