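"""Paired method-comparison statistics for volume measurements.

The battery mirrors standard agreement methodology for two measurement
methods observed on the same subjects:

* Lin's concordance correlation coefficient (CCC),

      rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2),

  with moment estimators using the n denominator, and a 95% CI from the
  Fisher z-transform with Lin's large-sample variance.  The CCC factors as
  rho_c = r * C_b where r is Pearson's correlation (precision) and
  C_b <= 1 a bias-correction factor (accuracy), so |rho_c| <= |r|.
* Bland-Altman analysis: mean difference, SD of differences (n-1
  denominator), and limits of agreement mean +/- z * SD (z = 1.96).
* Mean squared error of the paired differences, MSE = (1/n) sum d_i^2,
  identically dbar^2 + s^2 (n-1)/n; the n-1 variant is exposed alongside.
* Two-tailed paired t-test with a 95% CI for the mean difference.
* Shapiro-Wilk normality check of the differences (delegated to scipy).

Differences are oriented as (first-listed method) - (second); the
orientation is recorded in the labels.  Volumes are in cm^3.

The module is organised as a model/results pair: build a
:class:`MethodComparison` from the paired data, call :meth:`fit`, and read
everything off the returned :class:`AgreementResults` (or print its
``summary()``).  Free functions expose the individual statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateDataError",
    "PairedVolumes",
    "MethodComparison",
    "AgreementResults",
    "BlandAltman",
    "lins_ccc",
    "bland_altman",
    "mse_paired",
    "paired_t",
    "normality_check",
    "agreement_report",
    "t_from_confidence_interval",
    "loa_from_summary",
]


class DegenerateDataError(ValueError):
    """A statistic is undefined for the given data (e.g. both vectors
    constant, or zero-variance differences with nonzero mean)."""


@dataclass(frozen=True)
class PairedVolumes:
    """Same-length paired volume vectors from two methods, in cm^3."""

    x: np.ndarray
    y: np.ndarray
    labels: Tuple[str, str] = ("A", "B")

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.float64).ravel()
        y = np.asarray(self.y, dtype=np.float64).ravel()
        if x.shape != y.shape:
            raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
        if len(x) < 2:
            raise ValueError("paired comparison needs n >= 2")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("paired volumes must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def differences(self) -> np.ndarray:
        """d = x - y, first-listed method minus second."""
        return self.x - self.y

    def swapped(self) -> "PairedVolumes":
        return PairedVolumes(self.y, self.x, (self.labels[1], self.labels[0]))


def _as_paired(pv, y=None, labels=("A", "B")) -> PairedVolumes:
    if isinstance(pv, PairedVolumes):
        return pv
    return PairedVolumes(pv, y, labels)


# ---------------------------------------------------------------------------
# individual statistics
# ---------------------------------------------------------------------------


def lins_ccc(pv, y=None, labels=("A", "B"), alpha: float = 0.05):
    """Lin's concordance correlation coefficient with its (1-alpha) CI.

    Uses n-denominator moment estimators; the CI comes from the Fisher
    z-transform of rho_c with Lin's large-sample variance, back-transformed.
    Perfect agreement (|rho_c| = 1) degenerates the transform; the CI then
    collapses onto the point estimate.

    Returns ``(ccc, (lo, hi))``.
    """
    pv = _as_paired(pv, y, labels)
    if pv.n < 3:
        raise ValueError("CCC needs n >= 3")
    x, y_ = pv.x, pv.y
    n = pv.n
    sx2 = x.var()  # n denominator
    sy2 = y_.var()
    if sx2 == 0.0 and sy2 == 0.0:
        raise DegenerateDataError("CCC undefined: both vectors are constant")
    sxy = ((x - x.mean()) * (y_ - y_.mean())).mean()
    dmean = x.mean() - y_.mean()
    ccc = 2.0 * sxy / (sx2 + sy2 + dmean**2)

    # Lin's variance of the z-transformed estimate
    if sx2 == 0.0 or sy2 == 0.0:
        # Pearson r undefined; CI cannot be formed -> collapse (flagged)
        warnings.warn("one vector constant: CCC CI collapsed to the estimate")
        return float(ccc), (float(ccc), float(ccc))
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-12 or abs(r) >= 1.0 - 1e-12:
        return float(ccc), (float(ccc), float(ccc))
    u = dmean / (sx2 * sy2) ** 0.25
    one_m = 1.0 - ccc**2
    var_z = (
        (1.0 - r**2) * ccc**2 / (one_m * r**2)
        + 2.0 * ccc**3 * (1.0 - ccc) * u**2 / (r * one_m**2)
        - ccc**4 * u**4 / (2.0 * r**2 * one_m**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    z = np.arctanh(ccc)
    lo, hi = np.tanh(z - zq * np.sqrt(var_z)), np.tanh(z + zq * np.sqrt(var_z))
    return float(ccc), (float(lo), float(hi))


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman summary plus the per-subject points for plotting."""

    mean_diff: float
    sd_diff: float
    loa: Tuple[float, float]
    z: float
    means: np.ndarray
    diffs: np.ndarray
    labels: Tuple[str, str]


def bland_altman(pv, y=None, labels=("A", "B"), z: float = 1.96) -> BlandAltman:
    """Bland-Altman analysis of d = x - y.

    ``sd_diff`` uses the sample (n-1) denominator; the limits of agreement
    are ``mean_diff -/+ z * sd_diff``.  Also emits per-subject
    (mean, difference) pairs for the classic plot.
    """
    pv = _as_paired(pv, y, labels)
    d = pv.differences
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa=(mean_diff - z * sd_diff, mean_diff + z * sd_diff),
        z=z,
        means=0.5 * (pv.x + pv.y),
        diffs=d,
        labels=pv.labels,
    )


def loa_from_summary(mean_diff: float, sd_diff: float, z: float = 1.96) -> Tuple[float, float]:
    """Limits of agreement from published summary numbers alone."""
    return (mean_diff - z * sd_diff, mean_diff + z * sd_diff)


def mse_paired(pv, y=None, labels=("A", "B"), unbiased: bool = False) -> float:
    """Mean squared paired difference.

    Default is the n-denominator mean of squared differences,
    MSE = (1/n) sum d_i^2 = dbar^2 + s^2 (n-1)/n; ``unbiased=True`` divides
    the sum of squares by n-1 instead.
    """
    pv = _as_paired(pv, y, labels)
    d = pv.differences
    denom = pv.n - 1 if unbiased else pv.n
    return float(np.sum(d**2) / denom)


def paired_t(pv, y=None, labels=("A", "B"), alpha: float = 0.05):
    """Two-tailed paired t-test on d = x - y.

    Returns ``(t, df, p, (ci_lo, ci_hi))`` with the (1-alpha) CI for the
    mean difference, dbar +/- t_{1-alpha/2, n-1} * s / sqrt(n).
    """
    pv = _as_paired(pv, y, labels)
    d = pv.differences
    n = pv.n
    dbar = d.mean()
    s = d.std(ddof=1)
    df = n - 1
    if s == 0.0:
        if dbar != 0.0:
            raise DegenerateDataError(
                "paired t undefined: zero-variance differences with nonzero mean"
            )
        warnings.warn("all paired differences are identically zero; t set to 0")
        return 0.0, df, 1.0, (0.0, 0.0)
    se = s / np.sqrt(n)
    t = dbar / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tq = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t), int(df), float(p), (float(dbar - tq * se), float(dbar + tq * se))


def t_from_confidence_interval(mean_diff: float, ci: Sequence[float], n: int, alpha: float = 0.05) -> float:
    """Recover the paired t statistic from a published mean difference and
    its (1-alpha) confidence interval at sample size n.

    The CI half-width equals t_{1-alpha/2, n-1} * SE, so
    SE = half_width / t_crit and t = mean_diff / SE.  Useful for checking
    printed results arithmetic when only summaries are available.
    """
    lo, hi = float(ci[0]), float(ci[1])
    half = (hi - lo) / 2.0
    if half <= 0:
        raise ValueError("confidence interval must have positive width")
    tq = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    se = half / tq
    return float(mean_diff / se)


def normality_check(d, min_n: int = 3, max_n: int = 5000):
    """Shapiro-Wilk test of the differences; returns (W, p)."""
    d = np.asarray(d, dtype=np.float64).ravel()
    if not (min_n <= len(d) <= max_n):
        raise ValueError(f"Shapiro-Wilk supported for {min_n} <= n <= {max_n}, got {len(d)}")
    if np.ptp(d) == 0.0:
        raise DegenerateDataError("Shapiro-Wilk W undefined for a constant vector")
    w, p = stats.shapiro(d)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class MethodComparison:
    """Agreement model for two measurement methods on the same subjects.

    Parameters
    ----------
    x, y : array-like
        Paired volumes (cm^3); differences are oriented x - y.
    labels : (str, str)
        Method names, first for x.

    Examples
    --------
    >>> comp = MethodComparison(x, y, labels=("PDP", "VR-PS"))
    >>> res = comp.fit()
    >>> print(res.summary())
    """

    def __init__(self, x, y, labels=("A", "B")):
        self.data = _as_paired(x, y, labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, a: str, b: str) -> "MethodComparison":
        """Build from two columns of a cohort table."""
        return cls(df[a].to_numpy(), df[b].to_numpy(), labels=(a, b))

    def fit(self, z: float = 1.96, alpha: float = 0.05) -> "AgreementResults":
        """Compute the full battery and return an :class:`AgreementResults`."""
        pv = self.data
        if pv.n < 3:
            raise ValueError("agreement report needs n >= 3")
        ccc, ccc_ci = lins_ccc(pv, alpha=alpha)
        ba = bland_altman(pv, z=z)
        t, df, p, ci = paired_t(pv, alpha=alpha)
        d = pv.differences
        if np.ptp(d) == 0.0:
            shapiro_w = shapiro_p = float("nan")
        else:
            shapiro_w, shapiro_p = normality_check(d)
        x, y_ = pv.x, pv.y
        sx, sy = x.std(), y_.std()
        pearson = float(((x - x.mean()) * (y_ - y_.mean())).mean() / (sx * sy)) if sx > 0 and sy > 0 else float("nan")
        return AgreementResults(
            labels=pv.labels,
            n=pv.n,
            ccc=ccc,
            ccc_ci=ccc_ci,
            pearson_r=pearson,
            mean_diff=ba.mean_diff,
            sd_diff=ba.sd_diff,
            loa=ba.loa,
            loa_z=z,
            mse=mse_paired(pv),
            mse_unbiased=mse_paired(pv, unbiased=True),
            t_stat=t,
            df=df,
            p_value=p,
            mean_diff_ci=ci,
            shapiro_w=shapiro_w,
            shapiro_p=shapiro_p,
            ba_means=ba.means.tolist(),
            ba_diffs=ba.diffs.tolist(),
        )


@dataclass(frozen=True)
class AgreementResults:
    """Fitted agreement battery for one method pair.

    Invariants: ``loa[0] <= mean_diff <= loa[1]``; ``|ccc| <= 1`` and
    ``ccc_ci[0] <= ccc <= ccc_ci[1]``.  Differences are (labels[0] -
    labels[1]), in cm^3.
    """

    labels: Tuple[str, str]
    n: int
    ccc: float
    ccc_ci: Tuple[float, float]
    pearson_r: float
    mean_diff: float
    sd_diff: float
    loa: Tuple[float, float]
    loa_z: float
    mse: float
    mse_unbiased: float
    t_stat: float
    df: int
    p_value: float
    mean_diff_ci: Tuple[float, float]
    shapiro_w: float
    shapiro_p: float
    ba_means: list = field(default_factory=list, repr=False)
    ba_diffs: list = field(default_factory=list, repr=False)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["labels"] = list(self.labels)
        d["ccc_ci"] = list(self.ccc_ci)
        d["loa"] = list(self.loa)
        d["mean_diff_ci"] = list(self.mean_diff_ci)
        return d

    def to_json(self, path=None, **kwargs) -> Optional[str]:
        payload = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return payload
        with open(path, "w") as fh:
            fh.write(payload)
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementResults":
        d = dict(d)
        for key in ("labels", "ccc_ci", "loa", "mean_diff_ci"):
            d[key] = tuple(d[key])
        return cls(**d)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        a, b = self.labels
        lines = [
            f"Agreement: {a} vs {b} (n = {self.n}, differences = {a} - {b}, cm^3)",
            "-" * 64,
            f"  Lin's CCC            {self.ccc:8.4f}   95% CI ({self.ccc_ci[0]:.4f}, {self.ccc_ci[1]:.4f})",
            f"  Pearson r            {self.pearson_r:8.4f}",
            f"  mean difference      {self.mean_diff:8.3f}   95% CI ({self.mean_diff_ci[0]:.3f}, {self.mean_diff_ci[1]:.3f})",
            f"  SD of differences    {self.sd_diff:8.3f}",
            f"  limits of agreement  ({self.loa[0]:.3f}, {self.loa[1]:.3f})   [mean +/- {self.loa_z:.2f} SD]",
            f"  MSE (n denom)        {self.mse:8.3f}   (n-1 denom: {self.mse_unbiased:.3f})",
            f"  paired t             {self.t_stat:8.3f}   df = {self.df}, two-tailed p = {self.p_value:.4g}",
            f"  Shapiro-Wilk         W = {self.shapiro_w:.4f}, p = {self.shapiro_p:.4g}",
        ]
        return "\n".join(lines)

    def plot_bland_altman(self, ax=None):
        """Classic Bland-Altman plot: per-subject mean vs difference with
        the mean-difference line and limits of agreement."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        ax.scatter(self.ba_means, self.ba_diffs, s=24, alpha=0.8, edgecolor="k", linewidth=0.4)
        ax.axhline(self.mean_diff, color="C0", label=f"mean {self.mean_diff:.2f}")
        for lim in self.loa:
            ax.axhline(lim, color="C3", linestyle="--")
        ax.set_xlabel(f"mean of {self.labels[0]} and {self.labels[1]} (cm$^3$)")
        ax.set_ylabel(f"{self.labels[0]} - {self.labels[1]} (cm$^3$)")
        ax.set_title(f"Bland-Altman: {self.labels[0]} vs {self.labels[1]}")
        ax.legend(loc="best", fontsize=8)
        return ax


def agreement_report(pv, y=None, labels=("A", "B"), z: float = 1.96) -> AgreementResults:
    """One-call agreement battery; see :class:`MethodComparison`."""
    pv = _as_paired(pv, y, labels)
    return MethodComparison(pv.x, pv.y, pv.labels).fit(z=z)
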