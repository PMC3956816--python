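"""Densitometry statistics: precision, interobserver and cross-device analyses.

Long-term precision follows the Gluer root-mean-square convention: each
patient's visits give a sample SD (n-1 denominator, no detrending), and the
group precision is the RMS of those SDs - unweighted across patients by
default, since patients may contribute 3 or 4 visits.  The coefficient of
variation references the grand mean of the patient means.

Cross-device agreement is an ordinary least-squares regression of the
reference device on the test device (DXA ~ CTXA) with Pearson r and the
standard error of the estimate SEE = sqrt(RSS / (n - 2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError


@dataclass
class PrecisionResult:
    rms_sd: float  # g/cm2
    grand_mean: float  # g/cm2
    n_patients: int
    n_excluded: int = 0

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.rms_sd / self.grand_mean


@dataclass
class InterobserverResult:
    mean_obs1: float
    mean_obs2: float
    sd_obs1: float
    sd_obs2: float
    n: int
    t: float
    p: float
    paired: bool

    @property
    def mean_difference(self) -> float:
        return self.mean_obs2 - self.mean_obs1

    @property
    def percent_difference(self) -> float:
        """Absolute difference as a percentage of the observer-1 mean."""
        return 100.0 * abs(self.mean_difference) / self.mean_obs1


@dataclass
class RegressionResult:
    slope: float
    intercept: float  # g/cm2
    pearson_r: float
    see: float  # g/cm2
    n: int


@dataclass
class WelchResult:
    t: float
    df: float  # Satterthwaite
    p: float


@dataclass
class NormalityResult:
    a2: float  # Anderson-Darling A^2, mean and variance estimated
    a2_adjusted: float  # small-sample adjusted A^2*
    critical_5pct: float
    n: int

    @property
    def reject(self) -> bool:
        return self.a2_adjusted > self.critical_5pct


def _patient_groups(series) -> dict:
    """Normalise input to {patient_id: array of visit BMDs}.

    Accepts a mapping, a DataFrame with (patient_id, bmd) columns, or an
    iterable of per-patient sequences.
    """
    if isinstance(series, pd.DataFrame):
        return {pid: g["bmd"].to_numpy(float) for pid, g in series.groupby("patient_id")}
    if isinstance(series, dict):
        return {k: np.asarray(v, float) for k, v in series.items()}
    return {i: np.asarray(v, float) for i, v in enumerate(series)}


def rms_precision(series, df_weighted: bool = False, on_short: str = "warn") -> PrecisionResult:
    """Long-term RMS precision of a longitudinal BMD series.

    Per-patient sample SDs are combined as sqrt(mean of variances); with
    ``df_weighted`` the mean is weighted by each patient's degrees of
    freedom (n_i - 1) instead.  Patients with fewer than two visits are
    excluded with a warning (``on_short='error'`` raises).
    """
    groups = _patient_groups(series)
    variances, weights, means = [], [], []
    n_excluded = 0
    for pid, vals in groups.items():
        if len(vals) < 2:
            if on_short == "error":
                raise ValueError(f"patient {pid!r} has fewer than two visits")
            n_excluded += 1
            continue
        variances.append(np.var(vals, ddof=1))
        weights.append(len(vals) - 1)
        means.append(vals.mean())
    if len(variances) < 2:
        raise ValueError("need at least two patients with >=2 visits")
    variances = np.asarray(variances)
    if df_weighted:
        w = np.asarray(weights, float)
        mean_var = float((variances * w).sum() / w.sum())
    else:
        mean_var = float(variances.mean())
    return PrecisionResult(
        rms_sd=float(np.sqrt(mean_var)),
        grand_mean=float(np.mean(means)),
        n_patients=len(variances),
        n_excluded=n_excluded,
    )


def interobserver_compare(obs1, obs2, paired: bool = True) -> InterobserverResult:
    """Compare two observers' re-analyses of the same studies.

    Defaults to a paired two-tailed t-test (the natural choice when both
    observers analyse the same scans); an unpaired Welch test is available
    for unmatched designs.
    """
    a = np.asarray(obs1, float)
    b = np.asarray(obs2, float)
    if a.shape != b.shape:
        raise ValueError(f"observer series differ in length ({a.size} vs {b.size})")
    if a.size < 3:
        raise ValueError("need at least three pairs")
    if paired:
        d = b - a
        if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
            t, p = 0.0, 1.0  # identical re-analyses: no evidence of difference
        else:
            t, p = stats.ttest_rel(b, a)
    else:
        res = welch_t(b, a)
        t, p = res.t, res.p
    return InterobserverResult(
        mean_obs1=float(a.mean()), mean_obs2=float(b.mean()),
        sd_obs1=float(a.std(ddof=1)), sd_obs2=float(b.std(ddof=1)),
        n=a.size, t=float(t), p=float(p), paired=paired,
    )


def regress_with_see(x, y) -> RegressionResult:
    """OLS of y on x (reference ~ test device) with Pearson r and SEE."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x has zero variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    see = float(np.sqrt((resid**2).sum() / (n - 2)))
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue), see=see, n=n,
    )


def welch_t(group_a, group_b) -> WelchResult:
    """Two-sample t-test assuming unequal variances (Satterthwaite df)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        raise DegenerateFitError("both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


#: 5% critical value for the adjusted Anderson-Darling statistic when mean
#: and variance are estimated from the sample (case 3)
AD_CRITICAL_5PCT = 0.752


def anderson_darling_normality(x) -> NormalityResult:
    """Anderson-Darling normality test with estimated mean and variance.

    Uses the case-3 statistic with the standard small-sample adjustment
    A2* = A2 (1 + 0.75/n + 2.25/n^2) and the 5% critical value 0.752.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 8:
        raise ValueError("need at least eight observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateFitError("constant sample: normality test undefined")
    z = np.sort((x - x.mean()) / sd)
    cdf = stats.norm.cdf(z)
    eps = np.finfo(float).tiny
    logf = np.log(np.clip(cdf, eps, 1.0))
    logr = np.log(np.clip(1.0 - cdf[::-1], eps, 1.0))
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (logf + logr)) / n
    a2_adj = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    return NormalityResult(float(a2), float(a2_adj), AD_CRITICAL_5PCT, n)


def t_score(bmd: float, young_mean: float, young_sd: float) -> float:
    """Standardised BMD against a user-supplied young-normal reference.

    No reference population ships with the package; supply the mean and SD
    appropriate to the device and ROI.
    """
    if young_sd <= 0:
        raise ValueError("young-normal SD must be positive")
    return (bmd - young_mean) / young_sd


# ---------------------------------------------------------------------------
# CSV schemas (UTF-8, '.' decimal, header row)

def load_longitudinal_csv(path) -> pd.DataFrame:
    """Columns: patient_id, visit, bmd (g/cm2)."""
    df = pd.read_csv(path)
    _require(df, {"patient_id", "visit", "bmd"}, path)
    return df


def load_paired_csv(path) -> pd.DataFrame:
    """Columns: study_id, obs1, obs2 (g/cm2)."""
    df = pd.read_csv(path)
    _require(df, {"study_id", "obs1", "obs2"}, path)
    return df


def load_crossdevice_csv(path) -> pd.DataFrame:
    """Columns: subject_id, ctxa, dxa (g/cm2) and optional site."""
    df = pd.read_csv(path)
    _require(df, {"subject_id", "ctxa", "dxa"}, path)
    return df


def _require(df: pd.DataFrame, cols: set, path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
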