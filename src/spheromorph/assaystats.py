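"""Assay-QC statistics for plate-based viability readouts.

This layer holds the statistics used to compare viability assays and to
validate a luminescence readout against spheroid biomass:

* the coefficient of variation (CV = 100·SD/mean, sample SD with the n−1
  denominator), the reproducibility metric for both spheroid-size
  populations and assay replicates;
* Jarque–Bera and Lilliefors normality tests, applied as a *gate* before
  the two-tailed unpaired Student t-test (normality is verified first; a
  failing gate is a refusal, not a silent nonparametric fallback);
* the volume ↔ equivalent-diameter conversion d = (6V/π)^(1/3) linking
  volumetric categories (mm³) to diameters (μm);
* a replicate-design linearity assessment: least-squares line plus a
  lack-of-fit F-test (deviation of category means from the line against
  pure replicate error), operationalizing "deviance from linearity".

All Monte-Carlo p-values are seeded and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .images import SpheromorphError

__all__ = [
    "StatsError",
    "TestResult",
    "cv",
    "cv_from_moments",
    "jarque_bera",
    "lilliefors",
    "t_test_unpaired",
    "volume_to_diameter",
    "diameter_to_volume",
    "round_to_nearest",
    "LinearityResult",
    "linearity_assessment",
    "assay_summary",
]


class StatsError(SpheromorphError):
    pass


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value and provenance."""

    statistic: float
    pvalue: float
    n: tuple[int, ...]
    method: str
    null_reference: str
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------

def cv_from_moments(mean: float, sd: float) -> float:
    """CV in percent from a printed mean ± SD, reported to one decimal."""
    if mean == 0:
        raise StatsError("undefined CV: mean is zero")
    return round(100.0 * sd / mean, 1)


def cv(values) -> float:
    """Sample CV in percent (SD with n−1 denominator), to one decimal."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("need at least 2 values for a sample CV")
    m = float(x.mean())
    if m == 0:
        raise StatsError("undefined CV: mean is zero")
    return round(100.0 * float(x.std(ddof=1)) / m, 1)


# ---------------------------------------------------------------------------
# normality tests
# ---------------------------------------------------------------------------

def _skew_kurt(x: np.ndarray) -> tuple[float, float]:
    """Biased sample skewness S and (Pearson, non-excess) kurtosis K."""
    m = x.mean()
    d = x - m
    m2 = float((d**2).mean())
    if m2 == 0:
        raise StatsError("degenerate sample: zero variance")
    s = float((d**3).mean()) / m2**1.5
    k = float((d**4).mean()) / m2**2
    return s, k


def jarque_bera(values) -> TestResult:
    """Jarque–Bera normality test: JB = n/6·(S² + (K−3)²/4), χ²(2) reference."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise StatsError("jarque_bera requires n >= 8")
    s, k = _skew_kurt(x)
    jb = x.size / 6.0 * (s * s + (k - 3.0) ** 2 / 4.0)
    p = float(stats.chi2.sf(jb, df=2))
    return TestResult(
        statistic=float(jb),
        pvalue=p,
        n=(int(x.size),),
        method="jarque_bera",
        null_reference="chi2(2)",
        extras={"skewness": s, "kurtosis": k},
    )


def _lilliefors_stat(x: np.ndarray) -> float:
    """KS distance between the ECDF and a normal with estimated moments."""
    n = x.size
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("degenerate sample: zero variance")
    z = np.sort((x - mu) / sd)
    cdf = stats.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


def lilliefors(values, mc_reps: int = 10_000, seed: int = 0) -> TestResult:
    """Lilliefors normality test with a seeded Monte-Carlo p-value.

    The statistic is the KS distance to a normal with parameters estimated
    from the data; its null distribution is parameter-free, so the p-value
    is the fraction of ``mc_reps`` standard-normal resamples of the same
    size whose statistic is at least the observed one (add-one estimator).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise StatsError("lilliefors requires n >= 5")
    d_obs = _lilliefors_stat(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(mc_reps):
        d = _lilliefors_stat(rng.standard_normal(x.size))
        if d >= d_obs:
            exceed += 1
    p = (exceed + 1) / (mc_reps + 1)
    return TestResult(
        statistic=d_obs,
        pvalue=float(p),
        n=(int(x.size),),
        method="lilliefors",
        null_reference=f"monte_carlo({mc_reps})",
        extras={"seed": seed},
    )


# ---------------------------------------------------------------------------
# t-test with normality gate
# ---------------------------------------------------------------------------

def t_test_unpaired(
    a,
    b,
    check_normality: bool = True,
    welch: bool = False,
    alpha_gate: float = 0.05,
    gate_mc_reps: int = 2000,
    gate_seed: int = 0,
) -> TestResult:
    """Two-tailed unpaired Student t-test with a normality gate.

    Both groups must pass Jarque–Bera *and* Lilliefors at ``alpha_gate``
    before the test runs (matching the verify-normality-then-t workflow);
    pass ``check_normality=False`` to override. ``welch=True`` switches
    from the pooled-variance Student form to Welch's unequal-variance form.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise StatsError("both groups need n >= 2")
    if check_normality:
        for name, x in (("a", xa), ("b", xb)):
            gates = []
            if x.size >= 8:
                gates.append(("jarque_bera", jarque_bera(x).pvalue))
            if x.size >= 5:
                gates.append(
                    ("lilliefors", lilliefors(x, mc_reps=gate_mc_reps, seed=gate_seed).pvalue)
                )
            for gate, p in gates:
                if p < alpha_gate:
                    raise StatsError(
                        f"normality gate failed for group {name} "
                        f"({gate} p = {p:.4g}); pass check_normality=False to override"
                    )
    na, nb = xa.size, xb.size
    ma, mb = xa.mean(), xb.mean()
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            if ma == mb:
                return TestResult(0.0, 1.0, (na, nb), "welch_t", "t", {})
            raise StatsError("degenerate variance")
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        method = "welch_t"
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0:
            if ma == mb:
                return TestResult(0.0, 1.0, (na, nb), "student_t_pooled", "t", {})
            raise StatsError("degenerate variance")
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
        method = "student_t_pooled"
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(
        statistic=float(t),
        pvalue=min(1.0, p),
        n=(int(na), int(nb)),
        method=method,
        null_reference=f"t({df:.4g})",
        extras={"df": float(df)},
    )


# ---------------------------------------------------------------------------
# volume <-> diameter
# ---------------------------------------------------------------------------

def volume_to_diameter(volume_mm3: float) -> float:
    """Equivalent diameter (μm) of a sphere of the given volume (mm³)."""
    if volume_mm3 <= 0:
        raise StatsError("volume must be positive")
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0) * 1000.0


def diameter_to_volume(diameter_um: float) -> float:
    """Sphere volume (mm³) for an equivalent diameter (μm)."""
    if diameter_um <= 0:
        raise StatsError("diameter must be positive")
    return math.pi / 6.0 * (diameter_um / 1000.0) ** 3


def round_to_nearest(x: float, step: float = 50.0) -> float:
    """Round to the nearest multiple of ``step`` (ties away from zero)."""
    return step * math.floor(x / step + 0.5)


# ---------------------------------------------------------------------------
# linearity with lack-of-fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearityResult:
    """Least-squares line plus the replicate-design lack-of-fit F-test."""

    slope: float
    intercept: float
    f_statistic: float
    pvalue: float
    ss_lack_of_fit: float
    ss_pure_error: float
    df_lack_of_fit: int
    df_pure_error: int
    category_means: pd.Series

    @property
    def test(self) -> TestResult:
        return TestResult(
            statistic=self.f_statistic,
            pvalue=self.pvalue,
            n=(self.df_lack_of_fit + 2, self.df_pure_error),
            method="lack_of_fit_F",
            null_reference=f"F({self.df_lack_of_fit}, {self.df_pure_error})",
        )


def linearity_assessment(table: pd.DataFrame, x: str = "category", y: str = "value") -> LinearityResult:
    """Fit readout vs. category and test for deviance from linearity.

    ``table`` is long-format with a numeric category column (e.g. volume in
    mm³) and a readout column, ≥ 3 distinct categories and ≥ 2 replicates
    per category. The pure-error sum of squares comes from within-category
    replicate spread; the lack-of-fit F compares the category means'
    deviation from the fitted line against it:
    ``F = (SS_lof/(k−2)) / (SS_pe/(n−k))`` with reference F(k−2, n−k).
    """
    df = table[[x, y]].dropna()
    cats = df.groupby(x)[y]
    k = cats.ngroups
    if k < 3:
        raise StatsError("need at least 3 categories")
    counts = cats.count()
    if (counts < 2).any():
        raise StatsError("no pure-error estimate: a category has < 2 replicates")
    n = len(df)
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    slope, intercept = np.polyfit(xv, yv, 1)
    means = cats.mean()
    fitted_at_cat = slope * means.index.to_numpy(dtype=float) + intercept
    ss_lof = float((counts.to_numpy() * (means.to_numpy() - fitted_at_cat) ** 2).sum())
    group_mean = df.groupby(x)[y].transform("mean").to_numpy()
    ss_pe = float(((yv - group_mean) ** 2).sum())
    df_lof, df_pe = k - 2, n - k
    if ss_pe == 0:
        f_stat = math.inf if ss_lof > 1e-12 else 0.0
        p = 0.0 if ss_lof > 1e-12 else 1.0
    else:
        f_stat = (ss_lof / df_lof) / (ss_pe / df_pe)
        p = float(stats.f.sf(f_stat, df_lof, df_pe))
    return LinearityResult(
        slope=float(slope),
        intercept=float(intercept),
        f_statistic=float(f_stat),
        pvalue=p,
        ss_lack_of_fit=ss_lof,
        ss_pure_error=ss_pe,
        df_lack_of_fit=df_lof,
        df_pure_error=df_pe,
        category_means=means,
    )


# ---------------------------------------------------------------------------
# per-condition summaries
# ---------------------------------------------------------------------------

def assay_summary(
    table: pd.DataFrame,
    condition: str = "condition",
    value: str = "value",
    control: str | None = "CTR",
) -> tuple[pd.DataFrame, float]:
    """Per-condition mean, SD, CV and percent-of-control, plus average CV.

    The across-condition "average CV" is the unweighted mean of the
    per-condition CVs. If the control label is missing the
    percent-of-control column is omitted with a printed warning.
    """
    g = table.groupby(condition)[value]
    out = pd.DataFrame(
        {
            "n": g.count(),
            "mean": g.mean(),
            "sd": g.std(ddof=1),
        }
    )
    out["cv_percent"] = (100.0 * out["sd"] / out["mean"]).round(1)
    avg_cv = float(out["cv_percent"].mean())
    if control is not None and control in out.index:
        ctrl_mean = out.loc[control, "mean"]
        out["percent_of_control"] = 100.0 * out["mean"] / ctrl_mean
    elif control is not None:
        import warnings as _warnings

        _warnings.warn(f"control condition {control!r} not found; percent-of-control omitted")
    return out, avg_cv
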