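"""Reliability and cohort statistics for syndesmosis measurements.

Implements the validation statistics used for the measurement protocol:

* ICC(2,1): two-way random-effects, absolute-agreement, single-measurement
  intraclass correlation with its exact F-based 95% confidence interval
  (McGraw & Wong form, see :func:`icc_2_1`);
* RMS-SD precision: the root mean square of per-subject standard deviations
  over repeated measurements, ``RMS-SD = sqrt(sum(SD_i^2) / N)``;
* ANCOVA of sex differences with body height as covariate (ordinary least
  squares via statsmodels);
* classic paired t-tests for between-modality comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    """Raised when a statistic is undefined for the given data."""


@dataclass
class RaterTable:
    """Measurements as subjects x raters (x sessions), in mm.

    Missing cells are disallowed; at least two subjects and two raters.
    """

    values: np.ndarray
    parameter: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            pass
        elif self.values.ndim != 3:
            raise ValueError("values must be 2-D or 3-D "
                             "(subjects x raters [x sessions])")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need >= 2 subjects and >= 2 raters")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not allowed")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @property
    def n_sessions(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[2]

    def session(self, s: int = 0) -> np.ndarray:
        """2-D (subjects x raters) slice of one session."""
        return self.values if self.values.ndim == 2 else self.values[:, :, s]

    def to_tidy(self) -> pd.DataFrame:
        v = self.values if self.values.ndim == 3 else self.values[:, :, None]
        n, k, s = v.shape
        idx = np.indices((n, k, s))
        return pd.DataFrame({
            "subject": idx[0].ravel(), "rater": idx[1].ravel(),
            "session": idx[2].ravel(), "value": v.ravel(),
            "parameter": self.parameter, "modality": self.modality})

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, parameter: str = "",
                  modality: str = "") -> "RaterTable":
        if parameter:
            df = df[df["parameter"] == parameter]
        if modality:
            df = df[df["modality"] == modality]
        wide = df.pivot_table(index="subject", columns=["rater", "session"],
                              values="value")
        if wide.isna().any().any():
            raise ValueError("missing cells are not allowed")
        raters = sorted({r for r, _ in wide.columns})
        sessions = sorted({s for _, s in wide.columns})
        arr = np.stack([np.stack([wide[(r, s)].to_numpy()
                                  for s in sessions], axis=-1)
                        for r in raters], axis=1)
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        return cls(arr, parameter=parameter, modality=modality)


@dataclass
class ReliabilityReport:
    """ICC(2,1) with 95% CI, plus RMS-SD precision figures."""

    icc: float
    ci95: tuple[float, float]
    n: int
    k: int
    rms_sd: dict[str, float] = field(default_factory=dict)
    parameter: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.icc <= hi + 1e-12):
            raise ValueError("confidence interval must contain the estimate")


@dataclass
class CohortTable:
    """Per-subject parameter values with sex and body height (m)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"value", "sex", "height"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if (self.df["height"] <= 0).any():
            raise ValueError("heights must be positive")
        if self.df["sex"].nunique() > 2:
            raise ValueError("sex must be binary-coded")


def _anova_two_way(data: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows, columns, residual) of an n x k two-way layout."""
    n, k = data.shape
    grand = data.mean()
    rows = data.mean(axis=1)
    cols = data.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = data - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_2_1(table: RaterTable, session: int = 0,
            confidence: float = 0.95) -> ReliabilityReport:
    """ICC(2,1): absolute agreement, two-way random, single measurement.

    ``ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` from the
    two-way ANOVA decomposition.  The confidence interval is the exact
    F-based construction for this form: the lower bound uses
    ``F = F(1-alpha/2; n-1, v)`` with the Satterthwaite degrees of freedom
    ``v = (a MSC + b MSE)^2 / ((a MSC)^2/(k-1) + (b MSE)^2/((n-1)(k-1)))``
    where ``a = k ICC / (n (1-ICC))`` and ``b = 1 + k ICC (n-1)/(n (1-ICC))``,
    and the upper bound swaps the F degrees of freedom.
    """
    data = table.session(session)
    n, k = data.shape
    if np.ptp(data) == 0:
        raise StatsError("ICC undefined: table has zero total variance")
    msr, msc, mse = _anova_two_way(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise StatsError("ICC undefined: degenerate variance decomposition")
    icc = (msr - mse) / denom
    alpha = 1.0 - confidence
    if mse <= 1e-300 and msc <= 1e-300:
        ci = (1.0, 1.0)  # perfect agreement
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if not np.isfinite(a):
            ci = (1.0, 1.0)
        else:
            b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
            v = ((a * msc + b * mse) ** 2
                 / ((a * msc) ** 2 / (k - 1)
                    + (b * mse) ** 2 / ((n - 1) * (k - 1))))
            f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower = (n * (msr - f_lo * mse)
                     / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr))
            upper = (n * (f_hi * msr - mse)
                     / (k * msc + (k * n - k - n) * mse + n * f_hi * msr))
            ci = (float(min(lower, icc)), float(max(upper, icc)))
    return ReliabilityReport(icc=float(icc), ci95=ci, n=n, k=k,
                             parameter=table.parameter,
                             modality=table.modality)


def rms_sd(table: RaterTable, mode: str = "inter",
           rater_pair: tuple[int, int] = (0, 1),
           rater: int = 0) -> float:
    """Root mean square of per-subject SDs (sample SD, n-1 denominator).

    ``mode="inter"``: SD across the designated rater pair (one session).
    ``mode="intra"``: SD across sessions for one rater (needs >= 2 sessions).
    """
    if mode == "inter":
        data = table.session(0)[:, list(rater_pair)]
    elif mode == "intra":
        if table.n_sessions < 2:
            raise StatsError("intra-rater RMS-SD needs >= 2 sessions "
                             "(repeat measurements)")
        data = table.values[:, rater, :]
    else:
        raise ValueError("mode must be 'inter' or 'intra'")
    if data.shape[1] < 2:
        raise StatsError("RMS-SD needs >= 2 repeats per subject")
    sd = np.std(data, axis=1, ddof=1)
    return float(np.sqrt(np.mean(sd ** 2)))


@dataclass
class AncovaResult:
    f_stat: float
    p_value: float
    sex_effect: float            # difference of adjusted means
    adjusted_means: dict[str, float]
    slope_height: float
    n: int


def ancova_sex(cohort: CohortTable | pd.DataFrame,
               parameter: str | None = None) -> AncovaResult:
    """ANCOVA of a parameter on sex with body height as covariate.

    Fits ``value ~ sex + height`` by OLS, F-tests the sex term, and reports
    sex-adjusted means evaluated at the grand-mean height.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    if parameter is not None and "parameter" in df.columns:
        df = df[df["parameter"] == parameter]
    df = df[["value", "sex", "height"]].copy()
    levels = sorted(df["sex"].unique())
    if len(levels) < 2:
        raise StatsError("ANCOVA needs both sexes present")
    if np.ptp(df["height"].to_numpy(dtype=float)) == 0:
        raise StatsError("rank-deficient design: covariate 'height' is "
                         "constant")
    model = smf.ols("value ~ C(sex) + height", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_stat = float(table.loc["C(sex)", "F"])
    p_value = float(table.loc["C(sex)", "PR(>F)"])
    hbar = float(df["height"].mean())
    pred = model.predict(pd.DataFrame({"sex": levels,
                                       "height": [hbar, hbar]}))
    adjusted = {str(s): float(v) for s, v in zip(levels, pred)}
    slope = float(model.params["height"])
    effect = adjusted[str(levels[1])] - adjusted[str(levels[0])]
    return AncovaResult(f_stat=f_stat, p_value=p_value, sex_effect=effect,
                        adjusted_means=adjusted, slope_height=slope,
                        n=len(df))


def paired_t(x, y) -> tuple[float, float]:
    """Classic paired t-test on ``x - y``; two-sided p.

    Zero-variance differences are reported exactly instead of failing:
    identical samples give ``(0, 1)``; a constant nonzero difference gives
    ``(+-inf, 0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length 1-D samples, n >= 2")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(d)))):  # constant diffs
        sd = 0.0
    if sd == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    t = float(np.mean(d) / (sd / np.sqrt(len(d))))
    p = float(2.0 * sps.t.sf(abs(t), len(d) - 1))
    return t, p


def apply_bonferroni(p_values: dict[str, float]) -> dict[str, float]:
    """Optional multiple-testing correction (off by default, as in the
    measurement protocol)."""
    m = len(p_values)
    return {k: min(1.0, v * m) for k, v in p_values.items()}
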