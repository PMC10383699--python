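"""Three-tier method-agreement statistics for device validation.

For each device/parameter/velocity-stratum cell the analysis reports:

1. Pearson's correlation coefficient with a 95 % Fisher (inverse hyperbolic
   tangent) confidence interval;
2. an ordinary-least-products (OLP, also called geometric-mean or reduced
   major axis) calibration equation, appropriate because both the criterion
   and the device carry random measurement error:
   ``slope = sign(r) * SD(y) / SD(x)``, ``intercept = mean(y) - slope * mean(x)``,
   with confidence limits ``slope * (sqrt(B + 1) +/- sqrt(B))`` where
   ``B = t^2 (1 - r^2) / (n - 2)``;
3. the standard error of the estimate (SEE) from the residuals of the OLP
   calibration, with ``SEE% = 100 * SEE / mean(criterion)``.

Bias is flagged when the calibration interval excludes the identity line
(slope CI excluding 1 -> proportional bias; intercept CI excluding 0 ->
fixed bias).  Correlations are labelled large / very large / extremely
large at 0.5 / 0.7 / 0.9, and precision high / moderate / low at SEE
0.1 and 0.3 m/s.

`OLPRegression` packages the whole analysis as a scikit-learn style
estimator (criterion as X, device as y); the module-level functions are
thin wrappers kept for composability.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator, RegressorMixin

from .pairing import PairedObservation, PARAMETERS, STRATA

R_THRESHOLDS = ((0.9, "extremely large"), (0.7, "very large"), (0.5, "large"))
SEE_HIGH = 0.1   # m/s, below: high precision
SEE_LOW = 0.3    # m/s, above: low precision
MIN_N = 4


@dataclass
class OlpFit:
    """One calibration analysis (one device/parameter/stratum cell)."""

    n: int
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    r: float
    r_ci: tuple[float, float]
    see: float
    see_pct: float
    proportional_bias: bool
    fixed_bias: bool
    r_label: str
    precision_label: str

    def as_row(self) -> dict:
        d = asdict(self)
        for key in ("slope_ci", "intercept_ci", "r_ci"):
            lo, hi = d.pop(key)
            d[key.replace("_ci", "_lo")] = lo
            d[key.replace("_ci", "_hi")] = hi
        return d


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(x) < MIN_N:
        raise ValueError(f"need at least {MIN_N} paired observations, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    return x, y


def pearson_with_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Pearson r with a Fisher-transform confidence interval.

    The interval is ``tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3))``; it
    collapses to the point estimate when |r| = 1.
    """
    x, y = _validate_xy(x, y)
    r = float(sp_stats.pearsonr(x, y).statistic)
    ci = fisher_ci(r, len(x), alpha)
    return r, ci


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = sp_stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def olp_fit(x, y) -> tuple[float, float]:
    """Ordinary-least-products (geometric mean) slope and intercept."""
    x, y = _validate_xy(x, y)
    r = float(sp_stats.pearsonr(x, y).statistic)
    if r == 0:
        raise ValueError("r = 0: OLP slope sign is undefined")
    slope = float(np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(np.mean(y) - slope * np.mean(x))
    return slope, intercept


def olp_confidence_limits(
    x, y, slope: float, alpha: float = 0.05
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Confidence limits for the OLP slope and intercept.

    ``B = t^2 (1 - r^2) / (n - 2)`` with the two-sided Student quantile at
    ``alpha`` on n − 2 degrees of freedom; slope limits are
    ``slope * (sqrt(B + 1) -/+ sqrt(B))`` and each intercept limit pairs
    with the opposite slope limit through the centroid.
    """
    x, y = _validate_xy(x, y)
    n = len(x)
    r = float(sp_stats.pearsonr(x, y).statistic)
    t = sp_stats.t.ppf(1 - alpha / 2, n - 2)
    B = t * t * (1 - r * r) / (n - 2)
    lo = slope * (np.sqrt(B + 1) - np.sqrt(B))
    hi = slope * (np.sqrt(B + 1) + np.sqrt(B))
    slope_ci = tuple(sorted((float(lo), float(hi))))
    xbar, ybar = float(np.mean(x)), float(np.mean(y))
    int_a = ybar - slope_ci[1] * xbar
    int_b = ybar - slope_ci[0] * xbar
    return slope_ci, tuple(sorted((int_a, int_b)))


def see_from_olp(
    x, y, slope: float, intercept: float, residuals: str = "vertical"
) -> tuple[float, float]:
    """Standard error of the estimate around the OLP calibration line.

    Vertical residuals with n − 2 degrees of freedom by default; the
    perpendicular-distance variant divides residuals by sqrt(1 + slope^2).
    ``SEE%`` is referenced to the mean criterion value.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if n <= 2:
        raise ValueError("SEE needs more than 2 observations")
    res = y - intercept - slope * x
    if residuals == "perpendicular":
        res = res / np.sqrt(1 + slope * slope)
    elif residuals != "vertical":
        raise ValueError("residuals must be 'vertical' or 'perpendicular'")
    see = float(np.sqrt(np.sum(res**2) / (n - 2)))
    return see, float(100.0 * see / np.mean(x))


def bias_flags(
    slope_ci: tuple[float, float], intercept_ci: tuple[float, float]
) -> tuple[bool, bool]:
    """(proportional, fixed) bias: calibration CI excludes the identity line."""
    proportional = not (slope_ci[0] <= 1.0 <= slope_ci[1])
    fixed = not (intercept_ci[0] <= 0.0 <= intercept_ci[1])
    return proportional, fixed


def interpret(r: float, see: float) -> tuple[str, str]:
    """Magnitude label for r and precision label for the SEE."""
    r_label = "not large"
    for threshold, label in R_THRESHOLDS:
        if r >= threshold:
            r_label = label
            break
    if see < SEE_HIGH:
        precision = "high"
    elif see <= SEE_LOW:
        precision = "moderate"
    else:
        precision = "low"
    return r_label, precision


class OLPRegression(BaseEstimator, RegressorMixin):
    """Ordinary-least-products calibration with agreement statistics.

    Fit with the criterion measurements as ``X`` (shape ``(n,)`` or
    ``(n, 1)``) and the device measurements as ``y``.  After fitting, the
    full three-tier summary is available through the fitted attributes and
    :meth:`fit_summary`.

    Parameters
    ----------
    alpha : float
        Two-sided confidence level for every interval (default 0.05).
    residuals : {"vertical", "perpendicular"}
        Residual convention for the SEE.

    Attributes
    ----------
    slope_, intercept_ : float
        OLP calibration line (device = intercept_ + slope_ * criterion).
    slope_ci_, intercept_ci_, r_, r_ci_, see_, see_pct_ : agreement stats.
    proportional_bias_, fixed_bias_ : bool
    r_label_, precision_label_ : str
    n_ : int
    """

    def __init__(self, alpha: float = 0.05, residuals: str = "vertical") -> None:
        self.alpha = alpha
        self.residuals = residuals

    def fit(self, X, y) -> "OLPRegression":
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("OLPRegression is univariate; X must be (n,) or (n, 1)")
            x = x[:, 0]
        x, y = _validate_xy(x, y)
        self.n_ = len(x)
        self.r_, self.r_ci_ = pearson_with_ci(x, y, self.alpha)
        self.slope_, self.intercept_ = olp_fit(x, y)
        self.slope_ci_, self.intercept_ci_ = olp_confidence_limits(
            x, y, self.slope_, self.alpha
        )
        self.see_, self.see_pct_ = see_from_olp(
            x, y, self.slope_, self.intercept_, self.residuals
        )
        self.proportional_bias_, self.fixed_bias_ = bias_flags(
            self.slope_ci_, self.intercept_ci_
        )
        self.r_label_, self.precision_label_ = interpret(self.r_, self.see_)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.intercept_ + self.slope_ * x

    def fit_summary(self) -> OlpFit:
        return OlpFit(
            n=self.n_,
            slope=self.slope_,
            slope_ci=self.slope_ci_,
            intercept=self.intercept_,
            intercept_ci=self.intercept_ci_,
            r=self.r_,
            r_ci=self.r_ci_,
            see=self.see_,
            see_pct=self.see_pct_,
            proportional_bias=self.proportional_bias_,
            fixed_bias=self.fixed_bias_,
            r_label=self.r_label_,
            precision_label=self.precision_label_,
        )


def three_tier_report(
    observations: list[PairedObservation],
    alpha: float = 0.05,
    residuals: str = "vertical",
    min_n: int = MIN_N,
) -> pd.DataFrame:
    """One OLP analysis per (device, parameter, stratum).

    Strata are ``total`` (all repetitions), ``fast`` and ``slow`` by the
    criterion concentric duration.  Cells with fewer than ``min_n`` pairs
    are reported as not estimable rather than dropped.
    """
    devices = sorted({o.device for o in observations})
    rows = []
    for device in devices:
        for parameter in PARAMETERS:
            for stratum in STRATA:
                sel = [
                    o
                    for o in observations
                    if o.device == device
                    and o.parameter == parameter
                    and (stratum == "total" or o.spectrum == stratum)
                ]
                base = {"device": device, "parameter": parameter,
                        "stratum": stratum, "n": len(sel), "estimable": False}
                if len(sel) >= min_n:
                    x = np.array([o.criterion_value for o in sel])
                    y = np.array([o.device_value for o in sel])
                    try:
                        fit = OLPRegression(alpha=alpha, residuals=residuals).fit(x, y)
                    except ValueError:
                        rows.append(base)
                        continue
                    base.update(fit.fit_summary().as_row(), estimable=True)
                rows.append(base)
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Text table: one point-estimate line plus one bracketed CI line per cell."""
    lines = []
    header = f"{'Device':<14}{'Param':<8}{'Stratum':<9}{'n':>5}  " \
             f"{'Slope':>16}{'Intercept':>18}{'SEE (m/s, %)':>16}{'r':>16}"
    lines.append(header)
    lines.append("-" * len(header))
    for _, row in report.iterrows():
        if not row.get("estimable", False):
            lines.append(
                f"{row['device']:<14}{row['parameter']:<8}{row['stratum']:<9}"
                f"{row['n']:>5}  not estimable (n < {MIN_N})"
            )
            continue
        lines.append(
            f"{row['device']:<14}{row['parameter']:<8}{row['stratum']:<9}{row['n']:>5}  "
            f"{row['slope']:>16.3f}{row['intercept']:>18.3f}"
            f"{row['see']:>16.3f}{row['r']:>16.3f}"
        )
        lines.append(
            f"{'':<36}{'':>5}  "
            f"{f'[{row.slope_lo:.3f}, {row.slope_hi:.3f}]':>16}"
            f"{f'[{row.intercept_lo:.3f}, {row.intercept_hi:.3f}]':>18}"
            f"{f'{row.see_pct:.1f}%':>16}"
            f"{f'[{row.r_lo:.3f}, {row.r_hi:.3f}]':>16}"
        )
    return "\n".join(lines)


def plot_report(report: pd.DataFrame, path: str) -> None:
    """Bar plots of r and SEE per parameter and stratum, with the 0.9 / 0.1
    reference lines the interpretation thresholds imply."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = report[report["estimable"] == True]  # noqa: E712
    devices = sorted(est["device"].unique())
    fig, axes = plt.subplots(2, len(PARAMETERS), figsize=(4 * len(PARAMETERS), 7),
                             squeeze=False)
    width = 0.8 / max(len(devices), 1)
    for j, parameter in enumerate(PARAMETERS):
        for row_i, (field, ref, label) in enumerate(
            (("r", 0.9, "correlation coefficient r"), ("see", 0.1, "SEE (m/s)"))
        ):
            ax = axes[row_i][j]
            for k, device in enumerate(devices):
                sub = est[(est["device"] == device) & (est["parameter"] == parameter)]
                xs = [STRATA.index(s) + k * width for s in sub["stratum"]]
                ax.bar(xs, sub[field], width=width, label=device)
            ax.axhline(ref, linestyle=":", color="k", linewidth=1)
            ax.set_xticks([i + width * (len(devices) - 1) / 2 for i in range(len(STRATA))])
            ax.set_xticklabels(STRATA)
            ax.set_title(f"{parameter} — {label}", fontsize=10)
            if row_i == 0:
                ax.set_ylim(0, 1.05)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
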