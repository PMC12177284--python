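"""Candidate-form curve fitting and before/after-rainfall ANCOVA.

Uptake-potential (or uptake-water-content) relationships are fitted to
three predefined families — linear y = a + b x, power y = a |x|^b, and
exponential y = a exp(b x) — and the best form is the one with the
highest coefficient of determination among forms whose shape coefficient
b is significant at 0.05.  (R^2 is always computed on the original y
scale so the forms are comparable.)

Before/after-rainfall differences are tested by ANCOVA on the (possibly
transformed) covariate: equality of slopes via the group-by-covariate
interaction, then equality of intercepts given a common slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.optimize import curve_fit

FORMS = ("linear", "power", "exponential")


@dataclass(frozen=True)
class CurveFit:
    form: str
    params: tuple  # (a, b): intercept/scale and slope/shape
    r2: float
    p_value: float  # significance of the slope/shape coefficient b
    n: int
    group: str = "pooled"

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        a, b = self.params
        if self.form == "linear":
            out = a + b * x
        elif self.form == "power":
            out = a * np.abs(x) ** b
        elif self.form == "exponential":
            out = a * np.exp(b * x)
        else:  # pragma: no cover
            raise ValueError(f"unknown form {self.form!r}")
        return out if out.ndim else float(out)

    def __call__(self, x):
        return self.predict(x)


@dataclass
class CandidateFits:
    fits: list[CurveFit] = field(default_factory=list)
    best: CurveFit | None = None
    reason: str = ""


def _r2_original(y, yhat) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def _slope_p(x, y) -> float:
    res = sps.linregress(x, y)
    return float(res.pvalue)


def _fit_linear(x, y, group):
    res = sps.linregress(x, y)
    fit = CurveFit(
        form="linear",
        params=(float(res.intercept), float(res.slope)),
        r2=_r2_original(y, res.intercept + res.slope * x),
        p_value=float(res.pvalue),
        n=len(x),
        group=group,
    )
    return fit


def _fit_loglinear(x, y, form, group, refine=True):
    """Power/exponential by log-linear regression, optional NLS refinement.

    Power uses log|x| as covariate (sign handling: the model is in |x|);
    exponential uses x.  Requires all y > 0 — callers fall back to direct
    nonlinear least squares otherwise.
    """
    ly = np.log(y)
    cov = np.log(np.abs(x)) if form == "power" else x
    res = sps.linregress(cov, ly)
    a, b = float(np.exp(res.intercept)), float(res.slope)
    pval = float(res.pvalue)
    if refine:
        model = (
            (lambda xx, aa, bb: aa * np.abs(xx) ** bb)
            if form == "power"
            else (lambda xx, aa, bb: aa * np.exp(bb * xx))
        )
        try:
            (a, b), _ = curve_fit(model, x, y, p0=[a, b], maxfev=200)
        except RuntimeError:
            pass  # keep the log-linear estimate
    fit = CurveFit(
        form=form,
        params=(a, b),
        r2=_r2_original(y, CurveFit(form, (a, b), 0, 1, 0).predict(x)),
        p_value=pval,
        n=len(x),
        group=group,
    )
    return fit


def _fit_nls(x, y, form, group):
    model = (
        (lambda xx, aa, bb: aa * np.abs(xx) ** bb)
        if form == "power"
        else (lambda xx, aa, bb: aa * np.exp(bb * xx))
    )
    p0 = [np.sign(np.mean(y)) * max(abs(np.mean(y)), 1e-6), 0.5]
    (a, b), pcov = curve_fit(model, x, y, p0=p0, maxfev=5000)
    se_b = float(np.sqrt(pcov[1, 1]))
    dof = len(x) - 2
    tstat = b / se_b if se_b > 0 else np.inf
    pval = float(2 * sps.t.sf(abs(tstat), dof)) if dof > 0 else 1.0
    fit = CurveFit(
        form=form,
        params=(float(a), float(b)),
        r2=_r2_original(y, model(x, a, b)),
        p_value=pval,
        n=len(x),
        group=group,
    )
    return fit


def fit_candidates(
    x, y, forms=FORMS, group: str = "pooled", alpha: float = 0.05
) -> CandidateFits:
    """Fit each candidate form and select the best.

    Best = highest R^2 (original scale) among forms whose slope/shape
    coefficient is significant at ``alpha``.  All fits and their
    diagnostics are retained.  Requires n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        return CandidateFits(reason=f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CandidateFits(reason="degenerate: zero span in x or y")
    out = CandidateFits()
    for form in forms:
        try:
            if form == "linear":
                fit = _fit_linear(x, y, group)
            elif form in ("power", "exponential"):
                if np.all(y > 0) and (form == "exponential" or np.all(x != 0)):
                    fit = _fit_loglinear(x, y, form, group)
                else:
                    fit = _fit_nls(x, y, form, group)
            else:
                raise ValueError(f"unknown form {form!r}")
        except (RuntimeError, ValueError):
            continue
        if np.isfinite(fit.r2):
            out.fits.append(fit)
    significant = [f for f in out.fits if f.p_value < alpha]
    if significant:
        out.best = max(significant, key=lambda f: f.r2)
    elif not out.fits:
        out.reason = "all candidate fits degenerate"
    else:
        out.reason = f"no form significant at {alpha}"
    return out


@dataclass(frozen=True)
class AncovaResult:
    interaction_p: float  # equality-of-slopes test
    slope_contrast: float  # slope(B) - slope(A) on the working scale
    intercept_p: float  # equality of intercepts given a common slope
    intercept_contrast: float
    n_a: int
    n_b: int
    range_overlap: bool  # False -> contrasts involve extrapolation


def _working_scale(x, y, form):
    if form == "linear":
        return np.asarray(x, float), np.asarray(y, float)
    if form == "power":
        return np.log(np.abs(x)), np.log(y)
    if form == "exponential":
        return np.asarray(x, float), np.log(y)
    raise ValueError(f"unknown form {form!r}")


def ancova_compare(group_a, group_b, form: str = "linear") -> AncovaResult:
    """ANCOVA comparing two (x, y) groups on the form's working scale.

    ``group_a``/``group_b`` are (x, y) pairs of arrays.  Power and
    exponential forms are compared on their log-linearizing scales (all
    y > 0 required there).  A disjoint covariate range triggers a warning
    flag rather than an error.
    """
    xa, ya = _working_scale(*group_a, form)
    xb, yb = _working_scale(*group_b, form)
    if min(xa.size, xb.size) < 3:
        raise ValueError("each group needs n >= 3")
    overlap = (max(xa.min(), xb.min()) <= min(xa.max(), xb.max()))
    if not overlap:
        warnings.warn("covariate ranges do not overlap; contrasts extrapolate")
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    X_int = sm.add_constant(np.column_stack([x, g, x * g]))
    fit_int = sm.OLS(y, X_int).fit()
    interaction_p = float(fit_int.pvalues[3])
    slope_contrast = float(fit_int.params[3])
    X_add = sm.add_constant(np.column_stack([x, g]))
    fit_add = sm.OLS(y, X_add).fit()
    return AncovaResult(
        interaction_p=interaction_p,
        slope_contrast=slope_contrast,
        intercept_p=float(fit_add.pvalues[2]),
        intercept_contrast=float(fit_add.params[2]),
        n_a=int(xa.size),
        n_b=int(xb.size),
        range_overlap=bool(overlap),
    )


def split_by_rain(table: pd.DataFrame, split, date_col: str = "date"):
    """Partition a dated table into (before, after) at a rainfall date.

    The split day itself goes to the "after" group.  An empty side
    raises a warning, not an error.
    """
    split_day = pd.Timestamp(split).date()
    dates = pd.to_datetime(table[date_col]).dt.date
    before = table[dates < split_day]
    after = table[dates >= split_day]
    if before.empty or after.empty:
        warnings.warn(
            f"rain split at {split_day} leaves an empty group "
            f"({len(before)} before, {len(after)} after)"
        )
    return before, after
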