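"""Continuous benchmark-dose modelling with lognormal residuals.

The candidate set is the nested exponential family (five members) plus the
Hill model, the standard suite for continuous dose-response data:

* exp1:  y = a                                   (null)
* exp2:  y = a * exp(b*x)
* exp3:  y = a * exp(b*x**d)
* exp4:  y = a * (c - (c-1)*exp(-b*x))
* exp5:  y = a * (c - (c-1)*exp(-b*x**d))
* hill:  y = a * (1 + (c-1)*x**d / (k**d + x**d))

Responses are treated as lognormally distributed, so fitting is normal
maximum likelihood on log responses with a profiled residual SD.  The
benchmark dose (BMD) is the dose producing a benchmark response (BMR,
default 5%) relative change from the fitted background f(0); its lower and
upper confidence bounds (BMDL/BMDU, default one-sided 95% each) come from
the profile likelihood, re-fitting the nuisance parameters with the BMD
pinned and locating the deviance rise at the chi-square(1) critical value
of a 90% two-sided interval.

Model selection follows the conservative rule: among models with an
adequate fit (log-likelihood within the chi-square criterion of the best
family member and AIC within 2 of the minimum) the lowest BMDL is chosen;
if only the null model fits, the verdict is "no dose-response".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseDataset",
    "FitResult",
    "BMDResult",
    "MODELS",
    "fit_model",
    "fit_all",
    "bmd_from_fit",
    "bmdl_profile",
    "select_model",
    "apply_adjustment",
    "compare_reference",
]

MODELS = ("exp1", "exp2", "exp3", "exp4", "exp5", "hill")

#: chi-square(1) critical value for a 90% two-sided profile interval,
#: giving one-sided 95% BMDL/BMDU bounds.
_PROFILE_CRIT = stats.chi2.ppf(0.90, 1)


@dataclass
class DoseResponseDataset:
    """Doses (Intake or ExposedDW) vs fold-induction responses."""

    dose: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.dose.shape != self.response.shape:
            raise ValueError("dose and response lengths differ")
        if len(self.dose) < 4:
            raise ValueError("need at least 4 dose points")
        if np.any(self.dose < 0) or np.any(np.diff(np.unique(self.dose)) <= 0):
            raise ValueError("doses must be non-negative")
        if np.any(self.response <= 0):
            raise ValueError("responses must be positive (lognormal support)")

    @property
    def increasing(self) -> bool:
        """Direction of the data trend (log-linear regression sign)."""
        slope = np.polyfit(self.dose, np.log(self.response), 1)[0]
        return bool(slope >= 0)


def _predict(model: str, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if model == "exp1":
        (a,) = theta
        return np.full_like(x, a)
    if model == "exp2":
        a, b = theta
        return a * np.exp(b * x)
    if model == "exp3":
        a, b, d = theta
        return a * np.exp(b * x**d)
    if model == "exp4":
        a, b, c = theta
        return a * (c - (c - 1.0) * np.exp(-b * x))
    if model == "exp5":
        a, b, c, d = theta
        return a * (c - (c - 1.0) * np.exp(-b * x**d))
    if model == "hill":
        a, k, c, d = theta
        return a * (1.0 + (c - 1.0) * x**d / (k**d + x**d))
    raise ValueError(f"unknown model {model!r}")


def _n_params(model: str) -> int:
    return {"exp1": 1, "exp2": 2, "exp3": 3, "exp4": 3, "exp5": 4, "hill": 4}[model]


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model."""

    model: str
    theta: np.ndarray
    loglik: float
    sigma: float                # profiled residual log-SD
    converged: bool
    data: DoseResponseDataset
    adequate: bool | None = None
    bmd: float | None = None
    bmdl: float | None = None
    bmdu: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * (_n_params(self.model) + 1) - 2.0 * self.loglik

    def predict(self, x) -> np.ndarray:
        return _predict(self.model, self.theta, x)


def _loglik_from_rss(rss: float, n: int, logy_sum: float) -> tuple[float, float]:
    """Profile the residual SD out of the lognormal likelihood."""
    sigma2 = max(rss / n, 1e-12)
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0) - logy_sum
    return ll, math.sqrt(sigma2)


def _rss(model: str, theta: np.ndarray, data: DoseResponseDataset) -> float:
    pred = _predict(model, theta, data.dose)
    if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
        return np.inf
    r = np.log(data.response) - np.log(pred)
    return float(r @ r)


def _initial_guesses(model: str, data: DoseResponseDataset) -> list[np.ndarray]:
    y = data.response
    x = data.dose
    a0 = float(y[x == x.min()].mean())
    top = float(y[x == x.max()].mean())
    c0 = max(top / a0, 1e-3) if a0 > 0 else 1.0
    xs = x[x > 0]
    xmid = float(np.median(xs)) if len(xs) else 1.0
    b_lin = np.polyfit(x, np.log(y), 1)[0]
    guesses = {
        "exp1": [[np.exp(np.mean(np.log(y)))]],
        "exp2": [[a0, b_lin], [a0, b_lin * 2], [a0, b_lin / 2 if b_lin else 1e-3]],
        "exp3": [[a0, b_lin, 1.0], [a0, b_lin / xmid, 2.0], [a0, b_lin, 0.5]],
        "exp4": [[a0, 1.0 / xmid, c0], [a0, 0.1 / xmid, c0], [a0, 3.0 / xmid, c0]],
        "exp5": [
            [a0, 1.0 / xmid, c0, 1.0],
            [a0, 1.0 / xmid**2, c0, 2.0],
            [a0, 0.3 / xmid, c0, 0.7],
        ],
        "hill": [
            [a0, xmid, c0, 1.0],
            [a0, xmid, c0, 2.0],
            [a0, xmid / 3, c0, 1.5],
            [a0, 3 * xmid, c0, 0.8],
        ],
    }[model]
    return [np.asarray(g, dtype=float) for g in guesses]


def fit_model(data: DoseResponseDataset, model: str) -> FitResult:
    """Maximum-likelihood fit under lognormal residuals (multi-start)."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    n = len(data.dose)
    logy_sum = float(np.sum(np.log(data.response)))

    if model == "exp1":
        a_hat = math.exp(float(np.mean(np.log(data.response))))
        theta = np.array([a_hat])
        ll, sigma = _loglik_from_rss(_rss(model, theta, data), n, logy_sum)
        return FitResult(model, theta, ll, sigma, True, data)

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for guess in _initial_guesses(model, data):
            res = optimize.minimize(
                lambda th: _rss(model, th, data),
                guess,
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
    converged = bool(best is not None and np.isfinite(best.fun))
    theta = best.x if converged else np.asarray(_initial_guesses(model, data)[0])
    ll, sigma = _loglik_from_rss(
        _rss(model, theta, data) if converged else np.inf, n, logy_sum
    )
    out = FitResult(model, theta, ll, sigma, converged, data)
    if not converged:
        out.flags.append("non-convergence")
    return out


def bmd_from_fit(fit: FitResult, bmr: float = 0.05, increasing: bool | None = None) -> float | None:
    """Smallest dose with a ``bmr`` relative change from the background f(0).

    Closed forms where the family admits them, bracketed root otherwise;
    ``None`` (with a flag) when the fitted curve never changes by the BMR
    within the dose range.
    """
    if increasing is None:
        increasing = fit.data.increasing
    ratio = 1.0 + bmr if increasing else 1.0 - bmr
    model, th = fit.model, fit.theta
    if model == "exp1":
        fit.flags.append("BMD undefined for the null model")
        return None
    if model == "exp2":
        b = th[1]
        if b == 0 or (b > 0) != increasing:
            fit.flags.append("trend inconsistent with BMR direction")
            return None
        return math.log(ratio) / b
    if model == "exp3":
        b, d = th[1], th[2]
        if b == 0 or (b > 0) != increasing or d <= 0:
            fit.flags.append("trend inconsistent with BMR direction")
            return None
        return (math.log(ratio) / b) ** (1.0 / d)
    if model in ("exp4", "exp5"):
        c = th[2]
        arg = (c - ratio) / (c - 1.0) if c != 1.0 else -1.0
        if not 0.0 < arg < 1.0:
            fit.flags.append("asymptote closer than the BMR")
            return None
        b = th[1]
        inner = -math.log(arg) / b
        if inner <= 0:
            return None
        return inner if model == "exp4" else inner ** (1.0 / th[3])
    if model == "hill":
        k, c, d = th[1], th[2], th[3]
        delta = ratio - 1.0
        denom = (c - 1.0) - delta
        if (c - 1.0) == 0 or denom == 0 or (delta / denom) <= 0:
            fit.flags.append("asymptote closer than the BMR")
            return None
        u = delta / denom
        return k * u ** (1.0 / d)
    return None


def _profile_nll(
    model: str, bmd: float, data: DoseResponseDataset, bmr: float,
    increasing: bool, theta_hat: np.ndarray,
) -> float:
    """Min -loglik with the BMD pinned (b eliminated analytically)."""
    ratio = 1.0 + bmr if increasing else 1.0 - bmr
    n = len(data.dose)
    logy_sum = float(np.sum(np.log(data.response)))

    def b_of(nuisance: np.ndarray) -> np.ndarray | None:
        # returns full theta with b expressed from the pinned BMD
        if model == "exp2":
            b = math.log(ratio) / bmd
            return np.array([nuisance[0], b])
        if model == "exp3":
            d = nuisance[1]
            if d <= 0:
                return None
            b = math.log(ratio) / bmd**d
            return np.array([nuisance[0], b, d])
        if model in ("exp4", "exp5"):
            c = nuisance[1]
            arg = (c - ratio) / (c - 1.0) if c != 1.0 else -1.0
            if not 0.0 < arg < 1.0:
                return None
            if model == "exp4":
                b = -math.log(arg) / bmd
                return np.array([nuisance[0], b, c])
            d = nuisance[2]
            if d <= 0:
                return None
            b = -math.log(arg) / bmd**d
            return np.array([nuisance[0], b, c, d])
        if model == "hill":
            c, d = nuisance[1], nuisance[2]
            delta = ratio - 1.0
            denom = (c - 1.0) - delta
            if denom == 0 or (delta / denom) <= 0 or d <= 0:
                return None
            k = bmd * (delta / denom) ** (-1.0 / d)
            return np.array([nuisance[0], k, c, d])
        return None

    def nll(nuisance: np.ndarray) -> float:
        theta = b_of(nuisance)
        if theta is None:
            return np.inf
        rss = _rss(model, theta, data)
        if not np.isfinite(rss):
            return np.inf
        return -_loglik_from_rss(rss, n, logy_sum)[0]

    if model == "exp2":
        # a profiles out analytically on the log scale
        b = math.log(ratio) / bmd
        r = np.log(data.response) - b * data.dose
        a = math.exp(float(np.mean(r)))
        return nll(np.array([a]))
    idx = {"exp3": [0, 2], "exp4": [0, 2], "exp5": [0, 2, 3], "hill": [0, 2, 3]}[model]
    start = theta_hat[idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            nll, start, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-10},
        )
    return float(res.fun)


def bmdl_profile(
    fit: FitResult,
    bmr: float = 0.05,
    crit: float = _PROFILE_CRIT,
    increasing: bool | None = None,
) -> tuple[float | None, float | None]:
    """Profile-likelihood (BMDL, BMDU) for a converged fit.

    The bound is where the deviance ``2*(nll_profile - nll_hat)`` reaches
    the chi-square(1) critical value; if the profile never brackets the
    rise before the search floor/ceiling (10^-4 and 10^3 times the BMD),
    the bound is set to that edge and flagged.
    """
    if increasing is None:
        increasing = fit.data.increasing
    bmd = fit.bmd if fit.bmd is not None else bmd_from_fit(fit, bmr, increasing)
    if bmd is None or not fit.converged:
        return None, None
    nll_hat = -fit.loglik

    def deviance(candidate: float) -> float:
        nll = _profile_nll(fit.model, candidate, fit.data, bmr, increasing, fit.theta)
        return 2.0 * (nll - nll_hat) - crit

    def search(direction: int) -> float:
        factor = 0.7 if direction < 0 else 1.0 / 0.7
        limit = bmd * (1e-4 if direction < 0 else 1e3)
        prev = bmd
        cand = bmd * factor
        for _ in range(60):
            if (direction < 0 and cand < limit) or (direction > 0 and cand > limit):
                fit.flags.append(
                    f"profile bound hit the search edge ({'lower' if direction < 0 else 'upper'})"
                )
                return limit
            if deviance(cand) > 0:
                lo, hi = (cand, prev) if direction < 0 else (prev, cand)
                return float(optimize.brentq(deviance, lo, hi, xtol=1e-12, rtol=1e-8))
            prev = cand
            cand *= factor
        return limit

    bmdl = search(-1)
    bmdu = search(+1)
    return bmdl, bmdu


def fit_all(
    data: DoseResponseDataset,
    bmr: float = 0.05,
    models: tuple[str, ...] = MODELS,
) -> list[FitResult]:
    """Fit every candidate model and attach BMD/BMDL/BMDU."""
    fits = []
    for model in models:
        fit = fit_model(data, model)
        if fit.converged:
            fit.bmd = bmd_from_fit(fit, bmr)
            if fit.bmd is not None:
                fit.bmdl, fit.bmdu = bmdl_profile(fit, bmr)
        fits.append(fit)
    return fits


@dataclass
class BMDResult:
    """Per-model table plus the conservative selection."""

    fits: list[FitResult]
    selected: str | None
    selected_bmdl: float | None
    verdict: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": f.model,
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "converged": f.converged,
                    "adequate": f.adequate,
                    "bmd": f.bmd,
                    "bmdl": f.bmdl,
                    "bmdu": f.bmdu,
                    "flags": "; ".join(f.flags),
                }
                for f in self.fits
            ]
        )


def select_model(fits: list[FitResult], aic_slack: float = 2.0) -> BMDResult:
    """Conservative selection: lowest BMDL among adequately fitting models.

    Adequacy: the model's log-likelihood is within the chi-square
    likelihood-ratio criterion of the best candidate (df = parameter-count
    difference) and its AIC is within ``aic_slack`` of the minimum.  If no
    model with a defined BMD is adequate the verdict is "no dose-response".
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        return BMDResult(fits, None, None, "no converged model")
    best = max(usable, key=lambda f: f.loglik)
    min_aic = min(f.aic for f in usable)
    for f in usable:
        df = max(_n_params(best.model) - _n_params(f.model), 1)
        lr_ok = 2.0 * (best.loglik - f.loglik) <= stats.chi2.ppf(0.95, df)
        f.adequate = bool(lr_ok and f.aic <= min_aic + aic_slack)
    # if the flat model already fits adequately there is no dose-response
    null = next((f for f in usable if f.model == "exp1"), None)
    if null is not None and null.adequate:
        return BMDResult(fits, None, None, "no dose-response")
    candidates = [f for f in usable if f.adequate and f.bmdl is not None]
    if not candidates:
        return BMDResult(fits, None, None, "no dose-response")
    chosen = min(candidates, key=lambda f: f.bmdl)
    return BMDResult(fits, chosen.model, chosen.bmdl, "selected")


def apply_adjustment(bmdl: float, factor: float) -> float:
    """Divide a BMDL by an uncertainty/adjustment factor (>= 1)."""
    if factor < 1.0:
        raise ValueError("adjustment factor must be >= 1")
    return bmdl / factor


def compare_reference(value: float, reference: float, fold: bool = False) -> float:
    """Ratio to a reference value (``fold=True`` gives reference/value)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return reference / value if fold else value / reference
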