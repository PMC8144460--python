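"""Bayesian calibration of the sensitive PBK parameters.

Serum biomonitoring observations are linked to model predictions through a
multiplicative lognormal error model: an observed serum concentration y at
a prediction m contributes a lognormal log-density with log-mean log(m) and
log-SD sigma.  The calibrated parameters keep their truncated priors; the
error SD gets a weakly informative half-normal prior and is estimated
jointly.

Sampling is component-wise Metropolis on each parameter's own scale (log
scale for lognormal priors), with per-component proposal scales adapted
during burn-in toward a 20-40% acceptance rate.  Because the transporter
capacity enters the model only through a product (Vmax x RAF x protein
content), the posterior has ridge directions that pure component moves
traverse slowly; each sweep therefore also makes one joint multivariate
normal move whose covariance is adapted from the burn-in history.  All
adaptation is frozen after burn-in so the retained chain satisfies
detailed balance.  Convergence is summarised by the split-chain
Gelman-Rubin statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qivive.priors import DistributionSpec, PriorSet

__all__ = [
    "BiomonitoringData",
    "PosteriorSample",
    "log_likelihood",
    "run_mcmc",
    "credible_band",
    "csaf_quantile_ratio",
    "gelman_rubin",
    "MCMCError",
]

BIOMONITORING_COLUMNS = ("group", "exposed_dw_ugL", "time_h", "serum_ugL")


class MCMCError(RuntimeError):
    """Sampler pathology (e.g. all proposals rejected)."""


def validate_biomonitoring(data: pd.DataFrame) -> pd.DataFrame:
    missing = set(BIOMONITORING_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"biomonitoring table missing columns {sorted(missing)}")
    if (data["serum_ugL"] <= 0).any():
        raise ValueError("serum concentrations must be positive (lognormal support)")
    return data


#: alias used in type hints below; a validated biomonitoring table
BiomonitoringData = pd.DataFrame


def log_likelihood(predicted, observed, error_sd: float) -> float:
    """Lognormal error-model log likelihood.

    ``sum log LN(y | log m, sigma)`` over observations; any non-positive
    prediction yields -inf (the proposal is rejected).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if error_sd <= 0:
        return -math.inf
    if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
        return -math.inf
    z = (np.log(obs) - np.log(pred)) / error_sd
    return float(
        -0.5 * np.sum(z**2)
        - obs.size * math.log(error_sd)
        - np.sum(np.log(obs))
        - 0.5 * obs.size * math.log(2.0 * math.pi)
    )


# -- internal: per-parameter transforms -------------------------------------

def _to_internal(spec: DistributionSpec, x: float) -> float:
    return math.log(x) if spec.family == "lognormal" else x


def _to_natural(spec: DistributionSpec, z: float) -> float:
    return math.exp(z) if spec.family == "lognormal" else z


def _log_prior_internal(spec: DistributionSpec, z: float) -> float:
    """Log prior density on the internal (sampling) scale.

    For lognormal specs the internal coordinate is log(x), whose prior is
    the truncated normal itself, so no Jacobian is needed.
    """
    if not spec.lower <= z <= spec.upper:
        return -math.inf
    if spec.family == "uniform":
        return -math.log(spec.upper - spec.lower)
    return -0.5 * ((z - spec.location) / spec.spread) ** 2 - math.log(spec.spread)


@dataclass
class PosteriorSample:
    """Retained MCMC draws with diagnostics."""

    draws: pd.DataFrame              # columns: params + error_sd + log_post + chain + iteration
    rhat: dict[str, float]
    acceptance: dict[str, float]
    param_names: list[str] = field(default_factory=list)

    def parameter_matrix(self) -> pd.DataFrame:
        return self.draws[self.param_names]

    def summary(self) -> pd.DataFrame:
        """Median and 95% credible interval per parameter (posterior-summary layout)."""
        rows = []
        for name in [*self.param_names, "error_sd"]:
            med, lo, hi = np.percentile(self.draws[name], [50, 2.5, 97.5])
            rows.append(
                {"parameter": name, "median": med, "q2.5": lo, "q97.5": hi,
                 "rhat": self.rhat.get(name, np.nan)}
            )
        return pd.DataFrame(rows)

    def map_row(self) -> pd.Series:
        """Highest-posterior retained draw (the joint 'mode fit')."""
        return self.draws.loc[self.draws["log_post"].idxmax()]

    def correlations(self, threshold: float = 0.3) -> pd.DataFrame:
        """Posterior correlation pairs with |r| above ``threshold``."""
        corr = self.parameter_matrix().corr()
        rows = []
        names = list(corr.columns)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r = corr.loc[a, b]
                if abs(r) >= threshold:
                    rows.append({"param_a": a, "param_b": b, "r": r})
        return pd.DataFrame(rows, columns=["param_a", "param_b", "r"])


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half,
    giving at least four sequences even from two chains.
    """
    chains = np.asarray(chains, dtype=float)
    half = chains.shape[1] // 2
    seqs = np.vstack([chains[:, :half], chains[:, half: 2 * half]])
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def run_mcmc(
    priors: PriorSet,
    data: pd.DataFrame,
    predict,
    iterations: int = 2500,
    chains: int = 2,
    seed: int = 0,
    error_sd_prior_scale: float = 1.0,
    burn_in_fraction: float = 0.5,
    initial_step: float = 0.25,
    target_acceptance: tuple[float, float] = (0.2, 0.4),
    thin: int = 1,
) -> PosteriorSample:
    """Component-wise Metropolis calibration against biomonitoring data.

    ``predict(params: dict) -> array`` returns model serum predictions
    aligned with ``data`` rows.  Proposals are Gaussian on each parameter's
    internal scale, bounded by the prior truncation; step sizes adapt every
    50 iterations during burn-in and are frozen afterwards.  Draws after
    burn-in are pooled over chains.
    """
    if chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    validate_biomonitoring(data)
    specs = list(priors)
    names = [s.name for s in specs]
    observed = data["serum_ugL"].to_numpy()
    rng = np.random.default_rng(seed)
    burn = int(burn_in_fraction * iterations)

    def log_post(z: np.ndarray, log_sd: float) -> float:
        lp = 0.0
        for spec, zj in zip(specs, z):
            lp += _log_prior_internal(spec, zj)
            if not math.isfinite(lp):
                return -math.inf
        sd = math.exp(log_sd)
        # half-normal prior on sd, with the log-parameterisation Jacobian
        lp += -0.5 * (sd / error_sd_prior_scale) ** 2 + log_sd
        params = {s.name: _to_natural(s, zj) for s, zj in zip(specs, z)}
        return lp + log_likelihood(predict(params), observed, sd)

    all_rows = []
    rhat_chains: dict[str, list[np.ndarray]] = {n: [] for n in [*names, "error_sd"]}
    acc_total: dict[str, list[float]] = {n: [] for n in [*names, "error_sd"]}
    for chain in range(chains):
        # overdispersed start: random prior quantile per chain
        z = np.array(
            [
                _to_internal(s, _quantile_natural(s, rng.uniform(0.2, 0.8)))
                for s in specs
            ]
        )
        z = np.array([_to_internal_clip(s, zj) for s, zj in zip(specs, z)])
        log_sd = math.log(0.3)
        steps = np.array(
            [
                initial_step * (s.upper - s.lower) if s.family == "uniform"
                else initial_step * (s.spread if s.spread else 1.0)
                for s in specs
            ]
        )
        sd_step = 0.3
        lp = log_post(z, log_sd)
        if not math.isfinite(lp):
            z = np.array([_to_internal(s, s.central()) for s in specs])
            lp = log_post(z, log_sd)
        accepted = np.zeros(len(specs) + 1)
        proposed = np.zeros(len(specs) + 1)
        window_acc = np.zeros(len(specs) + 1)
        window_n = np.zeros(len(specs) + 1)
        kept = {n: [] for n in [*names, "error_sd"]}
        kept_lp = []
        d = len(specs)
        joint_scale = 2.38**2 / d
        joint_chol: np.ndarray | None = None
        history: list[np.ndarray] = []
        for it in range(iterations):
            for j in range(len(specs)):
                z_new = z.copy()
                z_new[j] += rng.normal(0.0, steps[j])
                lp_new = log_post(z_new, log_sd)
                proposed[j] += 1
                window_n[j] += 1
                if math.log(rng.uniform()) < lp_new - lp:
                    z, lp = z_new, lp_new
                    accepted[j] += 1
                    window_acc[j] += 1
            log_sd_new = log_sd + rng.normal(0.0, sd_step)
            lp_new = log_post(z, log_sd_new)
            proposed[-1] += 1
            window_n[-1] += 1
            if math.log(rng.uniform()) < lp_new - lp:
                log_sd, lp = log_sd_new, lp_new
                accepted[-1] += 1
                window_acc[-1] += 1
            # one joint move per sweep along the adapted covariance, to mix
            # ridge directions that component moves traverse slowly
            if joint_chol is not None:
                z_new = z + joint_chol @ rng.standard_normal(d)
                lp_new = log_post(z_new, log_sd)
                if math.log(rng.uniform()) < lp_new - lp:
                    z, lp = z_new, lp_new
            if it < burn:
                history.append(z.copy())
                if it + 1 >= 200 and (it + 1) % 100 == 0:
                    cov = np.cov(np.array(history[-1000:]), rowvar=False)
                    cov = joint_scale * (cov + 1e-12 * np.eye(d))
                    try:
                        joint_chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        joint_chol = None
            if it < burn and (it + 1) % 50 == 0:
                rates = window_acc / np.maximum(window_n, 1)
                lo_t, hi_t = target_acceptance
                factors = np.where(rates < lo_t, 0.7, np.where(rates > hi_t, 1.4, 1.0))
                steps *= factors[:-1]
                sd_step *= factors[-1]
                window_acc[:] = 0.0
                window_n[:] = 0.0
            if it >= burn and (it - burn) % thin == 0:
                for s, zj in zip(specs, z):
                    kept[s.name].append(_to_natural(s, zj))
                kept["error_sd"].append(math.exp(log_sd))
                kept_lp.append(lp)
        if accepted.sum() == 0:
            raise MCMCError(
                "all proposals rejected; proposal scales are pathological"
            )
        frame = pd.DataFrame(kept)
        frame["log_post"] = kept_lp
        frame["chain"] = chain
        frame["iteration"] = np.arange(len(frame))
        all_rows.append(frame)
        for n in rhat_chains:
            rhat_chains[n].append(frame[n].to_numpy())
        for idx, n in enumerate([*names, "error_sd"]):
            acc_total[n].append(accepted[idx] / max(proposed[idx], 1))

    draws = pd.concat(all_rows, ignore_index=True)
    rhat = {n: gelman_rubin(np.vstack(v)) for n, v in rhat_chains.items()}
    acceptance = {n: float(np.mean(v)) for n, v in acc_total.items()}
    return PosteriorSample(draws, rhat, acceptance, names)


def _quantile_natural(spec: DistributionSpec, p: float) -> float:
    from qivive.priors import quantile_truncated

    return quantile_truncated(spec, p)


def _to_internal_clip(spec: DistributionSpec, z: float) -> float:
    return min(max(z, spec.lower), spec.upper)


def credible_band(
    posterior: PosteriorSample,
    predict_curve,
    time_grid: np.ndarray,
    max_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Pointwise 95% credible band of predicted serum curves.

    ``predict_curve(params: dict, time_grid) -> array`` evaluates the model
    curve for one parameter vector.  The mode curve is the prediction at
    the highest-posterior draw; the band is the pointwise 2.5/97.5
    empirical percentile over (a subsample of) retained draws.
    """
    if len(posterior.draws) == 0:
        raise ValueError("empty posterior")
    time_grid = np.asarray(time_grid, dtype=float)
    draws = posterior.draws
    if len(draws) > max_draws:
        rng = np.random.default_rng(seed)
        draws = draws.iloc[rng.choice(len(draws), max_draws, replace=False)]
    curves = np.vstack(
        [
            predict_curve({n: row[n] for n in posterior.param_names}, time_grid)
            for _, row in draws.iterrows()
        ]
    )
    mode_row = posterior.map_row()
    mode_curve = predict_curve(
        {n: mode_row[n] for n in posterior.param_names}, time_grid
    )
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"time_h": time_grid, "mode": mode_curve, "lower": lo, "upper": hi}
    )


def csaf_quantile_ratio(values) -> float:
    """Chemical-specific adjustment factor: 95th/50th percentile quotient."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("values must be positive")
    q95, q50 = np.percentile(values, [95.0, 50.0])
    return float(q95 / q50)
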