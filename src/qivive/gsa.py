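"""Global sensitivity analysis: Morris elementary effects and eFAST.

Morris screening ranks parameters cheaply by the mean absolute elementary
effect (mu*) over randomised one-at-a-time trajectories; because single
rankings are noisy, the screen is repeated and a consensus rank is formed as
the mode of the per-repeat ranks (ties broken by mean rank).  The retained
sensitive subset is then examined with the extended Fourier Amplitude
Sensitivity Test (eFAST), which assigns each parameter a distinct driving
frequency and decomposes the output variance spectrally into first-order
(S_i) and total-order (S_Ti) indices.

Both designs operate on the unit hypercube and are mapped to parameter
space through the truncated-prior inverse CDFs, so bounded priors are a
precondition (all families used here are truncated or uniform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from qivive.priors import DistributionSpec, PriorSet, quantile_truncated

__all__ = [
    "MorrisResult",
    "FASTResult",
    "morris_screen",
    "efast",
    "lowry_data",
    "screen_and_fix",
]

# quantile_truncated rejects p in {0,1}; pad the unit cube by an epsilon
_EPS = 1.0e-9


def _map_to_priors(u: np.ndarray, specs: list[DistributionSpec]) -> np.ndarray:
    """Map unit-hypercube rows through the prior inverse CDFs."""
    x = np.empty_like(u)
    for j, spec in enumerate(specs):
        col = np.clip(u[:, j], _EPS, 1.0 - _EPS)
        if spec.family == "uniform":
            x[:, j] = spec.lower + col * (spec.upper - spec.lower)
        else:
            x[:, j] = [quantile_truncated(spec, p) for p in col]
    return x


@dataclass
class MorrisResult:
    """Per-parameter mu*, sigma and ranks over independent repeats."""

    names: list[str]
    mu_star: np.ndarray          # (repeats, k) mean |elementary effect|
    sigma: np.ndarray            # (repeats, k) SD of elementary effects
    ranks: np.ndarray            # (repeats, k), 1 = most influential
    consensus_rank: np.ndarray   # (k,) mode of ranks, ties by mean rank

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "mu_star": self.mu_star.mean(axis=0),
                "sigma": self.sigma.mean(axis=0),
                "consensus_rank": self.consensus_rank,
            }
        ).sort_values("consensus_rank", ignore_index=True)

    def retained(self, k: int) -> list[str]:
        """Names of the top-``k`` parameters by consensus rank."""
        order = np.argsort(self.consensus_rank, kind="stable")
        return [self.names[i] for i in order[:k]]


def _rank_desc(values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest value."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def morris_screen(
    model,
    priors: PriorSet,
    trajectories: int = 10,
    levels: int = 4,
    seed: int = 0,
    repeats: int = 6,
) -> MorrisResult:
    """Morris elementary-effects screen of ``model`` over the priors.

    ``model`` maps a dict of natural-scale parameter values to a scalar.
    Trajectories are built on a ``levels``-point grid in the unit hypercube
    with step ``levels / (2*(levels-1))``; elementary effects are normalised
    by the unit-cube step, and each repeat produces an independent ranking.
    """
    if trajectories < 4:
        raise ValueError("need at least 4 trajectories")
    specs = list(priors)
    names = [s.name for s in specs]
    k = len(specs)
    delta = levels / (2.0 * (levels - 1))
    base_grid = np.arange(0, levels / 2) / (levels - 1)  # start levels < 1-delta
    rng = np.random.default_rng(seed)

    mu_star = np.empty((repeats, k))
    sigma = np.empty((repeats, k))
    ranks = np.empty((repeats, k), dtype=int)
    for rep in range(repeats):
        effects: list[list[float]] = [[] for _ in range(k)]
        for _ in range(trajectories):
            x = rng.choice(base_grid, size=k)
            order = rng.permutation(k)
            direction = rng.choice([-1.0, 1.0], size=k)
            # keep steps inside the cube
            for j in range(k):
                if direction[j] > 0 and x[j] + delta > 1:
                    direction[j] = -1.0
                if direction[j] < 0 and x[j] - delta < 0:
                    direction[j] = 1.0
            pts = [x.copy()]
            for j in order:
                x = x.copy()
                x[j] += direction[j] * delta
                pts.append(x)
            u = np.clip(np.array(pts), 0.0, 1.0)
            vals = _map_to_priors(u, specs)
            y = np.array(
                [model(dict(zip(names, row))) for row in vals], dtype=float
            )
            for step, j in enumerate(order):
                effects[j].append((y[step + 1] - y[step]) / (direction[j] * delta))
        for j in range(k):
            ee = np.array(effects[j])
            mu_star[rep, j] = np.abs(ee).mean()
            sigma[rep, j] = ee.std(ddof=1) if len(ee) > 1 else 0.0
        ranks[rep] = _rank_desc(mu_star[rep])

    # consensus = per-parameter mode of ranks; ties broken by mean rank
    consensus = np.empty(k)
    for j in range(k):
        vals, counts = np.unique(ranks[:, j], return_counts=True)
        modes = vals[counts == counts.max()]
        consensus[j] = modes.mean() if len(modes) > 1 else float(modes[0])
    # refine ties across parameters by mean rank, then produce a permutation
    mean_rank = ranks.mean(axis=0)
    order = np.lexsort((mean_rank, consensus))
    consensus_rank = np.empty(k, dtype=int)
    consensus_rank[order] = np.arange(1, k + 1)
    return MorrisResult(names, mu_star, sigma, ranks, consensus_rank)


@dataclass
class FASTResult:
    """First-order and total-order variance shares per parameter."""

    names: list[str]
    Si: np.ndarray        # (k,) or (k, T) main effects
    STi: np.ndarray       # same shape, total effects
    times: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        si = np.atleast_2d(self.Si.T).T
        sti = np.atleast_2d(self.STi.T).T
        rows = []
        for t in range(si.shape[1]):
            for j, name in enumerate(self.names):
                rows.append(
                    {
                        "parameter": name,
                        "time": None if self.times is None else self.times[t],
                        "Si": si[j, t],
                        "STi": sti[j, t],
                    }
                )
        return pd.DataFrame(rows)


def _pick_driving_frequency(N: int, M: int) -> int:
    """Driving frequency <= (N-1)/(2M) whose aliased higher harmonics stay
    clear of the measured bins.

    The triangular search curve has slowly decaying harmonics beyond order
    M; with N samples, harmonic k*omega aliases to |k*omega mod N|
    (reflected at the Nyquist bin), and for unlucky omega these aliases land
    exactly on the first-order harmonics p*omega or inside the complementary
    band, biasing the indices.  Pick the omega with the largest clearance.
    """
    ceiling = (N - 1) // (2 * M)
    comp = max(1, ceiling // (2 * M))
    nyq = (N - 1) // 2
    best, best_dist = ceiling, -1
    for omega in range(ceiling, max(ceiling // 2, M), -1):
        measured = np.array([p * omega for p in range(1, M + 1)])
        dist = np.inf
        for k in range(M + 1, 3 * M + 1):
            alias = (k * omega) % N
            if alias > nyq:
                alias = N - alias
            dist = min(
                dist,
                float(np.min(np.abs(measured - alias))),
                float(max(alias - comp, 0)),  # clearance from the comp band
            )
        if dist >= 4 * comp:
            return omega
        if dist > best_dist:
            best, best_dist = omega, dist
    return best


def efast(
    model,
    priors: PriorSet,
    N: int = 1041,
    M: int = 4,
    seed: int = 0,
    resamples: int = 1,
) -> FASTResult:
    """Extended FAST first-order and total-order indices.

    ``model`` maps a parameter dict to a scalar or a 1-D array (e.g. one
    output per time point); indices are computed per output column and
    averaged over ``resamples`` random phase shifts.  ``N`` is the number of
    model evaluations per parameter per resample and must satisfy
    ``N >= 65*M**2`` for frequency separation with the interference factor
    ``M``.
    """
    specs = list(priors)
    names = [s.name for s in specs]
    k = len(specs)
    if k < 2:
        raise ValueError("eFAST needs at least 2 parameters")
    if N < 65 * M * M:
        raise ValueError(f"N={N} too small; need >= {65 * M * M} for M={M}")
    if N % 2 == 0:
        N += 1  # odd sample count keeps the spectrum symmetric
    rng = np.random.default_rng(seed)

    omega_max = _pick_driving_frequency(N, M)
    omega_comp_max = max(1, omega_max // (2 * M))  # complementary band
    si_acc = None
    sti_acc = None
    s = np.pi * (2.0 * np.arange(N) + 1.0 - N) / N
    for _ in range(resamples):
        for i in range(k):
            omegas = np.empty(k)
            omegas[i] = omega_max
            others = [j for j in range(k) if j != i]
            # spread complementary frequencies across [1, omega_comp_max]
            if omega_comp_max >= len(others):
                omegas[others] = np.floor(
                    np.linspace(1, omega_comp_max, len(others))
                )
            else:
                omegas[others] = 1 + (np.arange(len(others)) % omega_comp_max)
            phase = rng.uniform(0, 2 * np.pi, size=k)
            u = 0.5 + np.arcsin(np.sin(omegas[None, :] * s[:, None] + phase[None, :])) / np.pi
            x = _map_to_priors(u, specs)
            y = np.array([model(dict(zip(names, row))) for row in x], dtype=float)
            y2 = y[:, None] if y.ndim == 1 else y
            spectrum = np.abs(np.fft.rfft(y2, axis=0)[1:]) ** 2 / N
            variance = 2.0 * spectrum.sum(axis=0)
            harmonics = omega_max * np.arange(1, M + 1) - 1
            d1 = 2.0 * spectrum[harmonics].sum(axis=0)
            # everything below omega_max/2 is complementary-parameter energy
            dcomp = 2.0 * spectrum[: omega_max // 2].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                si_col = np.where(variance > 0, d1 / variance, 0.0)
                sti_col = np.where(variance > 0, 1.0 - dcomp / variance, 0.0)
            if si_acc is None:
                t_dim = y2.shape[1]
                si_acc = np.zeros((k, t_dim))
                sti_acc = np.zeros((k, t_dim))
            si_acc[i] += si_col
            sti_acc[i] += sti_col
    si = si_acc / resamples
    sti = sti_acc / resamples
    if si.shape[1] == 1:
        si, sti = si[:, 0], sti[:, 0]
    return FASTResult(names, si, sti)


def lowry_data(result: FASTResult, column: int | None = None) -> pd.DataFrame:
    """Ordered cumulative table for a Lowry plot.

    Parameters are sorted by total effect; the ribbon's lower bound is the
    cumulative sum of main effects and the upper bound the cumulative sum of
    total effects capped at 1.
    """
    si = np.atleast_2d(result.Si.T).T
    sti = np.atleast_2d(result.STi.T).T
    col = 0 if column is None else column
    si, sti = si[:, col], sti[:, col]
    order = np.argsort(-sti, kind="stable")
    frame = pd.DataFrame(
        {
            "parameter": [result.names[i] for i in order],
            "Si": si[order],
            "STi": sti[order],
        }
    )
    frame["cum_lower"] = frame["Si"].cumsum()
    frame["cum_upper"] = np.minimum(frame["STi"].cumsum(), 1.0)
    frame["cum_upper"] = np.maximum(frame["cum_upper"], frame["cum_lower"])
    return frame


def screen_and_fix(
    priors: PriorSet,
    morris: MorrisResult,
    keep: int | str = 13,
) -> tuple[PriorSet, dict[str, float]]:
    """Split priors into a retained sensitive subset and fixed central values.

    ``keep`` is either an integer (retain the top-k consensus ranks) or the
    string ``"mu_star>=frac"`` retaining parameters whose mean mu* is at
    least ``frac`` of the maximum (e.g. ``"mu_star>=0.05"``).
    """
    if isinstance(keep, str):
        if not keep.startswith("mu_star>="):
            raise ValueError(f"unknown keep rule {keep!r}")
        frac = float(keep.split(">=")[1])
        mu = morris.mu_star.mean(axis=0)
        names = [n for n, m in zip(morris.names, mu) if m >= frac * mu.max()]
    else:
        names = morris.retained(int(keep))
    if not names:
        raise ValueError("keep rule retained zero parameters")
    retained = priors.subset(names)
    retained.tag("morris-retained", names)
    fixed = {
        n: priors[n].central() for n in priors.names if n not in set(names)
    }
    return retained, fixed
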