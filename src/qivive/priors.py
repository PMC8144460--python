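"""Truncated prior distributions for the PFOA PBK parameter roster.

Each parameter of the kinetic model carries a prior given as a truncated
normal, truncated lognormal or uniform distribution.  Lognormal rows are
specified on the natural-log scale: ``location`` and ``spread`` are the mean
and SD of log(X), and the truncation bounds are log-scale bounds (so the
median of the sampled natural-scale values is ``exp(location)``).

Truncation is implemented by inverse-CDF restriction, which is deterministic
given a seed and exact at extreme bounds.  Sampling uses one independent
stream per parameter, derived from a root seed by stable hashing of the
parameter name, so adding or removing a parameter never shifts the draws of
the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FAMILIES = ("normal", "lognormal", "uniform", "loguniform")

__all__ = [
    "DistributionSpec",
    "PriorSet",
    "PhysiologyError",
    "sample_prior",
    "quantile_truncated",
    "summarize_sample",
    "constrain_physiology",
    "load_pfoa_priors",
    "derive_stream_seed",
    "PERFUSED_FRACTION",
]

#: Fraction of body weight treated as perfused tissue when closing the
#: volume balance; the rest-of-body volume fraction is this constant minus
#: the explicitly specified tissue fractions.
PERFUSED_FRACTION = 0.93


class PhysiologyError(ValueError):
    """A drawn parameter vector violates a mass-balance/flow constraint."""


@dataclass(frozen=True)
class DistributionSpec:
    """One prior: family, location/spread on the family's own scale, bounds.

    For ``normal`` and ``uniform`` every field is on the natural scale; for
    ``lognormal`` location, spread and bounds are on the log scale.  A
    ``loguniform`` spec is uniform in log space with natural-scale bounds
    (no location/spread), the conventional search prior for a positive
    quantity known only to within orders of magnitude.
    """

    name: str
    family: str
    location: float | None
    spread: float | None
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r} for {self.name}")
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.name}: inverted bounds [{self.lower}, {self.upper}]"
            )
        if self.family == "loguniform" and self.lower <= 0:
            raise ValueError(f"{self.name}: loguniform needs positive bounds")
        if self.family not in ("uniform", "loguniform"):
            if self.location is None or self.spread is None:
                raise ValueError(f"{self.name}: location/spread required")
            if not self.spread > 0:
                raise ValueError(f"{self.name}: spread must be positive")

    # -- internal helpers -------------------------------------------------
    def _cdf_bounds(self) -> tuple[float, float]:
        fa = stats.norm.cdf(self.lower, self.location, self.spread)
        fb = stats.norm.cdf(self.upper, self.location, self.spread)
        return fa, fb

    def natural_bounds(self) -> tuple[float, float]:
        """Truncation bounds on the natural scale of the parameter."""
        if self.family == "lognormal":
            return math.exp(self.lower), math.exp(self.upper)
        return self.lower, self.upper

    def central(self) -> float:
        """Central value (median of the truncated distribution)."""
        return quantile_truncated(self, 0.5)

    def logpdf(self, x: float) -> float:
        """Log density at natural-scale ``x`` (unnormalised truncation)."""
        lo, hi = self.natural_bounds()
        if not (lo <= x <= hi):
            return -math.inf
        if self.family == "uniform":
            return -math.log(hi - lo)
        if self.family == "loguniform":
            return -math.log(x) - math.log(math.log(hi / lo))
        if self.family == "normal":
            return stats.norm.logpdf(x, self.location, self.spread)
        return stats.norm.logpdf(math.log(x), self.location, self.spread) - math.log(x)


def quantile_truncated(spec: DistributionSpec, p: float) -> float:
    """Analytic quantile of the truncated prior on the natural scale.

    Returns ``F^-1(F(a) + p*(F(b)-F(a)))`` for the parent normal on the
    spec's scale, exponentiated for lognormal rows.
    """
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"p={p} outside (0, 1)")
    if spec.family == "uniform":
        return spec.lower + p * (spec.upper - spec.lower)
    if spec.family == "loguniform":
        return math.exp(
            math.log(spec.lower) + p * math.log(spec.upper / spec.lower)
        )
    fa, fb = spec._cdf_bounds()
    x = stats.norm.ppf(fa + p * (fb - fa), spec.location, spec.spread)
    return math.exp(x) if spec.family == "lognormal" else float(x)


def derive_stream_seed(root_seed: int, name: str) -> int:
    """Stable per-parameter seed (< 2**31) from a root seed and a name."""
    digest = hashlib.blake2b(
        f"{int(root_seed)}:{name}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") & 0x7FFFFFFF


def sample_prior(
    spec: DistributionSpec,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` natural-scale samples from a truncated prior.

    Inverse-CDF sampling: uniforms are mapped through the truncated parent
    quantile function, and exponentiated for lognormal specs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    if spec.family == "uniform":
        return spec.lower + u * (spec.upper - spec.lower)
    if spec.family == "loguniform":
        return np.exp(np.log(spec.lower) + u * math.log(spec.upper / spec.lower))
    fa, fb = spec._cdf_bounds()
    x = stats.norm.ppf(fa + u * (fb - fa), spec.location, spec.spread)
    # guard against ppf rounding at the extreme bounds
    x = np.clip(x, spec.lower, spec.upper)
    return np.exp(x) if spec.family == "lognormal" else x


def summarize_sample(values) -> tuple[float, float, float]:
    """(median, 2.5th, 97.5th) empirical percentiles of a sample."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    med, lo, hi = np.percentile(values, [50.0, 2.5, 97.5])
    return float(med), float(lo), float(hi)


@dataclass
class PriorSet:
    """Ordered collection of :class:`DistributionSpec` with subset tags."""

    specs: dict[str, DistributionSpec] = field(default_factory=dict)
    tags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, names in self.tags.items():
            missing = [m for m in names if m not in self.specs]
            if missing:
                raise ValueError(f"tag {tag!r} references unknown names {missing}")

    @property
    def names(self) -> list[str]:
        return list(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs.values())

    def __getitem__(self, name: str) -> DistributionSpec:
        return self.specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def add(self, spec: DistributionSpec) -> None:
        if spec.name in self.specs:
            raise ValueError(f"duplicate parameter {spec.name!r}")
        self.specs[spec.name] = spec

    def tag(self, tag: str, names) -> None:
        names = list(names)
        missing = [m for m in names if m not in self.specs]
        if missing:
            raise ValueError(f"tag {tag!r} references unknown names {missing}")
        self.tags[tag] = names

    def subset(self, tag_or_names) -> "PriorSet":
        """New PriorSet restricted to a tag name or explicit name list."""
        if isinstance(tag_or_names, str):
            names = self.tags[tag_or_names]
        else:
            names = list(tag_or_names)
        return PriorSet({n: self.specs[n] for n in names})

    def centrals(self) -> dict[str, float]:
        return {n: s.central() for n, s in self.specs.items()}

    def sample(self, n: int, seed: int) -> pd.DataFrame:
        """Sample all parameters; one hashed seed stream per parameter."""
        cols = {
            name: sample_prior(spec, n, derive_stream_seed(seed, name))
            for name, spec in self.specs.items()
        }
        return pd.DataFrame(cols)

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": s.name,
                "family": s.family,
                "location": s.location,
                "spread": s.spread,
                "lower": s.lower,
                "upper": s.upper,
                "units": s.units,
            }
            for s in self.specs.values()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PriorSet":
        required = {"name", "family", "location", "spread", "lower", "upper"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"priors table missing columns {sorted(missing)}")
        ps = cls()
        for _, row in frame.iterrows():
            loc = row["location"]
            spr = row["spread"]
            ps.add(
                DistributionSpec(
                    name=str(row["name"]),
                    family=str(row["family"]),
                    location=None if pd.isna(loc) else float(loc),
                    spread=None if pd.isna(spr) else float(spr),
                    lower=float(row["lower"]),
                    upper=float(row["upper"]),
                    units=str(row.get("units", "")),
                )
            )
        return ps

    @classmethod
    def from_csv(cls, path) -> "PriorSet":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


#: Volume-fraction parameters subtracted from the perfused fraction when the
#: rest-of-body volume fraction is closed.
_VOLUME_FRACTIONS = ("VLC", "VKC", "VplasC", "VfilC")


def constrain_physiology(
    draw: dict[str, float],
    perfused_fraction: float = PERFUSED_FRACTION,
) -> dict[str, float]:
    """Close the blood-flow and tissue-volume balances of a parameter draw.

    Adds ``QRC`` (rest-of-body flow fraction ``1 - QLC - QKC``) and ``VRC``
    (rest-of-body volume fraction, the perfused fraction minus the specified
    tissue fractions).  Raises :class:`PhysiologyError` when a remainder is
    non-positive, signalling that the draw should be rejected and resampled.
    """
    out = dict(draw)
    qrc = 1.0 - out["QLC"] - out["QKC"]
    if qrc <= 0.0:
        raise PhysiologyError(
            f"rest-of-body flow fraction {qrc:.4f} <= 0 "
            f"(QLC={out['QLC']}, QKC={out['QKC']})"
        )
    vrc = perfused_fraction - sum(out.get(k, 0.0) for k in _VOLUME_FRACTIONS)
    if vrc <= 0.0:
        raise PhysiologyError(f"rest-of-body volume fraction {vrc:.4f} <= 0")
    out["QRC"] = qrc
    out["VRC"] = vrc
    return out


def load_pfoa_priors() -> PriorSet:
    """The PFOA prior roster shipped with the package (34 parameters)."""
    from importlib import resources

    with resources.files("qivive.data").joinpath("pfoa_priors.csv").open() as fh:
        return PriorSet.from_csv(fh)
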