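"""Seeded generators for every input the pipeline consumes.

The package's pipeline was designed around community drinking-water
biomonitoring data and high-throughput in vitro screens; these generators
emulate both so every stage can be exercised end to end without external
data:

* serum biomonitoring tables - steady-state model predictions at known
  ("truth") parameters with multiplicative lognormal measurement noise,
  for the three water-district exposure groups (0.04, 1.0 and 4.9 ug/L);
* in vitro concentration-response tables - Hill curves with multiplicative
  noise on the assays' concentration grids;
* an analytic toy surrogate of the dose metric with a known inverse, used
  to validate the ABC and GSA estimators against closed forms.

What the generators deliberately do not emulate: assay plate artifacts,
cytotoxicity confounds, inter-individual kinetic variability within a
group (observations share one truth vector) and real sampling-time
heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qivive.invitro import ATG_FREE_CONC_UGL, ConcentrationResponse
from qivive.pbk import ExposureScenario, PBKParameters, steady_state

__all__ = [
    "SyntheticTruth",
    "DEFAULT_GROUPS_UGL",
    "gen_biomonitoring",
    "gen_invitro",
    "ToySurrogate",
    "gen_toy_surrogate",
]

#: Highest reported drinking-water PFOA concentration of each emulated
#: water district, ug/L.
DEFAULT_GROUPS_UGL = (0.04, 1.0, 4.9)


@dataclass(frozen=True)
class SyntheticTruth:
    """The generating parameter vector and noise level of a synthetic set."""

    params: PBKParameters = field(default_factory=PBKParameters)
    dw_total_Lday: float = 1.19841
    noise_log_sd: float = 0.3
    seed: int = 0


def gen_biomonitoring(
    truth: SyntheticTruth | None = None,
    groups=DEFAULT_GROUPS_UGL,
    n_per_group: int = 10,
    times_h=None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Synthetic serum biomonitoring table (group, water conc, time, serum).

    Observations are late-exposure cross-sections: serum equals the
    steady-state model CA at the truth parameters times a lognormal
    multiplicative error exp(N(0, noise_log_sd)).  Sampling times default
    to draws within the quasi-steady-state window (100,000-120,000 h).
    """
    truth = truth or SyntheticTruth()
    if truth.noise_log_sd <= 0:
        raise ValueError("noise log-SD must be positive")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rows = []
    for g, conc in enumerate(groups):
        scenario = ExposureScenario(
            exposed_dw_ugL=conc, dw_total_Lday=truth.dw_total_Lday
        )
        ca = float(steady_state(truth.params, scenario).CA[0])
        if not ca > 0:
            raise RuntimeError(f"model predicts non-positive serum for group {conc}")
        if times_h is None:
            t = rng.uniform(100_000.0, 120_000.0, size=n_per_group)
        else:
            t = np.resize(np.asarray(times_h, dtype=float), n_per_group)
        noise = np.exp(rng.normal(0.0, truth.noise_log_sd, size=n_per_group))
        for ti, ni in zip(t, noise):
            rows.append(
                {
                    "group": f"district-{g + 1}",
                    "exposed_dw_ugL": conc,
                    "time_h": ti,
                    "serum_ugL": ca * ni,
                }
            )
    return pd.DataFrame(rows), truth


def gen_invitro(
    baseline: float = 1.0,
    top: float = 3.0,
    ac50_ugL: float = 50.0,
    steepness: float = 1.5,
    conc_ugL=ATG_FREE_CONC_UGL,
    noise_cv: float = 0.05,
    seed: int = 0,
    assay: str = "synthetic-hill",
    metric: str | None = None,
) -> ConcentrationResponse:
    """Synthetic Hill-shaped assay on a given free-concentration grid.

    fold(c) = baseline + (top-baseline) * c^n / (ac50^n + c^n), with
    multiplicative lognormal noise of coefficient of variation
    ``noise_cv`` (0 disables noise).
    """
    conc = np.asarray(conc_ugL, dtype=float)
    fold = baseline + (top - baseline) * conc**steepness / (
        ac50_ugL**steepness + conc**steepness
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sd = math.sqrt(math.log(1.0 + noise_cv**2))
        fold = fold * np.exp(rng.normal(0.0, sd, size=fold.shape))
    return ConcentrationResponse(
        assay=assay,
        conc_ugL=conc,
        response_fold=fold,
        metric=metric or ("CA" if len(conc) == 4 else "CL"),
        cell_context="synthetic",
    )


@dataclass(frozen=True)
class ToySurrogate:
    """Analytic stand-in for the steady-state dose metric.

    metric = ExposedDW * DWtotal * k / (BW * CL_eff): intake divided by an
    effective clearance.  The inverse is closed-form, which makes it the
    oracle for ABC estimators (acceptance regions are intervals whose
    prior mass is computable) and for variance-based GSA.
    """

    k: float = 100.0

    def metric(self, params: dict) -> float:
        return (
            params["ExposedDW"] * params["DWtotal"] * self.k
            / (params["BW"] * params["CL_eff"])
        )

    def inverse(self, target: float, params: dict) -> float:
        """ExposedDW that exactly attains ``target`` given the other values."""
        return target * params["BW"] * params["CL_eff"] / (params["DWtotal"] * self.k)


def gen_toy_surrogate(k: float = 100.0) -> ToySurrogate:
    return ToySurrogate(k=k)
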