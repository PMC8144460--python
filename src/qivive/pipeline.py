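"""Stage orchestration for the full QIVIVE workflow.

Stages mirror the modelling workflow: ``simulate`` (scenario predictions),
``gsa-morris`` and ``gsa-efast`` (sensitivity screening of the dose
metrics), ``calibrate`` (MCMC against biomonitoring data), ``qivive``
(two-stage ABC per in vitro concentration) and ``bmd`` (benchmark-dose
table with adjustment factors).  ``all`` runs them in order.  Each stage
writes TSV artifacts plus a JSON manifest into the output directory and
reads its upstream artifacts from there, failing with a message naming the
producing stage when one is missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from qivive import calibration as cal
from qivive import reverse_dosimetry as rd
from qivive.bmd import DoseResponseDataset, apply_adjustment, fit_all, select_model
from qivive.gsa import efast, lowry_data, morris_screen, screen_and_fix
from qivive.invitro import read_assay_csv
from qivive.io import read_table, write_manifest, write_table
from qivive.pbk import ExposureScenario, PBKParameters, simulate, steady_state
from qivive.priors import PriorSet, load_pfoa_priors
from qivive.synthetic import SyntheticTruth, gen_biomonitoring, gen_invitro

__all__ = ["STAGES", "DEFAULT_CONFIG", "load_config", "run_stage", "MissingArtifactError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "gsa-morris", "gsa-efast", "calibrate", "qivive", "bmd", "all")

#: Parameters calibrated against biomonitoring data (the ten-parameter
#: posterior roster; a nine-parameter variant without PL is config-selectable).
CALIBRATED_PARAMS = [
    "BW", "Vmax_apical_invitro", "VfilC", "Free", "PR",
    "Protein", "RAFapi", "GFRC", "KurineC", "PL",
]

DEFAULT_CONFIG: dict = {
    "priors": None,                      # path to a priors CSV; default roster if null
    "groups_ugL": [0.04, 1.0, 4.9],
    "dw_total_Lday": 1.19841,
    "simulate": {"duration_h": 120_100.0, "n_out": 400},
    "morris": {"trajectories": 10, "levels": 4, "repeats": 6, "keep": 13},
    "efast": {"N": 1041, "M": 4},
    "calibrate": {
        "iterations": 1000,
        "chains": 2,
        "params": CALIBRATED_PARAMS,
        "biomonitoring": None,           # path; synthetic data if null
        "synthetic": {"n_per_group": 10, "noise_log_sd": 0.3},
    },
    "qivive": {
        "assays": None,                  # list of assay CSV paths; synthetic if null
        "synthetic": {
            "hepatocyte": {"baseline": 1.0, "top": 3.0, "ac50_ugL": 50.0,
                           "steepness": 1.5, "noise_cv": 0.05},
            "endothelial": {"baseline": 1.0, "top": 0.4, "ac50_ugL": 80.0,
                            "steepness": 1.5, "noise_cv": 0.05},
        },
        "abc": {"n1": 500, "tol1": 0.075, "tol2": 0.05,
                "chains": 4, "iterations": 2500},
    },
    "bmd": {"bmr": 0.05, "csaf": 1.4, "default_uf": 10.0},
}


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; the message names the producing stage."""


def load_config(path=None) -> dict:
    """Deep-merge a YAML config file over the defaults."""
    config = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(config, user)
    return config


def _deep_copy(obj):
    if isinstance(obj, dict):
        return {k: _deep_copy(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_deep_copy(v) for v in obj]
    return obj


def _deep_update(base: dict, extra: dict) -> None:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def _priors(config: dict) -> PriorSet:
    if config.get("priors"):
        return PriorSet.from_csv(config["priors"])
    return load_pfoa_priors()


def _require(outdir: Path, name: str, producer: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {name!r}; run the {producer!r} stage first"
        )
    return path


# -- model wrappers ---------------------------------------------------------

def _scenario_from_draw(draw: dict, config: dict) -> ExposureScenario:
    return ExposureScenario(
        exposed_dw_ugL=draw.get("ExposedDW", 1.0),
        dw_total_Lday=draw.get("DWtotal", config["dw_total_Lday"]),
        ingest_current_ugh=draw.get("Ingest_current", 0.0),
        ingest_past_ugh=draw.get("Ingest_past", 0.0),
    )


def _metric_model(config: dict, which: str):
    """Dose metric (steady-state CA or CL) as a function of a draw dict."""

    def model(draw: dict) -> float:
        p = PBKParameters.from_draw(draw)
        s = _scenario_from_draw(draw, config)
        res = steady_state(p, s)
        return float(res.CA[0] if which == "CA" else res.CL[0])

    return model


def _calibration_predict(config: dict, data: pd.DataFrame):
    groups = data["exposed_dw_ugL"].to_numpy()
    unique = np.unique(groups)

    def predict(params: dict) -> np.ndarray:
        p = PBKParameters.from_draw(params)
        by_group = {}
        for conc in unique:
            s = ExposureScenario(
                exposed_dw_ugL=float(conc), dw_total_Lday=config["dw_total_Lday"]
            )
            by_group[conc] = float(steady_state(p, s).CA[0])
        return np.array([by_group[g] for g in groups])

    return predict


# -- stages -----------------------------------------------------------------

def _stage_simulate(config: dict, outdir: Path, seed: int, fast: bool) -> list[str]:
    artifacts = []
    n_out = config["simulate"]["n_out"]
    duration = config["simulate"]["duration_h"]
    for conc in config["groups_ugL"]:
        s = ExposureScenario(
            exposed_dw_ugL=conc,
            dw_total_Lday=config["dw_total_Lday"],
            duration_h=duration,
        )
        res = simulate(
            PBKParameters(), s, t_eval=np.linspace(0, duration, n_out)
        )
        frame = res.to_frame().rename(columns={"time_h": "time_h"})
        name = f"simulation_{conc:g}ugL.tsv"
        write_table(frame, outdir / name, "simulation")
        artifacts.append(name)
    return artifacts


def _stage_morris(config: dict, outdir: Path, seed: int, fast: bool) -> list[str]:
    priors = _priors(config)
    mcfg = config["morris"]
    artifacts = []
    retained_names: dict[str, list[str]] = {}
    for which in ("CA", "CL"):
        result = morris_screen(
            _metric_model(config, which),
            priors,
            trajectories=mcfg["trajectories"],
            levels=mcfg["levels"],
            seed=seed,
            repeats=mcfg["repeats"],
        )
        name = f"morris_{which}.tsv"
        write_table(result.to_frame(), outdir / name, "morris")
        artifacts.append(name)
        retained, _ = screen_and_fix(priors, result, keep=mcfg["keep"])
        retained_names[which] = retained.names
    union = sorted(set(retained_names["CA"]) | set(retained_names["CL"]))
    write_table(
        pd.DataFrame({"parameter": union}), outdir / "morris_retained.tsv"
    )
    artifacts.append("morris_retained.tsv")
    return artifacts


def _stage_efast(config: dict, outdir: Path, seed: int, fast: bool) -> list[str]:
    priors = _priors(config)
    retained = read_table(
        _require(outdir, "morris_retained.tsv", "gsa-morris")
    )["parameter"].tolist()
    subset = priors.subset(retained)
    ecfg = config["efast"]
    artifacts = []
    for which in ("CA", "CL"):
        result = efast(
            _metric_model(config, which), subset,
            N=ecfg["N"], M=ecfg["M"], seed=seed,
        )
        name = f"efast_{which}.tsv"
        write_table(result.to_frame(), outdir / name, "efast")
        artifacts.append(name)
        lowry = lowry_data(result)
        write_table(lowry, outdir / f"lowry_{which}.tsv")
        artifacts.append(f"lowry_{which}.tsv")
    return artifacts


def _stage_calibrate(config: dict, outdir: Path, seed: int, fast: bool) -> list[str]:
    ccfg = config["calibrate"]
    if ccfg.get("biomonitoring"):
        data = read_table(ccfg["biomonitoring"], "biomonitoring")
    else:
        scfg = ccfg["synthetic"]
        truth = SyntheticTruth(
            dw_total_Lday=config["dw_total_Lday"],
            noise_log_sd=scfg["noise_log_sd"],
            seed=seed,
        )
        data, _ = gen_biomonitoring(
            truth, groups=config["groups_ugL"], n_per_group=scfg["n_per_group"]
        )
        write_table(data, outdir / "biomonitoring_synthetic.tsv", "biomonitoring")
    priors = _priors(config).subset(ccfg["params"])
    iterations = ccfg["iterations"] // 2 if fast else ccfg["iterations"]
    posterior = cal.run_mcmc(
        priors,
        data,
        _calibration_predict(config, data),
        iterations=iterations,
        chains=ccfg["chains"],
        seed=seed,
    )
    write_table(posterior.draws, outdir / "posterior_draws.tsv")
    write_table(posterior.summary(), outdir / "posterior_summary.tsv", "posterior_summary")
    logger.info("calibration R-hat: %s", posterior.rhat)
    return ["posterior_draws.tsv", "posterior_summary.tsv", "biomonitoring_synthetic.tsv"]


def _load_assays(config: dict, seed: int):
    qcfg = config["qivive"]
    if qcfg.get("assays"):
        return [read_assay_csv(p) for p in qcfg["assays"]]
    from qivive.invitro import ATG_FREE_CONC_UGL, BSK_FREE_CONC_UGL

    syn = qcfg["synthetic"]
    assays = []
    if "hepatocyte" in syn:
        assays.append(
            gen_invitro(
                conc_ugL=ATG_FREE_CONC_UGL, seed=seed,
                assay="synthetic-hepatocyte", metric="CL",
                **syn["hepatocyte"],
            )
        )
    if "endothelial" in syn:
        assays.append(
            gen_invitro(
                conc_ugL=BSK_FREE_CONC_UGL, seed=seed + 1,
                assay="synthetic-endothelial", metric="CA",
                **syn["endothelial"],
            )
        )
    return assays


def _stage_qivive(config: dict, outdir: Path, seed: int, fast: bool) -> list[str]:
    summary = read_table(
        _require(outdir, "posterior_summary.tsv", "calibrate"), "posterior_summary"
    )
    refined = rd.refined_priors(summary)
    qcfg = config["qivive"]["abc"]
    cfg0 = rd.ABCConfig(
        n1=qcfg["n1"], tol1=qcfg["tol1"], tol2=qcfg["tol2"],
        chains=qcfg["chains"], iterations=qcfg["iterations"],
    )
    priors_all = _priors(config)
    artifacts = []
    for assay in _load_assays(config, seed):
        import dataclasses

        cfg = dataclasses.replace(cfg0, metric=assay.metric)
        model = _metric_model(config, assay.metric)
        pooled: dict[float, pd.DataFrame] = {}
        responses: dict[float, float] = {}
        for i, target in enumerate(assay.conc_ugL):
            priors = PriorSet()
            for name in refined.names:
                priors.add(refined[name])
            priors.add(rd.exposure_prior_for_target(float(target)))
            priors.add(priors_all["DWtotal"])
            _, phase2 = rd.run_two_stage_abc(
                priors, model, float(target), cfg, seed=seed + 100 * i
            )
            pooled[float(target)] = phase2.samples
            responses[float(target)] = float(assay.response_fold[i])
            logger.info(
                "%s target %.3f ug/L: ABC-MCMC acceptance %.1f%%",
                assay.assay, target, 100 * phase2.acceptance_rate,
            )
            name = f"abc_{assay.assay}_{target:g}.tsv"
            write_table(phase2.samples, outdir / name)
            artifacts.append(name)
        table = rd.assemble_dose_response(pooled, responses)
        name = f"dose_response_{assay.assay}.tsv"
        write_table(table, outdir / name, "dose_response")
        artifacts.append(name)
    return artifacts


def _bmd_for_vector(dose: np.ndarray, response: np.ndarray, bmr: float) -> float | None:
    mask = np.isfinite(dose) & (dose > 0)
    if mask.sum() < 4:
        return None
    try:
        data = DoseResponseDataset(dose[mask], response[mask])
    except ValueError:
        return None
    result = select_model(fit_all(data, bmr=bmr))
    return result.selected_bmdl


def _stage_bmd(config: dict, outdir: Path, seed: int, fast: bool) -> list[str]:
    bcfg = config["bmd"]
    tables = sorted(outdir.glob("dose_response_*.tsv"))
    if not tables:
        raise MissingArtifactError(
            "missing artifacts 'dose_response_*.tsv'; run the 'qivive' stage first"
        )
    rows = []
    for path in tables:
        assay = path.stem.replace("dose_response_", "")
        table = read_table(path, "dose_response")
        response = table["response_fold"].to_numpy()
        entry: dict = {"assay": assay}
        for prefix, col in (("intake", "intake"), ("exposed_dw", "exposed_dw")):
            for stat in ("mode", "lo", "hi"):
                dose = table[f"{col}_{stat}"].to_numpy(dtype=float)
                entry[f"{prefix}_bmdl_{stat}"] = _bmd_for_vector(
                    dose, response, bcfg["bmr"]
                )
        entry["csaf"] = bcfg["csaf"]
        mode = entry["intake_bmdl_mode"]
        entry["intake_csaf_mode"] = (
            apply_adjustment(mode, bcfg["csaf"]) if mode is not None else None
        )
        entry["intake_default_mode"] = (
            apply_adjustment(mode, bcfg["default_uf"]) if mode is not None else None
        )
        rows.append(entry)
    summary = pd.DataFrame(rows)
    write_table(summary, outdir / "bmd_summary.tsv", "bmd_summary")
    return ["bmd_summary.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "gsa-morris": _stage_morris,
    "gsa-efast": _stage_efast,
    "calibrate": _stage_calibrate,
    "qivive": _stage_qivive,
    "bmd": _stage_bmd,
}


def run_stage(
    stage: str,
    config: dict | None = None,
    outdir="qivive_out",
    seed: int = 0,
    fast: bool = False,
) -> list[str]:
    """Run one pipeline stage (or ``all``); returns the artifact names."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    config = config if config is not None else _deep_copy(DEFAULT_CONFIG)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s != "all"] if stage == "all" else [stage]
    artifacts = []
    for s in stages:
        produced = _STAGE_FUNCS[s](config, outdir, seed, fast)
        write_manifest(outdir, s, seed, config, produced)
        artifacts.extend(produced)
    return artifacts
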