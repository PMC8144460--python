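"""Validated table I/O and run manifests.

Column names embed units (e.g. ``serum_ugL``) so unit drift is visible at
every file boundary.  Tables are written as TSV at full float precision so
a write-read round trip is lossless.  Every pipeline stage also writes a
JSON manifest (stage, seed, configuration hash, package version) from
which its artifacts can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "read_table",
    "write_table",
    "write_manifest",
    "config_hash",
    "SCHEMAS",
]


class SchemaError(ValueError):
    """Table does not match the declared schema; names the offending columns."""


#: Required columns per pipeline artifact kind.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "priors": ("name", "family", "location", "spread", "lower", "upper"),
    "biomonitoring": ("group", "exposed_dw_ugL", "time_h", "serum_ugL"),
    "simulation": ("time_h", "CA_ugL", "CL_ugL"),
    "morris": ("parameter", "mu_star", "sigma", "consensus_rank"),
    "efast": ("parameter", "Si", "STi"),
    "posterior_summary": ("parameter", "median", "q2.5", "q97.5"),
    "dose_response": (
        "conc_ugL",
        "intake_mode", "intake_lo", "intake_hi",
        "exposed_dw_mode", "exposed_dw_lo", "exposed_dw_hi",
        "dw_total_mode", "bw_mode",
    ),
    "bmd_summary": (
        "assay",
        "exposed_dw_bmdl_mode", "exposed_dw_bmdl_lo", "exposed_dw_bmdl_hi",
        "intake_bmdl_mode", "intake_bmdl_lo", "intake_bmdl_hi",
        "csaf", "intake_csaf_mode", "intake_default_mode",
    ),
}


def _validate(frame: pd.DataFrame, schema: str | tuple[str, ...]) -> None:
    required = SCHEMAS[schema] if isinstance(schema, str) else tuple(schema)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"table does not match schema "
            f"{schema if isinstance(schema, str) else 'explicit'}: "
            f"missing columns {missing}"
        )


def read_table(path, schema: str | tuple[str, ...] | None = None) -> pd.DataFrame:
    """Read a TSV/CSV table and validate it against a schema."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if schema is not None:
        _validate(frame, schema)
    return frame


def write_table(frame: pd.DataFrame, path, schema: str | tuple[str, ...] | None = None) -> Path:
    """Write a table (TSV for .tsv/.txt, CSV otherwise) at full precision."""
    if schema is not None:
        _validate(frame, schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, stage: str, seed: int, config: dict, artifacts: list[str]) -> Path:
    from qivive import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "artifacts": artifacts,
        "version": __version__,
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
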