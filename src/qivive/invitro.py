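"""Ingestion and unit conversion of in vitro concentration-response tables.

High-throughput screening assays report nominal applied concentrations
(log10 uM) and responses as log2 fold induction.  The reverse-dosimetry
stage needs free (bioavailable) concentrations in ug/L on the natural scale:
nominal uM are converted through the molar mass of PFOA and then reduced to
the bioavailable fraction (default 2.3% of nominal, a partitioning estimate
for a chemical of PFOA's log P).  Responses are converted to natural fold
induction.

Assay QC flags are carried as metadata and logged; they never drop rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qivive.pbk import MW_PFOA

__all__ = [
    "ConcentrationResponse",
    "um_to_ugL",
    "apply_free_fraction",
    "response_to_fold",
    "load_assay",
    "read_assay_csv",
    "DEFAULT_FREE_FRACTION",
    "ATG_FREE_CONC_UGL",
    "BSK_FREE_CONC_UGL",
]

logger = logging.getLogger(__name__)

#: Default in vitro bioavailable fraction of the nominal concentration.
DEFAULT_FREE_FRACTION = 0.023

#: Free (bioavailability-corrected) concentration grids of the four PFOA
#: assays, ug/L.  The seven-point grid belongs to the hepatocyte (HepG2)
#: transcription-factor assays whose target metric is the liver
#: concentration CL; the four-point grid to the endothelial immunotoxicity
#: assay targeted at serum CA.
ATG_FREE_CONC_UGL = (1.035, 4.141, 10.352, 41.407, 103.518, 310.553, 1035.175)
BSK_FREE_CONC_UGL = (9.524, 38.094, 95.236, 380.944)


def um_to_ugL(conc_uM, molar_mass: float = MW_PFOA):
    """Convert micromolar concentrations to ug/L (conc x molar mass)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    conc = np.asarray(conc_uM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    out = conc * molar_mass
    return float(out) if out.ndim == 0 else out


def apply_free_fraction(nominal_ugL, fraction: float = DEFAULT_FREE_FRACTION):
    """Bioavailable concentration: nominal x free fraction."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("free fraction must lie in (0, 1]")
    out = np.asarray(nominal_ugL, dtype=float) * fraction
    return float(out) if out.ndim == 0 else out


def response_to_fold(log2_fold):
    """Natural fold induction from a log2 fold-induction response."""
    out = np.exp2(np.asarray(log2_fold, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class ConcentrationResponse:
    """A curated assay: free concentrations (ug/L) vs fold induction."""

    assay: str
    conc_ugL: np.ndarray
    response_fold: np.ndarray
    metric: str                      # dose metric matched in vivo: CA or CL
    cell_context: str = ""
    ac50_uM: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.conc_ugL = np.asarray(self.conc_ugL, dtype=float)
        self.response_fold = np.asarray(self.response_fold, dtype=float)
        if self.conc_ugL.shape != self.response_fold.shape:
            raise ValueError("concentration and response vectors differ in length")
        if np.any(self.conc_ugL <= 0) or np.any(np.diff(self.conc_ugL) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.metric not in ("CA", "CL"):
            raise ValueError("metric must be CA or CL")

    def __len__(self) -> int:
        return len(self.conc_ugL)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"conc_ugL": self.conc_ugL, "response_fold": self.response_fold}
        )


CONC_UNITS = ("log10_uM", "uM", "ugL")
RESPONSE_UNITS = ("log2_fold", "fold")


def load_assay(
    table: pd.DataFrame,
    conc_units: str,
    response_units: str,
    assay: str = "",
    metric: str | None = None,
    free_fraction: float = DEFAULT_FREE_FRACTION,
    molar_mass: float = MW_PFOA,
    cell_context: str = "",
    ac50_uM: float | None = None,
    flags=(),
) -> ConcentrationResponse:
    """Normalise an assay table to free ug/L and natural fold induction.

    ``conc_units='ugL'`` declares concentrations already free and converted
    (loading such a table is the identity).  When ``metric`` is omitted it
    is inferred from the assay length: the four-concentration endothelial
    design targets serum (CA), the seven-concentration hepatocyte designs
    target liver (CL).
    """
    if conc_units not in CONC_UNITS:
        raise ValueError(f"conc_units must be one of {CONC_UNITS}")
    if response_units not in RESPONSE_UNITS:
        raise ValueError(f"response_units must be one of {RESPONSE_UNITS}")
    if not {"conc", "response"} <= set(table.columns):
        raise ValueError("assay table needs 'conc' and 'response' columns")

    conc = np.asarray(table["conc"], dtype=float)
    if conc_units == "log10_uM":
        conc = apply_free_fraction(um_to_ugL(10.0**conc, molar_mass), free_fraction)
    elif conc_units == "uM":
        conc = apply_free_fraction(um_to_ugL(conc, molar_mass), free_fraction)
    resp = np.asarray(table["response"], dtype=float)
    if response_units == "log2_fold":
        resp = response_to_fold(resp)

    if metric is None:
        metric = "CA" if len(conc) == 4 else "CL"
    flags = list(flags)
    for flag in flags:
        logger.warning("assay %s carries flag: %s (rows retained)", assay, flag)
    return ConcentrationResponse(
        assay=assay,
        conc_ugL=conc,
        response_fold=resp,
        metric=metric,
        cell_context=cell_context,
        ac50_uM=ac50_uM,
        flags=flags,
    )


def read_assay_csv(path, **kwargs) -> ConcentrationResponse:
    """Read an assay CSV whose header block declares units.

    Leading comment lines of the form ``# key: value`` declare
    ``conc_units``, ``response_units`` and optionally ``assay``, ``metric``,
    ``cell_context``, ``ac50_uM`` and ``flags`` (semicolon separated),
    followed by a regular CSV with columns ``conc,response``.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    if "conc_units" not in meta or "response_units" not in meta:
        raise ValueError(f"{path}: unit declaration header missing")
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])))
    call = dict(
        conc_units=meta["conc_units"],
        response_units=meta["response_units"],
        assay=meta.get("assay", ""),
        metric=meta.get("metric") or None,
        cell_context=meta.get("cell_context", ""),
        ac50_uM=float(meta["ac50_uM"]) if "ac50_uM" in meta else None,
        flags=[f for f in meta.get("flags", "").split(";") if f],
    )
    call.update(kwargs)
    return load_assay(table, **call)
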