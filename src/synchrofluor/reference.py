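"""Loaders for the packaged reference fixtures.

Two kinds of fixture ship with the package:

* transcriptions of the reference method's printed validation tables
  (recovery studies, method comparison, regression parameters) — real
  published numbers, usable as inputs and as expected values;
* reconstructed greenness inputs (eco-scale ledger, AGREE vectors,
  NEMI/GAPI profiles) — only their published totals are authoritative;
  the decompositions are synthetic and flagged as such in the files.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .errors import ConfigurationError
from .greenness import AgreeAssessment, CategoricalProfile, EcoScaleLedger
from .validate import MethodSummary

__all__ = [
    "data_path",
    "load_mixture_table",
    "load_plasma_table",
    "load_standard_addition_table",
    "load_printed_summaries",
    "load_method_comparison",
    "load_validation_parameters",
    "load_ecoscale_ledger",
    "load_agree_profile",
    "load_gapi_profile",
    "load_nemi_profile",
]

_METHODS = ("proposed", "hplc")


def data_path(name: str):
    """Filesystem path of a packaged data file."""
    path = resources.files("synchrofluor.data") / name
    if not path.is_file():
        raise ConfigurationError(f"no packaged data file named {name!r}")
    return path


def _read_table(name: str) -> pd.DataFrame:
    return pd.read_csv(data_path(name), comment="#")


def load_mixture_table() -> pd.DataFrame:
    """Added/found pairs (ng/mL) of the synthetic 1:2 mixture study."""
    return _read_table("mixture_recoveries.csv")


def load_plasma_table() -> pd.DataFrame:
    """Added/found pairs (ng/mL) of the spiked-plasma study."""
    return _read_table("plasma_recoveries.csv")


def load_standard_addition_table() -> pd.DataFrame:
    """Standard-addition rows: base sample plus pure-standard increments."""
    return _read_table("standard_addition.csv")


def load_validation_parameters() -> pd.DataFrame:
    """Reported regression/validation parameters (documentation constants)."""
    return _read_table("validation_parameters.csv").set_index("parameter")


def load_printed_summaries() -> dict:
    """Printed Mean/RSD lines of the recovery tables."""
    return json.loads(data_path("printed_summaries.json").read_text())


def load_method_comparison() -> dict:
    """Tablet-assay summaries and printed t/F statistics.

    Returns a dict with per-analyte :class:`~synchrofluor.validate.MethodSummary`
    pairs plus the printed statistics and tabulated critical values.
    """
    raw = json.loads(data_path("method_comparison.json").read_text())
    out: dict = {"critical_t": raw["critical_t"], "critical_f": raw["critical_f"]}
    for analyte in ("FEX", "PSE"):
        item = raw[analyte]
        out[analyte] = {
            "proposed": MethodSummary(**item["proposed"]),
            "reported_hplc": MethodSummary(**item["reported_hplc"]),
            "printed_t": item["printed_t"],
            "printed_f": item["printed_f"],
        }
    return out


def _check_method(method: str) -> str:
    if method not in _METHODS:
        raise ConfigurationError(f"method must be one of {_METHODS}, got {method!r}")
    return method


def load_ecoscale_ledger(method: str = "proposed") -> EcoScaleLedger:
    """Reconstructed eco-scale penalty ledger (only ``proposed`` ships)."""
    if method != "proposed":
        raise ConfigurationError("an eco-scale ledger ships only for 'proposed'")
    return EcoScaleLedger.from_json(data_path("ecoscale_proposed.json"))


def load_agree_profile(method: str = "proposed") -> AgreeAssessment:
    """Reconstructed 12-principle AGREE vector for either method."""
    return AgreeAssessment.from_json(data_path(f"agree_{_check_method(method)}.json"))


def load_gapi_profile(method: str = "proposed") -> CategoricalProfile:
    return CategoricalProfile.from_json(data_path(f"gapi_{_check_method(method)}.json"))


def load_nemi_profile(method: str = "proposed") -> CategoricalProfile:
    return CategoricalProfile.from_json(data_path(f"nemi_{_check_method(method)}.json"))
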