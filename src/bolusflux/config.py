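"""Flat key-value analysis configuration.

The config file is YAML restricted to flat dotted keys, e.g.::

    dose.amount_mg_per_kg: 3.0
    dose.molar_mass_g_per_mol: 147.14
    dose.isotopic_purity: 1.0
    infusion.compound: alanyl-glutamine
    infusion.rate_mg_per_kg_per_h: 25.0
    infusion.molar_mass_g_per_mol: 217.22
    infusion.stoichiometry: 1.0
    ape.convention: mole_fraction
    auc.method: linear
    auc.extrapolate: true
    auc.n_tail: 10
    auc.head_correction: false
    loq_ape: 0.01

Nested YAML mappings are accepted too and flattened with dots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["AnalysisConfig", "load_flat_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the curve-to-endoRa pipeline, with the package defaults."""

    ape_convention: str = "mole_fraction"
    loq_ape: float = 0.01          # % APE below which a point is unquantifiable
    auc_method: str = "linear"     # "linear" | "log"
    extrapolate: bool = True       # add the fitted terminal tail C/k
    n_tail: int = 10               # quantifiable points in the tail window
    head_correction: bool = False  # triangular leading edge, sensitivity only

    def __post_init__(self):
        if self.ape_convention not in ("mole_fraction", "ratio"):
            raise ConfigurationError(f"unknown APE convention {self.ape_convention!r}")
        if self.auc_method not in ("linear", "log"):
            raise ConfigurationError(f"unknown AUC method {self.auc_method!r}")
        if self.loq_ape < 0:
            raise ConfigurationError("loq_ape must be >= 0")
        if self.n_tail < 3:
            raise ConfigurationError("auc.n_tail must be >= 3")


def _flatten(mapping: dict, prefix: str = "") -> dict:
    flat: dict = {}
    for key, value in mapping.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, f"{dotted}."))
        else:
            flat[dotted] = value
    return flat


def load_flat_config(path: str | Path) -> dict:
    """Read a YAML config file into a flat dict of dotted keys."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return _flatten(data)


_ANALYSIS_KEYS = {
    "ape.convention": "ape_convention",
    "loq_ape": "loq_ape",
    "auc.method": "auc_method",
    "auc.extrapolate": "extrapolate",
    "auc.n_tail": "n_tail",
    "auc.head_correction": "head_correction",
}


def analysis_config_from_flat(flat: dict) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a flat dotted-key dict."""
    kwargs = {attr: flat[key] for key, attr in _ANALYSIS_KEYS.items() if key in flat}
    return AnalysisConfig(**kwargs)
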