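"""Run configuration: YAML loading, schema checking, object construction.

The configuration is a nested mapping with blocks ``geometry``,
``transport``, ``source``, ``response``, ``classifier``, ``scan`` and
``synth``; every key has a default, so an empty config is a valid run.
Unknown keys raise a schema error naming the offending path.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .classify import ClassThresholds
from .diffusion import (
    Geometry,
    HydrogelParams,
    InvalidParameterError,
    TransportParams,
    estimate_stokes_einstein_d0,
    hydrogel_corrected_d,
)
from .response import DoseResponseParams, ReporterParams, calibrated_max_fold

__all__ = ["DEFAULT_CONFIG", "ConfigError", "load_config", "RunConfig", "config_hash"]


class ConfigError(ValueError):
    """A configuration value or key violates the schema."""


DEFAULT_CONFIG: dict[str, Any] = {
    "geometry": {"h_mm": 5.0, "l_mm": 10.0},
    "transport": {
        "d0_mm2_s": None,  # None -> Stokes-Einstein from the block below
        "stokes_einstein": {
            "molecular_weight_da": 1700.0,
            "temperature_k": 303.0,
            "viscosity_pa_s": 7.97e-4,
            "partial_specific_volume_cm3_g": 0.73,
        },
        "agarose": {
            "solute_radius_nm": None,  # None -> sphere-equivalent from MW
            "fiber_radius_nm": 1.9,
            "polymer_volume_fraction": 0.0064,
            "scaling_constant_nm": 1.0,
        },
    },
    "source": {
        "c0_uM": 10.0,
        "secretion": {
            "od600": 0.75,
            "per_od_rate": None,  # None -> calibrated against the step source
            "reference_c0_uM": 10.0,
            "reference_od": 0.75,
            "reference_time_h": 6.0,
        },
    },
    "series": {"n_terms": 12},
    "response": {
        "ec50_nM": 10.0,
        "hill": 2.0,
        "shmoo_ceiling": 0.9,
        "basal_elongated": 0.05,
        "elongated_ceiling": 0.5,
        "ec50_elongated_nM": 5.0,
        "promoter_tau_min": 5.0,
        "max_fold_at_20min": 100.0,
        "maturation_halftime_min": 100.0,
        "production_rate": 1.0,
        "detection_factor": 3.0,
        "induction_threshold_nM": 10.0,
    },
    "classifier": {
        "e_circ_max": 0.60,
        "e_shmoo_min": 0.85,
        "area_min_px": 100,
        "area_max_px": 5000,
        "smoothing_sigma_px": 1.0,
        "positions": 16,
        "spacing_mm": 0.3,
        "offset_mm": 0.15,
    },
    "scan": {
        "pixel_size_mm": 0.1,
        "rel_threshold": 0.05,
        "compartment_mm": 5.0,
    },
    "synth": {
        "positions": 16,
        "cells_per_position": 60,
        "image_size_px": 600,
        "pixel_size_um": 0.5,
        "cell_radius_mean_px": 10.0,
        "cell_radius_sd_px": 1.0,
        "noise_sd": 4.0,
        "background_level": 20.0,
        "foreground_level": 120.0,
        "psf_sigma_px": 1.0,
        "survival_prob": 0.9,
    },
    "timepoints_h": [0.0, 2.0, 4.0, 6.0],
    "od_levels": [0.1, 0.5, 1.0, 2.0],
    "seed": 0,
}


def _merge_checked(defaults: Mapping[str, Any], user: Mapping[str, Any], path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], Mapping) and not isinstance(value, Mapping):
            raise ConfigError(f"expected a mapping at {here}")
        if isinstance(defaults[key], Mapping):
            out[key] = _merge_checked(defaults[key], value, here)
        else:
            out[key] = value
    return out


class RunConfig:
    """Resolved configuration with typed accessors for each pipeline stage."""

    def __init__(self, data: dict[str, Any]):
        self.data = data

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def geometry(self) -> Geometry:
        g = self.data["geometry"]
        return Geometry(source_extent_h=g["h_mm"], domain_length_l=g["l_mm"])

    def hydrogel(self) -> HydrogelParams:
        t = self.data["transport"]
        ag = t["agarose"]
        solute = ag["solute_radius_nm"]
        if solute is None:
            from .diffusion import solute_radius_nm

            se = t["stokes_einstein"]
            solute = solute_radius_nm(
                se["molecular_weight_da"], se["partial_specific_volume_cm3_g"]
            )
        return HydrogelParams(
            solute_radius=solute,
            fiber_radius=ag["fiber_radius_nm"],
            polymer_volume_fraction=ag["polymer_volume_fraction"],
            scaling_constant=ag["scaling_constant_nm"],
        )

    def transport(self) -> TransportParams:
        t = self.data["transport"]
        if t["d0_mm2_s"] is not None:
            d0 = float(t["d0_mm2_s"])
        else:
            se = t["stokes_einstein"]
            d0 = estimate_stokes_einstein_d0(
                se["molecular_weight_da"],
                se["temperature_k"],
                se["viscosity_pa_s"],
                se["partial_specific_volume_cm3_g"],
            )
        return TransportParams(
            d0_free=d0,
            d_effective=hydrogel_corrected_d(d0, self.hydrogel()),
            c0_initial=self.data["source"]["c0_uM"],
            n_image_terms=self.data["series"]["n_terms"],
        )

    def dose(self) -> DoseResponseParams:
        r = self.data["response"]
        return DoseResponseParams(
            ec50=r["ec50_nM"],
            hill_coefficient=r["hill"],
            shmoo_ceiling=r["shmoo_ceiling"],
            basal_elongated=r["basal_elongated"],
            elongated_ceiling=r["elongated_ceiling"],
            ec50_elongated=r["ec50_elongated_nM"],
        )

    def reporter(self) -> ReporterParams:
        r = self.data["response"]
        return ReporterParams(
            max_fold=calibrated_max_fold(
                r["max_fold_at_20min"], 20.0, r["promoter_tau_min"]
            ),
            promoter_tau=r["promoter_tau_min"],
            production_rate=r["production_rate"],
            maturation_halftime=r["maturation_halftime_min"],
            detection_factor=r["detection_factor"],
        )

    def thresholds(self) -> ClassThresholds:
        c = self.data["classifier"]
        return ClassThresholds(e_circ_max=c["e_circ_max"], e_shmoo_min=c["e_shmoo_min"])


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML config over the defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigError("config file must contain a mapping")
        data = dict(loaded)
    merged = _merge_checked(DEFAULT_CONFIG, data)
    if overrides:
        merged = _merge_checked(merged, dict(overrides))
    return RunConfig(merged)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the resolved configuration."""
    blob = json.dumps(cfg.data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
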