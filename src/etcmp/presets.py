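"""Shipped parameter fixtures: the calibrated soil profile and crop blocks."""

from __future__ import annotations

from importlib import resources

import yaml

from .fao56 import CropCalendar
from .soil import SoilLayer, SoilProfile, CropParams
from .synthetic import SEASONS

__all__ = ["load_profile", "load_crop_params", "load_crop_calendar", "crop_config"]


def _read_yaml(name: str) -> dict:
    with resources.files("etcmp.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_profile(name: str = "oued_souhil") -> SoilProfile:
    """Shipped soil profile by name (default: the calibrated sandy-loam plot)."""
    soils = _read_yaml("soils.yaml")
    if name not in soils:
        raise KeyError(f"unknown soil profile {name!r}; have {sorted(soils)}")
    layers = [SoilLayer(**entry) for entry in soils[name]["layers"]]
    return SoilProfile(layers)


def crop_config(crop: str) -> dict:
    crops = _read_yaml("crops.yaml")
    if crop not in crops:
        raise KeyError(f"unknown crop {crop!r}; have {sorted(crops)}")
    return crops[crop]


def load_crop_params(crop: str) -> CropParams:
    """Rooting + stress parameters for a shipped crop block."""
    cfg = crop_config(crop)
    return CropParams(
        name=crop,
        root_depth=cfg["root_depth"],
        **{k: cfg["feddes"][k] for k in ("h1", "h2", "h3_high", "h3_low", "h4")},
        ec_threshold=cfg["osmotic"]["ec_threshold"],
        slope_pct=cfg["osmotic"]["slope_pct"],
        t_high=cfg.get("t_high", 5.0),
        t_low=cfg.get("t_low", 1.0),
    )


def load_crop_calendar(season: int) -> CropCalendar:
    """Crop calendar for one of the three monitored seasons (1, 2, 3)."""
    crop, start, end, *_ = SEASONS[season]
    cfg = crop_config(crop)
    return CropCalendar(
        crop=crop, planting=start, harvest=end,
        kc_ini=cfg["kc"]["ini"], kc_mid=cfg["kc"]["mid"], kc_end=cfg["kc"]["end"],
        stage_fractions=tuple(cfg["stage_fractions"]),
        lai_points=[tuple(p) for p in cfg["lai_points"]],
        root_depth=cfg["root_depth"],
    )
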