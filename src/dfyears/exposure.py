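"""Alcohol-exposure categorisation.

One unit is 10 g of ethanol (8 g in a sensitivity recoding).  Moderate
consumption is 1-14 units/week read as (0, threshold]; heavy is anything
exceeding the threshold (14 by default, 21 as a sensitivity).  Any reported
positive consumption makes someone a drinker, however small.  Binge drinking
is a self-report of alcohol-induced loss of consciousness in the past year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CAT3 = ("non_drinker", "moderate", "heavy")
CAT6 = ("never", "former", "moderate_nonbinge", "moderate_binge",
        "heavy_nonbinge", "heavy_binge")
CAT5 = ("never", "former", "occasional", "moderate", "heavy")
MISSING = "missing"


@dataclass(frozen=True)
class CodingConfig:
    """Thresholds for the exposure coding; defaults are the main analysis."""

    heavy_threshold: float = 14.0  # units/week above which drinking is heavy
    unit_grams: float = 10.0       # grams of ethanol per unit

    def __post_init__(self) -> None:
        if self.heavy_threshold <= 0:
            raise ValueError("heavy_threshold must be positive")
        if self.unit_grams <= 0:
            raise ValueError("unit_grams must be positive")


def rescale_units(weekly_units_10g, unit_grams: float = 10.0):
    """Re-express weekly units recorded in 10 g units on another unit size."""
    if unit_grams <= 0:
        raise ValueError("unit_grams must be positive")
    u = np.asarray(weekly_units_10g, dtype=float)
    if (u < 0).any():
        raise ValueError("weekly units must be non-negative")
    out = u * 10.0 / unit_grams
    return float(out) if out.ndim == 0 else out


def _units_for(config: CodingConfig, weekly_units) -> np.ndarray:
    u = np.asarray(weekly_units, dtype=float)
    if (u < 0).any():
        raise ValueError("weekly units must be non-negative")
    return rescale_units(u, config.unit_grams) if config.unit_grams != 10.0 else u


def categorize3(weekly_units, config: CodingConfig = CodingConfig()):
    """Three-level consumption: non_drinker / moderate / heavy."""
    u = _units_for(config, weekly_units)
    out = np.select(
        [u == 0, u <= config.heavy_threshold], ["non_drinker", "moderate"], "heavy"
    )
    return out.item() if out.ndim == 0 else out


def categorize6(weekly_units, ever_drinker, former_drinker, binge,
                config: CodingConfig = CodingConfig()):
    """Six-level use: never/former split of non-drinkers, moderate/heavy x binge.

    Non-drinkers whose ever-drinking item is missing (NaN) are coded
    ``missing`` and dropped by the 6-category analysis downstream.
    """
    u = _units_for(config, weekly_units)
    ever = np.asarray(ever_drinker, dtype=float)
    former = np.asarray(former_drinker, dtype=float)
    bng = np.asarray(binge, dtype=float)
    heavy = u > config.heavy_threshold
    out = np.select(
        [
            (u == 0) & np.isnan(ever),
            (u == 0) & (former == 1),
            (u == 0) & (ever == 0),
            (u == 0),  # ever drinker, no former flag: former by elimination
            ~heavy & (bng == 1),
            ~heavy,
            bng == 1,
        ],
        [MISSING, "former", "never", "former",
         "moderate_binge", "moderate_nonbinge", "heavy_binge"],
        "heavy_nonbinge",
    )
    return out.item() if out.ndim == 0 else out


def categorize_ukb5(weekly_units, ever_drinker, former_drinker, occasional,
                    config: CodingConfig = CodingConfig()):
    """Five-level coding with an explicit occasional-drinking category.

    The occasional flag overrides the unit-based coding; a subject flagged
    occasional yet reporting units above the heavy threshold keeps the
    occasional label, with a warning.
    """
    u = _units_for(config, weekly_units)
    ever = np.asarray(ever_drinker, dtype=float)
    former = np.asarray(former_drinker, dtype=float)
    occ = np.asarray(occasional, dtype=float)
    conflict = (occ == 1) & (u > config.heavy_threshold)
    if np.any(conflict):
        log.warning("%d subjects flagged occasional but report heavy units; "
                    "occasional wins", int(np.sum(conflict)))
    out = np.select(
        [
            occ == 1,
            (u == 0) & (former == 1),
            (u == 0) & (ever == 0),
            (u == 0) & np.isnan(ever),
            u == 0,
            u <= config.heavy_threshold,
        ],
        ["occasional", "former", "never", MISSING, "former", "moderate"],
        "heavy",
    )
    return out.item() if out.ndim == 0 else out


def categorize_daily8(weekly_units):
    """Average daily doses binned 0,1,...,6,7+ (7 codes 7-or-more).

    Zero is reserved for exactly no consumption; any positive consumption maps
    to at least dose category 1 (half-up rounding of weekly/7 otherwise), so
    light drinkers are not conflated with abstainers.
    """
    u = np.asarray(weekly_units, dtype=float)
    if (u < 0).any():
        raise ValueError("weekly units must be non-negative")
    daily = np.floor(u / 7.0 + 0.5)  # round half up
    out = np.where(u == 0, 0, np.clip(daily, 1, 7)).astype(int)
    return int(out) if out.ndim == 0 else out


def add_categories(df: pd.DataFrame, config: CodingConfig = CodingConfig()) -> pd.DataFrame:
    """Append cat3/cat6/cat5/cat8 columns to a subject table."""
    out = df.copy()
    out["cat3"] = categorize3(df["weekly_units"], config)
    out["cat6"] = categorize6(
        df["weekly_units"], df["ever_drinker"], df["former_drinker"], df["binge"], config
    )
    occ = df["occasional"] if "occasional" in df else np.zeros(len(df))
    out["cat5"] = categorize_ukb5(
        df["weekly_units"], df["ever_drinker"], df["former_drinker"], occ, config
    )
    out["cat8"] = categorize_daily8(
        _units_for(config, df["weekly_units"])
    )
    return out
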