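"""Per-food, per-region acceptability bounds from cross-strata intake
distributions.

For each region and food, the distribution of stratum-level mean intakes is
collected over the strata in which the food was reported (zero means are
excluded).  The lower bound is the 10th percentile of that distribution; the
upper bound is the 70th (rigorous), 80th (moderate) or 90th (flexible)
percentile.  Percentiles use linear interpolation between order statistics
(the common "type 7" estimator) — fixed and documented because the bounds
feed the LP directly.  Foods never reported anywhere in a region get bounds
(0, 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .food_data import StratumProfile

__all__ = [
    "AcceptabilityBounds",
    "LEVELS",
    "LEVEL_UPPER_PERCENTILE",
    "LOWER_PERCENTILE",
    "derive_bounds",
    "bounds_for_stratum",
    "write_bounds",
]

LEVELS = ("rigorous", "moderate", "flexible")
LEVEL_UPPER_PERCENTILE = {"rigorous": 70.0, "moderate": 80.0, "flexible": 90.0}
LOWER_PERCENTILE = 10.0


@dataclass(frozen=True)
class AcceptabilityBounds:
    """Lower/upper intake bounds (g/day) per food for one region and level.

    ``ref_mean`` carries the mean of the contributing (non-zero) stratum
    means per food; it serves as the relative-deviation denominator for
    foods a stratum did not report.
    """

    region: str
    level: str
    lower: Mapping[str, float]
    upper: Mapping[str, float]
    ref_mean: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise InvalidInputError(f"unknown acceptability level {self.level!r}")
        for food in self.lower:
            lo, hi = self.lower[food], self.upper.get(food, 0.0)
            if not (0.0 <= lo <= hi):
                raise InvalidInputError(
                    f"food {food!r}: bounds must satisfy 0 <= lower <= upper, "
                    f"got ({lo}, {hi})"
                )


def derive_bounds(
    strata_means: Mapping[str, Mapping[str, float]],
    region_of: Mapping[str, str],
    level: str,
) -> dict[str, AcceptabilityBounds]:
    """Acceptability bounds per region at one level.

    ``strata_means`` maps stratum -> (food -> mean g/day) over the *full*
    population of strata; ``region_of`` assigns each stratum to a region.
    """
    if not strata_means:
        raise InvalidInputError("at least one stratum is required")
    if level not in LEVELS:
        raise InvalidInputError(f"unknown acceptability level {level!r}")
    upper_pct = LEVEL_UPPER_PERCENTILE[level]

    by_region: dict[str, dict[str, list[float]]] = {}
    for sid, means in strata_means.items():
        try:
            region = region_of[sid]
        except KeyError:
            raise InvalidInputError(f"stratum {sid!r} has no region") from None
        foods = by_region.setdefault(region, {})
        for food, mean in means.items():
            if mean < 0:
                raise InvalidInputError(f"negative mean intake for {food!r}")
            foods.setdefault(food, []).append(mean)

    out: dict[str, AcceptabilityBounds] = {}
    for region, foods in by_region.items():
        lower, upper, ref = {}, {}, {}
        for food, means in foods.items():
            nonzero = np.array([m for m in means if m > 0])
            if nonzero.size == 0:
                lower[food] = upper[food] = ref[food] = 0.0
                continue
            lower[food] = float(np.percentile(nonzero, LOWER_PERCENTILE, method="linear"))
            upper[food] = float(np.percentile(nonzero, upper_pct, method="linear"))
            ref[food] = float(nonzero.mean())
        out[region] = AcceptabilityBounds(region, level, lower, upper, ref)
    return out


def bounds_for_stratum(
    bounds: Mapping[str, AcceptabilityBounds] | AcceptabilityBounds,
    stratum: StratumProfile,
) -> dict[str, tuple[float, float]]:
    """Region bounds restricted to the stratum's food list.

    Foods absent from the region table (never reported in the region) get
    (0, 0) with a warning.
    """
    if isinstance(bounds, AcceptabilityBounds):
        region_bounds = bounds
    else:
        try:
            region_bounds = bounds[stratum.region]
        except KeyError:
            raise LookupError(f"no bounds for region {stratum.region!r}") from None
    out = {}
    for food in stratum.foods:
        if food not in region_bounds.lower:
            warnings.warn(
                f"food {food!r} never reported in region {region_bounds.region!r}; "
                "bounds set to (0, 0)",
                stacklevel=2,
            )
            out[food] = (0.0, 0.0)
        else:
            out[food] = (region_bounds.lower[food], region_bounds.upper[food])
    return out


def write_bounds(
    bounds_by_level: Mapping[str, Mapping[str, AcceptabilityBounds]],
    path: str | Path,
) -> None:
    """Audit CSV: region, level, food, lower, upper."""
    rows = []
    for level, by_region in bounds_by_level.items():
        for region, b in sorted(by_region.items()):
            for food in sorted(b.lower):
                rows.append(
                    {
                        "region": region,
                        "level": level,
                        "food": food,
                        "lower": b.lower[food],
                        "upper": b.upper[food],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
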