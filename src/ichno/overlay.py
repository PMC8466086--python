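"""Weighted linear combination with surficial-cover penalty.

The aggregated suitability for one ichnofossil type at a cell is

    N = (sum_i w_i * x_i) - (4 - K)

where x_i are the palaeoenvironmental factor scores (L, H, E, S, W on
the ordinal 1-4 scale), w_i their non-negative weights summing to 1,
and K the surficial-cover score.  With weights summing to 1 and K = 4
(uncovered bedrock) the result stays on the 1-4 scale; under heavy
cover it can fall as low as -2.  No clamping is applied.

Factors carrying a zero weight in a profile are ignored entirely and
need not be supplied.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ichno.catalogue import WeightProfile
from ichno.grids import Raster, ensure_shared_grid


class AggregationError(ValueError):
    """Missing required factor or incompatible rasters."""


def aggregate_cell(
    profile: WeightProfile,
    K: float,
    L: float | None = None,
    H: float | None = None,
    E: float | None = None,
    S: float | None = None,
    W: float | None = None,
) -> float:
    """Aggregate one cell's factor scores under ``profile``.

    Every factor with a positive weight must be supplied; zero-weight
    factors are ignored.  Returns the unclamped weighted sum minus the
    cover penalty ``4 - K``.
    """
    supplied = {"L": L, "H": H, "E": E, "S": S, "W": W}
    total = 0.0
    for factor, weight in profile.as_dict().items():
        if weight == 0.0:
            continue
        value = supplied[factor]
        if value is None:
            raise AggregationError(
                f"profile {profile.profile_name}: factor {factor} has weight "
                f"{weight} but no score was supplied"
            )
        total += weight * float(value)
    return total - (4.0 - float(K))


def aggregate_raster(
    factor_rasters: Mapping[str, Raster], profile: WeightProfile
) -> Raster:
    """Per-cell weighted overlay of factor rasters for one profile.

    A cell is nodata iff any required input cell (positive-weight
    factor or K) is nodata.  All rasters must share one grid.
    """
    required = list(profile.required_factors) + ["K"]
    missing = [f for f in required if f not in factor_rasters]
    if missing:
        raise AggregationError(
            f"profile {profile.profile_name}: missing factor raster(s) "
            f"{missing}"
        )
    used = {f: factor_rasters[f] for f in required}
    grid = ensure_shared_grid(used)
    total = np.zeros(grid.shape)
    for factor, weight in profile.as_dict().items():
        if weight == 0.0:
            continue
        total = total + weight * used[factor].values
    values = total - (4.0 - used["K"].values)
    return Raster(grid, values, kind=profile.profile_name)


def run_all_profiles(
    factor_rasters: Mapping[str, Raster],
    profiles: Mapping[str, WeightProfile],
) -> dict[str, Raster]:
    """One suitability raster per profile (A, B, C), on the shared grid."""
    return {
        name: aggregate_raster(factor_rasters, profile)
        for name, profile in profiles.items()
    }
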