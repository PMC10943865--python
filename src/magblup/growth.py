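"""Longitudinal average daily gain (ADG) from weekly weight series.

Seventeen weekly weights per animal cover four consecutive 4-week growth
intervals. Each interval's ADG is the ordinary-least-squares slope of
weight (kg) on day over five weight points; consecutive windows share
their boundary point (4 windows x 5 points - 3 shared = 17).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: slices of the 17-point series defining the four 5-point windows
ADG_WINDOWS = [slice(0, 5), slice(4, 9), slice(8, 13), slice(12, 17)]

ADG_NAMES = ["ADG_1", "ADG_2", "ADG_3", "ADG_4"]

N_POINTS = 17


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def compute_adg(days: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Four window slopes (kg/day) from one animal's 17-point series.

    Parameters
    ----------
    days
        Day offsets of the weighings, strictly increasing, length 17.
    weights
        Body weights in kg, positive, length 17.

    Returns
    -------
    ndarray of shape (4,) with ADG_1..ADG_4 in kg/day.
    """
    days = np.asarray(days, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if days.shape != (N_POINTS,) or weights.shape != (N_POINTS,):
        raise ValueError(
            f"expected exactly {N_POINTS} weight points, got {days.size}"
        )
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing without duplicates")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return np.array([_ols_slope(days[w], weights[w]) for w in ADG_WINDOWS])


def adg_table(weights: pd.DataFrame) -> pd.DataFrame:
    """ADG table (one row per animal) from a long weight table.

    Parameters
    ----------
    weights
        Long-format table with columns ``animal``, ``day``, ``weight_kg``.

    Returns
    -------
    DataFrame indexed by animal with columns ADG_1..ADG_4 (kg/day).
    """
    required = {"animal", "day", "weight_kg"}
    missing = required - set(weights.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    rows = {}
    for animal, grp in weights.groupby("animal", sort=True):
        grp = grp.sort_values("day")
        rows[animal] = compute_adg(
            grp["day"].to_numpy(), grp["weight_kg"].to_numpy()
        )
    out = pd.DataFrame.from_dict(rows, orient="index", columns=ADG_NAMES)
    out.index.name = "animal"
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite ADG computed; check input weights")
    return out
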