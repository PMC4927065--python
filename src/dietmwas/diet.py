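"""FFQ frequencies -> energy-adjusted food-group intakes (servings/week).

A food-frequency questionnaire records, per subject and food item, a category
on a 9-point scale from "never or less than once per month" to "6+ times per
day", plus total energy intake (kcal/day).  The chain here converts category
codes to servings/week via a configurable midpoint map, sums items into food
groups, and removes confounding by overall consumption with the residual
method: each group intake is replaced by its residual from a least-squares
regression on total energy, re-centred on the group mean so that units and
location are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ENERGY_COL = "energy_kcal"

#: 9-point frequency scale, code -> (label, servings/week midpoint).
#: The midpoints follow the EPIC-style convention: category centres on a
#: weekly basis, daily categories multiplied by 7.
FFQ_SCALE: dict[int, tuple[str, float]] = {
    0: ("never or <1/month", 0.0),
    1: ("1-3 per month", 0.5),
    2: ("once a week", 1.0),
    3: ("2-4 per week", 3.0),
    4: ("5-6 per week", 5.5),
    5: ("once a day", 7.0),
    6: ("2-3 per day", 17.5),
    7: ("4-5 per day", 31.5),
    8: ("6+ per day", 45.0),
}

DEFAULT_SCALE_MAP: dict[int, float] = {c: spw for c, (_, spw) in FFQ_SCALE.items()}

__all__ = [
    "ENERGY_COL",
    "FFQ_SCALE",
    "DEFAULT_SCALE_MAP",
    "FoodGroupMap",
    "frequency_to_servings",
    "aggregate_food_groups",
    "energy_adjust_residual",
    "energy_adjust_matrix",
    "ffq_to_food_groups",
]


@dataclass(frozen=True)
class FoodGroupMap:
    """Many-to-one mapping of FFQ items onto food groups."""

    item_to_group: dict[str, str]

    def __post_init__(self) -> None:
        if not self.item_to_group:
            raise ValueError("empty food-group map")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.item_to_group.values():
            seen.setdefault(g)
        return list(seen)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FoodGroupMap":
        return cls(dict(zip(df["item"].astype(str), df["group"].astype(str))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item": list(self.item_to_group), "group": list(self.item_to_group.values())}
        )


def _validate_scale_map(scale_map: dict[int, float]) -> None:
    codes = sorted(scale_map)
    if codes != list(range(9)):
        raise ValueError("scale map must cover exactly the 9 codes 0..8")
    vals = [scale_map[c] for c in codes]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValueError("scale map must be non-decreasing in frequency code")


def frequency_to_servings(
    ffq: pd.DataFrame, scale_map: dict[int, float] | None = None
) -> pd.DataFrame:
    """Map per-item 9-point frequency codes to servings/week.

    ``ffq`` has one row per subject, item columns holding integer codes 0..8,
    and optionally an ``energy_kcal`` column (passed through untouched is not
    needed here — it is simply excluded from the output).
    """
    scale_map = DEFAULT_SCALE_MAP if scale_map is None else scale_map
    _validate_scale_map(scale_map)
    items = [c for c in ffq.columns if c != ENERGY_COL]
    codes = ffq[items]
    valid = codes.isin(list(scale_map))
    if not valid.all().all():
        rows, cols = np.nonzero(~valid.to_numpy())
        subj, item = codes.index[rows[0]], items[cols[0]]
        raise ValueError(
            f"unknown frequency code {codes.iat[rows[0], cols[0]]!r} "
            f"for subject {subj!r}, item {item!r}"
        )
    out = codes.apply(lambda col: col.map(scale_map)).astype(float)
    return out


def aggregate_food_groups(items: pd.DataFrame, fg_map: FoodGroupMap) -> pd.DataFrame:
    """Sum item-level servings/week into food groups (subjects x groups)."""
    unmapped = [c for c in items.columns if c not in fg_map.item_to_group]
    if unmapped:
        raise ValueError(f"items not covered by the food-group map: {unmapped}")
    groups = fg_map.groups
    out = pd.DataFrame(0.0, index=items.index, columns=groups)
    for item, group in fg_map.item_to_group.items():
        if item in items.columns:
            out[group] = out[group] + items[item].astype(float)
    return out


def energy_adjust_residual(group_values: np.ndarray, energy: np.ndarray) -> np.ndarray:
    """Residual-method energy adjustment of one intake vector.

    Returns the residuals of the least-squares regression of ``group_values``
    on ``energy``, plus the sample mean of ``group_values``.  The output has
    the same mean as the input, is uncorrelated with energy, and never has
    larger variance than the input.
    """
    g = np.asarray(group_values, dtype=float).ravel()
    e = np.asarray(energy, dtype=float).ravel()
    if g.size != e.size:
        raise ValueError("group and energy vectors differ in length")
    if g.size < 3:
        raise ValueError("need at least 3 subjects for the residual method")
    if np.ptp(e) == 0:
        raise ValueError("energy intake is constant; residual method undefined")
    e_c = e - e.mean()
    slope = float(e_c @ (g - g.mean())) / float(e_c @ e_c)
    return g - slope * e_c


def energy_adjust_matrix(foods: pd.DataFrame, energy: pd.Series) -> pd.DataFrame:
    """Apply the residual method to every column of a food-group matrix."""
    if not foods.index.equals(energy.index):
        energy = energy.reindex(foods.index)
        if energy.isna().any():
            raise ValueError("energy missing for some subjects")
    e = energy.to_numpy(dtype=float)
    out = {g: energy_adjust_residual(foods[g].to_numpy(), e) for g in foods.columns}
    return pd.DataFrame(out, index=foods.index)[foods.columns]


def ffq_to_food_groups(
    ffq: pd.DataFrame,
    fg_map: FoodGroupMap,
    scale_map: dict[int, float] | None = None,
    adjust_order: str = "group",
) -> pd.DataFrame:
    """Full chain: codes -> servings/week -> group sums -> energy adjustment.

    ``adjust_order`` selects whether the residual adjustment runs on the item
    table before aggregation (``"item"``) or on the group sums (``"group"``,
    the default — effect sizes downstream are interpreted per food group).
    """
    if adjust_order not in ("group", "item"):
        raise ValueError("adjust_order must be 'group' or 'item'")
    if ENERGY_COL not in ffq.columns:
        raise ValueError(f"FFQ table lacks the {ENERGY_COL!r} column")
    energy = ffq[ENERGY_COL].astype(float)
    if (energy <= 0).any():
        bad = list(ffq.index[energy <= 0])
        raise ValueError(f"non-positive total energy for subjects {bad}")
    servings = frequency_to_servings(ffq, scale_map)
    if adjust_order == "item":
        servings = energy_adjust_matrix(servings, energy)
        return aggregate_food_groups(servings, fg_map)
    grouped = aggregate_food_groups(servings, fg_map)
    return energy_adjust_matrix(grouped, energy)
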