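"""Metabolite panels and the platform-specific preprocessing chains.

Two platforms are handled:

* ``non_targeted`` — relative MS intensities with run-day (batch) labels and
  missing values.  Chain: run-day median normalization -> missingness filter
  (strictly more than ``max_missing_frac`` missing excluded) -> run-day-minimum
  imputation -> rank-based inverse-normal transform.
* ``targeted`` — absolute concentrations (mM), right-skewed.  Chain: natural
  log -> removal of metabolites that duplicate the non-targeted panel.

Each operation returns a new panel and appends its name to ``steps``; the
preconditions check ``steps`` so the chains can only be applied in order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NON_TARGETED = "non_targeted"
TARGETED = "targeted"

__all__ = [
    "MetabolitePanel",
    "run_day_median_normalize",
    "filter_missingness",
    "impute_run_day_minimum",
    "inverse_normal_transform",
    "inverse_normal_panel",
    "log_transform_targeted",
    "drop_overlapping",
    "NON_TARGETED",
    "TARGETED",
]


@dataclass
class MetabolitePanel:
    """Subjects x metabolites value matrix with processing provenance.

    ``values`` holds one row per subject and one column per metabolite; missing
    measurements are NaN.  ``run_day`` labels the acquisition batch of each
    subject's sample.  ``truth_values`` optionally retains the pre-missingness
    matrix from a simulator for oracle checks; it takes no part in processing.
    """

    values: pd.DataFrame
    platform: str
    run_day: pd.Series | None = None
    steps: list[str] = field(default_factory=list)
    annotations: pd.DataFrame | None = None
    truth_values: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.platform not in (NON_TARGETED, TARGETED):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.run_day is not None:
            if not self.run_day.index.equals(self.values.index):
                raise ValueError("run_day index must match subject index")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.values.isna()

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=0)

    def _with(self, values: pd.DataFrame, step: str,
              extra_warnings: list[str] | None = None) -> "MetabolitePanel":
        return replace(
            self,
            values=values,
            steps=[*self.steps, step],
            warnings=[*self.warnings, *(extra_warnings or [])],
        )


def run_day_median_normalize(panel: MetabolitePanel) -> MetabolitePanel:
    """Divide each value by the median of its metabolite on its run day.

    After normalization the per-(metabolite, run-day) median of observed
    values equals 1 wherever at least one value was observed.  Run days on
    which a metabolite is entirely missing are left missing and logged.
    """
    if panel.platform != NON_TARGETED:
        raise ValueError("run-day median normalization applies to the "
                         "non_targeted platform only")
    if panel.run_day is None:
        raise ValueError("panel has no run-day labels")
    if panel.steps:
        raise ValueError(f"must be the first step; panel already has {panel.steps}")

    warns: list[str] = []
    out = panel.values.copy()
    for day, idx in panel.values.groupby(panel.run_day).groups.items():
        block = panel.values.loc[idx]
        med = block.median(axis=0, skipna=True)
        empty = med.isna() | (med == 0)
        for m in panel.values.columns[empty & block.isna().all(axis=0)]:
            msg = f"metabolite {m!r} entirely missing on run day {day!r}; left missing"
            warns.append(msg)
            logger.warning(msg)
        if (med == 0).any():
            bad = list(panel.values.columns[med == 0])
            raise ValueError(f"zero day median for {bad} on run day {day!r}")
        out.loc[idx] = block.div(med, axis=1)
    return panel._with(out, "run_day_median_normalize", warns)


def filter_missingness(
    panel: MetabolitePanel, max_missing_frac: float = 0.20
) -> tuple[MetabolitePanel, list[str]]:
    """Exclude metabolites missing in strictly more than ``max_missing_frac``.

    A metabolite missing in exactly the threshold fraction of samples is
    retained.  Column order of the retained metabolites is preserved.
    """
    frac = panel.missing_fraction()
    excluded = [m for m in panel.metabolites if frac[m] > max_missing_frac]
    kept = [m for m in panel.metabolites if m not in set(excluded)]
    out = panel._with(panel.values[kept], "filter_missingness")
    if out.annotations is not None:
        out = replace(out, annotations=out.annotations.loc[kept])
    if out.truth_values is not None:
        out = replace(out, truth_values=out.truth_values[kept])
    return out, excluded


def impute_run_day_minimum(panel: MetabolitePanel) -> MetabolitePanel:
    """Replace each missing value by its metabolite's run-day minimum.

    Missing cells on run days where the metabolite was never observed fall
    back to the metabolite's global minimum.  Requires the missingness filter
    to have run first, so every metabolite has at least one observed value.
    """
    if "filter_missingness" not in panel.steps:
        raise ValueError("apply filter_missingness before imputation")
    never = panel.values.isna().all(axis=0)
    if never.any():
        raise ValueError(
            f"metabolites with no observed values: {list(panel.metabolites[never])}"
        )
    if panel.run_day is None:
        raise ValueError("panel has no run-day labels")

    out = panel.values.copy()
    global_min = panel.values.min(axis=0, skipna=True)
    for _, idx in panel.values.groupby(panel.run_day).groups.items():
        block = out.loc[idx]
        day_min = block.min(axis=0, skipna=True).fillna(global_min)
        out.loc[idx] = block.fillna(day_min)
    return panel._with(out, "impute_run_day_minimum")


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform of a 1-D vector.

    Maps value of average rank r (ties averaged) among n to
    ``Phi^{-1}((r - 0.375) / (n + 0.25))``.  Undefined for constant input.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0:
        raise ValueError("inverse-normal transform undefined for a constant vector")
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.375) / (n + 0.25))


def inverse_normal_panel(panel: MetabolitePanel) -> MetabolitePanel:
    """Apply the Blom transform to every metabolite of a fully imputed panel."""
    if "impute_run_day_minimum" not in panel.steps:
        raise ValueError("apply impute_run_day_minimum before the inverse-normal step")
    if panel.values.isna().any().any():
        raise ValueError("panel still contains missing values")
    out = pd.DataFrame(np.column_stack(
        [inverse_normal_transform(panel.values[m].to_numpy())
         for m in panel.metabolites]),
        index=panel.subjects, columns=panel.metabolites)
    return panel._with(out, "inverse_normal")


def log_transform_targeted(panel: MetabolitePanel) -> MetabolitePanel:
    """Natural log of a targeted concentration panel (right-skew correction)."""
    if panel.platform != TARGETED:
        raise ValueError("log transform applies to the targeted platform only")
    vals = panel.values
    bad = (vals <= 0)
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        subj, met = vals.index[rows[0]], vals.columns[cols[0]]
        raise ValueError(
            f"non-positive concentration at subject {subj!r}, metabolite {met!r}"
        )
    return panel._with(np.log(vals), "log_transform")


def drop_overlapping(panel: MetabolitePanel, overlap_ids: list[str]) -> MetabolitePanel:
    """Remove metabolites that duplicate the other platform's panel.

    Overlap ids absent from the panel are reported as warnings, never silently
    ignored.  Applying the same list twice is a no-op the second time.
    """
    if panel.platform != TARGETED:
        raise ValueError("overlap removal applies to the targeted platform only")
    present = set(panel.metabolites)
    warns = []
    for m in overlap_ids:
        if m not in present:
            msg = f"overlap id {m!r} not found in targeted panel"
            warns.append(msg)
            logger.warning(msg)
    keep = [m for m in panel.metabolites if m not in set(overlap_ids)]
    out = panel._with(panel.values[keep], "drop_overlapping", warns)
    if out.annotations is not None:
        out = replace(out, annotations=out.annotations.loc[keep])
    if out.truth_values is not None:
        out = replace(out, truth_values=out.truth_values[keep])
    return out
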