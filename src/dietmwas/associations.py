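"""Discordance partitioning, discovery/replication regressions, meta-analysis.

The inference proceeds per food group:

1. the sample SD of the (energy-adjusted) intake is computed over all subjects
   with an observed value; complete MZ pairs whose within-pair intake
   difference is at least one SD are *discordant*;
2. discovery: every metabolite is regressed on the intake in the sample that
   excludes discordant MZ pairs, under a family random-intercept model with
   age, BMI and acquisition batch as covariates; Bonferroni correction over
   all (food group x metabolite) tests flags significant pairs;
3. replication: significant pairs are refitted on the discordant-MZ-pair
   sample — genetically matched co-twin controls — and count as replicated
   when the effect direction agrees with discovery and (non-targeted platform
   only) the replication p-value is below 5%;
4. the two estimates are combined by inverse-variance fixed-effect
   meta-analysis, which is the reported result.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import FamilyLMMResult, SingularDesignError, fit_family_reml
from .panels import NON_TARGETED, MetabolitePanel

logger = logging.getLogger(__name__)

DISCOVERY = "discovery"
REPLICATION = "replication"

MIN_FIT_SUBJECTS = 10

__all__ = [
    "DiscordancePartition",
    "AssociationRecord",
    "MetaRecord",
    "ResultsBundle",
    "classify_discordant_pairs",
    "fit_random_intercept",
    "bonferroni_threshold",
    "discovery_scan",
    "replicate",
    "meta_fixed_effect",
    "run_pipeline",
]


@dataclass
class DiscordancePartition:
    """Discovery/replication split of one food group's analysis sample."""

    food_group: str
    sd: float                       # sample SD of intake (servings/week)
    discovery_ids: list[str]
    replication_ids: list[str]      # members of discordant MZ pairs only
    discordant_pairs: dict[str, bool]  # complete MZ pairs -> discordant flag
    warning: str | None = None


@dataclass
class AssociationRecord:
    food_group: str
    metabolite: str
    platform: str
    stage: str                      # "discovery" | "replication"
    beta: float
    se: float
    p: float
    n: int
    n_families: int
    significant: bool = False       # discovery: p < Bonferroni threshold
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class MetaRecord:
    food_group: str
    metabolite: str
    platform: str
    beta: float
    se: float
    p: float
    replicated: bool
    significant: bool


def classify_discordant_pairs(
    food_group: pd.Series,
    cohort: pd.DataFrame,
    sd_multiplier: float = 1.0,
) -> DiscordancePartition:
    """Split subjects on MZ-pair intake discordance (>= ``sd_multiplier`` SDs).

    The SD is the sample SD (ddof=1) of the intake over all subjects with an
    observed value.  Complete MZ pairs at least ``sd_multiplier`` SDs apart go
    to replication; everyone else with an observed intake — DZ pairs,
    concordant MZ pairs, singletons, and twins whose co-twin intake is missing
    — goes to discovery.
    """
    name = str(food_group.name) if food_group.name is not None else "food_group"
    obs = food_group.dropna()
    sd = float(obs.std(ddof=1)) if obs.size > 1 else 0.0
    warning = None
    discordant: dict[str, bool] = {}
    replication: list[str] = []

    if sd == 0.0:
        warning = f"intake SD is zero for {name!r}; no pair can be discordant"
        logger.warning(warning)

    fam = cohort.loc[obs.index, ["family_id", "zygosity"]]
    for fam_id, members in fam[fam["zygosity"] == "MZ"].groupby("family_id").groups.items():
        if len(members) != 2:
            continue  # incomplete pair: observed member stays in discovery
        a, b = obs[members[0]], obs[members[1]]
        flag = sd > 0 and abs(a - b) >= sd_multiplier * sd
        discordant[str(fam_id)] = bool(flag)
        if flag:
            replication.extend([str(m) for m in members])

    rep_set = set(replication)
    discovery = [str(s) for s in obs.index if s not in rep_set]
    return DiscordancePartition(
        food_group=name,
        sd=sd,
        discovery_ids=discovery,
        replication_ids=replication,
        discordant_pairs=discordant,
        warning=warning,
    )


def _design(
    food: np.ndarray,
    age: np.ndarray,
    bmi: np.ndarray,
    batch: np.ndarray | None,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(food), food, age, bmi]
    names = ["intercept", "food_group", "age", "bmi"]
    if batch is not None:
        levels = sorted(pd.unique(batch))
        for lev in levels[1:]:  # first level (lexicographic) is the reference
            cols.append((batch == lev).astype(float))
            names.append(f"batch[{lev}]")
    return np.column_stack(cols), names


def fit_random_intercept(
    metabolite: np.ndarray,
    food_group: np.ndarray,
    age: np.ndarray,
    bmi: np.ndarray,
    batch: np.ndarray | None,
    family_id: np.ndarray,
) -> tuple[FamilyLMMResult, int]:
    """REML fit of metabolite ~ food + age + BMI + batch + (1 | family).

    Rows with any missing value are dropped (listwise deletion); the number of
    dropped rows is returned alongside the fit.
    """
    y = np.asarray(metabolite, dtype=float)
    arrays = [np.asarray(a, dtype=float) for a in (food_group, age, bmi)]
    keep = np.isfinite(y)
    for a in arrays:
        keep &= np.isfinite(a)
    n_dropped = int((~keep).sum())
    y = y[keep]
    food, age_v, bmi_v = (a[keep] for a in arrays)
    batch_v = None if batch is None else np.asarray(batch)[keep]
    fam = np.asarray(family_id)[keep]
    if y.size < MIN_FIT_SUBJECTS:
        raise ValueError(
            f"too few subjects after listwise deletion ({y.size} < {MIN_FIT_SUBJECTS})"
        )
    X, names = _design(food, age_v, bmi_v, batch_v)
    res = fit_family_reml(y, X, fam, exog_names=names)
    return res, n_dropped


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests controlling the family-wise error."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return alpha / n_tests


def _record_from_fit(
    res: FamilyLMMResult, food_group: str, metabolite: str, platform: str, stage: str
) -> AssociationRecord:
    j = res.exog_names.index("food_group")
    return AssociationRecord(
        food_group=food_group,
        metabolite=metabolite,
        platform=platform,
        stage=stage,
        beta=float(res.beta[j]),
        se=float(res.se[j]),
        p=float(res.pvalues[j]),
        n=res.n_obs,
        n_families=res.n_families,
    )


def _failed_record(food_group, metabolite, platform, stage, err) -> AssociationRecord:
    return AssociationRecord(
        food_group=food_group, metabolite=metabolite, platform=platform,
        stage=stage, beta=np.nan, se=np.nan, p=np.nan, n=0, n_families=0,
        error=str(err),
    )


def _fit_subset(
    panel: MetabolitePanel,
    metabolite: str,
    foods: pd.DataFrame,
    food_group: str,
    cohort: pd.DataFrame,
    subject_ids: Sequence[str],
    stage: str,
) -> AssociationRecord:
    idx = pd.Index(subject_ids)
    try:
        res, _ = fit_random_intercept(
            panel.values.loc[idx, metabolite].to_numpy(),
            foods.loc[idx, food_group].to_numpy(),
            cohort.loc[idx, "age"].to_numpy(),
            cohort.loc[idx, "bmi"].to_numpy(),
            None if panel.run_day is None else panel.run_day.loc[idx].to_numpy(),
            cohort.loc[idx, "family_id"].to_numpy(),
        )
    except (ValueError, SingularDesignError, np.linalg.LinAlgError) as err:
        return _failed_record(food_group, metabolite, panel.platform, stage, err)
    return _record_from_fit(res, food_group, metabolite, panel.platform, stage)


def discovery_scan(
    panels: MetabolitePanel | Sequence[MetabolitePanel],
    foods: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    sd_multiplier: float = 1.0,
    n_tests_override: int | None = None,
) -> tuple[list[AssociationRecord], dict[str, DiscordancePartition], float]:
    """Fit every (food group, metabolite) pair on its discovery subset.

    The Bonferroni denominator defaults to the number of tested pairs across
    all supplied panels; ``n_tests_override`` substitutes a fixed denominator
    (e.g. the full published scan size) instead.  Returns the records, the
    per-food-group partitions, and the per-test threshold.  Fit failures are
    collected as records carrying an ``error`` and do not abort the scan.
    """
    if isinstance(panels, MetabolitePanel):
        panels = [panels]
    n_met = sum(len(p.metabolites) for p in panels)
    n_tests = n_tests_override or len(foods.columns) * n_met
    threshold = bonferroni_threshold(alpha, n_tests)

    partitions: dict[str, DiscordancePartition] = {}
    records: list[AssociationRecord] = []
    n_failed = 0
    for g in foods.columns:
        part = classify_discordant_pairs(foods[g], cohort, sd_multiplier)
        partitions[str(g)] = part
        for panel in panels:
            for m in panel.metabolites:
                rec = _fit_subset(panel, m, foods, g, cohort,
                                  part.discovery_ids, DISCOVERY)
                if rec.ok:
                    rec.significant = rec.p < threshold
                else:
                    n_failed += 1
                records.append(rec)
    if n_failed:
        logger.warning("discovery scan: %d of %d fits failed", n_failed, len(records))
    return records, partitions, threshold


def replication_decision(
    disc: AssociationRecord,
    rep: AssociationRecord,
    replication_alpha: float = 0.05,
) -> bool:
    """Replicated iff the direction matches discovery and, for the
    non-targeted platform only, the replication p-value is below the 5%
    level (two-sided)."""
    if not rep.ok:
        return False
    same_direction = bool(np.sign(rep.beta) == np.sign(disc.beta))
    if disc.platform == NON_TARGETED:
        return same_direction and rep.p < replication_alpha
    return same_direction


def replicate(
    significant: Iterable[AssociationRecord],
    panels: MetabolitePanel | Sequence[MetabolitePanel],
    foods: pd.DataFrame,
    cohort: pd.DataFrame,
    partitions: dict[str, DiscordancePartition],
    replication_alpha: float = 0.05,
) -> tuple[list[AssociationRecord], list[bool]]:
    """Refit discovery-significant pairs on the discordant-MZ-pair sample.

    Replication requires the effect direction to match discovery; for the
    non-targeted platform the replication p-value must additionally fall below
    ``replication_alpha``.  Pairs whose replication sample is too small are
    marked unreplicable (reason on the record), never silently dropped.
    """
    if isinstance(panels, MetabolitePanel):
        panels = [panels]
    by_platform = {p.platform: p for p in panels}
    out: list[AssociationRecord] = []
    flags: list[bool] = []
    for disc in significant:
        if not disc.significant:
            raise ValueError(
                f"record ({disc.food_group}, {disc.metabolite}) is not "
                "discovery-significant"
            )
        part = partitions[disc.food_group]
        panel = by_platform[disc.platform]
        if len(part.replication_ids) < MIN_FIT_SUBJECTS:
            rec = _failed_record(
                disc.food_group, disc.metabolite, disc.platform, REPLICATION,
                f"replication set too small ({len(part.replication_ids)} subjects)",
            )
            out.append(rec)
            flags.append(False)
            continue
        rec = _fit_subset(panel, disc.metabolite, foods, disc.food_group,
                          cohort, part.replication_ids, REPLICATION)
        out.append(rec)
        flags.append(replication_decision(disc, rec, replication_alpha))
    return out, flags


def meta_fixed_effect(
    disc: AssociationRecord,
    rep: AssociationRecord,
    threshold: float = 0.05,
    replicated: bool = False,
) -> MetaRecord:
    """Inverse-variance fixed-effect combination of the two stage estimates.

    Weights are 1/SE^2; the meta p-value is the two-sided normal tail of
    beta/SE.  The combined SE never exceeds either stage SE and the combined
    beta lies between the stage betas.
    """
    if (disc.food_group, disc.metabolite) != (rep.food_group, rep.metabolite):
        raise ValueError(
            f"mismatched pair: ({disc.food_group}, {disc.metabolite}) vs "
            f"({rep.food_group}, {rep.metabolite})"
        )
    for r in (disc, rep):
        if not (np.isfinite(r.se) and r.se > 0):
            raise ValueError(f"invalid SE in {r.stage} record")
    w1, w2 = 1.0 / disc.se**2, 1.0 / rep.se**2
    beta = (w1 * disc.beta + w2 * rep.beta) / (w1 + w2)
    se = (w1 + w2) ** -0.5
    z = beta / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return MetaRecord(
        food_group=disc.food_group,
        metabolite=disc.metabolite,
        platform=disc.platform,
        beta=float(beta),
        se=float(se),
        p=p,
        replicated=replicated,
        significant=bool(replicated and p < threshold),
    )


@dataclass
class ResultsBundle:
    """Everything one pipeline run produced, plus provenance."""

    discovery: list[AssociationRecord]
    replication: list[AssociationRecord]
    meta: list[MetaRecord]
    partitions: dict[str, DiscordancePartition]
    threshold: float
    replication_alpha: float
    counts: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @staticmethod
    def _frame(records) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in records])

    def discovery_frame(self) -> pd.DataFrame:
        return self._frame(self.discovery)

    def replication_frame(self) -> pd.DataFrame:
        return self._frame(self.replication)

    def meta_frame(self) -> pd.DataFrame:
        return self._frame(self.meta)


def run_pipeline(
    panels: MetabolitePanel | Sequence[MetabolitePanel],
    foods: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    sd_multiplier: float = 1.0,
    replication_alpha: float = 0.05,
    n_tests_override: int | None = None,
    seed: int | None = None,
) -> ResultsBundle:
    """Discovery scan -> replication -> meta-analysis, with stage logging."""
    disc_records, partitions, threshold = discovery_scan(
        panels, foods, cohort, alpha, sd_multiplier, n_tests_override
    )
    significant = [r for r in disc_records if r.ok and r.significant]
    logger.info("discovery: %d tests, %d significant at %.3g",
                len(disc_records), len(significant), threshold)
    rep_records, flags = replicate(
        significant, panels, foods, cohort, partitions, replication_alpha
    )
    meta_records = []
    for disc, rep, flag in zip(significant, rep_records, flags):
        if rep.ok:
            meta_records.append(meta_fixed_effect(disc, rep, threshold, flag))
    n_sig = sum(m.significant for m in meta_records)
    logger.info("replication: %d replicated; meta: %d significant",
                sum(flags), n_sig)

    counts = {
        "n_tested": len(disc_records),
        "n_fit_failures": sum(not r.ok for r in disc_records),
        "n_discovery_significant": len(significant),
        "n_replicated": int(sum(flags)),
        "n_meta_significant": n_sig,
        "n_significant_replicated": int(
            sum(m.significant and m.replicated for m in meta_records)
        ),
        "n_distinct_metabolites": len(
            {m.metabolite for m in meta_records if m.significant and m.replicated}
        ),
        "n_distinct_food_groups": len(
            {m.food_group for m in meta_records if m.significant and m.replicated}
        ),
    }
    config = {
        "alpha": alpha,
        "sd_multiplier": sd_multiplier,
        "replication_alpha": replication_alpha,
        "n_tests_override": n_tests_override,
        "seed": seed,
    }
    provenance = {
        **config,
        "threshold": threshold,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    return ResultsBundle(
        discovery=disc_records,
        replication=rep_records,
        meta=meta_records,
        partitions=partitions,
        threshold=threshold,
        replication_alpha=replication_alpha,
        counts=counts,
        provenance=provenance,
    )
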