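"""Synthetic twin cohorts with known ground truth.

Generates the full data bundle the association pipeline consumes — cohort
table, item-level FFQ, non-targeted and targeted metabolite panels, additive
genotypes — with the statistical structure the co-twin-control analysis
assumes:

* family clustering via a per-family random intercept, with extra shared
  variance for monozygotic (MZ) pairs so MZ within-pair correlation exceeds
  dizygotic (DZ) correlation;
* planted linear food-group -> metabolite effects (the ground truth for
  parameter-recovery tests);
* age and BMI confounding with configurable slopes;
* multiplicative per-run-day batch shifts on the non-targeted panel;
* intensity-dependent (left-censoring-like) missingness;
* right-skewed targeted concentrations (log-normal).

Metabolite signals are built on the *energy-adjusted* food-group matrix
derived from the simulated FFQ through the same diet-preprocessing chain the
pipeline applies, so the planted slopes are exactly recoverable downstream in
the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet import DEFAULT_SCALE_MAP, ENERGY_COL, FoodGroupMap, ffq_to_food_groups
from .panels import NON_TARGETED, TARGETED, MetabolitePanel

__all__ = [
    "PlantedEffect",
    "SimParams",
    "SimTruth",
    "TwinCohortData",
    "default_food_group_map",
    "simulate_cohort",
    "inject_missingness",
]


@dataclass(frozen=True)
class PlantedEffect:
    """One true diet->metabolite effect: slope per serving/week."""

    food_group: int     # food-group index
    metabolite: int     # metabolite index within its platform
    platform: str       # "non_targeted" or "targeted"
    slope: float


@dataclass(frozen=True)
class SimParams:
    """Generator configuration.

    Defaults mirror the cohort the analysis was designed for: ~3560 adult
    female twins (1780 pairs), 71 food groups from a 131-item FFQ, 456
    non-targeted and 145 targeted metabolites.  Quantities the source data do
    not pin down (MZ fraction, run-day count, variance components) are fixed
    conventions documented in the methods note.
    """

    n_pairs: int = 1780
    frac_mz: float = 0.5
    n_food_groups: int = 71
    n_metabolites_nt: int = 456
    n_metabolites_t: int = 145
    n_run_days: int = 20
    effect_table: tuple[PlantedEffect, ...] = ()
    var_family: float = 0.3
    var_pair_mz_extra: float = 0.2
    var_noise: float = 0.5
    age_range: tuple[float, float] = (18.0, 75.0)
    bmi_mean_sd: tuple[float, float] = (25.0, 4.5)
    gamma_age: float = 0.0
    delta_bmi: float = 0.0
    missing_rate: float = 0.10
    batch_shift_sd: float = 0.10
    n_items_per_group: int = 2
    n_snps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if not 0.0 <= self.frac_mz <= 1.0:
            raise ValueError("frac_mz must lie in [0, 1]")
        for name in ("var_family", "var_pair_mz_extra", "var_noise",
                     "batch_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max)")
        dims = {NON_TARGETED: self.n_metabolites_nt, TARGETED: self.n_metabolites_t}
        for k, eff in enumerate(self.effect_table):
            if not isinstance(eff, PlantedEffect):
                raise TypeError(f"effect_table[{k}] is not a PlantedEffect")
            if eff.platform not in dims:
                raise ValueError(f"effect_table[{k}]: unknown platform {eff.platform!r}")
            if not 0 <= eff.food_group < self.n_food_groups:
                raise ValueError(
                    f"effect_table[{k}] ({eff}): food-group index out of range "
                    f"[0, {self.n_food_groups})"
                )
            if not 0 <= eff.metabolite < dims[eff.platform]:
                raise ValueError(
                    f"effect_table[{k}] ({eff}): metabolite index out of range "
                    f"[0, {dims[eff.platform]}) on platform {eff.platform}"
                )


@dataclass
class SimTruth:
    """Ground truth realized by one simulation: everything tests need."""

    params: SimParams
    effect_table: tuple[PlantedEffect, ...]
    food_groups: pd.DataFrame                  # energy-adjusted matrix used to plant effects
    family_effects: dict[str, pd.DataFrame]    # platform -> families x metabolites shared effect
    variance_components: dict[str, float]
    latent: dict[str, pd.DataFrame] = field(default_factory=dict)  # pre-batch/pre-skew signal


@dataclass
class TwinCohortData:
    cohort: pd.DataFrame
    ffq: pd.DataFrame
    panel_nt: MetabolitePanel
    panel_t: MetabolitePanel
    genotypes: pd.DataFrame
    truth: SimTruth

    def __iter__(self):
        return iter((self.cohort, self.ffq, self.panel_nt, self.panel_t,
                     self.genotypes, self.truth))


def default_food_group_map(n_groups: int, items_per_group: int) -> FoodGroupMap:
    """Items ``item_000..`` mapped blockwise onto groups ``fg_00..``."""
    mapping = {
        f"item_{i:03d}": f"fg_{i // items_per_group:02d}"
        for i in range(n_groups * items_per_group)
    }
    return FoodGroupMap(mapping)


def _metabolite_ids(platform: str, m: int) -> list[str]:
    prefix = "nt" if platform == NON_TARGETED else "t"
    return [f"{prefix}_{j:03d}" for j in range(m)]


def _shared_effects(rng, n_fam, n_met, zygosity, var_family, var_mz_extra):
    fam = rng.normal(0.0, np.sqrt(var_family), size=(n_fam, n_met))
    extra = rng.normal(0.0, np.sqrt(var_mz_extra), size=(n_fam, n_met))
    extra[zygosity != "MZ", :] = 0.0
    return fam + extra


def simulate_cohort(params: SimParams) -> TwinCohortData:
    """Generate one twin cohort.  Identical params (incl. seed) reproduce the
    output bit for bit."""
    rng = np.random.default_rng(params.seed)
    n_mz = int(round(params.frac_mz * params.n_pairs))
    n_fam = params.n_pairs
    n = 2 * n_fam

    family_ids = np.repeat([f"F{i:05d}" for i in range(n_fam)], 2)
    subject_ids = [f"F{i:05d}_{t}" for i in range(n_fam) for t in (1, 2)]
    zygosity_fam = np.array(["MZ"] * n_mz + ["DZ"] * (n_fam - n_mz))
    zygosity = np.repeat(zygosity_fam, 2)

    lo, hi = params.age_range
    age_fam = rng.uniform(lo, hi, size=n_fam)
    age = np.repeat(age_fam, 2)                 # twins share age exactly
    bmi_mean, bmi_sd = params.bmi_mean_sd
    bmi_fam = rng.normal(bmi_mean, bmi_sd / np.sqrt(2.0), size=n_fam)
    bmi = np.repeat(bmi_fam, 2) + rng.normal(0.0, bmi_sd / np.sqrt(2.0), size=n)

    cohort = pd.DataFrame(
        {
            "family_id": family_ids,
            "zygosity": zygosity,
            "age": age,
            "bmi": bmi,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )

    # FFQ: iid 9-point codes per item; energy correlated with total intake
    fg_map = default_food_group_map(params.n_food_groups, params.n_items_per_group)
    items = list(fg_map.item_to_group)
    codes = rng.integers(0, 9, size=(n, len(items)))
    spw = np.vectorize(DEFAULT_SCALE_MAP.get)(codes)
    energy = 600.0 + 0.8 * spw.sum(axis=1) + rng.normal(0.0, 150.0, size=n)
    energy = np.maximum(energy, 100.0)
    ffq = pd.DataFrame(codes, index=cohort.index, columns=items)
    ffq[ENERGY_COL] = energy

    # the signal is planted on the energy-adjusted food-group matrix, i.e.
    # exactly the X the association model will see
    foods = ffq_to_food_groups(ffq, fg_map)

    slopes = {
        NON_TARGETED: np.zeros((params.n_food_groups, params.n_metabolites_nt)),
        TARGETED: np.zeros((params.n_food_groups, params.n_metabolites_t)),
    }
    for eff in params.effect_table:
        slopes[eff.platform][eff.food_group, eff.metabolite] += eff.slope

    fam_idx = np.repeat(np.arange(n_fam), 2)
    day = np.array([f"day_{i % params.n_run_days:02d}" for i in range(n)])
    run_day = pd.Series(day, index=cohort.index, name="run_day")
    G = foods.to_numpy()

    truth_family: dict[str, pd.DataFrame] = {}
    latent: dict[str, pd.DataFrame] = {}
    fam_index = pd.Index([f"F{i:05d}" for i in range(n_fam)], name="family_id")

    def build_signal(platform: str, n_met: int, baseline: np.ndarray):
        shared = _shared_effects(rng, n_fam, n_met, zygosity_fam,
                                 params.var_family, params.var_pair_mz_extra)
        noise = (
            rng.normal(0.0, np.sqrt(params.var_noise), size=(n, n_met))
            if params.var_noise > 0
            else np.zeros((n, n_met))
        )
        z = (
            baseline[None, :]
            + G @ slopes[platform]
            + params.gamma_age * age[:, None]
            + params.delta_bmi * bmi[:, None]
            + shared[fam_idx, :]
            + noise
        )
        met_ids = _metabolite_ids(platform, n_met)
        truth_family[platform] = pd.DataFrame(shared, index=fam_index, columns=met_ids)
        latent[platform] = pd.DataFrame(z, index=cohort.index, columns=met_ids)
        return z, met_ids

    # non-targeted: linear signal times a per-(run day, metabolite) batch factor
    base_nt = rng.uniform(5.0, 15.0, size=params.n_metabolites_nt)
    z_nt, ids_nt = build_signal(NON_TARGETED, params.n_metabolites_nt, base_nt)
    batch = np.exp(
        rng.normal(0.0, params.batch_shift_sd,
                   size=(params.n_run_days, params.n_metabolites_nt))
    )
    day_idx = np.arange(n) % params.n_run_days
    vals_nt = z_nt * batch[day_idx, :]
    panel_nt = MetabolitePanel(
        values=pd.DataFrame(vals_nt, index=cohort.index, columns=ids_nt),
        platform=NON_TARGETED,
        run_day=run_day,
    )

    # targeted: log-normal concentrations (signal on the log scale)
    base_t = rng.normal(0.0, 0.5, size=params.n_metabolites_t)
    z_t, ids_t = build_signal(TARGETED, params.n_metabolites_t, base_t)
    panel_t = MetabolitePanel(
        values=pd.DataFrame(np.exp(z_t), index=cohort.index, columns=ids_t),
        platform=TARGETED,
        run_day=run_day.copy(),
    )

    # additive genotypes: MZ co-twins identical; DZ co-twins share one allele
    snp_ids = [f"snp_{j:03d}" for j in range(params.n_snps)]
    geno = np.zeros((n, params.n_snps), dtype=int)
    if params.n_snps:
        maf = rng.uniform(0.1, 0.5, size=params.n_snps)
        a_shared = rng.binomial(1, maf, size=(n_fam, params.n_snps))
        a1 = rng.binomial(1, maf, size=(n_fam, params.n_snps))
        a2 = rng.binomial(1, maf, size=(n_fam, params.n_snps))
        twin1 = a_shared + a1
        twin2 = np.where((zygosity_fam == "MZ")[:, None], a_shared + a1, a_shared + a2)
        geno[0::2, :] = twin1
        geno[1::2, :] = twin2
    genotypes = pd.DataFrame(geno, index=cohort.index, columns=snp_ids)

    if params.missing_rate > 0:
        panel_nt = inject_missingness(
            panel_nt, params.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    else:
        panel_nt.truth_values = panel_nt.values.copy()

    truth = SimTruth(
        params=params,
        effect_table=params.effect_table,
        food_groups=foods,
        family_effects=truth_family,
        variance_components={
            "var_family": params.var_family,
            "var_pair_mz_extra": params.var_pair_mz_extra,
            "var_noise": params.var_noise,
        },
        latent=latent,
    )
    return TwinCohortData(cohort, ffq, panel_nt, panel_t, genotypes, truth)


def inject_missingness(
    panel: MetabolitePanel, rate: float, seed: int
) -> MetabolitePanel:
    """Mask values missing-at-low-intensity with expected fraction ``rate``.

    Per metabolite, the masking probability is weighted toward the lowest
    intensity tertile (1.8r low, 0.9r middle, 0.3r high — mean r), emulating
    left-censoring of low-abundance compounds.  The unmasked matrix is kept on
    ``truth_values`` for oracle checks.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = panel.values.to_numpy(dtype=float).copy()
    if rate > 0:
        probs = np.empty_like(vals)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            q1, q2 = np.quantile(col, [1.0 / 3.0, 2.0 / 3.0])
            p = np.where(col <= q1, 1.8 * rate, np.where(col <= q2, 0.9 * rate, 0.3 * rate))
            probs[:, j] = np.clip(p, 0.0, 0.99)
        mask = rng.uniform(size=vals.shape) < probs
        vals[mask] = np.nan
    out = MetabolitePanel(
        values=pd.DataFrame(vals, index=panel.subjects, columns=panel.metabolites),
        platform=panel.platform,
        run_day=panel.run_day,
        steps=list(panel.steps),
        annotations=panel.annotations,
        truth_values=panel.values.copy(),
        warnings=list(panel.warnings),
    )
    return out
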