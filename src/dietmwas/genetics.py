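"""SNP -> food-intake follow-up scan.

For a curated list of (SNP, food group) pairs — variants known to associate
with the blood level of a diet-associated metabolite — the additive genotype
dosage is regressed on the energy-adjusted food-group intake with age as a
covariate and a family random intercept.  Both nominal (p < alpha) and
Bonferroni (p < alpha / n tests) significance are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedlm import SingularDesignError, fit_family_reml

logger = logging.getLogger(__name__)

__all__ = [
    "SnpFoodRecord",
    "validate_genotypes",
    "fit_snp_food",
    "snp_scan",
]

MIN_FIT_SUBJECTS = 10


@dataclass
class SnpFoodRecord:
    snp: str
    food_group: str
    beta: float          # servings/week per effect allele
    se: float
    p: float
    n: int
    nominal: bool        # p < alpha
    significant: bool    # p < alpha / n_tests
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def validate_genotypes(genotypes: pd.DataFrame, cohort: pd.DataFrame) -> None:
    """Check dosage coding and MZ co-twin identity; violations are errors.

    MZ twins share their germline sequence, so differing dosages within an MZ
    pair indicate corrupt input, not a borderline case.
    """
    vals = genotypes.to_numpy(dtype=float)
    obs = vals[np.isfinite(vals)]
    if not np.isin(obs, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0, 1 or 2 (or missing)")
    mz = cohort[cohort["zygosity"] == "MZ"]
    for fam, members in mz.groupby("family_id").groups.items():
        if len(members) != 2:
            continue
        a, b = genotypes.loc[members[0]], genotypes.loc[members[1]]
        both = a.notna() & b.notna()
        if not (a[both] == b[both]).all():
            snp = a[both].index[(a[both] != b[both]).to_numpy()][0]
            raise ValueError(
                f"MZ co-twins in family {fam!r} differ at {snp!r}: "
                "dosage data are inconsistent with zygosity"
            )


def fit_snp_food(
    dosage: np.ndarray,
    food_group: np.ndarray,
    age: np.ndarray,
    family_id: np.ndarray,
) -> tuple[float, float, float, int]:
    """REML fit of food ~ dosage + age + (1 | family); returns (beta, se, p, n)."""
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(food_group, dtype=float)
    a = np.asarray(age, dtype=float)
    keep = np.isfinite(d) & np.isfinite(y) & np.isfinite(a)
    d, y, a = d[keep], y[keep], a[keep]
    fam = np.asarray(family_id)[keep]
    if y.size < MIN_FIT_SUBJECTS:
        raise ValueError(f"too few subjects ({y.size} < {MIN_FIT_SUBJECTS})")
    if np.ptp(d) == 0:
        raise ValueError("monomorphic SNP: dosage is constant")
    X = np.column_stack([np.ones_like(y), d, a])
    res = fit_family_reml(y, X, fam, exog_names=["intercept", "dosage", "age"])
    return float(res.beta[1]), float(res.se[1]), float(res.pvalues[1]), res.n_obs


def snp_scan(
    snp_food_map: list[tuple[str, str]],
    genotypes: pd.DataFrame,
    foods: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[SnpFoodRecord], float]:
    """Run every listed (SNP, food group) test; one record per listed pair.

    The Bonferroni threshold is ``alpha`` over the number of listed tests.
    Unresolvable pairs or failed fits yield records carrying an ``error``
    marker; the scan continues.
    """
    if not snp_food_map:
        return [], float("nan")
    validate_genotypes(genotypes, cohort)
    threshold = alpha / len(snp_food_map)
    records: list[SnpFoodRecord] = []
    for snp, group in snp_food_map:
        if snp not in genotypes.columns or group not in foods.columns:
            missing = snp if snp not in genotypes.columns else group
            records.append(SnpFoodRecord(snp, group, np.nan, np.nan, np.nan, 0,
                                         False, False,
                                         error=f"{missing!r} not found in inputs"))
            continue
        idx = cohort.index
        try:
            beta, se, p, n = fit_snp_food(
                genotypes.loc[idx, snp].to_numpy(),
                foods.loc[idx, group].to_numpy(),
                cohort["age"].to_numpy(),
                cohort["family_id"].to_numpy(),
            )
        except (ValueError, SingularDesignError, np.linalg.LinAlgError) as err:
            records.append(SnpFoodRecord(snp, group, np.nan, np.nan, np.nan, 0,
                                         False, False, error=str(err)))
            continue
        records.append(SnpFoodRecord(
            snp, group, beta, se, p, n,
            nominal=bool(p < alpha), significant=bool(p < threshold),
        ))
    n_failed = sum(not r.ok for r in records)
    if n_failed:
        logger.warning("snp scan: %d of %d tests failed", n_failed, len(records))
    return records, threshold
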