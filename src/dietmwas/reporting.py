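"""Result summaries and the flat query-table export.

The export mirrors the convention of published association tables: one row
per significant, replicated meta-analysis association, effect sizes printed
as ``beta[SE]`` with three decimals and p-values in scientific notation with
three significant figures (e.g. ``0.075[0.009]``, ``1.08x10^-17``).
"""

from __future__ import annotations

import math

import pandas as pd

from .associations import ResultsBundle

__all__ = [
    "format_beta_se",
    "format_p_sci",
    "summarize_counts",
    "export_dietmetab",
]


def format_beta_se(beta: float, se: float) -> str:
    return f"{beta:.3f}[{se:.3f}]"


def format_p_sci(p: float) -> str:
    """p in scientific notation, 3 significant figures: ``1.23x10^-8``."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    exponent = math.floor(math.log10(p))
    mantissa = p / 10.0**exponent
    if round(mantissa, 2) >= 10.0:  # e.g. 9.996 rounds up a decade
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.2f}x10^{exponent}"


def summarize_counts(bundle: ResultsBundle) -> pd.DataFrame:
    """Counts of significant+replicated associations, overall and per platform.

    Recomputed from the record tables, so stored counts can be audited
    against this summary.
    """
    hits = [m for m in bundle.meta if m.significant and m.replicated]
    rows = []

    def row(scope: str, records) -> dict:
        return {
            "scope": scope,
            "n_associations": len(records),
            "n_food_groups": len({m.food_group for m in records}),
            "n_metabolites": len({m.metabolite for m in records}),
        }

    rows.append(row("all", hits))
    for platform in sorted({m.platform for m in bundle.meta}):
        rows.append(row(platform, [m for m in hits if m.platform == platform]))
    return pd.DataFrame(rows, columns=["scope", "n_associations",
                                       "n_food_groups", "n_metabolites"])


def export_dietmetab(bundle: ResultsBundle) -> pd.DataFrame:
    """Flat table of the significant replicated meta associations."""
    rows = [
        {
            "food_group": m.food_group,
            "metabolite": m.metabolite,
            "platform": m.platform,
            "beta_se": format_beta_se(m.beta, m.se),
            "p": format_p_sci(m.p),
            "beta": m.beta,
            "se": m.se,
            "p_value": m.p,
        }
        for m in bundle.meta
        if m.significant and m.replicated
    ]
    cols = ["food_group", "metabolite", "platform", "beta_se", "p",
            "beta", "se", "p_value"]
    return pd.DataFrame(rows, columns=cols)
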