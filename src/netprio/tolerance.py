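"""Prioritization tolerance: the critical-AUC statistic and classification.

A pathophenotype's "critical AUC" is the midpoint between its cross-validated
AUC on the original network and chance (0.5):

    critical_auc = auc_org - (auc_org - 0.5) / 2 = (auc_org + 0.5) / 2

The phenotype is *tolerant* when prioritization still performs at or above
this floor after half of the interactome is perturbed — both with 50% of
edges rewired (perm.) and with 50% deleted (del.).  Otherwise it is
non-tolerant.  Group differences between tolerant and non-tolerant
phenotypes (seed counts, functional diversity, ...) are assessed with the
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

TOLERANT = "tolerant"
NON_TOLERANT = "non_tolerant"


def critical_auc_change(auc_org: float) -> float:
    """Half the margin between the original-network AUC and chance (0.5)."""
    if not 0.0 <= auc_org <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    return (auc_org - 0.5) / 2.0


def critical_auc(auc_org: float) -> float:
    """The tolerance floor: auc_org minus the critical AUC change."""
    return auc_org - critical_auc_change(auc_org)


def critical_auc_percent(auc_org_pct: float) -> float:
    """Critical AUC on the percent scale, rounded half-up to one decimal.

    Works in decimal arithmetic so a printed original AUC maps to exactly the
    printed critical AUC (e.g. 70.3 -> 60.15 -> 60.2; binary floats round the
    wrong way for such midpoints).
    """
    if not 0 <= auc_org_pct <= 100:
        raise ValueError("AUC percentage must lie in [0, 100]")
    crit = (Decimal(repr(auc_org_pct)) + Decimal(50)) / 2
    return float(crit.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def perturbation_tolerance_level(auc_by_level: dict, auc_crit: float):
    """Smallest perturbation level whose mean AUC falls below the floor.

    Returns the level (percent) at which ``AUC(p) < auc_crit`` first holds,
    or ``"none"`` if the floor is never crossed (strict inequality: an AUC
    exactly at the floor has not crossed it).
    """
    if not auc_by_level:
        raise ValueError("auc_by_level must not be empty")
    for p in sorted(auc_by_level):
        if auc_by_level[p] < auc_crit:
            return p
    return "none"


@dataclass
class ToleranceRecord:
    """One phenotype's tolerance summary (a report row).

    AUCs are on the [0, 1] scale.  ``auc_by_level_perm`` / ``auc_by_level_del``
    map perturbation level (percent) to the ensemble-mean AUC under edge
    rewiring and edge deletion respectively.
    """

    phenotype_id: str
    auc_org: float
    auc_by_level_perm: dict
    auc_by_level_del: dict
    auc_crit: float = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.auc_crit = critical_auc(self.auc_org)
        self.label = classify(self)


def classify(record: ToleranceRecord, threshold_p: float = 50) -> str:
    """Tolerant iff the AUC at *threshold_p* stays >= the critical AUC under
    both rewiring and deletion; an AUC exactly at the floor counts as
    tolerant (it has not crossed it)."""
    try:
        perm = record.auc_by_level_perm[threshold_p]
        dele = record.auc_by_level_del[threshold_p]
    except KeyError as exc:
        raise ValueError(f"missing AUC at perturbation level {exc.args[0]}") from exc
    crit = critical_auc(record.auc_org)
    return TOLERANT if (perm >= crit and dele >= crit) else NON_TOLERANT


def compare_groups(values_tolerant, values_other, alternative: str = "two_sided") -> dict:
    """Wilcoxon rank-sum test between tolerant and non-tolerant group values.

    Uses the exact small-sample null distribution when there are no ties and
    both groups are small, the normal approximation otherwise (scipy's
    ``mannwhitneyu`` 'auto' policy).  Reports the statistic, the p-value and
    the alpha=0.05 verdict.
    """
    values_tolerant = list(values_tolerant)
    values_other = list(values_other)
    if not values_tolerant or not values_other:
        raise ValueError("both groups must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = stats.mannwhitneyu(values_tolerant, values_other, alternative=alt, method="auto")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "alpha": 0.05,
        "significant": bool(res.pvalue <= 0.05),
    }


def _pct(x: float) -> float:
    """Render an AUC fraction as a percentage with one decimal, half-up.

    Uses decimal arithmetic: float round() is round-half-even and would turn
    e.g. 64.15 into 64.1.
    """
    return float((Decimal(repr(x)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tolerance_table(records, threshold_p: float = 50) -> pd.DataFrame:
    """Tolerance report: org/crit/perm/del AUC percentages and the label.

    Percentages are rounded to one decimal for display only; classification
    uses the unrounded values.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "phenotype": rec.phenotype_id,
                "auc_org_pct": _pct(rec.auc_org),
                "auc_crit_pct": critical_auc_percent(_pct(rec.auc_org)),
                "auc_perm_pct": _pct(rec.auc_by_level_perm[threshold_p]),
                "auc_del_pct": _pct(rec.auc_by_level_del[threshold_p]),
                "label": classify(rec, threshold_p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype",
            "auc_org_pct",
            "auc_crit_pct",
            "auc_perm_pct",
            "auc_del_pct",
            "label",
        ],
    )
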