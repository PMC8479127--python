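"""Binary trait-presence scoring of meta-QTLs and co-localization statistics.

Each meta-QTL is scored 0/1 for every trait code in the controlled
vocabulary (exact string match — tissue-prefixed variants are distinct
traits).  For a target element T (Zn, Fe or Mn) the expected proportion

    MQTL_P(T) = (# meta-QTLs containing a T QTL) / (all meta-QTLs)

drives a chi-squared statistic, df = 1, for whether another trait's QTLs
co-localize with T more often than a random scatter would produce:

    chi2 = n_co * (1 - p)^2 / p

with n_co the number of meta-QTLs carrying both traits and p the
*two-decimal-rounded* MQTL_P (0.70 / 0.52 / 0.64 on the published table).
This statistic form — linear in n_co — is the one consistent with every
chi-squared cell of the published co-localization table; pass
``rounded_p=False`` for the exact-proportion variant, which deviates from
the printed values in the third decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .qtl_database import TRAIT_ORDER, MQTLRecord

DEFAULT_TARGETS = ("Zn", "Fe", "Mn")


@dataclass(frozen=True)
class ExpectedProportion:
    target: str
    value: float
    value_rounded: float  # two decimals, round-half-up


@dataclass(frozen=True)
class ColocResult:
    trait: str
    target: str
    n_trait: int  # meta-QTLs containing the trait
    n_target: int  # meta-QTLs containing the target
    n_co: int  # meta-QTLs containing both
    frequency: float | None  # n_co / n_target; None when undefined
    chi2: float | None
    p: float | None
    significant: bool | None  # at 0.05


def _round_half_up(x: float, ndigits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits), rounding=ROUND_HALF_UP))


def presence_matrix(mqtls: list[MQTLRecord]) -> pd.DataFrame:
    """MQTL × trait 0/1 matrix; columns in fixed vocabulary order."""
    if not mqtls:
        raise ValueError("empty meta-QTL collection")
    data = {
        trait: [1 if trait in m.traits else 0 for m in mqtls]
        for trait in TRAIT_ORDER
    }
    return pd.DataFrame(data, index=[m.mqtl_id for m in mqtls], columns=list(TRAIT_ORDER))


def expected_proportion(matrix: pd.DataFrame, target: str) -> ExpectedProportion:
    """Fraction of meta-QTLs that contain a QTL for the target trait."""
    if target not in matrix.columns:
        raise KeyError(f"unknown target trait {target!r}")
    value = float(matrix[target].sum()) / len(matrix)
    return ExpectedProportion(target=target, value=value,
                              value_rounded=_round_half_up(value, 2))


def coloc_frequency(matrix: pd.DataFrame, trait: str, target: str) -> float:
    """Fraction of target-containing meta-QTLs that also contain the trait."""
    n_target = int(matrix[target].sum())
    if n_target == 0:
        raise ZeroDivisionError(f"no meta-QTL contains target {target!r}")
    n_co = int((matrix[trait] & matrix[target]).sum())
    return n_co / n_target


def coloc_chi2(n_co: int, p_expected: float) -> tuple[float, float]:
    """chi2 = n_co (1−p)^2 / p and its upper-tail probability, df = 1."""
    if not (0 < p_expected < 1):
        raise ValueError(f"p_expected must lie in (0, 1), got {p_expected}")
    if n_co < 0:
        raise ValueError("n_co must be >= 0")
    chi2 = n_co * (1 - p_expected) ** 2 / p_expected
    p_value = float(stats.chi2.sf(chi2, df=1)) if n_co > 0 else 1.0
    return chi2, p_value


def coloc_table(
    matrix: pd.DataFrame,
    targets: tuple[str, ...] = DEFAULT_TARGETS,
    *,
    rounded_p: bool = True,
    alpha: float = 0.05,
) -> list[ColocResult]:
    """All (trait, target) co-localization rows; a trait is never tested
    against itself (those cells are reported as missing), and a trait absent
    from every target meta-QTL gets chi2 = 0 only when n_co is 0."""
    results: list[ColocResult] = []
    present_traits = [t for t in TRAIT_ORDER if matrix[t].sum() > 0]
    for trait in present_traits:
        n_trait = int(matrix[trait].sum())
        for target in targets:
            if trait == target:
                results.append(ColocResult(trait, target, n_trait,
                                           int(matrix[target].sum()),
                                           n_trait, None, None, None, None))
                continue
            ep = expected_proportion(matrix, target)
            p_exp = ep.value_rounded if rounded_p else ep.value
            n_target = int(matrix[target].sum())
            n_co = int((matrix[trait] & matrix[target]).sum())
            if n_target == 0 or n_co == 0:
                freq = (n_co / n_target) if n_target else None
                results.append(ColocResult(trait, target, n_trait, n_target,
                                           n_co, freq, None, None, None))
                continue
            freq = n_co / n_target
            chi2, p_value = coloc_chi2(n_co, p_exp)
            results.append(ColocResult(trait, target, n_trait, n_target, n_co,
                                       freq, chi2, p_value, p_value < alpha))
    return results


def coloc_table_frame(results: list[ColocResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def mqtl_summary(
    mqtls: list[MQTLRecord],
    mean_original_ci: float | None = None,
) -> dict:
    """Headline statistics of a meta-QTL table.

    Percentages use one decimal, round-half-up.  ``fold_reduction`` compares
    the member studies' mean original CI with the meta-QTL mean CI.
    """
    if not mqtls:
        raise ValueError("empty meta-QTL collection")
    cis = np.array([m.ci_length for m in mqtls])
    n = len(mqtls)
    n_lt1 = int((cis < 1.0).sum())
    n_ge6 = sum(1 for m in mqtls if m.n_populations >= 6)
    per_chrom: dict[str, int] = {}
    for m in mqtls:
        per_chrom[m.chromosome] = per_chrom.get(m.chromosome, 0) + 1
    out = {
        "n_mqtl": n,
        "mean_ci_cm": float(cis.mean()),
        "n_ci_lt_1cm": n_lt1,
        "pct_ci_lt_1cm": _round_half_up(100 * n_lt1 / n, 1),
        "n_ge6_populations": n_ge6,
        "pct_ge6_populations": _round_half_up(100 * n_ge6 / n, 1),
        "per_chromosome": dict(sorted(per_chrom.items())),
    }
    if mean_original_ci is not None:
        out["fold_reduction"] = mean_original_ci / float(cis.mean())
    return out
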