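"""Case-control association of a biallelic variant from genotype tables.

The default model is the carrier (dominant) model: subjects are classified by
presence of at least one minor allele and arranged in a 2x2 table
(cases-carrier, cases-noncarrier | controls-carrier, controls-noncarrier).
Association is tested by Pearson's chi-squared statistic on 1 df (no
continuity correction by default) or Fisher's exact test; the effect size is
the carrier odds ratio with a 95 % Woolf (logit) confidence interval,
Haldane-Anscombe corrected (+0.5 to every cell) only when some cell is zero.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

from scipy import stats

from .io_formats import GenotypeRow

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "build_carrier_table",
    "build_allele_table",
    "chi2_test",
    "odds_ratio_ci",
    "allele_frequency",
    "fisher_exact",
    "associate",
]

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """Raised when a margin of the 2x2 table is zero (test undefined)."""


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b, c, d = cases-carrier, cases-noncarrier, controls-carrier,
    controls-noncarrier (or allele counts under the allele model)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    chi2: float
    df: int
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    maf_cases: float
    maf_controls: float
    table: ContingencyTable2x2

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "ci_95": [self.ci_low, self.ci_high],
            "maf_cases": self.maf_cases,
            "maf_controls": self.maf_controls,
            "table": {"a": self.table.a, "b": self.table.b, "c": self.table.c, "d": self.table.d},
        }


def _split_groups(
    genotypes: Iterable[GenotypeRow],
    case_groups: Sequence[str],
    control_groups: Sequence[str],
) -> tuple[list[GenotypeRow], list[GenotypeRow]]:
    overlap = set(case_groups) & set(control_groups)
    if overlap:
        raise ValueError(f"groups assigned to both sides: {sorted(overlap)}")
    cases = [g for g in genotypes if g.group in case_groups]
    controls = [g for g in genotypes if g.group in control_groups]
    if not cases or not controls:
        raise ValueError("both case and control sides must be non-empty")
    return cases, controls


def build_carrier_table(
    genotypes: Iterable[GenotypeRow],
    case_groups: Sequence[str] = ("case",),
    control_groups: Sequence[str] = ("control_longlived", "control_healthy"),
) -> ContingencyTable2x2:
    """Carrier-model 2x2 table: carrier = genotype holds >= 1 minor allele."""
    cases, controls = _split_groups(list(genotypes), case_groups, control_groups)
    a = sum(g.is_carrier for g in cases)
    c = sum(g.is_carrier for g in controls)
    return ContingencyTable2x2(a, len(cases) - a, c, len(controls) - c)


def build_allele_table(
    genotypes: Iterable[GenotypeRow],
    case_groups: Sequence[str] = ("case",),
    control_groups: Sequence[str] = ("control_longlived", "control_healthy"),
) -> ContingencyTable2x2:
    """Allele-count 2x2 table (2 alleles per subject)."""
    cases, controls = _split_groups(list(genotypes), case_groups, control_groups)
    a = sum(g.minor_allele_count for g in cases)
    c = sum(g.minor_allele_count for g in controls)
    return ContingencyTable2x2(a, 2 * len(cases) - a, c, 2 * len(controls) - c)


def chi2_test(t: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 table, two-sided, df = 1.

    No continuity correction unless ``yates=True``. Requires all four margins
    positive.
    """
    if min(t.n_cases, t.n_controls, t.a + t.c, t.b + t.d) == 0:
        raise DegenerateTableError(f"zero margin in table {t.cells}")
    chi2, p, _, _ = stats.chi2_contingency(
        [[t.a, t.b], [t.c, t.d]], correction=yates
    )
    return float(chi2), float(p)


def odds_ratio_ci(
    t: ContingencyTable2x2, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Odds ratio (a*d)/(b*c) with the Woolf logit confidence interval.

    The Haldane-Anscombe correction (+0.5 per cell) is applied iff any cell is
    zero, for both the point estimate and the interval.
    """
    if all(v == 0 for v in t.cells):
        raise DegenerateTableError("all-zero table")
    cells = [float(v) for v in t.cells]
    if any(v == 0 for v in cells):
        cells = [v + 0.5 for v in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


def allele_frequency(genotypes: Sequence[GenotypeRow]) -> float:
    """Minor-allele frequency: minor-allele count over 2 x subjects, in [0, 0.5].

    Oriented to the minor allele: if the variant allele exceeds 0.5 the
    complementary frequency is returned.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("empty genotype list")
    f = sum(g.minor_allele_count for g in genotypes) / (2 * len(genotypes))
    return min(f, 1 - f)


def render_percent(frequency: float, digits: int = 0) -> str:
    """Render a frequency as a percent string at the displayed precision."""
    pct = round(frequency * 100, digits if digits > 0 else None)
    return f"{pct:.{digits}f} %" if digits else f"{pct:d} %"


def fisher_exact(t: ContingencyTable2x2, rule: str = "conditional") -> float:
    """Two-sided Fisher exact p-value.

    ``rule='conditional'`` (default) sums hypergeometric probabilities of
    tables, conditional on the margins, at most as probable as the observed
    one. ``rule='doubling'`` doubles the smaller one-sided tail (capped at 1).
    """
    table = [[t.a, t.b], [t.c, t.d]]
    if rule == "conditional":
        return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    if rule == "doubling":
        less = stats.fisher_exact(table, alternative="less").pvalue
        greater = stats.fisher_exact(table, alternative="greater").pvalue
        return float(min(1.0, 2 * min(less, greater)))
    raise ValueError(f"rule must be 'conditional' or 'doubling', got {rule!r}")


def hwe_chi2(genotypes: Sequence[GenotypeRow]) -> float:
    """Hardy-Weinberg chi-squared (1 df) for logging only, not a result."""
    n = len(genotypes)
    n_cc = sum(1 for g in genotypes if g.minor_allele_count == 2)
    n_tc = sum(1 for g in genotypes if g.minor_allele_count == 1)
    q = (2 * n_cc + n_tc) / (2 * n)
    exp = [n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2]
    obs = [n - n_cc - n_tc, n_tc, n_cc]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp) if e > 0)


def associate(
    genotypes: Iterable[GenotypeRow],
    case_groups: Sequence[str] = ("case",),
    control_groups: Sequence[str] = ("control_longlived", "control_healthy"),
    model: str = "carrier",
    yates: bool = False,
    alpha: float = 0.05,
) -> AssociationResult:
    """Full association analysis: table, chi2/p, OR with CI, per-side MAFs."""
    genotypes = list(genotypes)
    if model == "carrier":
        table = build_carrier_table(genotypes, case_groups, control_groups)
    elif model == "allele":
        table = build_allele_table(genotypes, case_groups, control_groups)
    else:
        raise ValueError(f"model must be 'carrier' or 'allele', got {model!r}")
    chi2, p = chi2_test(table, yates=yates)
    or_, lo, hi = odds_ratio_ci(table, alpha=alpha)
    cases = [g for g in genotypes if g.group in case_groups]
    controls = [g for g in genotypes if g.group in control_groups]
    hwe = hwe_chi2(controls)
    logger.info("control HWE chi2 = %.4f (1 df; logged only)", hwe)
    return AssociationResult(
        chi2=chi2,
        df=1,
        p_value=p,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        maf_cases=allele_frequency(cases),
        maf_controls=allele_frequency(controls),
        table=table,
    )
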