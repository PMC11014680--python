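"""Co-expression-module and cell-type enrichment, and prenatal expression bias.

Module / cell-type enrichment uses the explicit 2x2 construction over a
background gene universe:

    x1 = |set  ∩ category|        x2 = |set  \\ category|
    x3 = |category| - x1          x4 = |universe| - x1 - x2 - x3

with the sample odds ratio (x1*x4)/(x2*x3) and a two-sided Fisher exact
p-value. Prenatal/postnatal bias is a two-sided Wilcoxon signed-rank test
across genes of the mean log2(RPKM + 1) in prenatal vs postnatal samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

logger = logging.getLogger(__name__)

PRENATAL = "prenatal"
POSTNATAL = "postnatal"


@dataclass
class ExpressionMatrix:
    """Genes x samples of non-negative expression values with period labels.

    ``values``: frame indexed by gene, columns are sample ids.
    ``periods``: Series over samples with values 'prenatal'/'postnatal'.
    ``clusters``: optional Series over samples with cell-cluster labels.
    """

    values: pd.DataFrame
    periods: pd.Series | None = None
    clusters: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be >= 0")
        if self.periods is not None:
            missing = set(self.values.columns) - set(self.periods.index)
            if missing:
                raise ValueError(f"samples without period label: {sorted(missing)[:5]}")
            bad = set(self.periods.unique()) - {PRENATAL, POSTNATAL}
            if bad:
                raise ValueError(f"unknown period labels: {bad}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class MembershipTable:
    """Mapping of category (module or cell-type cluster) to member genes."""

    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"category {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    category: str
    x1: int
    x2: int
    x3: int
    x4: int
    odds_ratio: float
    p_two_sided: float
    odds_ratio_haldane: float = math.nan
    q_value: float = math.nan


@dataclass(frozen=True)
class BiasTestResult:
    statistic: float
    p_value: float
    direction: str  # 'prenatal', 'postnatal' or 'none'
    n_genes: int


def fisher_membership_enrichment(
    gene_set: GeneSet | Iterable[str],
    category_members: Iterable[str],
    universe: Iterable[str],
    set_name: str = "",
    category: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher enrichment of a gene set in a category.

    Both the set and the category are intersected with the universe first.
    When x2*x3 = 0 the sample OR is an infinity/NaN sentinel and the
    Haldane-corrected OR (0.5 added to every cell) is reported alongside.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    s = set(gene_set) & uni
    cat = set(category_members) & uni
    x1 = len(s & cat)
    x2 = len(s - cat)
    x3 = len(cat) - x1
    x4 = len(uni) - x1 - x2 - x3
    _, p = stats.fisher_exact([[x1, x2], [x3, x4]], alternative="two-sided")
    haldane = ((x1 + 0.5) * (x4 + 0.5)) / ((x2 + 0.5) * (x3 + 0.5))
    if x2 * x3 == 0:
        oratio = math.inf if x1 * x4 > 0 else math.nan
    else:
        oratio = (x1 * x4) / (x2 * x3)
    return EnrichmentResult(
        set_name or "gene_set",
        category or "category",
        x1,
        x2,
        x3,
        x4,
        oratio,
        float(p),
        haldane,
    )


def prenatal_bias_test(
    expr: ExpressionMatrix,
    gene_set: GeneSet | Iterable[str],
) -> BiasTestResult:
    """Wilcoxon signed-rank test of prenatal vs postnatal expression.

    For each gene in the set, the paired values are the mean log2(x + 1)
    over prenatal samples and over postnatal samples; the test is two-sided
    across genes. Direction is the period whose signed-rank sum dominates.
    """
    if expr.periods is None:
        raise ValueError("expression matrix has no period labels")
    genes = [g for g in set(gene_set) if g in expr.values.index]
    if len(genes) < 5:
        raise ValueError(f"need >= 5 genes with expression data, got {len(genes)}")
    pre_samples = expr.periods.index[expr.periods == PRENATAL]
    post_samples = expr.periods.index[expr.periods == POSTNATAL]
    if len(pre_samples) == 0 or len(post_samples) == 0:
        raise ValueError("both periods must have samples")
    logx = np.log2(expr.values.loc[genes] + 1.0)
    pre = logx[pre_samples].mean(axis=1)
    post = logx[post_samples].mean(axis=1)
    diff = (pre - post).to_numpy()
    if np.allclose(diff, 0.0):
        logger.warning("all prenatal/postnatal pairs tied; p = 1")
        return BiasTestResult(0.0, 1.0, "none", len(genes))
    res = stats.wilcoxon(diff, alternative="two-sided")
    # direction from the signed rank sums over nonzero differences
    nz = diff[diff != 0]
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    direction = PRENATAL if w_plus > w_minus else POSTNATAL if w_minus > w_plus else "none"
    return BiasTestResult(float(res.statistic), float(res.pvalue), direction, len(genes))


def celltype_enrichment(
    gene_set: GeneSet | Iterable[str],
    membership: MembershipTable,
    set_name: str = "",
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """One Fisher enrichment per category (cell cluster or module).

    Empty categories are skipped with a report. p-values are nominal by
    default; ``bh_correct=True`` adds Benjamini-Hochberg q-values.
    """
    s = set(gene_set) & membership.universe
    if not s:
        raise ValueError("gene set is disjoint from the universe")
    results: list[EnrichmentResult] = []
    skipped = []
    for name, members in membership.categories.items():
        if not members:
            skipped.append(name)
            continue
        results.append(
            fisher_membership_enrichment(
                s, members, membership.universe, set_name=set_name, category=name
            )
        )
    if skipped:
        logger.info("skipped %d empty categories: %s", len(skipped), skipped[:5])
    if bh_correct and results:
        ps = np.array([r.p_two_sided for r in results])
        qs = _benjamini_hochberg(ps)
        results = [
            EnrichmentResult(
                r.gene_set, r.category, r.x1, r.x2, r.x3, r.x4,
                r.odds_ratio, r.p_two_sided, r.odds_ratio_haldane, float(q),
            )
            for r, q in zip(results, qs)
        ]
    return results


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def membership_from_expression(
    expr: ExpressionMatrix,
    cutoff: float,
) -> MembershipTable:
    """Build cluster membership as 'mean expression within cluster > cutoff'.

    Convenience for synthetic data where memberships are not supplied as a
    precomputed table.
    """
    if expr.clusters is None:
        raise ValueError("expression matrix has no cluster labels")
    categories: dict[str, frozenset[str]] = {}
    for cluster in sorted(expr.clusters.unique()):
        samples = expr.clusters.index[expr.clusters == cluster]
        mean = expr.values[samples].mean(axis=1)
        categories[str(cluster)] = frozenset(mean.index[mean > cutoff])
    return MembershipTable(categories, frozenset(expr.values.index))


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in results])
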