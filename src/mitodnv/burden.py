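"""Burden and contribution analysis of de novo variants.

The burden test compares the observed DNV count in a cohort against the
expectation under a Poisson mutation model: for a gene set S, cohort size N
and variant class c, the expected count is

    lambda = 2 * N * sum_{g in S} mu_{g,c}

(two haploid genomes per proband), and the enrichment p-value is the upper
tail P(X >= observed) of Poisson(lambda). This is the expectation model
popularised by de novo enrichment tools for trio studies.

Two complements address the strong case/control size imbalance typical of
these cohorts: an exact Fisher test on per-sample event counts, and a
downsampled label-permutation test that repeatedly shrinks the case arm to
the control size.

Contribution is estimated with ascertainment differentials: the difference
in per-sample frequency of a variant type between cases and controls,
interpreted as the fraction of cases carrying a risk-mediating event.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, VariantClass

logger = logging.getLogger(__name__)

#: rate-table column per variant class
_CLASS_COLUMN = {
    VariantClass.SYNONYMOUS: "mu_syn",
    VariantClass.MISSENSE: "mu_mis",
    VariantClass.DMIS: "mu_dmis",
    VariantClass.PTV: "mu_ptv",
}

#: total number of protein-coding genes used as the genome-wide denominator
GENOME_GENE_COUNT = 20154


@dataclass(frozen=True)
class BurdenResult:
    """Observed vs expected DNV count for one cohort x class x gene set."""

    cohort: str
    variant_class: str
    observed: int
    expected: float
    oe_ratio: float
    p_value: float


@dataclass(frozen=True)
class ContributionResult:
    """Ascertainment-differential contribution estimate for one variant class.

    ``pct_events`` is the percentage of events in probands attributable to
    disease risk (scaled from the gene set to the genome denominator);
    ``pct_cases`` is the percentage of probands carrying a risk-mediating
    event, i.e. 100 x (case_rate - control_rate).
    """

    case_rate: float
    control_rate: float
    differential: float
    pct_events: float
    pct_cases: float


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_two_sided: float
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio_haldane: float


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_iter: int
    seed: int
    null_mean: float


def expected_count(
    rate_table: pd.DataFrame,
    gene_set: GeneSet,
    n_samples: int,
    variant_class: VariantClass | Iterable[VariantClass],
    missing: str = "error",
) -> float:
    """Poisson expectation lambda = 2 N sum(mu) over a gene set.

    ``variant_class`` may be a single class or an iterable (a class union
    such as PTV+missense), in which case the component lambdas are summed.
    ``missing`` controls genes absent from the rate table: "error" raises,
    "skip" drops them with a report.
    """
    if isinstance(variant_class, VariantClass):
        classes = [variant_class]
    else:
        classes = list(variant_class)
    genes = list(gene_set.members)
    if not genes:
        return 0.0
    present = [g for g in genes if g in rate_table.index]
    absent = len(genes) - len(present)
    if absent:
        if missing == "error":
            missing_genes = sorted(set(genes) - set(present))
            raise KeyError(
                f"{absent} genes missing from rate table, e.g. {missing_genes[:5]}"
            )
        logger.warning("%d genes missing from rate table; skipped", absent)
    total = 0.0
    for vc in classes:
        mu = rate_table.loc[present, _CLASS_COLUMN[vc]]
        if (mu.dropna() < 0).any():
            raise ValueError(f"negative mutation rate for class {vc}")
        total += float(mu.fillna(0.0).sum())
    return 2.0 * n_samples * total


def poisson_burden_test(
    observed: int,
    expected: float,
    cohort: str = "",
    variant_class: str = "",
) -> BurdenResult:
    """Exact Poisson upper-tail burden test.

    p = P(X >= observed) for X ~ Poisson(expected), i.e. the survival
    function evaluated at observed - 1. With expected = 0 the O/E ratio is
    undefined (NaN); the p-value is 1 when nothing was observed and 0 (with
    a warning) otherwise.
    """
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if expected < 0:
        raise ValueError("expected must be >= 0")
    if expected == 0:
        if observed == 0:
            return BurdenResult(cohort, variant_class, 0, 0.0, math.nan, 1.0)
        logger.warning(
            "observed %d events with zero expectation; p set to 0", observed
        )
        return BurdenResult(cohort, variant_class, observed, 0.0, math.inf, 0.0)
    p = float(stats.poisson.sf(observed - 1, expected))
    return BurdenResult(
        cohort, variant_class, observed, expected, observed / expected, p
    )


def case_control_fisher(
    case_events: int,
    case_n: int,
    control_events: int,
    control_n: int,
) -> FisherResult:
    """Two-sided Fisher's exact test on event carriers vs non-carriers.

    The 2x2 table is [[case_events, case_n - case_events],
    [control_events, control_n - control_events]]. The reported odds ratio
    is the sample (cross-product) OR; when a margin is zero it is NaN and
    the Haldane (add 0.5) OR is the usable summary.
    """
    if case_events > case_n or control_events > control_n:
        raise ValueError("events cannot exceed cohort size")
    a, b = case_events, case_n - case_events
    c, d = control_events, control_n - control_events
    table = ((a, b), (c, d))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if b * c == 0:
        logger.warning("zero margin in Fisher table; sample OR undefined")
        oratio = math.inf if a * d > 0 else math.nan
    else:
        oratio = (a * d) / (b * c)
    return FisherResult(oratio, float(p), table, haldane)


def downsample_permutation_test(
    case_counts: Sequence[float] | np.ndarray,
    control_counts: Sequence[float] | np.ndarray,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Downsampled label-permutation test for a case excess of per-sample counts.

    The observed statistic is the difference in mean per-sample DNV count,
    cases minus controls. Each iteration draws, without replacement, a case
    subset of the control arm's size, pools it with the controls, permutes
    the labels, and records the permuted difference d*. The empirical
    p-value is (1 + #{d* >= d_obs}) / (n_iter + 1), which is never zero.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the permutation test")
    cases = np.asarray(case_counts, dtype=float)
    controls = np.asarray(control_counts, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both cohorts must be non-empty")
    if controls.size > cases.size:
        raise ValueError("control arm must not exceed the case arm")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    m = controls.size
    d_obs = cases.mean() - controls.mean()
    rng = np.random.default_rng(seed)
    hits = 0
    null_sum = 0.0
    for _ in range(n_iter):
        sub = rng.choice(cases, size=m, replace=False)
        pooled = np.concatenate([sub, controls])
        rng.shuffle(pooled)
        d_star = pooled[:m].mean() - pooled[m:].mean()
        null_sum += d_star
        if d_star >= d_obs:
            hits += 1
    p = (1 + hits) / (n_iter + 1)
    return PermutationResult(d_obs, p, n_iter, seed, null_sum / n_iter)


def ascertainment_contribution(
    case_rate: float,
    control_rate: float,
    n_genes_set: int,
    n_genes_genome: int = GENOME_GENE_COUNT,
) -> ContributionResult:
    """Contribution estimate from ascertainment differentials.

    pct_events = 100 * [((case_rate - control_rate) / case_rate) * n_genes_set]
                 / n_genes_genome
    pct_cases  = 100 * (case_rate - control_rate)

    A negative differential (control rate above case rate) is reported as
    zero contribution with a warning.
    """
    if case_rate == 0:
        raise ValueError("case_rate must be > 0")
    if case_rate < 0 or control_rate < 0:
        raise ValueError("rates must be >= 0")
    differential = case_rate - control_rate
    if differential < 0:
        logger.warning(
            "negative ascertainment differential (%.4g); contribution set to 0",
            differential,
        )
        return ContributionResult(case_rate, control_rate, differential, 0.0, 0.0)
    pct_events = 100.0 * ((differential / case_rate) * n_genes_set) / n_genes_genome
    pct_cases = 100.0 * differential
    return ContributionResult(case_rate, control_rate, differential, pct_events, pct_cases)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def burden_report_frame(results: Sequence[BurdenResult]) -> pd.DataFrame:
    """Tabulate burden results with display rounding (O/E to 2 dp, p to 3 sig figs).

    Full precision is preserved in the numeric columns; the display columns
    mirror the conventional published layout.
    """
    df = pd.DataFrame([asdict(r) for r in results])
    df["oe_display"] = df["oe_ratio"].map(lambda x: f"{x:.2f}" if math.isfinite(x) else "NA")
    df["p_display"] = df["p_value"].map(lambda p: f"{p:.3g}")
    return df


def write_burden_report(
    results: Sequence[BurdenResult], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    df = burden_report_frame(results)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([asdict(r) for r in results], indent=2, default=float) + "\n"
        )
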