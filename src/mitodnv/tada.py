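"""TADA-denovo Bayesian gene prioritization.

For each gene and variant class, the de novo count x in a cohort of N trios
is modelled as Poisson. Under the null the rate is lambda = 2 N mu, where mu
is the gene's per-haploid mutation probability for the class. Under the
alternative the rate is inflated by a relative risk gamma drawn from a
Gamma(shape = gamma_mean * beta, rate = beta) prior, so the marginal of x is
negative binomial with size gamma_mean * beta and success probability
beta / (beta + lambda). The class Bayes factor is the ratio of the two
marginal likelihoods, evaluated in closed form (log-space).

Evidence is combined by multiplying Bayes factors across classes (and,
optionally, cohorts); an alternative meta mode pools counts and sample
sizes before computing a single BF. Gene ranking uses the Bayesian FDR:
with prior risk-gene fraction pi, the posterior null probability is
(1 - pi) / ((1 - pi) + pi * BF), and the q-value at rank i of the
BF-descending ordering is the running mean of the top-i posterior nulls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: default fraction of the missense rate assigned to deleterious missense
#: when a rate table has no Dmis column
DEFAULT_DMIS_FRACTION = 0.25


class Tier(Enum):
    """Evidence tier from the Bayesian FDR q-value."""

    STRONG = "strong"        # q <= 0.05
    POSSIBLE = "possible"    # 0.05 < q <= 0.1
    SUGGESTIVE = "suggestive"  # 0.1 < q <= 0.2
    NONE = "none"


@dataclass(frozen=True)
class TadaHyperParams:
    """Hyperparameters of the TADA-denovo model.

    pi is the prior fraction of risk genes; gamma_mean_* are the mean
    relative risks of a risk gene per class (>= 1); beta_* are the rate
    parameters of the Gamma priors on gamma.
    """

    pi: float = 0.05
    gamma_mean_ptv: float = 20.0
    gamma_mean_dmis: float = 8.0
    beta_ptv: float = 1.0
    beta_dmis: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise ValueError("pi must be in (0, 1)")
        if self.gamma_mean_ptv < 1 or self.gamma_mean_dmis < 1:
            raise ValueError("gamma means must be >= 1")
        if self.beta_ptv <= 0 or self.beta_dmis <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class TadaGeneResult:
    gene: str
    n_dmis: int
    n_ptv: int
    bf_dmis: float
    bf_ptv: float
    bf_total: float
    posterior_null: float
    q_value: float = math.nan
    tier: Tier = Tier.NONE


def class_bayes_factor(
    x: int | np.ndarray,
    mu: float | np.ndarray,
    n_samples: int,
    gamma_mean: float,
    beta: float,
) -> float | np.ndarray:
    """Closed-form class Bayes factor; vectorized over x and mu.

    BF = NB(x; size = gamma_mean*beta, p = beta/(beta+lambda)) / Poisson(x; lambda)
    with lambda = 2 N mu. Computed in log-space to avoid overflow.
    """
    x_arr = np.asarray(x)
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("x must be >= 0")
    if np.any(mu_arr <= 0):
        raise ValueError("mu must be > 0")
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    lam = 2.0 * n_samples * mu_arr
    size = gamma_mean * beta
    p = beta / (beta + lam)
    log_bf = stats.nbinom.logpmf(x_arr, size, p) - stats.poisson.logpmf(x_arr, lam)
    with np.errstate(over="ignore"):  # overwhelming evidence may exceed float range
        out = np.exp(log_bf)
    if np.isscalar(x) and np.isscalar(mu):
        return float(out)
    return out


def gene_bayes_factor(*bayes_factors: float | Iterable[float]) -> float:
    """Product of Bayes factors (per class and/or per cohort), in log-space.

    Accepts scalars and/or iterables; BF = 0 anywhere yields 0.
    """
    values: list[float] = []
    for bf in bayes_factors:
        if np.isscalar(bf):
            values.append(float(bf))
        else:
            values.extend(float(v) for v in bf)
    if any(v < 0 for v in values):
        raise ValueError("Bayes factors must be >= 0")
    if any(v == 0 for v in values):
        return 0.0
    return float(np.exp(np.sum(np.log(values))))


def estimate_gamma_from_burden(oe_ratio: float, pi: float) -> float:
    """Method-of-moments relative-risk estimate from a gene-set O/E ratio.

    Uses E[O/E] = (1 - pi) + pi * gamma_mean, floored at 1 (a risk gene
    cannot be protective under this model).
    """
    if oe_ratio <= 0:
        raise ValueError("oe_ratio must be > 0")
    if not 0 < pi < 1:
        raise ValueError("pi must be in (0, 1)")
    return max(1.0, (oe_ratio - (1.0 - pi)) / pi)


def bayesian_fdr(
    bf_by_gene: Mapping[str, float] | pd.Series,
    pi: float,
) -> pd.Series:
    """Bayesian FDR q-values from gene Bayes factors.

    posterior_null_g = (1-pi) / ((1-pi) + pi * BF_g); genes are sorted by BF
    descending and the q at rank i is the mean posterior null of the top i
    genes. Tied BFs share the worst (largest) q of their tie block. Returns
    a Series aligned with the input gene order.
    """
    s = pd.Series(bf_by_gene, dtype=float)
    if (s < 0).any():
        raise ValueError("Bayes factors must be >= 0")
    post = (1.0 - pi) / ((1.0 - pi) + pi * s)
    order = post.sort_values(kind="mergesort")  # BF desc == posterior asc
    q_sorted = order.expanding().mean()
    # ties on BF (== ties on posterior) share the worst q of the block
    q_sorted = q_sorted.groupby(order.values).transform("max")
    return q_sorted.reindex(s.index).clip(upper=1.0)


def assign_tier(q: float) -> Tier:
    """Map a q-value to an evidence tier (boundaries inclusive)."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    if q <= 0.05:
        return Tier.STRONG
    if q <= 0.1:
        return Tier.POSSIBLE
    if q <= 0.2:
        return Tier.SUGGESTIVE
    return Tier.NONE


def _dmis_rates(rate_table: pd.DataFrame, dmis_fraction: float) -> pd.Series:
    """Dmis rate column with the documented fallback mu_dmis = f * mu_mis."""
    mu_dmis = rate_table["mu_dmis"]
    if mu_dmis.isna().any():
        n = int(mu_dmis.isna().sum())
        logger.warning(
            "mu_dmis missing for %d genes; using %.2f x mu_mis as the Dmis rate",
            n,
            dmis_fraction,
        )
        mu_dmis = mu_dmis.fillna(dmis_fraction * rate_table["mu_mis"])
    return mu_dmis


def run_tada(
    counts: pd.DataFrame,
    rate_table: pd.DataFrame,
    n_samples: int,
    params: TadaHyperParams = TadaHyperParams(),
    dmis_fraction: float = DEFAULT_DMIS_FRACTION,
) -> pd.DataFrame:
    """TADA-denovo over a gene universe for one cohort.

    ``counts`` is a frame indexed by gene with integer columns ``n_dmis``
    and ``n_ptv``; genes with zero counts must be present (they receive
    BF < 1 and keep the FDR denominator equal to the analyzed universe).
    Returns a frame indexed by gene with BFs, posterior null, q and tier,
    sorted by q ascending.
    """
    genes = counts.index
    missing = genes.difference(rate_table.index)
    if len(missing):
        raise KeyError(f"genes missing from rate table, e.g. {list(missing[:5])}")
    rt = rate_table.loc[genes]
    mu_dmis = _dmis_rates(rt, dmis_fraction)
    bf_dmis = class_bayes_factor(
        counts["n_dmis"].to_numpy(),
        mu_dmis.to_numpy(),
        n_samples,
        params.gamma_mean_dmis,
        params.beta_dmis,
    )
    bf_ptv = class_bayes_factor(
        counts["n_ptv"].to_numpy(),
        rt["mu_ptv"].to_numpy(),
        n_samples,
        params.gamma_mean_ptv,
        params.beta_ptv,
    )
    bf_total = bf_dmis * bf_ptv
    q = bayesian_fdr(pd.Series(bf_total, index=genes), params.pi)
    post = (1.0 - params.pi) / ((1.0 - params.pi) + params.pi * bf_total)
    out = pd.DataFrame(
        {
            "n_dmis": counts["n_dmis"],
            "n_ptv": counts["n_ptv"],
            "bf_dmis": bf_dmis,
            "bf_ptv": bf_ptv,
            "bf_total": bf_total,
            "posterior_null": post,
            "q_value": q,
        },
        index=genes,
    )
    out["tier"] = [assign_tier(v).value for v in out["q_value"]]
    return out.sort_values(["q_value", "bf_total"], ascending=[True, False])


def run_tada_meta(
    counts_by_cohort: Mapping[str, pd.DataFrame],
    rate_table: pd.DataFrame,
    n_samples_by_cohort: Mapping[str, int],
    params: TadaHyperParams = TadaHyperParams(),
    mode: str = "pooled",
    dmis_fraction: float = DEFAULT_DMIS_FRACTION,
) -> pd.DataFrame:
    """Meta-analysis across cohorts.

    ``mode="pooled"`` (default) sums counts and sample sizes and runs a
    single TADA pass; ``mode="product"`` runs each cohort separately and
    multiplies the gene Bayes factors before the FDR step. The two agree
    exactly when per-cohort priors and per-cohort lambda are identical.
    """
    cohorts = list(counts_by_cohort)
    if not cohorts:
        raise ValueError("no cohorts supplied")
    if mode == "pooled":
        pooled = sum(counts_by_cohort[c][["n_dmis", "n_ptv"]] for c in cohorts)
        pooled_n = sum(n_samples_by_cohort[c] for c in cohorts)
        return run_tada(pooled, rate_table, pooled_n, params, dmis_fraction)
    if mode != "product":
        raise ValueError(f"unknown meta mode {mode!r}")
    per = {
        c: run_tada(
            counts_by_cohort[c], rate_table, n_samples_by_cohort[c], params, dmis_fraction
        )
        for c in cohorts
    }
    genes = per[cohorts[0]].index.sort_values()
    bf_total = pd.Series(1.0, index=genes)
    n_dmis = pd.Series(0, index=genes)
    n_ptv = pd.Series(0, index=genes)
    for c in cohorts:
        t = per[c].reindex(genes)
        bf_total *= t["bf_total"]
        n_dmis += t["n_dmis"]
        n_ptv += t["n_ptv"]
    q = bayesian_fdr(bf_total, params.pi)
    post = (1.0 - params.pi) / ((1.0 - params.pi) + params.pi * bf_total)
    out = pd.DataFrame(
        {
            "n_dmis": n_dmis,
            "n_ptv": n_ptv,
            "bf_total": bf_total,
            "posterior_null": post,
            "q_value": q,
        }
    )
    out["tier"] = [assign_tier(v).value for v in out["q_value"]]
    return out.sort_values(["q_value", "bf_total"], ascending=[True, False])


def tier_counts(results: pd.DataFrame) -> dict[str, int]:
    """Number of genes per evidence tier in a TADA result frame."""
    return {t.value: int((results["tier"] == t.value).sum()) for t in Tier}


def write_tada_report(results: pd.DataFrame, tsv_path, params: TadaHyperParams | None = None):
    """Write a gene-per-row report (Gene, nDmis, nPTV, FDR, tier, BFs)."""
    out = results.rename(
        columns={"n_dmis": "nDmis", "n_ptv": "nPTV", "q_value": "FDR"}
    )
    out.index.name = "Gene"
    out.to_csv(tsv_path, sep="\t", float_format="%.6g")
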