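"""Synthetic cohorts, rate tables, PPI graphs and expression matrices.

Every generator here inverts a piece of the analysis model so that each
pipeline stage can be tested against known ground truth:

* per-gene mutation rates are drawn log-normally with fixed class ratios;
* a designated fraction pi of genes are risk genes whose per-class relative
  risk gamma is drawn from a Gamma(shape = gamma_mean * beta, rate = beta)
  prior, and per-gene de novo counts are Poisson(2 N mu gamma);
* PPI graphs are preferential-attachment backbones with extra edges wired
  among risk genes;
* expression matrices are log-normal with a configurable prenatal shift for
  a biased gene subset.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, MembershipTable, PRENATAL, POSTNATAL
from .io import GeneSet, VariantClass, VariantRecord, aggregate_counts, CohortCounts

logger = logging.getLogger(__name__)

#: class-rate ratios relative to the missense rate; chosen so the expected
#: class proportions echo large published trio cohorts (PTV roughly a tenth
#: of missense, synonymous roughly four tenths).
DEFAULT_CLASS_RATIOS = {"ptv": 0.1, "syn": 0.4, "dmis": 0.25}

_PTV_CONSEQUENCE_CYCLE = ("frameshift", "stop-gain", "splice-site", "stop-loss")


def gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated cohort.

    ``gamma`` is a frame indexed by gene with columns 'ptv' and 'dmis'
    holding the per-class relative risks (1.0 for non-risk genes).
    """

    genes: tuple[str, ...]
    is_risk: Mapping[str, bool]
    gamma: pd.DataFrame
    pi: float
    gamma_mean_ptv: float
    gamma_mean_dmis: float
    beta: float
    seed: int

    @property
    def risk_genes(self) -> frozenset[str]:
        return frozenset(g for g in self.genes if self.is_risk[g])

    @property
    def n_risk(self) -> int:
        return len(self.risk_genes)


def make_truth(
    genes: Sequence[str],
    pi: float = 0.05,
    gamma_mean_ptv: float = 20.0,
    gamma_mean_dmis: float = 8.0,
    beta: float = 1.0,
    seed: int = 0,
) -> SimulationTruth:
    """Draw risk flags (Bernoulli pi) and per-class relative risks."""
    if not 0 < pi < 1:
        raise ValueError("pi must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = tuple(genes)
    risk = rng.random(len(genes)) < pi
    gamma = pd.DataFrame(1.0, index=list(genes), columns=["ptv", "dmis"])
    n_risk = int(risk.sum())
    if n_risk:
        gamma.loc[risk, "ptv"] = rng.gamma(gamma_mean_ptv * beta, 1.0 / beta, n_risk)
        gamma.loc[risk, "dmis"] = rng.gamma(gamma_mean_dmis * beta, 1.0 / beta, n_risk)
    logger.info("truth: %d/%d risk genes (pi=%.3g)", n_risk, len(genes), pi)
    return SimulationTruth(
        genes=genes,
        is_risk={g: bool(r) for g, r in zip(genes, risk)},
        gamma=gamma,
        pi=pi,
        gamma_mean_ptv=gamma_mean_ptv,
        gamma_mean_dmis=gamma_mean_dmis,
        beta=beta,
        seed=seed,
    )


def simulate_rate_table(
    n_genes: int,
    seed: int,
    log_mu_mean: float = -11.0,
    log_mu_sd: float = 1.0,
    class_ratios: Mapping[str, float] = DEFAULT_CLASS_RATIOS,
) -> pd.DataFrame:
    """Log-normal per-gene missense rates with fixed class ratios.

    mu_mis ~ exp(Normal(log_mu_mean, log_mu_sd)); mu_ptv, mu_syn and mu_dmis
    are fixed multiples of mu_mis. Deterministic given the seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    mu_mis = np.exp(rng.normal(log_mu_mean, log_mu_sd, n_genes))
    genes = gene_names(n_genes)
    return pd.DataFrame(
        {
            "mu_syn": class_ratios["syn"] * mu_mis,
            "mu_mis": mu_mis,
            "mu_dmis": class_ratios["dmis"] * mu_mis,
            "mu_ptv": class_ratios["ptv"] * mu_mis,
        },
        index=pd.Index(genes, name="Gene"),
    )


def simulate_cohort(
    rate_table: pd.DataFrame,
    n_samples: int,
    truth: SimulationTruth,
    seed: int,
    cohort: str = "UDD",
    dmis_threshold: float = 0.7,
) -> tuple[list[VariantRecord], CohortCounts]:
    """Draw a cohort of de novo variants under the Poisson-Gamma model.

    Per gene, counts are Poisson(2 N mu_class gamma_class): gamma applies to
    PTV and Dmis; synonymous and benign missense (mu_mis - mu_dmis) are
    neutral. Counts are expanded to one VariantRecord per event with
    synthetic sample ids and class-consistent consequences (Dmis rows score
    above the threshold, benign missense below). A sample may carry several
    events, matching how per-sample rates are computed (events / N).
    """
    missing = [g for g in truth.genes if g not in rate_table.index]
    if missing:
        raise KeyError(f"truth genes missing from rate table, e.g. {missing[:5]}")
    rng = np.random.default_rng(seed)
    genes = list(truth.genes)
    rt = rate_table.loc[genes]
    two_n = 2.0 * n_samples
    gamma_ptv = truth.gamma.loc[genes, "ptv"].to_numpy()
    gamma_dmis = truth.gamma.loc[genes, "dmis"].to_numpy()
    mu_dmis = rt["mu_dmis"].fillna(0.25 * rt["mu_mis"]).to_numpy()
    mu_benign_mis = np.maximum(rt["mu_mis"].to_numpy() - mu_dmis, 0.0)
    lam = {
        "syn": two_n * rt["mu_syn"].to_numpy(),
        "mis": two_n * mu_benign_mis,
        "dmis": two_n * mu_dmis * gamma_dmis,
        "ptv": two_n * rt["mu_ptv"].to_numpy() * gamma_ptv,
    }
    counts = {k: rng.poisson(v) for k, v in lam.items()}

    records: list[VariantRecord] = []
    id_width = max(5, len(str(n_samples)))
    for gi, gene in enumerate(genes):
        for kind in ("syn", "mis", "dmis", "ptv"):
            for j in range(counts[kind][gi]):
                sample = int(rng.integers(1, n_samples + 1))
                pos = int(rng.integers(1, 1_000_000))
                if kind == "syn":
                    consequence, score = "synonymous", None
                elif kind == "mis":
                    consequence = "missense"
                    score = round(float(rng.uniform(0.0, dmis_threshold * 0.999)), 4)
                elif kind == "dmis":
                    consequence = "missense"
                    score = round(float(rng.uniform(dmis_threshold, 1.0)), 4)
                else:
                    consequence = _PTV_CONSEQUENCE_CYCLE[j % len(_PTV_CONSEQUENCE_CYCLE)]
                    score = None
                records.append(
                    VariantRecord(
                        sample_id=f"{cohort}{sample:0{id_width}d}",
                        cohort=cohort,
                        gene=gene,
                        chrom=str(1 + gi % 22),
                        pos=pos,
                        ref="A",
                        alt="G",
                        consequence=consequence,
                        dmis_score=score,
                    )
                )
    gene_set = GeneSet(f"{cohort}_universe", frozenset(genes))
    cohort_counts = aggregate_counts(
        records, gene_set, cohort, n_samples, dmis_threshold=dmis_threshold
    )
    return records, cohort_counts


def counts_frame(records_counts: CohortCounts, genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene n_dmis / n_ptv frame (TADA input) from aggregated counts."""
    return pd.DataFrame(
        {
            "n_dmis": [
                records_counts.gene_class_count(g, VariantClass.DMIS) for g in genes
            ],
            "n_ptv": [
                records_counts.gene_class_count(g, VariantClass.PTV) for g in genes
            ],
        },
        index=pd.Index(list(genes), name="Gene"),
    )


def simulate_annotations(
    genes: Sequence[str],
    risk_genes: Sequence[str] | frozenset[str],
    seed: int,
    risk_loeuf_scale: float = 0.3,
    null_loeuf_scale: float = 0.9,
) -> pd.DataFrame:
    """Synthetic constraint annotations (LOEUF, mis_Z), gene-indexed.

    Risk genes draw LOEUF from a tighter (more constrained) distribution and
    higher mis_Z, echoing the tendency of haploinsufficient disease genes to
    be PTV-intolerant. Purely a test/demonstration scaffold.
    """
    rng = np.random.default_rng(seed)
    risk = set(risk_genes)
    loeuf = np.empty(len(genes))
    mis_z = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g in risk:
            loeuf[i] = rng.gamma(2.0, risk_loeuf_scale / 2.0)
            mis_z[i] = rng.normal(2.5, 1.0)
        else:
            loeuf[i] = rng.gamma(2.0, null_loeuf_scale / 2.0)
            mis_z[i] = rng.normal(0.0, 1.0)
    return pd.DataFrame(
        {"loeuf": np.round(loeuf, 4), "mis_z": np.round(mis_z, 4)},
        index=pd.Index(list(genes), name="Gene"),
    )


def simulate_ppi(
    genes: Sequence[str],
    risk_genes: Sequence[str] | frozenset[str],
    attachment: int = 2,
    risk_boost: float = 0.0,
    seed: int = 0,
    decoy_fraction: float = 0.3,
) -> nx.Graph:
    """Scale-free PPI graph with optional extra wiring among risk genes.

    A preferential-attachment backbone is scored in (600, 1000]; each risk
    gene pair gains an extra edge with probability ``risk_boost``. A
    fraction of additional decoy edges scored <= 600 is added so that
    score thresholding is exercised. No self-loops or duplicate edges.
    """
    genes = list(genes)
    risk = set(risk_genes)
    if not risk <= set(genes):
        raise ValueError("risk_genes must be a subset of genes")
    rng = np.random.default_rng(seed)
    backbone = nx.barabasi_albert_graph(
        len(genes), attachment, seed=int(rng.integers(0, 2**31 - 1))
    )
    g = nx.relabel_nodes(backbone, dict(enumerate(genes)))
    for u, v in g.edges:
        g[u][v]["score"] = int(rng.integers(601, 1001))
    if risk_boost > 0:
        risk_sorted = sorted(risk)
        for i, u in enumerate(risk_sorted):
            for v in risk_sorted[i + 1 :]:
                if not g.has_edge(u, v) and rng.random() < risk_boost:
                    g.add_edge(u, v, score=int(rng.integers(601, 1001)))
    n_decoys = int(decoy_fraction * g.number_of_edges())
    added = 0
    while added < n_decoys:
        u, v = rng.choice(len(genes), size=2, replace=False)
        u, v = genes[u], genes[v]
        if not g.has_edge(u, v):
            g.add_edge(u, v, score=int(rng.integers(1, 601)))
            added += 1
    return g


def simulate_expression(
    genes: Sequence[str],
    n_pre: int,
    n_post: int,
    biased_set: Sequence[str] | frozenset[str],
    effect: float,
    seed: int,
    n_modules: int = 5,
    module_bias: float = 0.6,
    base_log_mean: float = 3.0,
    log_sd: float = 1.0,
) -> tuple[ExpressionMatrix, MembershipTable]:
    """Log-normal expression matrix with a prenatal shift for a biased set.

    Values are 2**Normal(base_log_mean, log_sd); biased genes get +effect on
    the prenatal log2 mean. Module memberships are drawn so that module 'M1'
    over-contains the biased set: a biased gene joins M1 with probability
    ``module_bias``, any other gene with module_bias / n_modules.
    """
    genes = list(genes)
    biased = set(biased_set)
    if not biased <= set(genes):
        raise ValueError("biased_set must be a subset of genes")
    rng = np.random.default_rng(seed)
    samples = [f"pre{i:03d}" for i in range(1, n_pre + 1)] + [
        f"post{i:03d}" for i in range(1, n_post + 1)
    ]
    periods = pd.Series(
        [PRENATAL] * n_pre + [POSTNATAL] * n_post, index=samples, name="period"
    )
    log_means = np.full((len(genes), n_pre + n_post), base_log_mean)
    biased_rows = np.array([g in biased for g in genes])
    log_means[np.ix_(biased_rows, np.arange(n_pre))] += effect
    values = 2.0 ** rng.normal(log_means, log_sd)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), periods=periods
    )
    categories: dict[str, set[str]] = {f"M{i}": set() for i in range(1, n_modules + 1)}
    others = [f"M{i}" for i in range(2, n_modules + 1)]
    for g in genes:
        p_m1 = module_bias if g in biased else module_bias / n_modules
        if rng.random() < p_m1:
            categories["M1"].add(g)
        else:
            categories[others[int(rng.integers(0, len(others)))]].add(g)
    membership = MembershipTable(
        {k: frozenset(v) for k, v in categories.items()}, frozenset(genes)
    )
    return expr, membership
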