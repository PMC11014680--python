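"""End-to-end orchestration of the DNV analysis pipeline.

The pipeline mirrors the shape of a cohort DNV study: synthetic (or user)
DNV tables are aggregated per cohort, burden-tested against the Poisson
expectation, contribution is estimated from ascertainment differentials,
genes are prioritized with TADA-denovo, and the prioritized set is
characterized by PPI connectivity, hub centralities, co-expression module
enrichment and prenatal expression bias.

Every stochastic stage draws its seed deterministically from the single
top-level seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import burden as bd
from . import expression as ex
from . import io as dio
from . import network as net
from . import simulate as sim
from . import tada as td

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(Exception):
    """Missing or malformed input data (CLI exit code 3)."""


class StageError(Exception):
    """A pipeline stage failed (CLI exit code 4)."""


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the shipped demo scenario as default."""

    seed: int = 1
    out_dir: str = "mitodnv_out"
    # synthetic scenario
    n_genes: int = 400
    n_udd: int = 6000
    n_asd: int = 2000
    n_control: int = 1500
    pi: float = 0.05
    gamma_mean_ptv: float = 20.0
    gamma_mean_dmis: float = 8.0
    beta: float = 1.0
    log_mu_mean: float = -11.0
    log_mu_sd: float = 1.0
    risk_boost: float = 0.4
    n_pre: int = 20
    n_post: int = 20
    expression_effect: float = 1.0
    # analysis thresholds
    dmis_threshold: float = 0.7
    min_ppi_score: int = 600
    loeuf_max: float = 0.35
    tier_cutoffs: tuple[float, float, float] = (0.05, 0.1, 0.2)
    n_downsample_iter: int = 2000
    n_perm_network: int = 2000
    genome_gene_count: int = bd.GENOME_GENE_COUNT
    # optional user data (overrides the synthetic scenario when all set)
    dnv_table: str | None = None
    rate_table: str | None = None
    gene_set: str | None = None

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")
        for name in ("n_genes", "n_udd", "n_asd", "n_control"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.pi < 1:
            raise ConfigError("pi must be in (0, 1)")
        if not 0 < self.dmis_threshold < 1:
            raise ConfigError("dmis_threshold must be in (0, 1)")
        if not 0 <= self.min_ppi_score <= 1000:
            raise ConfigError("min_ppi_score must be in [0, 1000]")
        if self.loeuf_max <= 0:
            raise ConfigError("loeuf_max must be > 0")
        t = tuple(self.tier_cutoffs)
        if len(t) != 3 or not (0 < t[0] < t[1] < t[2] <= 1):
            raise ConfigError("tier_cutoffs must be three increasing values in (0, 1]")
        object.__setattr__(self, "tier_cutoffs", t)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["tier_cutoffs"] = list(self.tier_cutoffs)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        d = asdict(self)
        d["tier_cutoffs"] = list(self.tier_cutoffs)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31 derived from the top seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


_COHORTS = (dio.UDD, dio.ASD, dio.CONTROL)


def run_simulate(config: PipelineConfig, out_dir: Path) -> dict[str, Any]:
    """Generate the synthetic scenario and write all input tables."""
    out_dir.mkdir(parents=True, exist_ok=True)
    rates = sim.simulate_rate_table(
        config.n_genes,
        seed=config.stage_seed("rates"),
        log_mu_mean=config.log_mu_mean,
        log_mu_sd=config.log_mu_sd,
    )
    dio.write_rate_table(rates, out_dir / "rates.tsv")
    genes = list(rates.index)
    truth = sim.make_truth(
        genes,
        pi=config.pi,
        gamma_mean_ptv=config.gamma_mean_ptv,
        gamma_mean_dmis=config.gamma_mean_dmis,
        beta=config.beta,
        seed=config.stage_seed("truth"),
    )
    null_truth = sim.SimulationTruth(
        genes=tuple(genes),
        is_risk={g: False for g in genes},
        gamma=pd.DataFrame(1.0, index=genes, columns=["ptv", "dmis"]),
        pi=config.pi,
        gamma_mean_ptv=1.0,
        gamma_mean_dmis=1.0,
        beta=config.beta,
        seed=config.stage_seed("truth"),
    )
    all_records = []
    sizes = {dio.UDD: config.n_udd, dio.ASD: config.n_asd, dio.CONTROL: config.n_control}
    for cohort in _COHORTS:
        t = null_truth if cohort == dio.CONTROL else truth
        records, _ = sim.simulate_cohort(
            rates,
            sizes[cohort],
            t,
            seed=config.stage_seed(f"cohort:{cohort}"),
            cohort=cohort,
            dmis_threshold=config.dmis_threshold,
        )
        all_records.extend(records)
    dio.write_dnv_table(all_records, out_dir / "dnv.tsv")
    dio.write_gene_set(dio.GeneSet("universe", frozenset(genes)), out_dir / "genes.txt")
    annotations = sim.simulate_annotations(
        genes, truth.risk_genes, seed=config.stage_seed("annotations")
    )
    ann_out = annotations.rename(columns={"loeuf": "LOEUF", "mis_z": "MisZ"})
    ann_out.to_csv(out_dir / "annotations.tsv", sep="\t")
    ppi = sim.simulate_ppi(
        genes,
        truth.risk_genes,
        risk_boost=config.risk_boost,
        seed=config.stage_seed("ppi"),
    )
    net.write_edge_table(ppi, out_dir / "ppi_edges.tsv")
    expr, membership = sim.simulate_expression(
        genes,
        config.n_pre,
        config.n_post,
        truth.risk_genes,
        effect=config.expression_effect,
        seed=config.stage_seed("expression"),
    )
    expr.values.round(4).to_csv(out_dir / "expression.tsv", sep="\t")
    expr.periods.to_csv(out_dir / "periods.tsv", sep="\t")
    with open(out_dir / "modules.gmt", "w") as fh:
        for name in sorted(membership.categories):
            members = "\t".join(sorted(membership.categories[name]))
            fh.write(f"{name}\tsynthetic module\t{members}\n")
    dio.write_gene_set(
        dio.GeneSet("risk_truth", truth.risk_genes), out_dir / "risk_truth.txt"
    )
    config.to_yaml(out_dir / "scenario.yaml")
    return {
        "rates": rates,
        "truth": truth,
        "records": all_records,
        "genes": genes,
        "sizes": sizes,
        "ppi": ppi,
        "expr": expr,
        "membership": membership,
        "annotations": annotations,
    }


_BURDEN_CLASSES: dict[str, Any] = {
    "synonymous": dio.VariantClass.SYNONYMOUS,
    "missense": dio.VariantClass.MISSENSE,
    "ptv": dio.VariantClass.PTV,
    "ptv+missense": (dio.VariantClass.PTV, dio.VariantClass.MISSENSE),
}


def run_burden(
    records,
    rates: pd.DataFrame,
    gene_set: dio.GeneSet,
    sizes: dict[str, int],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Observed/expected burden per cohort x variant class.

    Case cohorts are reported individually and combined; significance is
    flagged at the Bonferroni level 0.05 / (4 classes x 2 arms).
    """
    by_cohort = {c: [r for r in records if r.cohort == c] for c in sizes}
    arms: dict[str, tuple[list, int]] = {
        c: (by_cohort[c], sizes[c]) for c in sizes
    }
    case_cohorts = [c for c in sizes if c != dio.CONTROL]
    if len(case_cohorts) > 1:
        combined = [r for c in case_cohorts for r in by_cohort[c]]
        arms["+".join(case_cohorts)] = (combined, sum(sizes[c] for c in case_cohorts))
    results = []
    alpha = 0.05 / (len(_BURDEN_CLASSES) * 2)
    for cohort, (recs, n) in arms.items():
        counts = dio.aggregate_counts(
            recs, gene_set, cohort, n, dmis_threshold=config.dmis_threshold
        )
        for label, vc in _BURDEN_CLASSES.items():
            observed = (
                sum(counts.class_total(c) for c in vc)
                if isinstance(vc, tuple)
                else counts.class_total(vc)
            )
            expected = bd.expected_count(rates, gene_set, n, vc, missing="error")
            results.append(bd.poisson_burden_test(observed, expected, cohort, label))
    df = bd.burden_report_frame(results)
    df["significant"] = df["p_value"] < alpha
    return df


def run_contribution(
    records,
    gene_set: dio.GeneSet,
    sizes: dict[str, int],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Ascertainment-differential contribution of PTV and Dmis events."""
    case_cohorts = [c for c in sizes if c != dio.CONTROL]
    case_records = [r for r in records if r.cohort in case_cohorts]
    control_records = [r for r in records if r.cohort == dio.CONTROL]
    n_cases = sum(sizes[c] for c in case_cohorts)
    n_controls = sizes[dio.CONTROL]
    case_counts = dio.aggregate_counts(
        case_records, gene_set, "cases", n_cases, config.dmis_threshold
    )
    ctrl_counts = dio.aggregate_counts(
        control_records, gene_set, dio.CONTROL, n_controls, config.dmis_threshold
    )
    rows = []
    for label, vc in (("ptv", dio.VariantClass.PTV), ("dmis", dio.VariantClass.DMIS)):
        case_rate = case_counts.per_sample_rate(vc)
        ctrl_rate = ctrl_counts.per_sample_rate(vc)
        if case_rate == 0:
            logger.warning("no case events for class %s; contribution skipped", label)
            continue
        contrib = bd.ascertainment_contribution(
            case_rate, ctrl_rate, len(gene_set), config.genome_gene_count
        )
        fisher = bd.case_control_fisher(
            case_counts.class_total(vc), n_cases, ctrl_counts.class_total(vc), n_controls
        )
        # per-sample event counts for the downsampled permutation test
        case_events = _per_sample_counts(case_records, gene_set, vc, n_cases, config)
        ctrl_events = _per_sample_counts(control_records, gene_set, vc, n_controls, config)
        perm = bd.downsample_permutation_test(
            case_events,
            ctrl_events,
            n_iter=config.n_downsample_iter,
            seed=config.stage_seed(f"downsample:{label}"),
        )
        rows.append(
            {
                "variant_class": label,
                "case_rate": contrib.case_rate,
                "control_rate": contrib.control_rate,
                "differential": contrib.differential,
                "pct_events": contrib.pct_events,
                "pct_cases": contrib.pct_cases,
                "fisher_or": fisher.odds_ratio,
                "fisher_p": fisher.p_two_sided,
                "permutation_p": perm.p_value,
            }
        )
    return pd.DataFrame(rows)


def _per_sample_counts(records, gene_set, vc, n_samples, config) -> np.ndarray:
    per_sample: dict[str, int] = {}
    for r in records:
        if r.gene not in gene_set:
            continue
        if dio.classify_variant(r, config.dmis_threshold) is vc:
            per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + 1
    counts = np.zeros(n_samples)
    carriers = list(per_sample.values())
    counts[: len(carriers)] = carriers  # remaining samples carry zero events
    return counts


def run_tada_stage(
    records,
    rates: pd.DataFrame,
    genes: list[str],
    sizes: dict[str, int],
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """Per-cohort and pooled-meta TADA over the gene universe."""
    params = td.TadaHyperParams(
        pi=config.pi,
        gamma_mean_ptv=config.gamma_mean_ptv,
        gamma_mean_dmis=config.gamma_mean_dmis,
        beta_ptv=config.beta,
        beta_dmis=config.beta,
    )
    gene_set = dio.GeneSet("universe", frozenset(genes))
    case_cohorts = [c for c in sizes if c != dio.CONTROL]
    counts_by_cohort = {}
    for c in case_cohorts:
        recs = [r for r in records if r.cohort == c]
        agg = dio.aggregate_counts(recs, gene_set, c, sizes[c], config.dmis_threshold)
        counts_by_cohort[c] = sim.counts_frame(agg, genes)
    out = {
        c: td.run_tada(counts_by_cohort[c], rates, sizes[c], params)
        for c in case_cohorts
    }
    out["meta"] = td.run_tada_meta(
        counts_by_cohort, rates, {c: sizes[c] for c in case_cohorts}, params, mode="pooled"
    )
    return out


def run_network_stage(
    ppi_edges,
    prioritized: dio.GeneSet,
    known_risk: dio.GeneSet,
    config: PipelineConfig,
) -> dict[str, Any]:
    graph = net.build_graph(ppi_edges, min_score=config.min_ppi_score)
    result = net.connectivity_permutation_test(
        graph,
        prioritized,
        known_risk,
        n_perm=config.n_perm_network,
        seed=config.stage_seed("network"),
    )
    hubs = net.hub_genes(graph, k=10)
    return {"connectivity": result, "hubs": hubs, "graph": graph}


def run_expression_stage(
    expr: ex.ExpressionMatrix,
    membership: ex.MembershipTable,
    prioritized: dio.GeneSet,
    config: PipelineConfig,
) -> dict[str, Any]:
    enrich = ex.celltype_enrichment(prioritized, membership, set_name=prioritized.name)
    bias = ex.prenatal_bias_test(expr, prioritized)
    return {"module_enrichment": enrich, "prenatal_bias": bias}


def run_full(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage, isolating failures, and write the report bundle.

    Returns a summary dict (also written as summary.json). A stage failure
    marks downstream dependents SKIPPED rather than aborting the bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    statuses = summary["stages"]

    def fail(stage: str, exc: Exception) -> None:
        logger.error("stage %s failed: %s", stage, exc)
        statuses[stage] = {"status": "FAILED", "error": str(exc)}

    data = None
    try:
        data = run_simulate(config, out_dir)
        statuses["simulate"] = {"status": "OK", "n_records": len(data["records"])}
    except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
        fail("simulate", exc)

    gene_set = (
        dio.GeneSet("universe", frozenset(data["genes"])) if data else None
    )

    burden_df = None
    if data:
        try:
            burden_df = run_burden(
                data["records"], data["rates"], gene_set, data["sizes"], config
            )
            burden_df.to_csv(out_dir / "burden.tsv", sep="\t", index=False)
            statuses["burden"] = {"status": "OK"}
        except Exception as exc:
            fail("burden", exc)
    else:
        statuses["burden"] = {"status": "SKIPPED"}

    if data:
        try:
            contrib_df = run_contribution(data["records"], gene_set, data["sizes"], config)
            contrib_df.to_csv(out_dir / "contribution.tsv", sep="\t", index=False)
            statuses["contribution"] = {"status": "OK"}
        except Exception as exc:
            fail("contribution", exc)
    else:
        statuses["contribution"] = {"status": "SKIPPED"}

    tada_results = None
    if data:
        try:
            tada_results = run_tada_stage(
                data["records"], data["rates"], data["genes"], data["sizes"], config
            )
            for name, frame in tada_results.items():
                td.write_tada_report(frame, out_dir / f"tada_{name}.tsv")
            statuses["tada"] = {
                "status": "OK",
                "tiers_meta": td.tier_counts(tada_results["meta"]),
            }
        except Exception as exc:
            fail("tada", exc)
    else:
        statuses["tada"] = {"status": "SKIPPED"}

    prioritized = None
    if tada_results is not None:
        meta = tada_results["meta"]
        hits = meta.index[meta["q_value"] <= config.tier_cutoffs[2]]
        if len(hits):
            prioritized = dio.GeneSet("prioritized", frozenset(hits))
            dio.write_gene_set(prioritized, out_dir / "prioritized.txt")
            if data is not None:
                intolerant, report = dio.filter_by_constraint(
                    prioritized, data["annotations"], config.loeuf_max
                )
                statuses["tada"]["n_prioritized"] = len(prioritized)
                statuses["tada"]["n_ptv_intolerant"] = report.n_kept

    if prioritized is not None and data:
        try:
            known = dio.GeneSet("risk_truth", data["truth"].risk_genes)
            net_out = run_network_stage(
                out_dir / "ppi_edges.tsv", prioritized, known, config
            )
            conn = net_out["connectivity"]
            (out_dir / "network.json").write_text(
                json.dumps(
                    {
                        "observed_links": conn.observed_links,
                        "null_mean": conn.null_mean,
                        "empirical_p": conn.empirical_p,
                        "n_perm": conn.n_perm,
                        "seed": conn.seed,
                        "hubs": net_out["hubs"],
                    },
                    indent=2,
                )
                + "\n"
            )
            statuses["network"] = {"status": "OK", "p": conn.empirical_p}
        except Exception as exc:
            fail("network", exc)
    else:
        statuses["network"] = {"status": "SKIPPED"}

    if prioritized is not None and data:
        try:
            ex_out = run_expression_stage(
                data["expr"], data["membership"], prioritized, config
            )
            ex.enrichment_frame(ex_out["module_enrichment"]).to_csv(
                out_dir / "module_enrichment.tsv", sep="\t", index=False
            )
            bias = ex_out["prenatal_bias"]
            statuses["expression"] = {
                "status": "OK",
                "prenatal_bias_p": bias.p_value,
                "direction": bias.direction,
            }
        except Exception as exc:
            fail("expression", exc)
    else:
        statuses["expression"] = {"status": "SKIPPED"}

    summary["seeds"] = {
        stage: config.stage_seed(stage)
        for stage in ("rates", "truth", "ppi", "expression", "network")
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
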