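"""Domain types and tabular I/O for de novo variant (DNV) analysis.

This module defines the core record types used throughout the package —
annotated DNV calls, per-gene mutation-rate records, gene sets, constraint
annotations and per-cohort count summaries — together with readers and
writers for the plain-text formats they travel in (tab-separated tables and
one-symbol-per-line / GMT gene lists).

Variant classification follows the convention used in trio sequencing
studies of neurodevelopmental disorders: protein-truncating variants (PTVs:
frameshift, stop-gain/loss and canonical splice-site disruptions) and
deleterious missense variants (Dmis: missense calls whose deleteriousness
score exceeds a threshold) together form the "damaging DNV" class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# Cohort label constants. Records may carry any string label; these are the
# ones the pipeline and the synthetic generator use.
UDD = "UDD"
ASD = "ASD"
CONTROL = "CONTROL"

#: Controlled vocabulary for the ``consequence`` field of a variant record.
CONSEQUENCES = frozenset(
    {
        "frameshift",
        "stop-gain",
        "stop-loss",
        "splice-site",
        "missense",
        "synonymous",
        "other",
    }
)

#: Consequences that define a protein-truncating variant.
PTV_CONSEQUENCES = frozenset({"frameshift", "stop-gain", "stop-loss", "splice-site"})

#: Default deleteriousness-score threshold above which a missense call is Dmis.
DEFAULT_DMIS_THRESHOLD = 0.7


class VariantClass(Enum):
    """Analysis classes a DNV is assigned to.

    ``DMIS`` is semantically a subset of missense: a record classified DMIS
    also counts toward MISSENSE totals in :func:`aggregate_counts`.
    ``EXCLUDED`` is the sentinel for consequences outside the four analyzed
    classes (e.g. non-canonical splice region); aggregation drops it.
    """

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    DMIS = "dmis"
    PTV = "ptv"
    EXCLUDED = "excluded"


#: The "damaging DNV" (dDNV) class union: PTVs plus deleterious missense.
DAMAGING_CLASSES = frozenset({VariantClass.DMIS, VariantClass.PTV})


@dataclass(frozen=True)
class VariantRecord:
    """One annotated de novo variant call in one individual.

    ``dmis_score`` is a deleteriousness score in [0, 1]; it is only
    meaningful for missense calls and must be ``None`` otherwise.
    Coordinates are 1-based inclusive (VCF convention); the gene symbol is
    the join key for all downstream analysis.
    """

    sample_id: str
    cohort: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    dmis_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"consequence {self.consequence!r} not in controlled vocabulary "
                f"{sorted(CONSEQUENCES)}"
            )
        if self.dmis_score is not None:
            if self.consequence != "missense":
                raise ValueError(
                    "dmis_score is only meaningful for missense variants "
                    f"(got consequence={self.consequence!r})"
                )
            if not 0.0 <= self.dmis_score <= 1.0:
                raise ValueError(f"dmis_score must be in [0, 1], got {self.dmis_score}")


@dataclass(frozen=True)
class GeneRateRecord:
    """Per-gene haploid per-generation mutation probabilities by class.

    ``mu_mis`` is the total missense rate; ``mu_dmis`` is the deleterious
    subset of it, hence ``mu_dmis <= mu_mis``.
    """

    gene: str
    mu_syn: float
    mu_mis: float
    mu_dmis: float
    mu_ptv: float

    def __post_init__(self) -> None:
        for name in ("mu_syn", "mu_mis", "mu_dmis", "mu_ptv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for gene {self.gene}")
        if self.mu_dmis > self.mu_mis:
            raise ValueError(
                f"mu_dmis ({self.mu_dmis}) exceeds mu_mis ({self.mu_mis}) "
                f"for gene {self.gene}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """Constraint annotation: LOEUF (PTV intolerance) and mis_Z (missense)."""

    gene: str
    loeuf: float | None = None
    mis_z: float | None = None

    def __post_init__(self) -> None:
        if self.loeuf is not None and self.loeuf < 0:
            raise ValueError(f"loeuf must be >= 0, got {self.loeuf}")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            logger.warning("gene set %r is empty", self.name)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(self.sorted_members)

    @property
    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass
class CohortCounts:
    """Per-(gene, class) DNV counts for one cohort of ``n_samples`` probands."""

    cohort: str
    n_samples: int
    counts: dict[tuple[str, VariantClass], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")

    def gene_class_count(self, gene: str, variant_class: VariantClass) -> int:
        return self.counts.get((gene, variant_class), 0)

    def class_total(self, variant_class: VariantClass) -> int:
        return sum(
            n for (_, vc), n in self.counts.items() if vc is variant_class
        )

    def per_sample_rate(self, variant_class: VariantClass) -> float:
        return self.class_total(variant_class) / self.n_samples

    def genes(self) -> set[str]:
        return {g for (g, _) in self.counts}


# ---------------------------------------------------------------------------
# Variant classification and count aggregation
# ---------------------------------------------------------------------------


def classify_variant(
    record: VariantRecord,
    dmis_threshold: float = DEFAULT_DMIS_THRESHOLD,
    strict: bool = False,
) -> VariantClass:
    """Assign a variant to exactly one analysis class.

    Frameshift / stop-gain / stop-loss / splice-site map to PTV; missense
    with ``dmis_score >= dmis_threshold`` to DMIS, other missense to
    MISSENSE; synonymous to SYNONYMOUS; anything else to the EXCLUDED
    sentinel that aggregation drops.

    A missense record with no score is an error in ``strict`` mode and a
    plain MISSENSE (with a warning) otherwise.
    """
    c = record.consequence
    if c in PTV_CONSEQUENCES:
        return VariantClass.PTV
    if c == "missense":
        if record.dmis_score is None:
            if strict:
                raise ValueError(
                    f"missense variant {record.gene}:{record.pos} has no "
                    "deleteriousness score (strict mode)"
                )
            logger.warning(
                "missense variant %s:%s has no deleteriousness score; "
                "classified as MISSENSE",
                record.gene,
                record.pos,
            )
            return VariantClass.MISSENSE
        return (
            VariantClass.DMIS
            if record.dmis_score >= dmis_threshold
            else VariantClass.MISSENSE
        )
    if c == "synonymous":
        return VariantClass.SYNONYMOUS
    return VariantClass.EXCLUDED


def aggregate_counts(
    records: Iterable[VariantRecord],
    gene_set: GeneSet,
    cohort: str,
    n_samples: int,
    dmis_threshold: float = DEFAULT_DMIS_THRESHOLD,
) -> CohortCounts:
    """Tally per-(gene, class) DNV counts for records whose gene is in the set.

    A DMIS record increments both the DMIS and the MISSENSE counters, so
    missense totals are inclusive of the deleterious subset (the convention
    used when missense and Dmis burdens are reported side by side).
    Records outside ``gene_set`` or with EXCLUDED class are skipped.
    """
    out = CohortCounts(cohort=cohort, n_samples=n_samples)
    for rec in records:
        if rec.gene not in gene_set:
            logger.debug("record in %s outside gene set %s; skipped", rec.gene, gene_set.name)
            continue
        vc = classify_variant(rec, dmis_threshold=dmis_threshold)
        if vc is VariantClass.EXCLUDED:
            continue
        key = (rec.gene, vc)
        out.counts[key] = out.counts.get(key, 0) + 1
        if vc is VariantClass.DMIS:
            mkey = (rec.gene, VariantClass.MISSENSE)
            out.counts[mkey] = out.counts.get(mkey, 0) + 1
    return out


def curate_gene_list(
    list_a: GeneSet,
    list_b: GeneSet,
    exclude: GeneSet,
    name: str | None = None,
) -> GeneSet:
    """Union of two gene lists minus an exclusion list.

    This is the curation step that merges two mitochondrial-gene inventories
    and removes the mtDNA-encoded genes, leaving the nuclear-encoded set.
    """
    members = (list_a.members | list_b.members) - exclude.members
    result = GeneSet(name or f"({list_a.name}|{list_b.name})-{exclude.name}", members)
    if not members:
        logger.warning("curated gene list %r is empty", result.name)
    return result


@dataclass(frozen=True)
class ConstraintReport:
    """Accounting for a constraint-filter pass."""

    n_input: int
    n_kept: int
    n_missing_loeuf: int


def filter_by_constraint(
    gene_set: GeneSet,
    annotations: pd.DataFrame,
    loeuf_max: float = 0.35,
) -> tuple[GeneSet, ConstraintReport]:
    """Keep genes with LOEUF strictly below ``loeuf_max`` (PTV-intolerant).

    ``annotations`` is a frame indexed by gene with a ``loeuf`` column (as
    returned by :func:`read_annotation_table`). Genes absent from the table
    or with missing LOEUF are excluded and counted in the report.
    """
    if loeuf_max <= 0:
        raise ValueError("loeuf_max must be > 0")
    kept: set[str] = set()
    n_missing = 0
    for gene in gene_set.members:
        if gene not in annotations.index or pd.isna(annotations.loc[gene, "loeuf"]):
            n_missing += 1
            continue
        if float(annotations.loc[gene, "loeuf"]) < loeuf_max:
            kept.add(gene)
    report = ConstraintReport(len(gene_set), len(kept), n_missing)
    logger.info(
        "constraint filter LOEUF<%s: kept %d/%d (%d missing LOEUF)",
        loeuf_max,
        report.n_kept,
        report.n_input,
        report.n_missing_loeuf,
    )
    return GeneSet(f"{gene_set.name}_loeuf<{loeuf_max}", frozenset(kept)), report


# ---------------------------------------------------------------------------
# File readers / writers
# ---------------------------------------------------------------------------

#: Default column-name mapping for DNV tables.
DEFAULT_DIALECT: Mapping[str, str] = {
    "sample_id": "SampleID",
    "cohort": "Cohort",
    "gene": "Gene",
    "chrom": "Chrom",
    "pos": "Pos",
    "ref": "Ref",
    "alt": "Alt",
    "consequence": "Consequence",
    "dmis_score": "DmisScore",
}

_MANDATORY_FIELDS = (
    "sample_id",
    "cohort",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
)


def parse_dnv_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[VariantRecord]:
    """Read a tab-separated DNV table into :class:`VariantRecord` objects.

    ``dialect`` maps field names to header names (defaults to
    :data:`DEFAULT_DIALECT`; the score column is optional). In strict mode a
    malformed row raises with its 1-based data line number; in lenient mode
    it is logged and skipped. Row-count conservation is logged either way.
    """
    path = Path(path)
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld in _MANDATORY_FIELDS:
        col = dialect[fld]
        if col not in df.columns:
            raise ValueError(f"DNV table {path} is missing mandatory column {col!r}")
    score_col = dialect.get("dmis_score")
    has_score = score_col in df.columns

    records: list[VariantRecord] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            raw_pos = row[dialect["pos"]]
            try:
                pos = int(raw_pos)
            except ValueError:
                raise ValueError(f"unparseable Pos {raw_pos!r}") from None
            score: float | None = None
            if has_score:
                raw = row[score_col].strip()
                if raw not in ("", "NA", "nan", "."):
                    score = float(raw)
            records.append(
                VariantRecord(
                    sample_id=row[dialect["sample_id"]],
                    cohort=row[dialect["cohort"]],
                    gene=row[dialect["gene"]],
                    chrom=row[dialect["chrom"]],
                    pos=pos,
                    ref=row[dialect["ref"]],
                    alt=row[dialect["alt"]],
                    consequence=row[dialect["consequence"]],
                    dmis_score=score,
                )
            )
        except ValueError as exc:
            if strict:
                raise ValueError(f"{path} line {i}: {exc}") from exc
            n_skipped += 1
            logger.warning("%s line %d skipped: %s", path, i, exc)
    if len(df) == 0:
        logger.warning("DNV table %s contains a header but no rows", path)
    logger.info(
        "parsed %s: %d rows -> %d records (%d skipped)",
        path,
        len(df),
        len(records),
        n_skipped,
    )
    return records


def write_dnv_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a tab-separated table readable by :func:`parse_dnv_table`."""
    rows = []
    for r in records:
        rows.append(
            {
                "SampleID": r.sample_id,
                "Cohort": r.cohort,
                "Gene": r.gene,
                "Chrom": r.chrom,
                "Pos": r.pos,
                "Ref": r.ref,
                "Alt": r.alt,
                "Consequence": r.consequence,
                "DmisScore": "NA" if r.dmis_score is None else repr(r.dmis_score),
            }
        )
    pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values())).to_csv(
        path, sep="\t", index=False
    )


RATE_COLUMNS = {"MuSyn": "mu_syn", "MuMis": "mu_mis", "MuDmis": "mu_dmis", "MuPTV": "mu_ptv"}


def read_rate_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene mutation-rate table (Gene, MuSyn, MuMis, MuDmis, MuPTV).

    Returns a frame indexed by gene with columns mu_syn/mu_mis/mu_dmis/mu_ptv.
    Negative rates are a hard error; mu_dmis must not exceed mu_mis.
    """
    df = pd.read_csv(path, sep="\t")
    if "Gene" not in df.columns:
        raise ValueError(f"rate table {path} is missing mandatory column 'Gene'")
    missing = [c for c in RATE_COLUMNS if c not in df.columns and c != "MuDmis"]
    if missing:
        raise ValueError(f"rate table {path} is missing columns {missing}")
    df = df.rename(columns=RATE_COLUMNS).set_index("Gene")
    if "mu_dmis" not in df.columns:
        df["mu_dmis"] = math.nan
    for col in ("mu_syn", "mu_mis", "mu_dmis", "mu_ptv"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"negative mutation rate in column {col} of {path}")
    bad = df.dropna(subset=["mu_dmis"]).query("mu_dmis > mu_mis")
    if len(bad):
        raise ValueError(f"mu_dmis > mu_mis for genes {list(bad.index)[:5]} in {path}")
    return df[["mu_syn", "mu_mis", "mu_dmis", "mu_ptv"]]


def write_rate_table(rates: pd.DataFrame, path: str | Path) -> None:
    out = rates.rename(columns={v: k for k, v in RATE_COLUMNS.items()})
    out.index.name = "Gene"
    out.to_csv(path, sep="\t", float_format="%.8g")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read constraint annotations (Gene, LOEUF, MisZ) into a gene-indexed frame."""
    df = pd.read_csv(path, sep="\t")
    for col in ("Gene", "LOEUF", "MisZ"):
        if col not in df.columns:
            raise ValueError(f"annotation table {path} is missing column {col!r}")
    df = df.rename(columns={"LOEUF": "loeuf", "MisZ": "mis_z"}).set_index("Gene")
    return df[["loeuf", "mis_z"]]


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list."""
    path = Path(path)
    members = {
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return GeneSet(name or path.stem, frozenset(members))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_set.sorted_members) + "\n")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file (name <tab> description <tab> genes...) into gene sets."""
    out: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        out[parts[0]] = GeneSet(parts[0], frozenset(p for p in parts[2:] if p))
    return out
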