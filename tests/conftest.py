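import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mitodnv.io import GeneSet, VariantRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_dnv_tsv(tmp_path):
    """Three-row DNV table: one frameshift, one missense (0.9), one synonymous."""
    path = tmp_path / "dnv.tsv"
    path.write_text(
        "SampleID\tCohort\tGene\tChrom\tPos\tRef\tAlt\tConsequence\tDmisScore\n"
        "S1\tUDD\tGENE1\t1\t100\tA\tAT\tframeshift\tNA\n"
        "S2\tUDD\tGENE2\t2\t200\tC\tT\tmissense\t0.9\n"
        "S3\tCONTROL\tGENE1\t1\t300\tG\tA\tsynonymous\tNA\n"
    )
    return path


@pytest.fixture
def rate_table():
    rng = np.random.default_rng(42)
    genes = [f"GENE{i}" for i in range(1, 51)]
    mu_mis = np.exp(rng.normal(-11, 1, 50))
    return pd.DataFrame(
        {
            "mu_syn": 0.4 * mu_mis,
            "mu_mis": mu_mis,
            "mu_dmis": 0.25 * mu_mis,
            "mu_ptv": 0.1 * mu_mis,
        },
        index=pd.Index(genes, name="Gene"),
    )


@pytest.fixture
def gene_universe(rate_table):
    return GeneSet("universe", frozenset(rate_table.index))


def make_record(**kwargs) -> VariantRecord:
    defaults = dict(
        sample_id="S1",
        cohort="UDD",
        gene="GENE1",
        chrom="1",
        pos=100,
        ref="A",
        alt="G",
        consequence="missense",
        dmis_score=0.9,
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)
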