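import numpy as np
import pytest

from askit import simulate, workflows
from askit.haplotypes import Exon, GeneModel, Variant, VariantTable


@pytest.fixture(scope="session")
def sim_locus():
    """A seeded synthetic two-strain locus with its full design result."""
    cfg = simulate.SimConfig(seed=7)
    gene, table, truth = simulate.make_strain_pair(cfg)
    design = workflows.design_guides(gene, table)
    return cfg, gene, table, truth, design


@pytest.fixture
def toy_gene():
    """A 60-nt locus with one coding exon at (10, 40)."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    return GeneModel("locus", seq, [Exon(10, 40, True)])


def random_variant_table(gene, rng, n_variants=10, p_indel=0.3,
                         max_indel=6):
    """Random non-overlapping variants against a gene, for property tests."""
    seq = gene.sequence
    recs, cursor = [], 1
    positions = sorted(rng.choice(
        np.arange(1, len(seq) - max_indel - 2),
        size=min(n_variants * 3, len(seq) // (max_indel + 2)), replace=False))
    for p in positions:
        if len(recs) >= n_variants or p < cursor:
            continue
        p = int(p)
        ref_b = seq[p]
        if rng.random() < p_indel:
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:
                recs.append(Variant(p, seq[p:p + 1 + size], ref_b))
                cursor = p + 1 + size
            else:
                ins = "".join(rng.choice(list("ACGT"), size=size))
                recs.append(Variant(p, ref_b, ref_b + ins))
                cursor = p + 1
        else:
            alt = str(rng.choice([b for b in "ACGT" if b != ref_b]))
            recs.append(Variant(p, ref_b, alt))
            cursor = p + 1
    return VariantTable(recs, source="random")
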