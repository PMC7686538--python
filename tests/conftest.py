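import numpy as np
import pytest

import mitonuclear as mn


@pytest.fixture(scope="session")
def small_dataset():
    """Three populations, 2 mt + 2 nuc genes, mild divergence."""
    cfg = mn.SimulationConfig(
        pop_sizes=(40, 40, 37),
        genes=[
            mn.GeneSpec("MTA", "mitochondrial", 5, 0.05),
            mn.GeneSpec("MTB", "mitochondrial", 4, 0.0),
            mn.GeneSpec("NUCA", "nuclear", 8, 0.05),
            mn.GeneSpec("NUCB", "nuclear", 6, 0.0),
        ],
        seed=11,
    )
    blocks, panel = mn.simulate_dataset(cfg)
    blocks = {k: mn.filter_invariant(b) for k, b in blocks.items()}
    return blocks, panel


@pytest.fixture()
def toy_vcf(tmp_path):
    """Hand-written VCF: 1 mt + 3 nuclear biallelic sites, 4 subjects.

    Includes a multiallelic record, an indel and a missing-call record that
    the reader must skip.
    """
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=MT>",
            "##contig=<ID=1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4",
            "MT\t100\tmt1\tA\tG\t.\tPASS\t.\tGT\t0\t1\t1\t0",
            "1\t500\trs1\tA\tC\t.\tPASS\t.\tGT\t0|0\t0|1\t1|0\t1|1",
            "1\t600\trs2\tG\tT\t.\tPASS\t.\tGT\t0|1\t0|0\t0|0\t0|0",
            "1\t650\trs_multi\tG\tT,C\t.\tPASS\t.\tGT\t0|1\t0|2\t0|0\t0|0",
            "1\t660\trs_indel\tGA\tG\t.\tPASS\t.\tGT\t0|1\t0|0\t0|0\t0|0",
            "1\t670\trs_miss\tG\tA\t.\tPASS\t.\tGT\t.|.\t0|1\t0|0\t0|0",
            "1\t700\trs3\tC\tA\t.\tPASS\t.\tGT\t1|1\t1|1\t0|1\t0|0",
            "",
        ]
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    panel = mn.PopulationPanel(
        {"S1": "GBR", "S2": "GBR", "S3": "FIN", "S4": "FIN"}
    )
    return path, panel


def make_block(states, mitochondrial=False, name="G", subject_ids=None):
    """GenotypeBlock from a raw state matrix (test helper)."""
    states = np.asarray(states, dtype=np.int8)
    n, m = states.shape
    chrom = "MT" if mitochondrial else "1"
    region = mn.GeneRegion(name, chrom, 100, 100 + 10 * m)
    sites = [
        mn.VariantSite(chrom, 100 + 10 * j, f"{name}_s{j}", "A", "G")
        for j in range(m)
    ]
    ids = subject_ids or [f"S{i}" for i in range(n)]
    return mn.GenotypeBlock(region, sites, states, ids)
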