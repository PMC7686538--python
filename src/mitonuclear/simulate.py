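"""Synthetic three-population genotype datasets with known structure.

Per-population allele frequencies follow the Balding–Nichols model: around an
ancestral frequency ``p`` each population draws its own frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, where the differentiation parameter ``F``
equals the expected Fst. Mitochondrial sites are haploid Bernoulli draws;
nuclear sites are two independent Bernoulli alleles collapsed to a genotype
state (Hardy–Weinberg within population).

Mitonuclear interactions are planted by *reassigning* nuclear genotype values
among the subjects of one population, aligned to their mitochondrial allele at
a chosen site. Because only existing values are permuted, per-population
marginal state counts are preserved exactly — the joint distribution of
(mt allele, nuclear genotype) is the only thing that changes. The coupling
strength ``delta`` interpolates between independence (0) and the comonotone
Fréchet upper bound (1), so every ``delta`` in [0, 1] is feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genotype_io import (
    GeneRegion,
    GenotypeBlock,
    PopulationPanel,
    VariantSite,
)

DEFAULT_POP_NAMES = ("GBR", "FIN", "TSI")
DEFAULT_POP_SIZES = (100, 100, 97)  # n = 297


@dataclass
class GeneSpec:
    """One simulated gene: genome class, size and differentiation."""

    name: str
    genome_class: str  # "mitochondrial" | "nuclear"
    n_sites: int
    fst: float = 0.0  # Balding–Nichols F
    freq_range: tuple[float, float] = (0.05, 0.95)  # ancestral law U(a, b)
    ld_copies: int = 0  # extra near-duplicate columns (LD test aid)
    ld_flip_prob: float = 0.02

    def __post_init__(self):
        if self.genome_class not in ("mitochondrial", "nuclear"):
            raise ValueError(f"bad genome_class {self.genome_class!r}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("F must lie in [0, 1)")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class InteractionSpec:
    """A planted joint-only mitonuclear association.

    ``nuc_sites`` (defaults to all sites of ``nuc_gene``) are each coupled to
    the mitochondrial allele at ``mt_site`` of ``mt_gene`` within
    ``population``, with strength ``delta``.
    """

    mt_gene: str
    nuc_gene: str
    population: str
    mt_site: int = 0
    nuc_sites: list[int] | None = None
    delta: float = 1.0
    style: str = "hom_swap"  # or "dosage"
    anti: bool = False  # reverse the designated cell-pairing

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(
                f"delta={self.delta} infeasible; the feasible range is "
                f"[0, 1] (1 = the Fréchet bound given the marginals)"
            )
        if self.style not in ("hom_swap", "dosage"):
            raise ValueError(f"unknown interaction style {self.style!r}")


@dataclass
class SimulationConfig:
    pop_names: tuple[str, ...] = DEFAULT_POP_NAMES
    pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES
    genes: list[GeneSpec] = field(default_factory=list)
    interactions: list[InteractionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if len(self.pop_names) != len(self.pop_sizes):
            raise ValueError("pop_names and pop_sizes lengths differ")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")
        for spec in self.interactions:
            if spec.population not in self.pop_names:
                raise ValueError(f"unknown population {spec.population}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genes = [GeneSpec(**g) for g in raw.pop("genes", [])]
        for g in genes:
            if isinstance(g.freq_range, list):
                g.freq_range = tuple(g.freq_range)
        inter = [InteractionSpec(**i) for i in raw.pop("interactions", [])]
        if "pop_names" in raw:
            raw["pop_names"] = tuple(raw["pop_names"])
        if "pop_sizes" in raw:
            raw["pop_sizes"] = tuple(raw["pop_sizes"])
        return cls(genes=genes, interactions=inter, **raw)


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Draw per-population alternate-allele frequencies for every gene.

    Returns gene name -> (n_pops, n_sites) array. Under F=0 all populations
    share the ancestral frequency exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_pops = len(config.pop_names)
    out = {}
    for gene in config.genes:
        lo, hi = gene.freq_range
        p = rng.uniform(lo, hi, size=gene.n_sites)
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise ValueError("ancestral frequency at 0 or 1: site would be invariant")
        if gene.fst == 0.0:
            freqs = np.tile(p, (n_pops, 1))
        else:
            f = gene.fst
            a = p * (1.0 - f) / f
            b = (1.0 - p) * (1.0 - f) / f
            freqs = rng.beta(a, b, size=(n_pops, gene.n_sites))
        out[gene.name] = freqs
    return out


def _auto_regions(config: SimulationConfig) -> dict[str, GeneRegion]:
    """Lay simulated genes out on MT / autosomes with 10 bp site spacing."""
    regions = {}
    mt_cursor, nuc_chrom = 100, 0
    for gene in config.genes:
        span = 10 * (gene.n_sites + gene.ld_copies)
        if gene.genome_class == "mitochondrial":
            regions[gene.name] = GeneRegion(gene.name, "MT", mt_cursor, mt_cursor + span)
            mt_cursor += span + 100
        else:
            nuc_chrom += 1
            regions[gene.name] = GeneRegion(gene.name, str(nuc_chrom), 1000, 1000 + span)
    return regions


def simulate_genotypes(
    freqs: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, GenotypeBlock], PopulationPanel]:
    """Draw genotype blocks from per-population frequencies.

    Deterministic under a fixed config seed (when ``rng`` is not supplied the
    generator is seeded from ``config.seed + 1`` so frequency and genotype
    draws are decoupled).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pop_of_subject: dict[str, str] = {}
    subject_ids: list[str] = []
    pop_rows: dict[str, np.ndarray] = {}
    row = 0
    for pop, size in zip(config.pop_names, config.pop_sizes):
        ids = [f"{pop}{i:04d}" for i in range(size)]
        subject_ids.extend(ids)
        pop_of_subject.update({s: pop for s in ids})
        pop_rows[pop] = np.arange(row, row + size)
        row += size
    panel = PopulationPanel(pop_of_subject)
    regions = _auto_regions(config)

    blocks = {}
    for gene in config.genes:
        region = regions[gene.name]
        n_total = len(subject_ids)
        gene_freqs = freqs[gene.name]
        cols = np.empty((n_total, gene.n_sites), dtype=np.int8)
        for pop, rows in pop_rows.items():
            k = list(config.pop_names).index(pop)
            q = gene_freqs[k]
            if gene.genome_class == "mitochondrial":
                cols[rows] = rng.random((len(rows), gene.n_sites)) < q
            else:
                draws = (rng.random((len(rows), gene.n_sites, 2)) < q[None, :, None])
                cols[rows] = draws.sum(axis=2)
        if gene.ld_copies:
            src = rng.integers(0, gene.n_sites, size=gene.ld_copies)
            extra = cols[:, src].copy()
            max_state = 1 if gene.genome_class == "mitochondrial" else 2
            flips = rng.random(extra.shape) < gene.ld_flip_prob
            extra[flips] = rng.integers(0, max_state + 1, size=int(flips.sum()))
            cols = np.column_stack([cols, extra])
        n_cols = cols.shape[1]
        sites = [
            VariantSite(
                region.chrom,
                region.start + 10 * j,
                f"{gene.name}_s{j}",
                "A",
                "G",
            )
            for j in range(n_cols)
        ]
        blocks[gene.name] = GenotypeBlock(region, sites, cols, list(subject_ids))
    return blocks, panel


def plant_interaction(
    blocks: dict[str, GenotypeBlock],
    spec: InteractionSpec,
    panel: PopulationPanel,
    rng: np.random.Generator | None = None,
) -> dict[str, GenotypeBlock]:
    """Couple nuclear genotypes to a mitochondrial allele in one population.

    Two styles, both exact count-preserving rearrangements of the existing
    nuclear genotype values within the affected population (other populations
    are untouched):

    ``hom_swap`` (default)
        Homozygote exchange between mt-allele classes: hom-ref genotypes of
        mt-allele-1 carriers are swapped against hom-alt genotypes of
        mt-allele-0 carriers (reversed when ``anti``). Heterozygotes are left
        alone, so at allele frequency 1/2 the two homozygote states have
        identical frequency and the coupling is invisible to any per-site
        rarity statistic while the joint (mt allele, genotype-class)
        distribution is tilted — a pure mitonuclear-matching signal. ``delta``
        is the swapped fraction of the feasible (Fréchet) maximum,
        min(#hom-ref among mt-1, #hom-alt among mt-0).

    ``dosage``
        Rank coupling: a fraction ``delta`` of subjects receives the
        comonotone assignment (descending genotype dosage to descending mt
        allele; ascending when ``anti``), the rest are reshuffled at random.

    Returns the blocks dict with the nuclear block replaced.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    mt_block = blocks[spec.mt_gene]
    nuc_block = blocks[spec.nuc_gene]
    if not mt_block.region.is_mitochondrial or nuc_block.region.is_mitochondrial:
        raise ValueError("interaction must couple a mitochondrial and a nuclear gene")
    if not 0 <= spec.mt_site < mt_block.n_sites:
        raise ValueError(f"mt_site {spec.mt_site} out of range")
    nuc_sites = (
        list(range(nuc_block.n_sites)) if spec.nuc_sites is None else spec.nuc_sites
    )
    rows = np.array(
        [i for i, s in enumerate(nuc_block.subject_ids) if panel[s] == spec.population]
    )
    mt_alleles = mt_block.states[rows, spec.mt_site]

    new_states = nuc_block.states.copy()
    n = len(rows)
    n_coupled = int(round(spec.delta * n))
    for j in nuc_sites:
        if not 0 <= j < nuc_block.n_sites:
            raise ValueError(f"nuc site {j} out of range")
        values = new_states[rows, j]
        if spec.style == "hom_swap":
            give, take = (2, 0) if spec.anti else (0, 2)
            donors = np.flatnonzero((mt_alleles == 1) & (values == give))
            acceptors = np.flatnonzero((mt_alleles == 0) & (values == take))
            feasible = min(len(donors), len(acceptors))
            n_swap = int(round(spec.delta * feasible))
            if n_swap:
                d = rng.choice(donors, size=n_swap, replace=False)
                a = rng.choice(acceptors, size=n_swap, replace=False)
                values = values.copy()
                values[d], values[a] = take, give
            assigned = values
        else:
            # extremal target: descending (comonotone) or ascending (antitone)
            # genotype dosage to descending mt allele, random tie-break within
            # allele classes
            order = np.lexsort((rng.random(n), -mt_alleles))
            assigned = np.empty(n, dtype=values.dtype)
            ranked = np.sort(values) if spec.anti else np.sort(values)[::-1]
            assigned[order] = ranked
            if n_coupled < n:
                free = rng.choice(n, size=n - n_coupled, replace=False)
                assigned[free] = rng.permutation(assigned[free])
        new_states[rows, j] = assigned

    out = dict(blocks)
    out[spec.nuc_gene] = GenotypeBlock(
        nuc_block.region, nuc_block.sites, new_states, nuc_block.subject_ids
    )
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, GenotypeBlock], PopulationPanel]:
    """Frequencies -> genotypes -> planted interactions, all from one seed."""
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(3)]
    freqs = simulate_frequencies(config, rngs[0])
    blocks, panel = simulate_genotypes(freqs, config, rngs[1])
    for spec in config.interactions:
        blocks = plant_interaction(blocks, spec, panel, rngs[2])
    return blocks, panel


def write_fixture(
    blocks: dict[str, GenotypeBlock],
    panel: PopulationPanel,
    out_dir,
) -> dict[str, Path]:
    """Write blocks as an uncompressed VCF v4.2 + panel + region table.

    Mitochondrial records carry haploid GT fields ("0"/"1"), nuclear records
    phased diploid fields; heterozygotes are written as "0|1". Round-trips
    exactly through :mod:`mitonuclear.genotype_io`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    first = next(iter(blocks.values()))
    subjects = first.subject_ids
    for b in blocks.values():
        if b.subject_ids != subjects:
            raise ValueError("all blocks must share one subject ordering")

    records = []
    for name, b in blocks.items():
        gt_of = (
            {0: "0", 1: "1"}
            if b.region.is_mitochondrial
            else {0: "0|0", 1: "0|1", 2: "1|1"}
        )
        for j, site in enumerate(b.sites):
            gts = "\t".join(gt_of[int(s)] for s in b.states[:, j])
            records.append(
                (
                    site.chrom,
                    site.pos,
                    f"{site.chrom}\t{site.pos}\t{site.site_id}\t"
                    f"{site.ref_allele}\t{site.alt_allele}\t.\tPASS\t.\tGT\t{gts}",
                )
            )
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(r[0] for r in records))}
    records.sort(key=lambda r: (chrom_order[r[0]], r[1]))

    vcf_path = out_dir / "genotypes.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mitonuclear-simulate\n")
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(subjects)
            + "\n"
        )
        for _, _, line in records:
            fh.write(line + "\n")

    panel_path = out_dir / "panel.tsv"
    panel.to_frame().to_csv(panel_path, sep="\t", index=False, header=False)

    regions_path = out_dir / "regions.tsv"
    with open(regions_path, "w") as fh:
        fh.write("name\tchrom\tstart\tend\n")
        for name, b in blocks.items():
            r = b.region
            fh.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\n")

    return {"vcf": vcf_path, "panel": panel_path, "regions": regions_path}
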