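"""Reading genotype data into per-gene state matrices.

Genotypes are represented per gene as a subjects x sites integer matrix of
*states*: mitochondrial sites are haploid alleles coded {0, 1}; nuclear sites
are unordered diploid genotypes coded {0: hom-ref, 1: het, 2: hom-alt}
(phase is discarded — ``0|1`` and ``1|0`` are the same state). Only biallelic
SNVs with complete calls are retained, and sites that do not vary across the
pooled subjects are filtered out before any downstream analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MT_CHROMS = {"MT", "chrM", "chrMT", "M", "NC_012920.1"}

#: state alphabets by genome class
MT_STATES = (0, 1)
NUC_STATES = (0, 1, 2)

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic SNV."""

    chrom: str
    pos: int  # 1-based
    site_id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GeneRegion:
    """A named 1-based inclusive genomic interval."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"region {self.name}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"region {self.name}: start must be >= 1")

    @property
    def genome_class(self) -> str:
        return "mitochondrial" if self.chrom in MT_CHROMS else "nuclear"

    @property
    def is_mitochondrial(self) -> bool:
        return self.genome_class == "mitochondrial"

    def __len__(self) -> int:
        return self.end - self.start + 1


class PopulationPanel:
    """Mapping from subject id to population code (e.g. GBR/FIN/TSI)."""

    def __init__(self, mapping: dict[str, str]):
        if len(set(mapping.values())) < 2:
            raise ValueError("panel must contain at least 2 populations")
        self._map = dict(mapping)

    def __len__(self):
        return len(self._map)

    def __contains__(self, subject: str) -> bool:
        return subject in self._map

    def __getitem__(self, subject: str) -> str:
        return self._map[subject]

    @property
    def populations(self) -> list[str]:
        """Distinct population codes, in first-appearance order."""
        return list(dict.fromkeys(self._map.values()))

    def subjects(self, population: str | None = None) -> list[str]:
        if population is None:
            return list(self._map)
        return [s for s, p in self._map.items() if p == population]

    def labels(self, subject_ids) -> np.ndarray:
        return np.array([self._map[s] for s in subject_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": list(self._map), "pop": list(self._map.values())}
        )


@dataclass
class GenotypeBlock:
    """Subjects x sites state matrix for one gene region.

    ``states`` holds integers from the genome-class alphabet: {0,1} for
    mitochondrial blocks, {0,1,2} for nuclear blocks.
    """

    region: GeneRegion
    sites: list[VariantSite]
    states: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D subjects x sites matrix")
        if self.states.shape != (len(self.subject_ids), len(self.sites)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.sites)} sites"
            )
        hi = 1 if self.region.is_mitochondrial else 2
        if self.n_sites and (
            self.states.min() < 0 or self.states.max() > hi
        ):
            raise ValueError(
                f"states outside alphabet [0, {hi}] for "
                f"{self.region.genome_class} block {self.region.name}"
            )
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate site ids in block {self.region.name}")

    @property
    def n_subjects(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    @property
    def n_states(self) -> int:
        return 2 if self.region.is_mitochondrial else 3

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage (0/1 haploid, 0/1/2 diploid)."""
        return self.states.astype(np.int16)

    def subset_sites(self, index) -> "GenotypeBlock":
        index = np.asarray(index)
        return replace(
            self,
            sites=[self.sites[i] for i in index],
            states=self.states[:, index],
        )

    def subset_subjects(self, subject_ids: list[str]) -> "GenotypeBlock":
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [lookup[s] for s in subject_ids]
        return replace(
            self, states=self.states[rows, :], subject_ids=list(subject_ids)
        )


def read_gene_regions(path) -> list[GeneRegion]:
    """Read a 4-column (name, chrom, start, end) tab-delimited region table."""
    regions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.replace(",", "\t").split("\t") if f.strip()]
            if lineno == 1 and fields[:1] == ["name"]:
                continue  # header
            if len(fields) != 4:
                raise ValueError(
                    f"{path} line {lineno}: expected 4 fields "
                    f"(name, chrom, start, end), got {len(fields)}"
                )
            name, chrom, start, end = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {lineno}: non-integer coordinate"
                ) from exc
            regions.append(GeneRegion(name, chrom, start_i, end_i))
    return regions


def read_panel(path) -> PopulationPanel:
    """Read a two-column (subject, population) panel file.

    Compatible with the 1000 Genomes panel layout (extra columns ignored,
    header line beginning with ``sample`` skipped).
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            fields = raw.split()
            if not fields:
                continue
            if fields[0] == "sample":
                continue
            mapping[fields[0]] = fields[1]
    return PopulationPanel(mapping)


def _decode_diploid(gt: tuple[int, ...], mitochondrial: bool) -> int | None:
    """Map a cyvcf2 genotype tuple (allele indices, phase flag last) to a state."""
    alleles = [a for a in gt[:-1] if a is not None]
    if any(a < 0 for a in alleles):
        return None  # missing call
    if mitochondrial:
        uniq = set(alleles)
        if len(uniq) != 1:
            raise ValueError(
                "heterozygous mitochondrial call encountered; "
                "heteroplasmy is not supported"
            )
        return uniq.pop()
    if len(alleles) != 2:
        return None
    return int(alleles[0] > 0) + int(alleles[1] > 0)


def read_vcf_block(
    vcf_path, region: GeneRegion, panel: PopulationPanel
) -> GenotypeBlock:
    """Read the biallelic SNVs of ``region`` from a VCF into a GenotypeBlock.

    The file is streamed in full and filtered in Python so plain-text VCFs
    need no tabix index. Multiallelic sites, non-SNVs and sites with any
    missing call are excluded (logged). Subjects are restricted to the panel;
    a VCF subject absent from the panel is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    vcf_samples = list(vcf.samples)
    missing = [s for s in vcf_samples if s not in panel]
    if missing:
        raise ValueError(
            f"VCF subjects absent from panel: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    mito = region.is_mitochondrial
    for v in vcf:
        if v.CHROM != region.chrom or not (region.start <= v.POS <= region.end):
            continue
        if len(v.ALT) != 1:
            logger.info("skipping multiallelic site %s:%d", v.CHROM, v.POS)
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            logger.info("skipping non-SNV site %s:%d", v.CHROM, v.POS)
            continue
        states = [_decode_diploid(gt, mito) for gt in v.genotypes]
        if any(s is None for s in states):
            logger.info("skipping site %s:%d with missing calls", v.CHROM, v.POS)
            continue
        site_id = v.ID if v.ID else f"{v.CHROM}:{v.POS}"
        sites.append(VariantSite(v.CHROM, v.POS, site_id, v.REF, v.ALT[0]))
        columns.append(np.array(states, dtype=np.int8))
    vcf.close()

    if not sites:
        warnings.warn(f"no sites found in region {region.name}", stacklevel=2)
        states = np.empty((len(vcf_samples), 0), dtype=np.int8)
    else:
        order = np.argsort([s.pos for s in sites], kind="stable")
        sites = [sites[i] for i in order]
        states = np.column_stack([columns[i] for i in order])
    return GenotypeBlock(region, sites, states, vcf_samples)


def filter_invariant(block: GenotypeBlock) -> GenotypeBlock:
    """Drop sites whose state is constant across all pooled subjects.

    Idempotent; preserves site order. An all-invariant block yields an empty
    block with a warning (downstream operations reject empty blocks).
    """
    if block.n_sites == 0:
        return block
    keep = np.array(
        [len(np.unique(block.states[:, j])) > 1 for j in range(block.n_sites)]
    )
    if not keep.any():
        warnings.warn(
            f"all sites invariant in {block.region.name}; block is now empty",
            stacklevel=2,
        )
    if keep.all():
        return block
    return block.subset_sites(np.flatnonzero(keep))
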