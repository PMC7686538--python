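"""End-to-end orchestration: data -> features -> classifiers -> reports.

One pipeline seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn``, so each stage is individually
reproducible; every output is stamped with the seed and a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import popgen, simulate, specificity
from .classify import ExperimentResult, _spawn_seeds, run_experiment_set
from .genotype_io import (
    GenotypeBlock,
    PopulationPanel,
    filter_invariant,
    read_gene_regions,
    read_panel,
    read_vcf_block,
)

logger = logging.getLogger(__name__)

MODES = ("mt", "nuc", "pair")


@dataclass
class PipelineConfig:
    """Inputs and parameters for a full run.

    Provide either ``sim`` (a synthetic-data configuration) or the three
    input paths ``vcf`` / ``panel`` / ``regions``.
    """

    sim: simulate.SimulationConfig | None = None
    vcf: str | None = None
    panel: str | None = None
    regions: str | None = None
    populations: list[str] | None = None
    modes: tuple[str, ...] = MODES
    seed: int = 0
    n_trees: int = 500
    n_folds: int = 10
    tolerance: float = 0.01
    n_perm: int = 200
    ld_window: int = 50
    ld_step: int = 10
    ld_threshold: float = 0.1
    top_k: int = 100
    snv_nuc_gene: str | None = None
    run_baselines: bool = True

    def __post_init__(self):
        has_paths = all(x is not None for x in (self.vcf, self.panel, self.regions))
        if (self.sim is None) == (not has_paths):
            raise ValueError(
                "provide either a simulation config or vcf+panel+regions paths"
            )
        bad = [m for m in self.modes if m not in MODES]
        if bad:
            raise ValueError(f"unknown modes {bad}")
        for name in ("n_trees", "n_folds", "n_perm", "ld_window", "ld_step", "top_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim_raw = raw.pop("sim", None)
        sim = None
        if sim_raw is not None:
            genes = [simulate.GeneSpec(**g) for g in sim_raw.pop("genes", [])]
            inter = [
                simulate.InteractionSpec(**i)
                for i in sim_raw.pop("interactions", [])
            ]
            for key in ("pop_names", "pop_sizes"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = simulate.SimulationConfig(genes=genes, interactions=inter, **sim_raw)
        if "modes" in raw:
            raw["modes"] = tuple(raw["modes"])
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_blocks(
    config: PipelineConfig,
) -> tuple[dict[str, GenotypeBlock], PopulationPanel]:
    """Simulate or read the genotype blocks, then filter invariant sites."""
    if config.sim is not None:
        blocks, panel = simulate.simulate_dataset(config.sim)
    else:
        panel = read_panel(config.panel)
        regions = read_gene_regions(config.regions)
        blocks = {r.name: read_vcf_block(config.vcf, r, panel) for r in regions}
    filtered = {}
    for name, block in blocks.items():
        fb = filter_invariant(block)
        if fb.n_sites == 0:
            warnings.warn(f"gene {name} has no variable sites; dropped", stacklevel=2)
            continue
        filtered[name] = fb
    if not filtered:
        raise ValueError("no gene retained any variable site")
    return filtered, panel


def _nuclear_gene_roles(
    spec_reports: dict[str, dict[str, specificity.SpecificityReport]],
    gains: dict[tuple[str, str], dict[str, list[str]]],
    nuc_genes: list[str],
) -> pd.DataFrame:
    """Per-nuclear-gene summary: important alone vs important with mtDNA."""
    rows = []
    for gene in nuc_genes:
        alone = sorted(
            pop
            for pop, rep in spec_reports.get("nuc", {}).items()
            if gene in rep.specific_features
        )
        with_mt = set()
        for pop, rep in spec_reports.get("pair", {}).items():
            if any(f.partition("+")[2] == gene for f in rep.specific_features):
                with_mt.add(pop)
        for (ref, tgt), g in gains.items():
            hits = g["increased_importance"] + g["only_in_combination"]
            if any(f.partition("+")[2] == gene for f in hits):
                with_mt.add(f"{ref} vs. {tgt}")
        rows.append(
            {
                "gene": gene,
                "important_alone": ", ".join(alone) if alone else "-",
                "important_with_mt": ", ".join(sorted(with_mt)) if with_mt else "-",
            }
        )
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a result bundle (plain dict)."""
    t0 = time.time()
    stage_seeds = _spawn_seeds(config.seed, 8)
    bundle: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    def _stage(name, fn, *args, **kwargs):
        t = time.time()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # preserve partial bundle, name the stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", name, time.time() - t)
        return out

    blocks, panel = _stage("load", load_blocks, config)
    bundle["genes"] = {
        name: {"genome_class": b.region.genome_class, "n_sites": b.n_sites}
        for name, b in blocks.items()
    }
    pops = config.populations or panel.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")

    mt_genes = [n for n, b in blocks.items() if b.region.is_mitochondrial]
    nuc_genes = [n for n, b in blocks.items() if not b.region.is_mitochondrial]

    experiments: dict[str, dict] = {}
    for i, mode in enumerate(config.modes):
        if mode in ("mt", "pair") and not mt_genes:
            logger.warning("no mitochondrial genes; skipping mode %s", mode)
            continue
        if mode in ("nuc", "pair") and not nuc_genes:
            logger.warning("no nuclear genes; skipping mode %s", mode)
            continue
        experiments[mode] = _stage(
            f"classify[{mode}]",
            run_experiment_set,
            blocks,
            panel,
            pops,
            mode,
            seed=stage_seeds[0] + i,
            n_trees=config.n_trees,
            n_folds=config.n_folds,
            tolerance=config.tolerance,
        )
    bundle["experiments"] = experiments

    spec_reports: dict[str, dict] = {}
    for mode, res in experiments.items():
        spec_reports[mode] = {
            p: specificity.population_specific(res, p) for p in pops
        }
    bundle["specificity"] = spec_reports

    gains: dict = {}
    if all(m in experiments for m in MODES):
        for key in experiments["pair"]:
            gains[key] = specificity.combination_gains(
                experiments["mt"][key],
                experiments["nuc"][key],
                experiments["pair"][key],
            )
    bundle["combination_gains"] = gains
    bundle["gene_roles"] = _nuclear_gene_roles(spec_reports, gains, nuc_genes)

    if config.snv_nuc_gene is not None:
        if config.snv_nuc_gene not in nuc_genes:
            raise RuntimeError(
                f"pipeline stage 'snv_pair' failed: unknown nuclear gene "
                f"{config.snv_nuc_gene!r}"
            )
        bundle["snv_pair"] = _stage(
            "snv_pair",
            specificity.snv_pair_mode,
            blocks[config.snv_nuc_gene],
            {g: blocks[g] for g in mt_genes},
            panel,
            top_k=config.top_k,
            n_trees=config.n_trees,
            n_folds=config.n_folds,
            seed=stage_seeds[1],
        )

    if config.run_baselines:
        fst_rows, fst_results = [], {}
        dapc_rows = []
        pair_list = [
            (pops[i], pops[j])
            for i in range(len(pops))
            for j in range(i + 1, len(pops))
        ]
        for gi, (name, block) in enumerate(blocks.items()):
            pruned = popgen.prune_ld(
                block, config.ld_window, config.ld_step, config.ld_threshold
            )
            pvals = {}
            for a, b in pair_list:
                try:
                    res = popgen.fst_permutation_p(
                        pruned, panel, a, b,
                        n_perm=config.n_perm,
                        seed=stage_seeds[2] + gi,
                    )
                except ValueError:
                    continue
                pvals[frozenset((a, b))] = res.p_value
                fst_results[(name, a, b)] = res
                fst_rows.append(
                    {
                        "gene": name,
                        "pop_a": a,
                        "pop_b": b,
                        "theta": res.theta,
                        "p_value": res.p_value,
                        "n_sites_pruned": pruned.n_sites,
                    }
                )
            if len(pvals) == len(pair_list) == 3:
                call = popgen.fst_specificity(pvals)
                for row in fst_rows[-3:]:
                    row["specificity"] = call
            if not block.region.is_mitochondrial:
                d = popgen.dapc(pruned, panel)
                for key, dist in d.centroid_distances.items():
                    a, b = sorted(key)
                    dapc_rows.append(
                        {"gene": name, "pop_a": a, "pop_b": b,
                         "centroid_distance": dist, "n_pca": d.n_pca}
                    )
        bundle["fst"] = pd.DataFrame(fst_rows)
        bundle["fst_results"] = fst_results
        bundle["dapc"] = pd.DataFrame(dapc_rows)

    bundle["runtime_s"] = time.time() - t0
    return bundle


# ---------------------------------------------------------------------------
# reporting


def accuracy_matrix(experiments: dict[tuple[str, str], ExperimentResult]) -> pd.DataFrame:
    """Reference x target matrix of 'accuracy (optimal k)' strings."""
    pops = sorted({p for key in experiments for p in key})
    mat = pd.DataFrame("-", index=pops, columns=pops)
    mat.index.name = "reference\\target"
    for (ref, tgt), res in experiments.items():
        mat.loc[ref, tgt] = f"{res.accuracy:.3f} ({res.optimal_k})"
    return mat


def _stamp(fh, bundle):
    fh.write(f"# seed={bundle['seed']} config_hash={bundle['config_hash']}\n")


def report(bundle: dict, out_dir) -> Path:
    """Write the bundle as markdown + TSV tables (+ accuracy-curve PNGs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for mode, res in bundle.get("experiments", {}).items():
        path = out / f"accuracy_matrix_{mode}.tsv"
        with open(path, "w") as fh:
            _stamp(fh, bundle)
            accuracy_matrix(res).to_csv(fh, sep="\t")
        rows = [
            {
                "reference": r.ref_pop,
                "target": r.target_pop,
                "accuracy": r.accuracy,
                "optimal_k": r.optimal_k,
                "optimal_features": ";".join(r.optimal_features),
            }
            for r in res.values()
        ]
        with open(out / f"experiments_{mode}.tsv", "w") as fh:
            _stamp(fh, bundle)
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    spec_rows = []
    for mode, reports in bundle.get("specificity", {}).items():
        for pop, rep in reports.items():
            feats = rep.specific_features
            spec_rows.append(
                {
                    "mode": mode,
                    "population": pop,
                    "specific_features": ";".join(feats) if feats else "none",
                }
            )
    if spec_rows:
        with open(out / "population_specific.tsv", "w") as fh:
            _stamp(fh, bundle)
            pd.DataFrame(spec_rows).to_csv(fh, sep="\t", index=False)

    gain_rows = []
    for (ref, tgt), g in bundle.get("combination_gains", {}).items():
        gain_rows.append(
            {
                "reference": ref,
                "target": tgt,
                "increased_importance": ";".join(g["increased_importance"]) or "none",
                "only_in_combination": ";".join(g["only_in_combination"]) or "none",
            }
        )
    if gain_rows:
        with open(out / "combination_gains.tsv", "w") as fh:
            _stamp(fh, bundle)
            pd.DataFrame(gain_rows).to_csv(fh, sep="\t", index=False)

    if "gene_roles" in bundle and len(bundle["gene_roles"]):
        with open(out / "nuclear_gene_roles.tsv", "w") as fh:
            _stamp(fh, bundle)
            bundle["gene_roles"].to_csv(fh, sep="\t", index=False)

    if "snv_pair" in bundle:
        sp = bundle["snv_pair"]
        rows = []
        for (a, b), exp in sp["experiments"].items():
            for rank, feat in enumerate(exp["top_features"], start=1):
                rows.append(
                    {"pop_a": a, "pop_b": b, "rank": rank, "snv_pair": feat,
                     "importance": exp["importances"][feat],
                     "accuracy": exp["accuracy"]}
                )
        with open(out / "snv_pairs.tsv", "w") as fh:
            _stamp(fh, bundle)
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
        with open(out / "snv_pair_specific.tsv", "w") as fh:
            _stamp(fh, bundle)
            pd.DataFrame(
                [
                    {"population": p, "specific_pairs": ";".join(v) if v else "none"}
                    for p, v in sp["specific"].items()
                ]
            ).to_csv(fh, sep="\t", index=False)

    for key in ("fst", "dapc"):
        if key in bundle and len(bundle[key]):
            with open(out / f"{key}.tsv", "w") as fh:
                _stamp(fh, bundle)
                bundle[key].to_csv(fh, sep="\t", index=False)

    _plot_curves(bundle, out)

    md = out / "summary.md"
    with open(md, "w") as fh:
        fh.write("# Mitonuclear classification report\n\n")
        fh.write(
            f"seed: {bundle['seed']}  \nconfig hash: {bundle['config_hash']}\n\n"
        )
        for mode, res in bundle.get("experiments", {}).items():
            fh.write(f"## Accuracy ({mode} mode)\n\n")
            fh.write(accuracy_matrix(res).to_markdown() + "\n\n")
        if spec_rows:
            fh.write("## Population-specific features\n\n")
            fh.write(pd.DataFrame(spec_rows).to_markdown(index=False) + "\n\n")
        if gain_rows:
            fh.write("## Combination gains\n\n")
            fh.write(pd.DataFrame(gain_rows).to_markdown(index=False) + "\n\n")
    return md


def _plot_curves(bundle, out: Path):
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    for mode, res in bundle.get("experiments", {}).items():
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for (ref, tgt), r in res.items():
            ks = np.arange(1, len(r.cv_curve) + 1)
            ax.plot(ks, r.cv_curve, marker="o", ms=3, label=f"{ref}->{tgt}")
        ax.set_xlabel("top-k features")
        ax.set_ylabel("CV accuracy")
        ax.set_title(f"serial selection ({mode})")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / f"curves_{mode}.png", dpi=110)
        plt.close(fig)
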