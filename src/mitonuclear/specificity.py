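"""Population-specific features by intersection of optimal feature lists.

A gene (or gene pair, or SNV pair) is *specific* to a population when it
appears in the optimal feature list of every classification experiment that
involves that population: with three populations that is four experiments in
the reference/target gene modes (P as reference twice, P as target twice) and
two in the reference-free SNV-pair mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .classify import ExperimentResult, _spawn_seeds
from .genotype_io import GenotypeBlock, PopulationPanel

logger = logging.getLogger(__name__)


@dataclass
class SpecificityReport:
    population: str
    mode: str
    specific_features: list[str]
    experiments: list[tuple[str, str]] = field(default_factory=list)


def _index_results(results) -> dict[tuple[str, str], ExperimentResult]:
    if isinstance(results, dict):
        return dict(results)
    return {(r.ref_pop, r.target_pop): r for r in results}


def population_specific(results, population: str) -> SpecificityReport:
    """Intersect the optimal lists of all experiments involving a population.

    ``results`` holds one mode's experiments keyed (reference, target); the
    four experiments required for ``population`` P are (P, other) and
    (other, P) for both other populations.
    """
    res = _index_results(results)
    pops = sorted({p for key in res for p in key})
    if population not in pops:
        raise ValueError(f"population {population!r} absent from results")
    others = [p for p in pops if p != population]
    needed = [(population, o) for o in others] + [(o, population) for o in others]
    missing = [k for k in needed if k not in res]
    if missing:
        raise ValueError(f"missing experiments: {missing}")
    modes = {res[k].mode for k in needed}
    if len(modes) != 1:
        raise ValueError(f"mixed modes in experiment set: {modes}")
    lists = [res[k].optimal_features for k in needed]
    common = set(lists[0])
    for lst in lists[1:]:
        common &= set(lst)
    # deterministic order: as ranked in the first experiment
    ordered = [f for f in lists[0] if f in common]
    return SpecificityReport(population, modes.pop(), ordered, needed)


def _normalized_rank(result: ExperimentResult) -> dict[str, float]:
    """1.0 for the top-ranked feature, 0.0 for the last (0.5-ties at K=1)."""
    k = len(result.ranked_features)
    if k == 1:
        return {result.ranked_features[0]: 1.0}
    return {
        f: 1.0 - i / (k - 1) for i, f in enumerate(result.ranked_features)
    }


def combination_gains(
    mt_result: ExperimentResult,
    nuc_result: ExperimentResult,
    pair_result: ExperimentResult,
    method: str = "rank",
) -> dict[str, list[str]]:
    """Gene pairs that outperform their constituent genes.

    Returns two disjoint lists for one (reference, target) orientation:

    - ``increased_importance``: pairs in the pair-mode optimal list whose
      constituents were both selected in their single-genome optimal lists
      but whose pair importance exceeds both constituents' importances;
    - ``only_in_combination``: pairs in the pair-mode optimal list with at
      least one constituent absent from its single-genome optimal list.

    ``method='rank'`` compares normalized within-model ranks (importances are
    normalized within each model, so raw scores are not directly comparable
    across models of different size); ``method='raw'`` compares raw
    importance scores.
    """
    if method not in ("rank", "raw"):
        raise ValueError(f"unknown method {method!r}")
    for r in (mt_result, nuc_result, pair_result):
        if (r.ref_pop, r.target_pop) != (pair_result.ref_pop, pair_result.target_pop):
            raise ValueError("results must share one (reference, target) pair")
    if {mt_result.mode, nuc_result.mode, pair_result.mode} != {"mt", "nuc", "pair"}:
        raise ValueError("need one result each of modes mt, nuc, pair")

    if method == "rank":
        mt_score = _normalized_rank(mt_result)
        nuc_score = _normalized_rank(nuc_result)
        pair_score = _normalized_rank(pair_result)
    else:
        mt_score = mt_result.importances
        nuc_score = nuc_result.importances
        pair_score = pair_result.importances

    increased, only_combo = [], []
    for pair_name in pair_result.optimal_features:
        mt_gene, _, nuc_gene = pair_name.partition("+")
        selected_alone = (
            mt_gene in mt_result.optimal_features
            and nuc_gene in nuc_result.optimal_features
        )
        if not selected_alone:
            only_combo.append(pair_name)
        elif (
            pair_score[pair_name] > mt_score.get(mt_gene, 0.0)
            and pair_score[pair_name] > nuc_score.get(nuc_gene, 0.0)
        ):
            increased.append(pair_name)
    return {"increased_importance": increased, "only_in_combination": only_combo}


def snv_pair_features(
    nuc_block: GenotypeBlock, mt_blocks: dict[str, GenotypeBlock]
) -> pd.DataFrame:
    """Joint-state categories (0..5) for every (mt site, nuc site) pair.

    Each feature encodes ``3 * mt_allele + nuc_genotype``; the six categories
    follow the fixed joint-state order (mt 0 with hom-ref/het/hom-alt, then
    mt 1 likewise). Feature count is the product of retained site counts.
    """
    if nuc_block.region.is_mitochondrial:
        raise ValueError("nuc_block must be a nuclear gene")
    subjects = nuc_block.subject_ids
    cols, names = [], []
    for gene, mt_block in mt_blocks.items():
        if not mt_block.region.is_mitochondrial:
            raise ValueError(f"{gene} is not mitochondrial")
        if mt_block.subject_ids != subjects:
            raise ValueError("blocks disagree on subject ordering")
        A = mt_block.states  # (n, m)
        G = nuc_block.states  # (n, k)
        joint = (3 * A[:, :, None] + G[:, None, :]).reshape(len(subjects), -1)
        cols.append(joint)
        names.extend(
            f"{ms.site_id}+{ns.site_id}"
            for ms in mt_block.sites
            for ns in nuc_block.sites
        )
    return pd.DataFrame(
        np.column_stack(cols), index=pd.Index(subjects, name="subject"),
        columns=names,
    )


def snv_pair_mode(
    nuc_block: GenotypeBlock,
    mt_blocks: dict[str, GenotypeBlock],
    panel: PopulationPanel,
    top_k: int = 100,
    n_trees: int = 500,
    n_folds: int = 10,
    seed: int = 0,
) -> dict:
    """SNV-level pair analysis for one nuclear gene against all mt genes.

    No reference population is used: the raw joint-state categories are the
    features. For each unordered population pair a binary forest is fit; the
    ``top_k`` features by importance are retained per experiment, and a pair
    is specific to population P when it appears in both retained lists of the
    experiments involving P.
    """
    table = snv_pair_features(nuc_block, mt_blocks)
    labels = panel.labels(table.index)
    pops = [p for p in panel.populations if (labels == p).any()]
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
    seeds = _spawn_seeds(seed, len(pairs))

    if table.shape[1] < top_k:
        logger.warning(
            "only %d SNV-pair features available (top_k=%d); retaining all",
            table.shape[1],
            top_k,
        )
    experiments = {}
    for (a, b), s in zip(pairs, seeds):
        keep = np.isin(labels, [a, b])
        X, y = table.values[keep].astype(float), labels[keep]
        forest_seed, fold_seed = _spawn_seeds(s, 2)
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=forest_seed, n_jobs=1
        )
        cv = StratifiedKFold(n_folds, shuffle=True, random_state=fold_seed)
        acc = float(cross_val_score(forest, X, y, cv=cv, n_jobs=1).mean())
        imp = forest.fit(X, y).feature_importances_
        order = sorted(
            range(len(imp)), key=lambda i: (-imp[i], table.columns[i])
        )
        top = [table.columns[i] for i in order[:top_k]]
        experiments[(a, b)] = {
            "accuracy": acc,
            "top_features": top,
            "importances": {table.columns[i]: float(imp[i]) for i in order[:top_k]},
        }

    specific = {}
    for p in pops:
        involved = [exp for key, exp in experiments.items() if p in key]
        common = set(involved[0]["top_features"])
        for exp in involved[1:]:
            common &= set(exp["top_features"])
        first = involved[0]["top_features"]
        specific[p] = [f for f in first if f in common]
    return {
        "experiments": experiments,
        "specific": specific,
        "n_features": table.shape[1],
        "top_k": top_k,
    }
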