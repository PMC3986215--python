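"""Cross-validated ROC AUC of a prioritizer and ensemble-averaged AUC.

The evaluation is a jackknifing (hidden-seed) test: one fold of seeds is
hidden — demoted to the non-seed score, not removed from the network — the
prioritizer runs from the remaining seeds, and the AUC measures how highly
the hidden seeds rank among all nodes that are not training seeds.  Per-fold
AUCs are averaged; ensembles of perturbed networks are summarized by the mean
AUC per perturbation level with a normal-approximation 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import roc_auc_score

from .interactome import NodeScores, PhenotypeSeeds
from .perturb import PerturbedEnsemble
from .prioritize import PrioritizerConfig, netscore, netscore_kernel, prioritize


@dataclass
class FoldSplit:
    """Balanced random partition of a seed set into k folds (sizes differ <= 1)."""

    k: int
    assignment: dict  # seed node -> fold index in 1..k
    rng_seed: int

    def fold(self, f: int) -> set:
        return {u for u, i in self.assignment.items() if i == f}


@dataclass
class AUCRecord:
    """Per-fold AUCs of one (phenotype, method, network) evaluation."""

    phenotype_id: str
    method: str
    per_fold_auc: list
    mean_auc: float = field(init=False)
    ci95: tuple = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_fold_auc, dtype=float)
        self.mean_auc = float(arr.mean())
        half = 1.96 * arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
        self.ci95 = (self.mean_auc - float(half), self.mean_auc + float(half))


@dataclass
class EnsembleAUC:
    """Mean AUC (with 95% CI) over the replicates of one perturbation level."""

    level: float
    per_instance_auc: list
    mean: float = field(init=False)
    ci95: tuple = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_instance_auc, dtype=float)
        self.mean = float(arr.mean())
        half = 1.96 * arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
        self.ci95 = (self.mean - float(half), self.mean + float(half))


def kfold_split(seeds, k: int = 5, rng_seed: int = 0) -> FoldSplit:
    """Random balanced k-fold partition of *seeds*, reproducible via rng_seed."""
    seeds = sorted(seeds)
    if len(seeds) < k:
        raise ValueError(f"need at least k={k} seeds, got {len(seeds)}")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(seeds))
    assignment = {seeds[j]: (pos % k) + 1 for pos, j in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment, rng_seed=rng_seed)


def roc_auc(scores: NodeScores, positives, negatives) -> float:
    """ROC AUC of *scores* separating positives from negatives.

    Equals the normalized Mann-Whitney statistic
    (concordant + 0.5 * tied) / (|pos| * |neg|); ties count half.
    """
    positives, negatives = set(positives), set(negatives)
    if not positives or not negatives:
        raise ValueError("positives and negatives must both be non-empty")
    if positives & negatives:
        raise ValueError("positives and negatives must be disjoint")
    y = [1] * len(positives) + [0] * len(negatives)
    s = [scores[u] for u in sorted(positives)] + [scores[u] for u in sorted(negatives)]
    if len(set(s)) == 1:
        return 0.5  # all tied: chance performance by definition
    return float(roc_auc_score(y, s))


def cross_validate(
    net: nx.Graph,
    ph: PhenotypeSeeds,
    config: PrioritizerConfig,
    split: FoldSplit,
) -> AUCRecord:
    """Hidden-seed cross-validation of one prioritizer on one network.

    For each fold f, seeds outside f keep the seed score and the fold's seeds
    are demoted to the non-seed score; after prioritization the AUC is taken
    with the fold's seeds as positives and all nodes that are seeds of
    neither set as negatives.
    """
    all_seeds = set(split.assignment)
    nodes = set(net.nodes)
    # NetScore's kernel depends only on topology: build once, reuse per fold.
    kernel = (
        netscore_kernel(net, config.iterations) if config.method == "netscore" else None
    )
    per_fold = []
    for f in range(1, split.k + 1):
        test_seeds = split.fold(f) & nodes
        train_seeds = (all_seeds - split.fold(f)) & nodes
        if not test_seeds or not train_seeds:
            raise ValueError(f"fold {f}: empty train or test seed set on this network")
        init = {
            u: (ph.seed_score if u in train_seeds else ph.nonseed_score) for u in net.nodes
        }
        if kernel is not None:
            scores = netscore(net, init, r=config.repetitions, i=config.iterations, kernel=kernel)
        else:
            scores = prioritize(net, init, config)
        negatives = nodes - all_seeds
        per_fold.append(roc_auc(scores, test_seeds, negatives))
    return AUCRecord(phenotype_id=ph.phenotype_id, method=config.method, per_fold_auc=per_fold)


def ensemble_auc(
    ensemble: PerturbedEnsemble,
    ph: PhenotypeSeeds,
    config: PrioritizerConfig,
    split_seed: int = 0,
    k: int = 5,
    net: nx.Graph | None = None,
) -> list:
    """Mean cross-validated AUC per perturbation level of an ensemble.

    The same fold split (from *split_seed*) is reused across every instance
    of the ensemble, so the per-level variance reflects the network (or
    seed-set) perturbation alone.  For seed-swap ensembles the fixed network
    must be passed via *net* and each instance's own (partly false) seed set
    is cross-validated on it.
    """
    results = []
    if ensemble.kind != "seed_swap":
        split = kfold_split(ph.mapped_seeds(ensemble.source), k=k, rng_seed=split_seed)
    for p in ensemble.levels:
        aucs = []
        for spec, instance in ensemble:
            if spec.level != p:
                continue
            if ensemble.kind == "seed_swap":
                graph = net if net is not None else ensemble.net
                inst_split = kfold_split(
                    instance.mapped_seeds(graph), k=k, rng_seed=split_seed
                )
                rec = cross_validate(graph, instance, config, inst_split)
            else:
                rec = cross_validate(instance, ph, config, split)
            aucs.append(rec.mean_auc)
        results.append(EnsembleAUC(level=p, per_instance_auc=aucs))
    return results
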