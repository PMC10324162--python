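"""Drug-wise cross-validation, ranking metrics, and novel-pair ranking.

The evaluation protocol is cold-start on drugs: whole drugs, with their
interaction rows and similarity rows/columns, are withheld from training and
re-embedded out-of-sample from their similarity profile to the training
drugs.  One AUROC/AUPRC is computed per test fold over all its drug-target
pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from mokpe.model import (
    DtiNetwork,
    Embedding,
    EmbeddingConfig,
    embed_new_drug,
    fit,
    predict_pair_scores,
)

__all__ = [
    "FoldPlan",
    "CvResult",
    "NovelPrediction",
    "make_fold_plan",
    "mask_network_for_fold",
    "auroc",
    "auprc",
    "cross_validate",
    "rank_novel_pairs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """One (replication, fold) cell of the cross-validation design."""

    replication: int
    fold: int
    test_drugs: tuple[int, ...]
    train_drugs: tuple[int, ...]

    def __post_init__(self):
        if set(self.test_drugs) & set(self.train_drugs):
            raise ValueError("test and train drug sets overlap")


@dataclass
class CvResult:
    """Per-fold AUROC/AUPRC records plus two summary conventions.

    ``summary`` averages over all folds; ``summary_by_replication`` first
    averages within each replication, then across replications (same means,
    different standard deviations).
    """

    records: pd.DataFrame
    folds: int
    reps: int

    @property
    def summary(self) -> pd.DataFrame:
        valid = self.records.dropna(subset=["auroc", "auprc"])
        return valid[["auroc", "auprc"]].agg(["mean", "std"])

    @property
    def summary_by_replication(self) -> pd.DataFrame:
        valid = self.records.dropna(subset=["auroc", "auprc"])
        per_rep = valid.groupby("replication")[["auroc", "auprc"]].mean()
        return per_rep.agg(["mean", "std"])


@dataclass(frozen=True)
class NovelPrediction:
    """A candidate interaction absent from the adjacency, ranked by distance."""

    drug_id: str
    target_id: str
    distance: float
    rank: int


def make_fold_plan(
    n_drugs: int, folds: int = 10, reps: int = 10, seed: int = 0
) -> list[FoldPlan]:
    """Uniformly random partitions of the drug set, one per replication.

    Fold sizes within a replication differ by at most one; deterministic
    given ``seed``.
    """
    if folds > n_drugs:
        raise ValueError(f"cannot split {n_drugs} drugs into {folds} folds")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(1, reps + 1):
        perm = rng.permutation(n_drugs)
        for k, chunk in enumerate(np.array_split(perm, folds), start=1):
            test = tuple(int(i) for i in np.sort(chunk))
            train = tuple(int(i) for i in np.sort(np.setdiff1d(perm, chunk)))
            plans.append(FoldPlan(replication=rep, fold=k, test_drugs=test,
                                  train_drugs=train))
    return plans


def mask_network_for_fold(
    network: DtiNetwork, plan: FoldPlan
) -> tuple[DtiNetwork, np.ndarray, np.ndarray]:
    """Withhold the fold's test drugs entirely from the training network.

    Returns (train network, test similarity profiles to train drugs,
    held-out adjacency rows).  Test drugs are removed from the interaction
    matrix and from both axes of the drug similarity matrix.
    """
    train = list(plan.train_drugs)
    test = list(plan.test_drugs)
    if not train:
        raise ValueError("empty training set")
    train_net = DtiNetwork(
        drug_ids=tuple(network.drug_ids[i] for i in train),
        target_ids=network.target_ids,
        adjacency=network.adjacency[train, :],
        sim_drugs=network.sim_drugs[np.ix_(train, train)],
        sim_targets=network.sim_targets,
    )
    profiles = network.sim_drugs[np.ix_(test, train)]
    labels = network.adjacency[test, :]
    return train_net, profiles, labels


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected AUROC: P(score+ > score-) + P(score+ == score-) / 2.

    Computed from mid-ranks (the Mann-Whitney statistic), so tied scores are
    handled exactly and the result is permutation-invariant.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: labels contain a single class")
    ranks = rankdata(scores, method="average")
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision with tied scores handled as a block.

    Entries are processed in descending-score order; all entries sharing a
    score form one block and its positives contribute the precision at the
    end of the block, making the value permutation-invariant.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]

    total = 0.0
    seen = 0
    seen_pos = 0
    i = 0
    n = scores.size
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        block_pos = int(l_sorted[i:j].sum())
        seen += j - i
        seen_pos += block_pos
        total += block_pos * (seen_pos / seen)
        i = j
    return total / n_pos


def cross_validate(
    network: DtiNetwork,
    cfg: EmbeddingConfig | None = None,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
) -> CvResult:
    """Cold-start drug-wise cross-validation of the full pipeline.

    For every fold: fit on the masked training network, embed each test drug
    from its similarity profile, score all test-drug x target pairs, and pool
    them into one AUROC and one AUPRC.  The fold RNG (``seed``) is a separate
    stream from the model-init RNG (``cfg.seed``).  Folds whose pooled pairs
    contain a single class are recorded as NA and excluded from summaries.
    """
    cfg = cfg or EmbeddingConfig()
    plans = make_fold_plan(network.n_drugs, folds=folds, reps=reps, seed=seed)
    rows = []
    for plan in plans:
        train_net, profiles, labels = mask_network_for_fold(network, plan)
        emb = fit(train_net, cfg)
        vecs = np.vstack([
            embed_new_drug(emb, profiles[i], cfg) for i in range(profiles.shape[0])
        ])
        scores = predict_pair_scores(vecs, emb, cfg)
        flat_scores = scores.ravel()
        flat_labels = labels.ravel().astype(int)
        n_pos = int(flat_labels.sum())
        n_neg = flat_labels.size - n_pos
        if n_pos == 0 or n_neg == 0:
            logger.warning(
                "replication %d fold %d has a single label class "
                "(%d positives, %d negatives); recording NA",
                plan.replication, plan.fold, n_pos, n_neg,
            )
            roc = prc = np.nan
        else:
            roc = auroc(flat_scores, flat_labels)
            prc = auprc(flat_scores, flat_labels)
        rows.append({
            "replication": plan.replication,
            "fold": plan.fold,
            "auroc": roc,
            "auprc": prc,
            "n_positive": n_pos,
            "n_negative": n_neg,
        })
    return CvResult(records=pd.DataFrame(rows), folds=folds, reps=reps)


def rank_novel_pairs(
    emb: Embedding, network: DtiNetwork, k: int = 25
) -> list[NovelPrediction]:
    """Top-k non-interacting pairs by ascending embedded Euclidean distance.

    Known interacting pairs are excluded; ties are broken by (drug id,
    target id) lexicographic order.  The embedding must have been trained on
    the full network.
    """
    if emb.X_d.n != network.n_drugs or emb.X_t.n != network.n_targets:
        raise ValueError("embedding dimensions do not match the network")
    diff = emb.drug_coords[:, None, :] - emb.target_coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    novel = np.argwhere(network.adjacency == 0)
    if k > len(novel):
        logger.warning(
            "requested top %d but only %d non-interacting pairs exist", k, len(novel)
        )
        k = len(novel)
    entries = sorted(
        (
            (float(dist[i, j]), network.drug_ids[i], network.target_ids[j])
            for i, j in novel
        ),
        key=lambda e: (e[0], e[1], e[2]),
    )
    return [
        NovelPrediction(drug_id=d, target_id=t, distance=dd, rank=r)
        for r, (dd, d, t) in enumerate(entries[:k], start=1)
    ]
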