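"""Per-disease cross-validation, ROC/AUC and rank-position flagging.

For a disease d the miRNAs are split into five stratified folds. Each fold is
scored by rebuilding the combined matrix with the held-out miRNAs' knowledge
of d removed — their disease-block entry for d is zeroed, the Lin propagation
is recomputed without the (i, d) pair, and their entire word-block row is
blanked (so nothing learned from the literature leaks) — refitting the latent
space, and querying d.

Flagging uses rank positions: a known association is putatively false when
more than ``threshold`` of the negatives rank above it; a non-association is
a novel candidate when more than ``threshold`` of the known positives rank
below it. Both comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Sequence

import numpy as np

from . import latent
from .features import (
    CombinedMatrix,
    MD_FLOOR,
    MN_FLOOR,
    NeighborParams,
    build_disease_matrix,
    build_family_matrix,
    build_neighbor_matrix,
    build_target_matrix,
    build_word_matrix,
    concatenate,
    disease_similarity_matrix,
)
from .io import Dataset
from .latent import RankedList
from .ontology import DiseaseOntology

__all__ = [
    "RocPoint",
    "CvResult",
    "Pipeline",
    "make_folds",
    "run_fold",
    "cross_validate",
    "repeated_cross_validate",
    "roc",
    "flag_putative_false",
    "flag_novel",
    "flag_disease",
]

FLAG_THRESHOLD = 0.85
MIN_POSITIVES_HINT = (
    "too few positive miRNAs for stratified folds; restrict evaluation to "
    "diseases associated with at least 20 miRNAs"
)


@dataclass
class RocPoint:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


@dataclass
class CvResult:
    disease: str
    seed: int
    folds: dict[str, int]
    fold_rocs: list[list[RocPoint]]
    fold_aucs: list[float]
    pooled_auc: float
    #: each miRNA's score from the one fold in which it was held out
    held_out_scores: dict[str, float] = field(default_factory=dict)
    flagged_false: list[tuple[str, float]] = field(default_factory=list)
    flagged_novel: list[tuple[str, float]] = field(default_factory=list)


def make_folds(
    mirna_ids: Sequence[str],
    positives: Iterable[str],
    n_folds: int = 5,
    seed: int = 0,
) -> dict[str, int]:
    """Stratified random partition into ``n_folds`` folds, deterministic per seed.

    Positives and negatives are each split as evenly as possible, so fold
    sizes (and per-fold positive counts) differ by at most one.
    """
    positives = set(positives)
    pos = sorted(m for m in mirna_ids if m in positives)
    neg = sorted(m for m in mirna_ids if m not in positives)
    if len(pos) < n_folds:
        raise ValueError(
            f"{len(pos)} positives < {n_folds} folds: {MIN_POSITIVES_HINT}"
        )
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    cursor = 0  # continue the deal across strata so overall sizes stay even
    for group in (pos, neg):
        order = rng.permutation(len(group))
        for idx in order:
            folds[group[idx]] = cursor % n_folds
            cursor += 1
    return folds


def roc(scores: Sequence[float], labels: Sequence[int]) -> tuple[list[RocPoint], float]:
    """Threshold sweep over the distinct scores; trapezoidal AUC.

    Tied scores form a single step so the AUC equals the Mann-Whitney
    concordance probability with ties credited one half. Raises on
    single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    points: list[RocPoint] = []
    tp = fp = 0
    auc = 0.0
    prev_tpr = prev_fpr = 0.0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += int(labels[i:j].sum())
        fp += (j - i) - int(labels[i:j].sum())
        point = RocPoint(threshold=float(scores[i]), tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
        points.append(point)
        auc += (point.fpr - prev_fpr) * (point.tpr + prev_tpr) / 2.0
        prev_tpr, prev_fpr = point.tpr, point.fpr
        i = j
    return points, auc


class Pipeline:
    """Caches the fold-invariant feature blocks for repeated CV refits.

    Only the disease block (per-fold Lin re-propagation) and the word block
    (row blanking) change between folds; neighbor, target and family blocks
    are built once.
    """

    def __init__(
        self,
        dataset: Dataset,
        ontology: DiseaseOntology,
        neighbor_params: NeighborParams | None = None,
        md_floor: float = MD_FLOOR,
        mn_floor: float = MN_FLOOR,
        md_agg: str = "max",
    ):
        self.dataset = dataset
        self.ontology = ontology
        self.md_floor = md_floor
        self.md_agg = md_agg
        self.similarity = disease_similarity_matrix(dataset.diseases, ontology)
        self._static = [
            build_neighbor_matrix(dataset, neighbor_params, floor=mn_floor),
            build_target_matrix(dataset),
            build_family_matrix(dataset),
        ]
        self._word_full = build_word_matrix(dataset)

    def combined(
        self,
        exclude: dict[str, set[str]] | None = None,
        zero_word_rows: set[str] | None = None,
    ) -> CombinedMatrix:
        md = build_disease_matrix(
            self.dataset,
            self.ontology,
            floor=self.md_floor,
            agg=self.md_agg,
            similarity=self.similarity,
            exclude=exclude,
        )
        if zero_word_rows:
            mw = build_word_matrix(self.dataset, zero_rows=zero_word_rows)
        else:
            mw = self._word_full
        return concatenate([md, mw, *self._static])

    def positives(self, disease: str) -> set[str]:
        return {rec.id for rec in self.dataset.mirnas if disease in rec.diseases}


def run_fold(
    pipeline: Pipeline,
    disease: str,
    folds: dict[str, int],
    fold_index: int,
    rank: int,
    seed: int = 0,
) -> dict[str, float]:
    """Scores of the held-out miRNAs for one fold (masked-matrix refit)."""
    test = sorted(m for m, f in folds.items() if f == fold_index)
    if not test:
        raise ValueError(f"fold {fold_index} is empty")
    cm = pipeline.combined(
        exclude={m: {disease} for m in test}, zero_word_rows=set(test)
    )
    ls = latent.fit(cm, rank, seed=seed, cap=True)
    ranked = latent.query(ls, disease)
    all_scores = ranked.scores()
    return {m: all_scores[m] for m in test}


def cross_validate(
    pipeline: Pipeline,
    disease: str,
    rank: int,
    n_folds: int = 5,
    seed: int = 0,
) -> CvResult:
    """Stratified n-fold CV for one disease; pooled AUC = mean of fold AUCs."""
    positives = pipeline.positives(disease)
    folds = make_folds(pipeline.dataset.mirna_ids, positives, n_folds=n_folds, seed=seed)
    fold_rocs: list[list[RocPoint]] = []
    fold_aucs: list[float] = []
    held_out: dict[str, float] = {}
    for k in range(n_folds):
        scores = run_fold(pipeline, disease, folds, k, rank, seed=seed)
        held_out.update(scores)
        labels = [1 if m in positives else 0 for m in scores]
        points, auc = roc(list(scores.values()), labels)
        fold_rocs.append(points)
        fold_aucs.append(auc)
    # flags from the pooled held-out ranking: every miRNA was scored exactly
    # once, with its own link to the disease (and its literature) removed
    pooled = RankedList(
        disease=disease,
        entries=sorted(held_out.items(), key=lambda e: (-e[1], e[0])),
    )
    return CvResult(
        disease=disease,
        seed=seed,
        folds=folds,
        fold_rocs=fold_rocs,
        fold_aucs=fold_aucs,
        pooled_auc=mean(fold_aucs),
        held_out_scores=held_out,
        flagged_false=flag_putative_false(pooled, positives),
        flagged_novel=flag_novel(pooled, positives),
    )


def repeated_cross_validate(
    pipeline: Pipeline,
    disease: str,
    rank: int,
    n_folds: int = 5,
    seed: int = 0,
    repeats: int = 1,
) -> CvResult:
    """Cross-validation repeated over fold seeds, with averaged held-out scores.

    A single partition is noisy for rank-position flagging: when a paralog or
    co-located neighbor of a held-out miRNA lands in the same fold, the
    evidence for both is removed at once. Averaging each miRNA's held-out
    score over ``repeats`` partitions (seeds ``seed .. seed+repeats-1``)
    stabilizes the pooled ranking; ROC curves and AUCs are collected from all
    repeats. ``repeats=1`` reduces to :func:`cross_validate`.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    results = [
        cross_validate(pipeline, disease, rank, n_folds=n_folds, seed=seed + rep)
        for rep in range(repeats)
    ]
    if repeats == 1:
        return results[0]
    held_out: dict[str, float] = {}
    for res in results:
        for mirna, score in res.held_out_scores.items():
            held_out[mirna] = held_out.get(mirna, 0.0) + score / repeats
    pooled = RankedList(
        disease=disease,
        entries=sorted(held_out.items(), key=lambda e: (-e[1], e[0])),
    )
    positives = pipeline.positives(disease)
    return CvResult(
        disease=disease,
        seed=seed,
        folds=results[0].folds,
        fold_rocs=[points for res in results for points in res.fold_rocs],
        fold_aucs=[auc for res in results for auc in res.fold_aucs],
        pooled_auc=mean(res.pooled_auc for res in results),
        held_out_scores=held_out,
        flagged_false=flag_putative_false(pooled, positives),
        flagged_novel=flag_novel(pooled, positives),
    )


def _rank_fractions(ranked: RankedList, positives: set[str]) -> dict[str, tuple[int, int]]:
    """For each miRNA: (#positives strictly above it, #negatives strictly above it)."""
    out: dict[str, tuple[int, int]] = {}
    pos_above = neg_above = 0
    for mirna, _ in ranked.entries:
        out[mirna] = (pos_above, neg_above)
        if mirna in positives:
            pos_above += 1
        else:
            neg_above += 1
    return out


def flag_putative_false(
    ranked: RankedList,
    positives: Iterable[str],
    threshold: float = FLAG_THRESHOLD,
) -> list[tuple[str, float]]:
    """Known positives with more than ``threshold`` of negatives ranked above.

    Returns (miRNA, negatives-fraction-above) pairs, worst first. Strict
    inequality: a fraction exactly at the threshold is not flagged.
    """
    positives = set(positives)
    n_neg = sum(1 for m, _ in ranked.entries if m not in positives)
    if n_neg == 0:
        return []
    above = _rank_fractions(ranked, positives)
    flagged = [
        (m, above[m][1] / n_neg)
        for m, _ in ranked.entries
        if m in positives and above[m][1] / n_neg > threshold
    ]
    return sorted(flagged, key=lambda e: (-e[1], e[0]))


def flag_novel(
    ranked: RankedList,
    positives: Iterable[str],
    threshold: float = FLAG_THRESHOLD,
) -> list[tuple[str, float]]:
    """Non-associated miRNAs with more than ``threshold`` of positives below.

    Returns (miRNA, positives-fraction-below) pairs, best first. Strict
    inequality at the threshold.
    """
    positives = set(positives)
    n_pos = len(positives & {m for m, _ in ranked.entries})
    if n_pos == 0:
        return []
    above = _rank_fractions(ranked, positives)
    flagged = [
        (m, (n_pos - above[m][0]) / n_pos)
        for m, _ in ranked.entries
        if m not in positives and (n_pos - above[m][0]) / n_pos > threshold
    ]
    return sorted(flagged, key=lambda e: (-e[1], e[0]))


def flag_disease(
    pipeline: Pipeline,
    disease: str,
    rank: int,
    threshold: float = FLAG_THRESHOLD,
    seed: int = 0,
    mask_pair: bool = True,
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Full-data flagging for one disease.

    Novel candidates come from a single full-data fit. Putative-false flags
    score each known positive with its own (i, d) pair masked out of the
    matrix (refit per positive) unless ``mask_pair`` is False, in which case
    the plain full-data ranking is used for both.
    """
    positives = pipeline.positives(disease)
    ls = latent.fit(pipeline.combined(), rank, seed=seed, cap=True)
    ranked = latent.query(ls, disease)
    novel = flag_novel(ranked, positives, threshold)

    if not mask_pair:
        return flag_putative_false(ranked, positives, threshold), novel

    n_neg = len(ranked.entries) - len(positives)
    false_flags: list[tuple[str, float]] = []
    for mirna in sorted(positives):
        cm = pipeline.combined(exclude={mirna: {disease}})
        ls_m = latent.fit(cm, rank, seed=seed, cap=True)
        ranked_m = latent.query(ls_m, disease)
        neg_above = sum(
            1
            for other, _ in ranked_m.entries[
                : next(i for i, (m, _) in enumerate(ranked_m.entries) if m == mirna)
            ]
            if other not in positives
        )
        fraction = neg_above / n_neg if n_neg else 0.0
        if fraction > threshold:
            false_flags.append((mirna, fraction))
    return sorted(false_flags, key=lambda e: (-e[1], e[0])), novel
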