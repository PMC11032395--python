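"""Benchmark metrics: per-read scoring, L1, precision/sensitivity,
weighted UniFrac and rarefaction.

Read scoring compares each predicted annotation against ground truth at
every official rank after projecting both onto that rank; the TPR is the
fraction of correctly annotated reads among annotated reads. Profile
comparisons use four measures: the per-rank L1 distance (0 = identical,
2 = no shared taxa), binary-detection precision TP/(TP+FP) and sensitivity
TP/(TP+FN) under an abundance cut-off, and the weighted UniFrac distance —
the earth-mover's distance between the two abundance distributions placed
on the taxonomy tree, with an edge length of 1 per official-rank step.
Rarefaction subsamples reads without replacement at a ladder of fractions
and counts detected taxa, to reveal richness overestimation from spurious
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .integration import ReadAnnotation
from .profiling import TaxonomicProfile, apply_min_abundance, build_profile
from .taxonomy import EVAL_RANKS, TaxonomyTree

DEFAULT_RAREFACTION_FRACTIONS = (1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)


# ---------------------------------------------------------------------------
# per-read scoring
# ---------------------------------------------------------------------------


@dataclass
class RankScore:
    """Correct / incorrect / unannotated read counts at one rank."""

    correct: int = 0
    incorrect: int = 0
    unannotated: int = 0

    @property
    def total(self) -> int:
        return self.correct + self.incorrect + self.unannotated

    @property
    def tpr(self) -> float:
        """Correct reads per annotated read; 0 when nothing is annotated."""
        annotated = self.correct + self.incorrect
        return self.correct / annotated if annotated else 0.0

    @property
    def accuracy(self) -> float:
        """Correct reads per total read (convenience, not the TPR)."""
        return self.correct / self.total if self.total else 0.0


class ReadScoreTable(dict):
    """rank → :class:`RankScore`; tabular view via :meth:`to_frame`."""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": rank,
                "correct": s.correct,
                "incorrect": s.incorrect,
                "unannotated": s.unannotated,
                "tpr": s.tpr,
                "accuracy": s.accuracy,
            }
            for rank, s in self.items()
        ]
        return pd.DataFrame(rows)


def score_read_annotations(
    predicted: Sequence[ReadAnnotation],
    truth: Mapping[str, str],
    tree: TaxonomyTree,
    ranks: Sequence[str] = EVAL_RANKS,
) -> ReadScoreTable:
    """Score predictions against per-read truth at each rank.

    At rank r a read is *correct* when the projections of prediction and
    truth onto r both exist and agree, *incorrect* when the prediction
    projects onto r but differs, and *unannotated* when the prediction is
    unclassified or stops above r.
    """
    table = ReadScoreTable({rank: RankScore() for rank in ranks})
    for a in predicted:
        if a.read_id not in truth:
            raise ValidationError(f"read {a.read_id!r} missing from ground truth")
        true_taxon = tree.resolve(truth[a.read_id])
        pred_taxon = tree.resolve(a.taxon) if a.taxon is not None else None
        for rank in ranks:
            score = table[rank]
            pred_r = tree.taxon_at_rank(pred_taxon, rank) if pred_taxon else None
            if pred_r is None:
                score.unannotated += 1
                continue
            true_r = tree.taxon_at_rank(true_taxon, rank)
            if pred_r == true_r:
                score.correct += 1
            else:
                score.incorrect += 1
    return table


# ---------------------------------------------------------------------------
# profile distance metrics
# ---------------------------------------------------------------------------


def l1_distance(p1: TaxonomicProfile, p2: TaxonomicProfile, rank: str) -> float:
    """Sum of absolute abundance differences over the union of taxa at a rank."""
    if rank not in p1.per_rank or rank not in p2.per_rank:
        raise ValueError(f"both profiles must carry rank {rank!r}")
    a, b = p1.per_rank[rank], p2.per_rank[rank]
    return float(sum(abs(a.get(t, 0.0) - b.get(t, 0.0)) for t in set(a) | set(b)))


@dataclass(frozen=True)
class DetectionCounts:
    """Binary detection outcome at one rank: TP, FP, FN taxon counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("detection counts must be >= 0")


def detection_counts(
    predicted: TaxonomicProfile,
    reference: TaxonomicProfile,
    rank: str,
    cutoff: float = 0.0,
) -> DetectionCounts:
    """TP/FP/FN of detected taxa at a rank under an abundance cut-off.

    A taxon counts as detected when its predicted abundance is at least
    ``cutoff``; reference presence is any positive abundance.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    detected = {t for t, p in predicted.per_rank.get(rank, {}).items() if p >= cutoff and p > 0}
    present = reference.taxa(rank)
    return DetectionCounts(
        tp=len(detected & present),
        fp=len(detected - present),
        fn=len(present - detected),
    )


def precision(counts: DetectionCounts) -> float | None:
    """TP / (TP + FP); None (undefined) when nothing is detected."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else None


def sensitivity(counts: DetectionCounts) -> float | None:
    """TP / (TP + FN); None (undefined) when the reference is empty."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else None


# ---------------------------------------------------------------------------
# weighted UniFrac (tree earth-mover's distance)
# ---------------------------------------------------------------------------


def _node_masses(
    profile: TaxonomicProfile, tree: TaxonomyTree, ranks: Sequence[str]
) -> dict[str, float]:
    """Exclusive mass per taxonomy node: abundance annotated exactly there.

    The per-rank maps are nested projections (a species' reads also appear
    under its genus, family, ...), so the mass sitting *on* a node is its
    own fraction minus the fraction already accounted for by its descendants
    at the next official rank.
    """
    masses: dict[str, float] = {}
    for i, rank in enumerate(ranks):
        deeper: dict[str, float] = {}
        if i + 1 < len(ranks):
            for t, p in profile.per_rank.get(ranks[i + 1], {}).items():
                anc = tree.taxon_at_rank(t, rank)
                if anc is not None:
                    deeper[anc] = deeper.get(anc, 0.0) + p
        for t, p in profile.per_rank.get(rank, {}).items():
            m = p - deeper.get(t, 0.0)
            if m > 1e-12:
                masses[t] = masses.get(t, 0.0) + m
    return masses


def weighted_unifrac(
    p1: TaxonomicProfile,
    p2: TaxonomicProfile,
    tree: TaxonomyTree,
    ranks: Sequence[str] = EVAL_RANKS,
    tol: float = 1e-6,
) -> float:
    """Earth-mover's distance between two profiles on the taxonomy tree.

    Mass annotated at internal nodes stays on the node itself. Both
    distributions are renormalised over their classified mass (EMD needs
    equal totals); edge lengths are 1 per official-rank step, so moving
    mass between sibling species costs 2. Computed by the bottom-up
    push-to-parent scheme: traverse nodes deepest-rank first, push each
    node's signed surplus to its nearest official-rank ancestor, and
    accumulate |pushed| x rank-steps.
    """
    m1 = _node_masses(p1, tree, ranks)
    m2 = _node_masses(p2, tree, ranks)
    t1, t2 = sum(m1.values()), sum(m2.values())
    if t1 <= tol or t2 <= tol:
        if t1 <= tol and t2 <= tol:
            return 0.0
        raise ValidationError(
            "cannot compare a profile with classified mass to an empty one"
        )
    m1 = {t: m / t1 for t, m in m1.items()}
    m2 = {t: m / t2 for t, m in m2.items()}

    net: dict[str, float] = {}
    for t, m in m1.items():
        net[t] = net.get(t, 0.0) + m
    for t, m in m2.items():
        net[t] = net.get(t, 0.0) - m

    root_idx = tree.rank_index("root")
    max_idx = max((tree.official_rank_index(t) for t in net), default=0)
    cost = 0.0
    # level-by-level, deepest official rank first; pushes create entries at
    # strictly shallower levels, so each level is complete when visited
    for level in range(max_idx, root_idx, -1):
        at_level = sorted(
            t for t in net if t != tree.root and tree.official_rank_index(t) == level
        )
        for t in at_level:
            surplus = net.pop(t)
            if surplus == 0.0:
                continue
            # nearest ancestor at a strictly shallower official rank
            anc = tree.root
            anc_idx = root_idx
            for a in reversed(tree.lineage(t)[:-1]):
                a_idx = tree.official_rank_index(a)
                if a_idx < level:
                    anc, anc_idx = a, a_idx
                    break
            cost += abs(surplus) * (level - anc_idx)
            net[anc] = net.get(anc, 0.0) + surplus
    residual = abs(net.get(tree.root, 0.0))
    if residual > max(tol, 1e-6):
        raise ValidationError(f"unbalanced mass after transport: {residual}")
    return cost


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------


def rarefaction(
    read_annotations: Sequence[ReadAnnotation],
    tree: TaxonomyTree,
    rank: str,
    fractions: Sequence[float] = DEFAULT_RAREFACTION_FRACTIONS,
    repeats: int = 10,
    cutoff: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Detected-taxa counts in random read subsets of increasing size.

    ``fractions`` are percentages of the read total; each is drawn
    ``repeats`` times without replacement and the profile is rebuilt on the
    subsample's own denominator before the optional abundance cut-off.
    Returns a tidy frame with columns fraction, repeat, n_taxa.
    """
    for f in fractions:
        if not (0 < f <= 100):
            raise ValueError(f"fractions must be in (0, 100], got {f}")
    rng = np.random.default_rng(seed)
    n = len(read_annotations)
    annotations = np.asarray(read_annotations, dtype=object)
    rows = []
    for f in fractions:
        k = max(1, int(round(n * f / 100.0)))
        for rep in range(repeats):
            if k >= n:
                subset = read_annotations
            else:
                idx = rng.choice(n, size=k, replace=False)
                subset = list(annotations[idx])
            profile = build_profile(subset, tree, total_reads=len(subset), ranks=(rank,))
            if cutoff is not None:
                profile = apply_min_abundance(profile, cutoff)
            rows.append({"fraction": f, "repeat": rep, "n_taxa": len(profile.taxa(rank))})
    return pd.DataFrame(rows)
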