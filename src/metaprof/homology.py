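"""Homology-hit annotation: r-window LCA for single queries, bit-score voting
for contigs and bins.

Two primitives drive every taxon call in the workflow:

* **r-window LCA** — for one query (an ORF, a read, or a whole contig
  compared directly in protein space), keep the hits whose bit-score is
  within a fraction ``r`` of the top hit (default 0.10) and assign the
  lowest common ancestor of their subject taxa. Queries hitting several
  related organisms thus land on the ancestor they share, which for novel
  sequences is a high rank.

* **bit-score voting** — a contig's (or bin's) ORF annotations each push
  their top bit-score onto every taxon along the lineage of their LCA call.
  Scores are normalised by the total over annotated ORFs, so along any
  root→leaf path they are non-increasing and at a single rank the support
  of competing taxa sums to at most 1. The sequence is assigned the deepest
  taxon whose support strictly exceeds the majority fraction ``f``
  (default 0.5); an exact 50/50 split therefore escalates to the shared
  ancestor. Values of f below 0.5 would allow multiple winners per
  sequence and are rejected.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, UnsupportedParameterError
from .taxonomy import TaxonomyTree

DEFAULT_R = 0.10
DEFAULT_F = 0.5

#: provenance labels for sequence/read annotations, most to least reliable
SOURCES = ("mag", "contig_cat", "contig_direct", "read_direct", "unclassified")


@dataclass(frozen=True)
class Hit:
    """One homology hit: query, subject taxon, alignment bit-score."""

    query_id: str
    subject_taxon: str
    bit_score: float

    def __post_init__(self):
        if self.bit_score < 0:
            raise ValueError(f"bit_score must be >= 0, got {self.bit_score}")


@dataclass
class OrfAnnotation:
    """LCA annotation of a single ORF; ``taxon`` is None when it had no hits."""

    orf_id: str
    parent_sequence: str
    taxon: str | None
    top_bit_score: float = 0.0


@dataclass
class SequenceAnnotation:
    """Voted annotation of a contig or bin.

    ``lineage_scores`` maps each taxon on the chosen lineage to its support
    fraction; ``support`` is the fraction at the assigned taxon. ``taxon``
    is None when no member ORF had any hit.
    """

    sequence_id: str
    taxon: str | None
    support: float
    lineage_scores: dict[str, float] = field(default_factory=dict)
    source: str = "contig_cat"


@dataclass(frozen=True)
class AnnotationParams:
    """Hit-window fraction r and majority fraction f."""

    r: float = DEFAULT_R
    f: float = DEFAULT_F

    def __post_init__(self):
        if not (0 < self.r <= 1):
            raise UnsupportedParameterError(f"r must be in (0, 1], got {self.r}")
        if not (0.5 <= self.f < 1):
            raise UnsupportedParameterError(
                f"f values < 0.5 are not supported (and f must be < 1); got {self.f}"
            )


def filter_hits_by_r(hits: Sequence[Hit], r: float = DEFAULT_R) -> list[Hit]:
    """Hits within fraction ``r`` of the top bit-score (boundary inclusive).

    The top hit is always retained; ties with the top hit are never dropped.
    """
    if not hits:
        raise ValueError("filter_hits_by_r requires a non-empty hit list")
    top = max(h.bit_score for h in hits)
    threshold = (1.0 - r) * top
    return [h for h in hits if h.bit_score >= threshold]


def annotate_query_lca(
    hits: Sequence[Hit], r: float, tree: TaxonomyTree
) -> str | None:
    """LCA of the subject taxa of the r-filtered hits; None for no hits."""
    if not hits:
        return None
    kept = filter_hits_by_r(hits, r)
    return tree.lca({tree.resolve(h.subject_taxon) for h in kept})


def vote_sequence(
    sequence_id: str,
    orf_annotations: Iterable[OrfAnnotation],
    f: float,
    tree: TaxonomyTree,
    source: str = "contig_cat",
) -> SequenceAnnotation:
    """Assign a contig/bin by bit-score voting over its ORF annotations.

    Each annotated ORF contributes its top bit-score to every taxon on the
    lineage of its LCA call; support fractions are these sums divided by
    the total top-score over annotated ORFs. The assigned taxon is the
    deepest one with support strictly greater than ``f``; when no taxon
    below the root exceeds f the sequence stays at the root. ORFs without
    hits are excluded from the denominator; a sequence whose ORFs all lack
    hits gets ``taxon=None``.
    """
    if f < 0.5:
        raise UnsupportedParameterError(
            f"f values < 0.5 are not supported, got {f}"
        )
    annotated = [o for o in orf_annotations if o.taxon is not None]
    if not annotated:
        return SequenceAnnotation(sequence_id, None, 0.0, {}, source)

    total = sum(o.top_bit_score for o in annotated)
    if total <= 0:
        raise ValueError(f"total bit-score for {sequence_id!r} is not positive")
    scores: dict[str, float] = {}
    for o in annotated:
        for tid in tree.lineage(o.taxon):
            scores[tid] = scores.get(tid, 0.0) + o.top_bit_score
    for tid in scores:
        scores[tid] /= total

    # descend from the root along the (unique, since f >= 0.5 and support is
    # strict) chain of children whose support exceeds f
    current = tree.root
    while True:
        winners = [c for c in tree.children(current) if scores.get(c, 0.0) > f]
        if not winners:
            break
        current = max(winners, key=lambda c: (scores[c], c))
    lineage_scores = {tid: scores[tid] for tid in tree.lineage(current)}
    return SequenceAnnotation(sequence_id, current, scores[current], lineage_scores, source)


def annotate_mag(
    bin_id: str,
    orf_annotations: Iterable[OrfAnnotation],
    f: float,
    tree: TaxonomyTree,
) -> SequenceAnnotation:
    """Vote over the pooled ORF annotations of all contigs in one bin."""
    orfs = list(orf_annotations)
    if not orfs:
        raise ValueError(f"bin {bin_id!r} has no member ORFs")
    return vote_sequence(bin_id, orfs, f, tree, source="mag")


# ---------------------------------------------------------------------------
# hit-table I/O and grouping helpers
# ---------------------------------------------------------------------------

_ORF_SUFFIX = re.compile(r"_\d+$")


def orf_parent(orf_id: str) -> str:
    """Parent contig of an ORF named by the ``<contig_id>_<n>`` convention."""
    return _ORF_SUFFIX.sub("", orf_id)


def read_hit_table(path: str | os.PathLike) -> dict[str, list[Hit]]:
    """Read a DIAMOND-tabular-style TSV into hits grouped by query.

    Columns: query_id, subject_taxon_id, bit_score. A header row is
    detected by a non-numeric third column; ``#`` comment lines are ignored.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] < 3:
        raise ParseError(f"hit table {path} has {df.shape[1]} columns, expected >= 3")
    df = df.iloc[:, :3]
    df.columns = ["query_id", "subject_taxon_id", "bit_score"]
    # header row? third column not parseable as a number
    try:
        float(df.iloc[0, 2])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    hits: dict[str, list[Hit]] = {}
    for q, s, b in df.itertuples(index=False):
        try:
            score = float(b)
        except (ValueError, TypeError):
            raise ParseError(f"bit-score {b!r} for query {q!r} is not numeric") from None
        hits.setdefault(str(q), []).append(Hit(str(q), str(s), score))
    return hits


def read_orf2contig(path: str | os.PathLike) -> dict[str, str]:
    """Explicit ORF→contig map (2-column TSV), overriding the id convention."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"orf2contig table {path} needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def annotate_orfs(
    orf_hits: Mapping[str, Sequence[Hit]],
    r: float,
    tree: TaxonomyTree,
    orf2contig: Mapping[str, str] | None = None,
) -> list[OrfAnnotation]:
    """Per-ORF r-window LCA annotation for a whole hit table."""
    out = []
    for orf_id in sorted(orf_hits):
        hits = orf_hits[orf_id]
        parent = orf2contig[orf_id] if orf2contig else orf_parent(orf_id)
        taxon = annotate_query_lca(hits, r, tree)
        top = max((h.bit_score for h in hits), default=0.0)
        out.append(OrfAnnotation(orf_id, parent, taxon, top))
    return out


def annotate_queries_direct(
    query_hits: Mapping[str, Sequence[Hit]], r: float, tree: TaxonomyTree
) -> dict[str, str]:
    """Direct (no ORF calling) r-window LCA per query; queries without hits
    are omitted from the result."""
    out: dict[str, str] = {}
    for q in sorted(query_hits):
        taxon = annotate_query_lca(query_hits[q], r, tree)
        if taxon is not None:
            out[q] = taxon
    return out
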