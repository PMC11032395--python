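"""Glue running the full annotation workflow on in-memory inputs.

Stages: filter/assign read mappings → per-ORF LCA annotation → contig and
bin voting → direct contig/read LCA annotation → priority integration →
per-rank profile. Used by the CLI, the test-suite and the acceptance
script; each stage is also callable on its own through the underlying
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .homology import (
    Hit,
    OrfAnnotation,
    SequenceAnnotation,
    annotate_mag,
    annotate_orfs,
    annotate_queries_direct,
    vote_sequence,
)
from .integration import ReadAnnotation, filter_and_assign_mappings, integrate, source_counts
from .profiling import TaxonomicProfile, build_profile
from .taxonomy import TaxonomyTree


@dataclass
class PipelineResult:
    """All intermediate and final outputs of one integrated run."""

    read_annotations: list[ReadAnnotation]
    profile: TaxonomicProfile
    assignment: dict[str, str]
    mag_annotations: dict[str, SequenceAnnotation]
    contig_annotations: dict[str, SequenceAnnotation]
    contig_direct: dict[str, str]
    read_direct: dict[str, str]
    source_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    tree: TaxonomyTree,
    read_ids: Sequence[str],
    mappings,
    bin_map: Mapping[str, str],
    orf_hits: Mapping[str, Sequence[Hit]],
    contig_hits: Mapping[str, Sequence[Hit]] | None = None,
    read_hits: Mapping[str, Sequence[Hit]] | None = None,
    orf2contig: Mapping[str, str] | None = None,
    mode: str = "mcr",
    r: float = 0.10,
    f: float = 0.5,
    min_mapq: int = 2,
    seed: int = 0,
) -> PipelineResult:
    """Run mapping-filter → annotation → voting → integration → profile."""
    assignment = filter_and_assign_mappings(mappings, min_mapq=min_mapq, seed=seed)

    orf_annotations = annotate_orfs(orf_hits, r, tree, orf2contig)
    by_contig: dict[str, list[OrfAnnotation]] = {}
    for o in orf_annotations:
        by_contig.setdefault(o.parent_sequence, []).append(o)

    contig_annotations = {
        cid: vote_sequence(cid, orfs, f, tree) for cid, orfs in sorted(by_contig.items())
    }

    by_bin: dict[str, list[OrfAnnotation]] = {}
    for cid, bin_id in bin_map.items():
        for o in by_contig.get(cid, []):
            by_bin.setdefault(bin_id, []).append(o)
    mag_annotations = {
        bid: annotate_mag(bid, orfs, f, tree) for bid, orfs in sorted(by_bin.items())
    }

    # direct protein-space annotation only backs up contigs the voting
    # stage could not annotate, and unmapped reads
    contig_direct: dict[str, str] = {}
    if contig_hits:
        unannotated = {
            cid: hits for cid, hits in contig_hits.items()
            if contig_annotations.get(cid) is None or contig_annotations[cid].taxon is None
        }
        contig_direct = annotate_queries_direct(unannotated, r, tree)
    read_direct = annotate_queries_direct(read_hits, r, tree) if read_hits else {}

    annotations = integrate(
        read_ids, assignment, bin_map, mag_annotations, contig_annotations,
        contig_direct, read_direct, mode=mode,
    )
    profile = build_profile(annotations, tree, total_reads=len(read_ids))
    return PipelineResult(
        annotations, profile, assignment, mag_annotations, contig_annotations,
        contig_direct, read_direct, source_counts(annotations),
    )


def run_on_dataset(ds, mode: str = "mcr", r: float = 0.10, f: float = 0.5,
                   min_mapq: int = 2, seed: int | None = None) -> PipelineResult:
    """Convenience wrapper for a :class:`~metaprof.simulate.SimulatedDataset`."""
    if seed is None:
        seed = ds.config.seed
    return run_pipeline(
        ds.tree, ds.read_ids, ds.mappings, ds.bin_map, ds.orf_hits,
        ds.contig_hits, ds.read_hits, ds.orf2contig,
        mode=mode, r=r, f=f, min_mapq=min_mapq, seed=seed,
    )
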