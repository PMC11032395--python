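"""Per-read signal integration: MAG > contig > direct read, or unclassified.

Each read inherits the most reliable taxonomic signal available to it:

1. ``mag`` — the read maps to a binned contig and the bin is annotated;
2. ``contig_cat`` — the read maps to a contig with an ORF-voting annotation;
3. ``contig_direct`` — the contig lacks a voting annotation but was
   annotated directly in protein space;
4. ``read_direct`` — the read is unmapped (or its contig is unannotated)
   and has its own direct annotation;
5. ``unclassified`` — no signal at all.

Mode ``mc`` drops the two direct signals (3, 4); mode ``cr`` ignores MAG
annotations. Mappings are pre-filtered to primary records with MAPQ at or
above a threshold (default 2); among surviving mappings of one read the
highest MAPQ wins, with equal-MAPQ ties broken by a seeded random draw.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ParseError, ValidationError
from .homology import SequenceAnnotation
from .taxonomy import TaxonomyTree

MODES = ("mcr", "mc", "cr")
DEFAULT_MIN_MAPQ = 2


@dataclass(frozen=True)
class ReadMapping:
    """One read-to-contig mapping record."""

    read_id: str
    contig_id: str
    is_primary: bool = True
    mapq: int = 0

    def __post_init__(self):
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass(frozen=True)
class ReadAnnotation:
    """Final taxon call for one read with its provenance label."""

    read_id: str
    taxon: str | None
    source: str

    def __post_init__(self):
        if (self.taxon is None) != (self.source == "unclassified"):
            raise ValidationError(
                f"read {self.read_id!r}: taxon is None iff source is 'unclassified'"
            )


# ---------------------------------------------------------------------------
# mapping I/O
# ---------------------------------------------------------------------------


def read_mappings_tsv(path: str | os.PathLike) -> list[ReadMapping]:
    """4-column TSV dialect: read_id, contig_id, is_primary (0/1), mapq."""
    out: list[ReadMapping] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"expected 4 columns, got {len(parts)}", line=i)
            try:
                out.append(
                    ReadMapping(parts[0], parts[1], parts[2] == "1", int(parts[3]))
                )
            except ValueError as e:
                raise ParseError(str(e), line=i) from None
    return out


def read_mappings_sam(path: str | os.PathLike) -> list[ReadMapping]:
    """Read mappings from a SAM file (primary flag and MAPQ honoured)."""
    out: list[ReadMapping] = []
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            primary = not (rec.is_secondary or rec.is_supplementary)
            out.append(
                ReadMapping(rec.query_name, rec.reference_name, primary, rec.mapping_quality)
            )
    return out


def read_bin_map(path: str | os.PathLike) -> dict[str, str]:
    """2-column TSV contig_id → bin_id; a contig may belong to one bin only."""
    bins: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"expected 2 columns, got {len(parts)}", line=i)
            contig, bin_id = parts[0], parts[1]
            if contig in bins and bins[contig] != bin_id:
                raise ValidationError(
                    f"contig {contig!r} assigned to two bins: {bins[contig]!r}, {bin_id!r}"
                )
            bins[contig] = bin_id
    return bins


# ---------------------------------------------------------------------------
# mapping filter + assignment
# ---------------------------------------------------------------------------


def filter_and_assign_mappings(
    mappings: Iterable[ReadMapping],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    seed: int = 0,
) -> dict[str, str]:
    """One contig per read from its surviving mappings.

    Secondary/supplementary records and primaries with MAPQ below
    ``min_mapq`` are dropped first; then the highest-MAPQ mapping wins and
    equal-MAPQ ties are broken by a seeded random draw. Reads with no
    surviving mapping are absent from the result.
    """
    rng = np.random.default_rng(seed)
    surviving: dict[str, list[ReadMapping]] = {}
    for m in mappings:
        if not m.is_primary or m.mapq < min_mapq:
            continue
        surviving.setdefault(m.read_id, []).append(m)

    assignment: dict[str, str] = {}
    for read_id in sorted(surviving):
        ms = surviving[read_id]
        best = max(m.mapq for m in ms)
        # sort for a stable candidate order before the seeded draw
        candidates = sorted(m.contig_id for m in ms if m.mapq == best)
        if len(candidates) == 1:
            assignment[read_id] = candidates[0]
        else:
            assignment[read_id] = candidates[int(rng.integers(len(candidates)))]
    return assignment


# ---------------------------------------------------------------------------
# integration cascade
# ---------------------------------------------------------------------------


def _taxon_of(obj) -> str | None:
    return obj.taxon if isinstance(obj, SequenceAnnotation) else obj


def integrate(
    read_ids: Iterable[str],
    assignment: Mapping[str, str],
    bin_map: Mapping[str, str],
    mag_annotations: Mapping[str, SequenceAnnotation | str | None],
    contig_cat_annotations: Mapping[str, SequenceAnnotation | str | None],
    contig_direct_annotations: Mapping[str, str | None] | None = None,
    read_direct_annotations: Mapping[str, str | None] | None = None,
    mode: str = "mcr",
) -> list[ReadAnnotation]:
    """Assign every read its highest-priority available annotation.

    Annotation maps may hold plain taxon ids or :class:`SequenceAnnotation`
    objects; entries whose taxon is None count as unannotated and the read
    falls through to the next signal. Every read in ``read_ids`` appears
    exactly once in the output.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    contig_direct_annotations = contig_direct_annotations or {}
    read_direct_annotations = read_direct_annotations or {}
    use_direct = mode in ("mcr", "cr")
    use_mags = mode in ("mcr", "mc")

    out: list[ReadAnnotation] = []
    for read_id in read_ids:
        taxon: str | None = None
        source = "unclassified"
        contig = assignment.get(read_id)
        if contig is not None:
            if use_mags:
                bin_id = bin_map.get(contig)
                if bin_id is not None:
                    t = _taxon_of(mag_annotations.get(bin_id))
                    if t is not None:
                        taxon, source = t, "mag"
            if taxon is None:
                t = _taxon_of(contig_cat_annotations.get(contig))
                if t is not None:
                    taxon, source = t, "contig_cat"
            if taxon is None and use_direct:
                t = contig_direct_annotations.get(contig)
                if t is not None:
                    taxon, source = t, "contig_direct"
        if taxon is None and use_direct:
            t = read_direct_annotations.get(read_id)
            if t is not None:
                taxon, source = t, "read_direct"
        out.append(ReadAnnotation(read_id, taxon, source))
    return out


def source_counts(annotations: Sequence[ReadAnnotation]) -> dict[str, int]:
    """Read counts per provenance label (for run logs)."""
    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.source] = counts.get(a.source, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# per-read annotation I/O
# ---------------------------------------------------------------------------


def write_read_annotations(
    annotations: Sequence[ReadAnnotation],
    path: str | os.PathLike,
    tree: TaxonomyTree | None = None,
) -> None:
    """TSV: read_id, source, taxon_id, root-to-taxon lineage string."""
    with open(path, "w") as fh:
        fh.write("read_id\tsource\ttaxon_id\tlineage\n")
        for a in annotations:
            lineage = ""
            if a.taxon is not None and tree is not None:
                lineage = ";".join(tree.lineage(a.taxon))
            fh.write(f"{a.read_id}\t{a.source}\t{a.taxon or ''}\t{lineage}\n")


def read_read_annotations(path: str | os.PathLike) -> list[ReadAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"read_id", "source", "taxon_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"annotation table {path} lacks columns {sorted(required)}")
    return [
        ReadAnnotation(r.read_id, r.taxon_id or None, r.source)
        for r in df.itertuples(index=False)
    ]
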