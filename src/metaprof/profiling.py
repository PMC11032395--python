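"""Per-rank taxonomic profiles built from read annotations.

A profile stores, at each official rank, the fraction of all sequenced
reads assigned to each taxon (sequence abundance), plus the fraction of
fully unclassified reads. A read annotated above a rank contributes to
neither a taxon nor the unclassified bucket at that rank, so the classified
fraction shrinks with depth. The per-rank minimum-abundance cut-off
(default 0.001%) removes rare taxa independently at each rank: a species
below the cut-off can still contribute at the genus rank through its genus.

Profiles are written in a bioboxes/CAMI-style columnar format (taxon id,
rank, lineage id path, lineage name path, percentage) with extra header
lines carrying the read total and per-rank unclassified percentages so the
round-trip is lossless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ParseError, TaxonNotFoundError, ValidationError
from .integration import ReadAnnotation
from .taxonomy import EVAL_RANKS, TaxonomyTree

DEFAULT_MIN_ABUNDANCE = 1e-5  # 0.001 %


@dataclass
class TaxonomicProfile:
    """Per-rank relative-abundance map plus unclassified fractions."""

    total_reads: int
    per_rank: dict[str, dict[str, float]]
    unclassified: dict[str, float] = field(default_factory=dict)
    ranks: tuple[str, ...] = EVAL_RANKS

    def __post_init__(self):
        self.ranks = tuple(self.ranks)
        for rank in self.ranks:
            self.per_rank.setdefault(rank, {})
            self.unclassified.setdefault(rank, 0.0)
        self.validate()

    def validate(self) -> None:
        for rank in self.ranks:
            total = 0.0
            for taxon, frac in self.per_rank[rank].items():
                if not (0.0 <= frac <= 1.0):
                    raise ValidationError(
                        f"fraction {frac} for taxon {taxon!r} at rank {rank!r} outside [0, 1]"
                    )
                total += frac
            uncl = self.unclassified[rank]
            if not (0.0 <= uncl <= 1.0):
                raise ValidationError(f"unclassified fraction {uncl} at {rank!r} outside [0, 1]")
            if total + uncl > 1.0 + 1e-9:
                raise ValidationError(
                    f"fractions at rank {rank!r} sum to {total + uncl:.12f} > 1"
                )

    def classified_fraction(self, rank: str) -> float:
        return sum(self.per_rank[rank].values())

    def taxa(self, rank: str) -> set[str]:
        return {t for t, p in self.per_rank[rank].items() if p > 0}


def build_profile(
    read_annotations: Sequence[ReadAnnotation],
    tree: TaxonomyTree,
    total_reads: int | None = None,
    ranks: Sequence[str] = EVAL_RANKS,
) -> TaxonomicProfile:
    """Count reads per taxon at each official rank and normalise.

    Each annotated read contributes, at rank r, to the projection of its
    taxon onto r (nothing when its annotation stops above r). The
    denominator is the total number of sequenced reads, which defaults to
    the number of annotation records.
    """
    n = len(read_annotations)
    if total_reads is None:
        total_reads = n
    if total_reads < n:
        raise ValidationError(
            f"total_reads ({total_reads}) is less than the number of annotation records ({n})"
        )
    counts: dict[str, dict[str, int]] = {rank: {} for rank in ranks}
    n_unclassified = 0
    for a in read_annotations:
        if a.taxon is None:
            n_unclassified += 1
            continue
        resolved = tree.resolve(a.taxon)  # raises TaxonNotFoundError on stale ids
        for rank in ranks:
            t = tree.taxon_at_rank(resolved, rank)
            if t is not None:
                c = counts[rank]
                c[t] = c.get(t, 0) + 1
    per_rank = {
        rank: {t: c / total_reads for t, c in counts[rank].items()}
        for rank in ranks
    }
    uncl = {rank: n_unclassified / total_reads for rank in ranks}
    return TaxonomicProfile(total_reads, per_rank, uncl, tuple(ranks))


def apply_min_abundance(
    profile: TaxonomicProfile, cutoff: float = DEFAULT_MIN_ABUNDANCE
) -> TaxonomicProfile:
    """Drop taxa below ``cutoff`` at each rank independently.

    Other ranks are untouched: a species removed here can still be counted
    at the genus rank through its genus entry.
    """
    if not (0.0 <= cutoff < 1.0):
        raise ValueError(f"cutoff must be in [0, 1), got {cutoff}")
    per_rank = {
        rank: {t: p for t, p in taxa.items() if p >= cutoff}
        for rank, taxa in profile.per_rank.items()
    }
    return TaxonomicProfile(
        profile.total_reads, per_rank, dict(profile.unclassified), profile.ranks
    )


# ---------------------------------------------------------------------------
# genome-size normalisation (sequence → taxonomic abundance)
# ---------------------------------------------------------------------------


def read_genome_sizes(path: str | os.PathLike) -> dict[str, float]:
    """2-column TSV taxon_id → weighted mean genome size (bases)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"genome-size table {path} needs 2 columns")
    sizes: dict[str, float] = {}
    for tid, size in zip(df.iloc[:, 0], df.iloc[:, 1]):
        s = float(size)
        if s <= 0:
            raise ValidationError(f"genome size for taxon {tid!r} must be > 0, got {s}")
        sizes[str(tid)] = s
    return sizes


def _size_for(taxon: str, sizes: Mapping[str, float], tree: TaxonomyTree | None) -> float | None:
    if taxon in sizes:
        return sizes[taxon]
    if tree is not None and taxon in tree:
        for anc in reversed(tree.lineage(taxon)[:-1]):
            if anc in sizes:
                return sizes[anc]
    return None


def to_taxonomic_abundance(
    profile: TaxonomicProfile,
    sizes: Mapping[str, float],
    tree: TaxonomyTree | None = None,
) -> TaxonomicProfile:
    """Convert sequence abundance to genome-copy (taxonomic) abundance.

    Per rank, each fraction is divided by the taxon's weighted mean genome
    size (falling back to the nearest ancestor with a size entry when a
    tree is supplied) and the result rescaled so the retained mass at that
    rank is unchanged. Uniform size scaling therefore leaves the profile
    untouched.
    """
    missing = []
    per_rank: dict[str, dict[str, float]] = {}
    for rank, taxa in profile.per_rank.items():
        mass = sum(taxa.values())
        weighted: dict[str, float] = {}
        for t, p in taxa.items():
            size = _size_for(t, sizes, tree)
            if size is None:
                missing.append((rank, t))
                continue
            weighted[t] = p / size
        wsum = sum(weighted.values())
        if wsum > 0:
            per_rank[rank] = {t: w * mass / wsum for t, w in weighted.items()}
        else:
            per_rank[rank] = {}
    if missing:
        offenders = ", ".join(f"{t} ({rank})" for rank, t in missing[:20])
        raise ValidationError(
            f"no genome size on any ancestor for {len(missing)} taxa: {offenders}"
        )
    return TaxonomicProfile(
        profile.total_reads, per_rank, dict(profile.unclassified), profile.ranks
    )


# ---------------------------------------------------------------------------
# profile I/O (CAMI-style columns + lossless extras)
# ---------------------------------------------------------------------------


def write_profile(
    profile: TaxonomicProfile,
    path: str | os.PathLike,
    tree: TaxonomyTree | None = None,
    sample_id: str = "sample",
) -> None:
    """Write a profile in CAMI-profiling-style columns.

    Header ``@`` lines carry the sample id, rank list, total read count and
    per-rank unclassified percentages; data rows are taxon id, rank,
    lineage id path, lineage name path, percentage (0–100).
    """
    with open(path, "w") as fh:
        fh.write(f"@SampleID:{sample_id}\n")
        fh.write("@Version:0.10.0\n")
        fh.write("@Ranks:" + "|".join(profile.ranks) + "\n")
        fh.write(f"@TotalReads:{profile.total_reads}\n")
        uncl = "|".join(
            f"{rank}:{profile.unclassified[rank] * 100:.10g}" for rank in profile.ranks
        )
        fh.write(f"@Unclassified:{uncl}\n")
        fh.write("@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n")
        for rank in profile.ranks:
            for taxon in sorted(profile.per_rank[rank]):
                frac = profile.per_rank[rank][taxon]
                taxpath = taxpathsn = ""
                if tree is not None and taxon in tree:
                    lin = tree.lineage(taxon)[1:]  # drop the root, CAMI-style
                    taxpath = "|".join(lin)
                    taxpathsn = "|".join(tree.name(t) or t for t in lin)
                fh.write(f"{taxon}\t{rank}\t{taxpath}\t{taxpathsn}\t{frac * 100:.10g}\n")


def read_profile(path: str | os.PathLike) -> TaxonomicProfile:
    """Read a profile written by :func:`write_profile` (lossless round-trip)."""
    ranks: tuple[str, ...] = EVAL_RANKS
    total_reads = 0
    unclassified: dict[str, float] = {}
    per_rank: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("@@"):
                continue
            if line.startswith("@"):
                key, _, value = line[1:].partition(":")
                if key == "Ranks":
                    ranks = tuple(value.split("|"))
                elif key == "TotalReads":
                    total_reads = int(value)
                elif key == "Unclassified":
                    for part in value.split("|"):
                        if not part:
                            continue
                        rank, _, pct = part.partition(":")
                        unclassified[rank] = float(pct) / 100.0
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"expected 5 columns, got {len(parts)}", line=i)
            taxon, rank, _taxpath, _taxpathsn, pct = parts
            try:
                frac = float(pct) / 100.0
            except ValueError:
                raise ParseError(f"percentage {pct!r} is not numeric", line=i) from None
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"line {i}: fraction {frac} outside [0, 1]")
            per_rank.setdefault(rank, {})[taxon] = frac
    return TaxonomicProfile(total_reads, per_rank, unclassified, ranks)
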