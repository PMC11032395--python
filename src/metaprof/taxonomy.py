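"""Reference taxonomy: loading, lineage, rank projection and LCA queries.

The taxonomy is a rooted tree of taxa. Official ranks are ordered root →
superkingdom (NCBI) / domain (GTDB) → phylum → class → order → family →
genus → species; nodes with non-official ranks ("no rank", strain, genome
accessions below species) may interleave on any path and are retained in
the tree but skipped by rank projection. Exactly one node is its own
parent: the root.

Two loaders are provided: the NCBI taxdump dialect (nodes.dmp / names.dmp /
merged.dmp with ``\\t|\\t`` field separators) and the GTDB two-column TSV of
genome accession → seven-rank prefixed lineage string. Both produce the
same :class:`TaxonomyTree`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ParseError, TaxonNotFoundError, TaxonomyError

#: Official rank vocabulary, root-first. NCBI "superkingdom" and GTDB
#: "domain" share the same slot so profiles from either taxonomy live on
#: one rank axis.
OFFICIAL_RANKS: tuple[str, ...] = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: The six ranks at which profiles are evaluated.
EVAL_RANKS: tuple[str, ...] = OFFICIAL_RANKS[2:]

_GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
_GTDB_RANKS = ("superkingdom",) + EVAL_RANKS

ROOT_ID = "1"


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: id, parent id (self for the root), rank label, display name."""

    taxon_id: str
    parent_id: str
    rank: str = "no rank"
    name: str = ""


class TaxonomyTree:
    """Rooted, rank-labelled taxonomy supporting lineage / LCA / rank queries.

    Parameters
    ----------
    nodes
        All taxa, keyed or iterable; exactly one must satisfy
        ``parent_id == taxon_id`` (the root).
    merged
        Optional map of retired taxon ids to their current replacement;
        lookups remap transparently.
    rank_order
        Ordered official rank vocabulary; defaults to :data:`OFFICIAL_RANKS`.
    """

    def __init__(
        self,
        nodes: Iterable[TaxonNode] | Mapping[str, TaxonNode],
        merged: Mapping[str, str] | None = None,
        rank_order: tuple[str, ...] = OFFICIAL_RANKS,
    ):
        if isinstance(nodes, Mapping):
            self.nodes: dict[str, TaxonNode] = dict(nodes)
        else:
            self.nodes = {n.taxon_id: n for n in nodes}
        self.merged: dict[str, str] = dict(merged or {})
        self.rank_order = tuple(rank_order)
        self._rank_index = {r: i for i, r in enumerate(self.rank_order)}
        self._children: dict[str, list[str]] | None = None
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        roots = [n.taxon_id for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise TaxonomyError(
                f"taxonomy must have exactly one root (parent == self); found {len(roots)}"
            )
        self.root = roots[0]
        for n in self.nodes.values():
            if n.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"node {n.taxon_id!r} has parent {n.parent_id!r} absent from the taxonomy"
                )
        # acyclicity: every node must reach the root
        seen_ok: set[str] = {self.root}
        for tid in self.nodes:
            path = []
            cur = tid
            while cur not in seen_ok:
                path.append(cur)
                cur = self.nodes[cur].parent_id
                if cur in path:
                    raise TaxonomyError(f"cycle in taxonomy involving node {cur!r}")
            seen_ok.update(path)

    # -- basic queries -------------------------------------------------------

    def resolve(self, taxon_id: str) -> str:
        """Canonical id for ``taxon_id``, following the merged-id map."""
        tid = str(taxon_id)
        if tid in self.nodes:
            return tid
        if tid in self.merged:
            new = self.merged[tid]
            if new in self.nodes:
                return new
        raise TaxonNotFoundError(tid)

    def __contains__(self, taxon_id: str) -> bool:
        try:
            self.resolve(taxon_id)
            return True
        except TaxonNotFoundError:
            return False

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        return self.nodes[self.resolve(taxon_id)]

    def parent(self, taxon_id: str) -> str:
        return self.nodes[self.resolve(taxon_id)].parent_id

    def children(self, taxon_id: str) -> list[str]:
        if self._children is None:
            ch: dict[str, list[str]] = {tid: [] for tid in self.nodes}
            for n in self.nodes.values():
                if n.parent_id != n.taxon_id:
                    ch[n.parent_id].append(n.taxon_id)
            self._children = ch
        return self._children[self.resolve(taxon_id)]

    def name(self, taxon_id: str) -> str:
        return self.node(taxon_id).name

    def rank(self, taxon_id: str) -> str:
        return self.node(taxon_id).rank

    def rank_index(self, rank: str) -> int:
        try:
            return self._rank_index[rank]
        except KeyError:
            raise ValueError(f"unknown rank label: {rank!r}") from None

    # -- lineage / LCA / rank projection ------------------------------------

    def lineage(self, taxon_id: str) -> list[str]:
        """Root-first path of taxon ids from the root to ``taxon_id``."""
        cur = self.resolve(taxon_id)
        path = [cur]
        while cur != self.root:
            cur = self.nodes[cur].parent_id
            path.append(cur)
        path.reverse()
        return path

    def depth(self, taxon_id: str) -> int:
        """Number of edges from the root (root has depth 0)."""
        return len(self.lineage(taxon_id)) - 1

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxon ids."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca requires at least one taxon id")
        paths = [self.lineage(t) for t in taxa]
        anc = self.root
        for level in zip(*paths):
            first = level[0]
            if any(t != first for t in level[1:]):
                break
            anc = first
        return anc

    def taxon_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor-or-self of ``taxon_id`` at an official ``rank``.

        Returns ``None`` when the lineage does not reach that rank
        (annotation above the queried rank). Non-official nodes on the
        lineage are skipped.
        """
        if rank not in self._rank_index:
            raise ValueError(f"unknown rank label: {rank!r}")
        for tid in self.lineage(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def official_rank_index(self, taxon_id: str) -> int:
        """Rank-order index of the deepest official rank on the node's lineage.

        A node with a non-official rank inherits the index of its nearest
        official ancestor (the root at worst).
        """
        idx = 0
        for tid in self.lineage(taxon_id):
            r = self.nodes[tid].rank
            if r in self._rank_index:
                idx = self._rank_index[r]
        return idx


# ---------------------------------------------------------------------------
# NCBI taxdump dialect
# ---------------------------------------------------------------------------


def _dmp_fields(line: str) -> list[str]:
    # records end with "\t|"; fields separated by "\t|\t"
    return line.rstrip("\r\n").rstrip("|").rstrip("\t").split("\t|\t")


def load_ncbi_taxonomy(
    nodes_path: str | os.PathLike,
    names_path: str | os.PathLike | None = None,
    merged_path: str | os.PathLike | None = None,
) -> TaxonomyTree:
    """Load a taxonomy from NCBI-style nodes.dmp / names.dmp / merged.dmp.

    ``names.dmp`` is optional; when several name classes exist for a taxon
    the "scientific name" entry wins. ``merged.dmp`` rows make retired ids
    transparently resolvable.
    """
    raw: dict[str, tuple[str, str]] = {}
    with open(nodes_path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _dmp_fields(line)
            if len(f) < 3:
                raise ParseError(f"nodes.dmp record has {len(f)} fields, expected >= 3", line=i)
            raw[f[0]] = (f[1], f[2])

    names: dict[str, str] = {}
    if names_path is not None:
        with open(names_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                f = _dmp_fields(line)
                if len(f) < 4:
                    continue
                tid, name, name_class = f[0], f[1], f[3]
                if name_class == "scientific name" or tid not in names:
                    names[tid] = name

    merged: dict[str, str] = {}
    if merged_path is not None:
        with open(merged_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                f = _dmp_fields(line)
                if len(f) >= 2:
                    merged[f[0]] = f[1]

    nodes = [
        TaxonNode(tid, parent, rank, names.get(tid, ""))
        for tid, (parent, rank) in raw.items()
    ]
    return TaxonomyTree(nodes, merged=merged)


def write_ncbi_taxonomy(tree: TaxonomyTree, out_dir: str | os.PathLike) -> None:
    """Serialize a tree back to nodes.dmp / names.dmp / merged.dmp (round-trip)."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "nodes.dmp"), "w") as fh:
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(f"{n.taxon_id}\t|\t{n.parent_id}\t|\t{n.rank}\t|\n")
    with open(os.path.join(out_dir, "names.dmp"), "w") as fh:
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            if n.name:
                fh.write(f"{n.taxon_id}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")
    with open(os.path.join(out_dir, "merged.dmp"), "w") as fh:
        for old in sorted(tree.merged):
            fh.write(f"{old}\t|\t{tree.merged[old]}\t|\n")


# ---------------------------------------------------------------------------
# GTDB taxonomy TSV
# ---------------------------------------------------------------------------


def load_gtdb_taxonomy(tsv_path: str | os.PathLike) -> TaxonomyTree:
    """Load a GTDB taxonomy TSV (genome accession → 7-rank lineage string).

    One node is created per distinct prefixed name per rank, parented by the
    preceding rank's node; genome accessions attach as leaves below species.
    GTDB's domains become children of a single synthetic root so LCA across
    domains is defined.
    """
    nodes: dict[str, TaxonNode] = {
        ROOT_ID: TaxonNode(ROOT_ID, ROOT_ID, "root", "root")
    }
    with open(tsv_path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(parts)}", line=i
                )
            accession, lineage_str = parts
            fields = lineage_str.split(";")
            if len(fields) != 7:
                raise ParseError(
                    f"expected 7 semicolon-separated rank fields, got {len(fields)}",
                    line=i,
                )
            parent = ROOT_ID
            for fld, prefix, rank in zip(fields, _GTDB_PREFIXES, _GTDB_RANKS):
                fld = fld.strip()
                if not fld.startswith(prefix):
                    raise ParseError(
                        f"rank field {fld!r} does not start with expected prefix {prefix!r}",
                        line=i,
                    )
                existing = nodes.get(fld)
                if existing is not None:
                    if existing.parent_id != parent:
                        raise ParseError(
                            f"taxon {fld!r} appears with two different parents", line=i
                        )
                else:
                    nodes[fld] = TaxonNode(fld, parent, rank, fld[len(prefix):])
                parent = fld
            nodes[accession] = TaxonNode(accession, parent, "no rank", accession)
    return TaxonomyTree(nodes)
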