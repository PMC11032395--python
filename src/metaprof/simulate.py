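"""Seeded synthetic communities with full ground truth.

The simulator emulates the shape of a simulated-benchmark evaluation: a
random rank-complete taxonomy, a log-normal species abundance profile,
reads drawn from that profile, a configurable share of reads assembled
into (pure, per-species) contigs, a share of those contigs binned, and
homology hit tables for ORFs, contigs and reads. Noise enters in two ways:

* ``hit_noise`` — a direct read hit's subject is drawn from an unrelated
  clade with this probability, emulating spurious short-read annotations;
* ``novel_fraction`` — this share of species is treated as absent from the
  reference: their hits scatter among sister species with bit-scores
  inside the r-window, so LCA annotation lands at the genus rank or above,
  reflecting their unknownness.

No sequences are generated: every downstream stage consumes only mappings
and hit tables. All artifacts are byte-identical under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .homology import Hit
from .integration import ReadMapping
from .profiling import TaxonomicProfile, build_profile, write_profile
from .integration import ReadAnnotation
from .taxonomy import ROOT_ID, TaxonNode, TaxonomyTree, write_ncbi_taxonomy

_RANK_PREFIX = {
    "superkingdom": "sk",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one synthetic dataset; defaults emulate a moderately
    well-assembled benchmark sample at desk scale."""

    seed: int = 0
    n_species: int = 100
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    n_reads: int = 20000
    assembled_fraction: float = 0.8
    binned_fraction: float = 0.9
    novel_fraction: float = 0.1
    hit_noise: float = 0.3
    orfs_per_contig: tuple[int, int] = (3, 8)
    contigs_per_species: int = 3
    contamination: float = 0.0  # probability a binned contig lands in a foreign bin

    def __post_init__(self):
        for name in ("assembled_fraction", "binned_fraction", "novel_fraction",
                     "hit_noise", "contamination"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if self.n_reads < 1:
            raise ValidationError("n_reads must be >= 1")
        lo, hi = self.orfs_per_contig
        if not (1 <= lo <= hi):
            raise ValidationError(f"invalid orfs_per_contig range {self.orfs_per_contig}")


@dataclass
class GroundTruth:
    """Planted truth: per-read taxa, the realised read profile, and the
    true taxon of every contig and bin."""

    read_taxa: dict[str, str]
    profile: TaxonomicProfile
    contig_taxa: dict[str, str]
    bin_taxa: dict[str, str]
    community: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the planted ground truth."""

    tree: TaxonomyTree
    config: SimulationConfig
    mappings: list[ReadMapping]
    bin_map: dict[str, str]
    orf_hits: dict[str, list[Hit]]
    orf2contig: dict[str, str]
    contig_hits: dict[str, list[Hit]]
    read_hits: dict[str, list[Hit]]
    truth: GroundTruth

    @property
    def read_ids(self) -> list[str]:
        return sorted(self.truth.read_taxa)


# ---------------------------------------------------------------------------
# taxonomy generation
# ---------------------------------------------------------------------------


def make_taxonomy(
    seed: int,
    n_species: int,
    min_fanout: int = 2,
    max_fanout: int = 4,
) -> TaxonomyTree:
    """Random taxonomy with every official rank present on every lineage.

    Species leaves are grouped bottom-up into genera, families, ..., with
    group sizes drawn uniformly from [min_fanout, max_fanout]; deterministic
    under the seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not (1 <= min_fanout <= max_fanout):
        raise ValueError(f"invalid fanout range [{min_fanout}, {max_fanout}]")
    rng = np.random.default_rng(seed)
    nodes: dict[str, TaxonNode] = {ROOT_ID: TaxonNode(ROOT_ID, ROOT_ID, "root", "root")}
    # bottom-up: current level ids, grouped into the next shallower rank
    level_ids = [f"s{i + 1}" for i in range(n_species)]
    all_levels: list[tuple[str, list[str]]] = [("species", level_ids)]
    parent_of: dict[str, str] = {}
    ranks_up = ["genus", "family", "order", "class", "phylum", "superkingdom"]
    for rank in ranks_up:
        prefix = _RANK_PREFIX[rank]
        groups: list[list[str]] = []
        i = 0
        while i < len(level_ids):
            size = int(rng.integers(min_fanout, max_fanout + 1))
            groups.append(level_ids[i:i + size])
            i += size
        new_ids = []
        for gi, members in enumerate(groups):
            gid = f"{prefix}{gi + 1}"
            new_ids.append(gid)
            for m in members:
                parent_of[m] = gid
        level_ids = new_ids
        all_levels.append((rank, new_ids))
    for tid in level_ids:  # superkingdoms hang off the root
        parent_of[tid] = ROOT_ID
    for rank, ids in all_levels:
        for tid in ids:
            nodes[tid] = TaxonNode(tid, parent_of[tid], rank, tid)
    return TaxonomyTree(nodes)


def sample_community(tree: TaxonomyTree, config: SimulationConfig) -> dict[str, float]:
    """Log-normal species abundances normalised to 1 (sigma=0 → uniform)."""
    species = sorted(t for t, n in tree.nodes.items() if n.rank == "species")
    if len(species) < config.n_species:
        raise ValidationError(
            f"tree has {len(species)} species, config wants {config.n_species}"
        )
    species = species[: config.n_species]
    rng = np.random.default_rng(config.seed)
    raw = rng.lognormal(config.abundance_mu, config.abundance_sigma, len(species))
    raw /= raw.sum()
    return dict(zip(species, raw))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _sister_scatter(tree: TaxonomyTree, species: str, rng: np.random.Generator) -> list[str]:
    """Subject species for a 'novel' query: relatives under the nearest
    ancestor that holds at least two other species, never the species itself."""
    species_by_node: dict[str, list[str]] = {}

    def descend_species(node: str) -> list[str]:
        if node in species_by_node:
            return species_by_node[node]
        if tree.rank(node) == "species":
            out = [node]
        else:
            out = [s for c in tree.children(node) for s in descend_species(c)]
        species_by_node[node] = out
        return out

    for anc in reversed(tree.lineage(species)[:-1]):
        others = sorted(s for s in descend_species(anc) if s != species)
        if len(others) >= 2:
            k = min(3, len(others))
            picked = rng.choice(len(others), size=k, replace=False)
            return [others[i] for i in sorted(picked)]
    # degenerate tree (single species): fall back to the species itself
    return [species]


def _unrelated_species(
    tree: TaxonomyTree, species: str, pool: Sequence[str], rng: np.random.Generator
) -> str:
    """A decoy species from outside the query's genus (a different clade)."""
    genus = tree.taxon_at_rank(species, "genus")
    for _ in range(20):
        cand = pool[int(rng.integers(len(pool)))]
        if cand != species and tree.taxon_at_rank(cand, "genus") != genus:
            return cand
    others = [s for s in pool if s != species]
    return others[int(rng.integers(len(others)))] if others else species


def simulate_dataset(
    config: SimulationConfig,
    tree: TaxonomyTree | None = None,
    community: dict[str, float] | None = None,
) -> SimulatedDataset:
    """Generate one complete synthetic dataset with planted ground truth.

    The true profile is the realised per-read profile (computed from the
    drawn read taxa), so a noiseless run can recover it exactly.
    """
    if tree is None:
        tree = make_taxonomy(config.seed, config.n_species)
    if community is None:
        community = sample_community(tree, config)
    rng = np.random.default_rng(config.seed + 1)
    species = sorted(community)
    probs = np.array([community[s] for s in species])
    probs = probs / probs.sum()

    novel: set[str] = set()
    if config.novel_fraction > 0:
        k = int(round(config.novel_fraction * len(species)))
        if config.novel_fraction == 1.0:
            k = len(species)
        idx = rng.choice(len(species), size=k, replace=False)
        novel = {species[i] for i in sorted(idx)}

    # contigs and bins (pure per-species bins; optional contamination)
    contig_taxa: dict[str, str] = {}
    contigs_of: dict[str, list[str]] = {}
    bin_map: dict[str, str] = {}
    bin_taxa: dict[str, str] = {}
    for sp in species:
        contigs_of[sp] = []
        for k in range(config.contigs_per_species):
            cid = f"ctg_{sp}_{k + 1}"
            contigs_of[sp].append(cid)
            contig_taxa[cid] = sp
            if rng.random() < config.binned_fraction:
                host = sp
                if config.contamination > 0 and rng.random() < config.contamination:
                    host = _unrelated_species(tree, sp, species, rng)
                bin_map[cid] = f"bin_{host}"
                bin_taxa.setdefault(f"bin_{host}", host)

    # reads
    read_species = rng.choice(len(species), size=config.n_reads, p=probs)
    read_taxa = {
        f"read_{i + 1:07d}": species[j] for i, j in enumerate(read_species)
    }

    # scatter targets for novel species, fixed per species
    scatter = {sp: _sister_scatter(tree, sp, rng) for sp in sorted(novel)}

    # mappings: assembled reads map (primary, mapq 30) to a contig of their species
    mappings: list[ReadMapping] = []
    for rid in sorted(read_taxa):
        if rng.random() < config.assembled_fraction:
            sp = read_taxa[rid]
            cands = contigs_of[sp]
            cid = cands[int(rng.integers(len(cands)))]
            mappings.append(ReadMapping(rid, cid, True, 30))

    # ORF hit tables: each contig carries a handful of ORFs hitting its
    # species (or scattering among sisters when the species is novel)
    orf_hits: dict[str, list[Hit]] = {}
    orf2contig: dict[str, str] = {}
    lo, hi = config.orfs_per_contig
    for sp in species:
        for cid in contigs_of[sp]:
            n_orfs = int(rng.integers(lo, hi + 1))
            for k in range(n_orfs):
                oid = f"{cid}_{k + 1}"
                orf2contig[oid] = cid
                if sp in novel:
                    subjects = scatter[sp]
                    scores = [100.0] + [
                        float(rng.uniform(92.0, 99.0)) for _ in subjects[1:]
                    ]
                    orf_hits[oid] = [
                        Hit(oid, s, sc) for s, sc in zip(subjects, scores)
                    ]
                else:
                    orf_hits[oid] = [Hit(oid, sp, float(rng.uniform(90.0, 110.0)))]

    # direct contig hit tables (protein-space comparison of the whole contig)
    contig_hits: dict[str, list[Hit]] = {}
    for sp in species:
        for cid in contigs_of[sp]:
            if sp in novel:
                subjects = scatter[sp]
                scores = [100.0] + [float(rng.uniform(92.0, 99.0)) for _ in subjects[1:]]
                contig_hits[cid] = [Hit(cid, s, sc) for s, sc in zip(subjects, scores)]
            else:
                contig_hits[cid] = [Hit(cid, sp, float(rng.uniform(90.0, 110.0)))]

    # direct read hit tables: true species, a decoy with probability
    # hit_noise, or sister scatter for novel species
    read_hits: dict[str, list[Hit]] = {}
    for rid in sorted(read_taxa):
        sp = read_taxa[rid]
        score = float(rng.uniform(50.0, 70.0))
        if sp in novel:
            subjects = scatter[sp]
            scores = [score] + [score * float(rng.uniform(0.92, 0.99)) for _ in subjects[1:]]
            read_hits[rid] = [Hit(rid, s, sc) for s, sc in zip(subjects, scores)]
        elif rng.random() < config.hit_noise:
            decoy = _unrelated_species(tree, sp, species, rng)
            read_hits[rid] = [Hit(rid, decoy, score)]
        else:
            read_hits[rid] = [Hit(rid, sp, score)]

    truth_annotations = [
        ReadAnnotation(rid, read_taxa[rid], "read_direct") for rid in sorted(read_taxa)
    ]
    true_profile = build_profile(truth_annotations, tree, total_reads=config.n_reads)
    truth = GroundTruth(read_taxa, true_profile, contig_taxa, bin_taxa, community)
    return SimulatedDataset(
        tree, config, mappings, bin_map, orf_hits, orf2contig,
        contig_hits, read_hits, truth,
    )


# ---------------------------------------------------------------------------
# fixture emission (the exact dialects the loaders consume)
# ---------------------------------------------------------------------------


def _write_hit_table(hits: dict[str, list[Hit]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# query_id\tsubject_taxon_id\tbit_score\n")
        for q in sorted(hits):
            for h in hits[q]:
                fh.write(f"{h.query_id}\t{h.subject_taxon}\t{h.bit_score:.6g}\n")


def write_dataset(ds: SimulatedDataset, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write every artifact in the formats the pipeline loaders consume.

    Returns a name → path map. Byte-identical across runs with equal seeds.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    tax_dir = os.path.join(out_dir, "taxonomy")
    write_ncbi_taxonomy(ds.tree, tax_dir)
    paths = {
        "nodes": os.path.join(tax_dir, "nodes.dmp"),
        "names": os.path.join(tax_dir, "names.dmp"),
        "merged": os.path.join(tax_dir, "merged.dmp"),
        "mappings": os.path.join(out_dir, "mappings.tsv"),
        "contig2bin": os.path.join(out_dir, "contig2bin.tsv"),
        "orf_hits": os.path.join(out_dir, "orf_hits.tsv"),
        "orf2contig": os.path.join(out_dir, "orf2contig.tsv"),
        "contig_hits": os.path.join(out_dir, "contig_hits.tsv"),
        "read_hits": os.path.join(out_dir, "read_hits.tsv"),
        "truth_reads": os.path.join(out_dir, "truth_reads.tsv"),
        "truth_profile": os.path.join(out_dir, "truth_profile.tsv"),
    }
    with open(paths["mappings"], "w") as fh:
        for m in ds.mappings:
            fh.write(f"{m.read_id}\t{m.contig_id}\t{int(m.is_primary)}\t{m.mapq}\n")
    with open(paths["contig2bin"], "w") as fh:
        for cid in sorted(ds.bin_map):
            fh.write(f"{cid}\t{ds.bin_map[cid]}\n")
    _write_hit_table(ds.orf_hits, paths["orf_hits"])
    _write_hit_table(ds.contig_hits, paths["contig_hits"])
    _write_hit_table(ds.read_hits, paths["read_hits"])
    with open(paths["orf2contig"], "w") as fh:
        for oid in sorted(ds.orf2contig):
            fh.write(f"{oid}\t{ds.orf2contig[oid]}\n")
    with open(paths["truth_reads"], "w") as fh:
        for rid in sorted(ds.truth.read_taxa):
            fh.write(f"{rid}\t{ds.truth.read_taxa[rid]}\n")
    write_profile(ds.truth.profile, paths["truth_profile"], ds.tree, sample_id="truth")
    return paths
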