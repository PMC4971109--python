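"""Presence structure of a gene collection across strains.

Builds ortholog clusters (via a documented greedy stand-in, or a supplied
precomputed table), derives per-cluster presence profiles, stratifies the
pangenome into the five presence classes (strain-specific through core), and
computes pan/core rarefaction curves over seeded strain-order permutations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .errors import ValidationError
from .io_formats import ClusterTable, GeneRecord

logger = logging.getLogger(__name__)

SET_LABELS = (
    "strain_specific",
    "lowly_shared",
    "moderately_shared",
    "highly_shared",
    "core",
)


@dataclass
class PresenceProfile:
    """Per-cluster strain presence and paralog multiplicity."""

    presence_count: dict[str, int]
    strains_present: dict[str, set[str]]
    paralog_count: dict[str, dict[str, int]]

    @property
    def n_clusters(self) -> int:
        return len(self.presence_count)


@dataclass
class GeneSetPartition:
    """Assignment of clusters (and their genes) to the five presence classes."""

    cluster_labels: dict[str, str]
    gene_labels: dict[str, str]
    bin_edges: tuple[int, int, int, int]
    n_strains: int

    def counts_by_label(self) -> dict[str, int]:
        out = {label: 0 for label in SET_LABELS}
        for label in self.cluster_labels.values():
            out[label] += 1
        return out


@dataclass
class RarefactionCurve:
    """Pan/core cluster counts for growing strain subsets.

    ``pan`` and ``core`` have shape (n_permutations, n_strains); medians are
    taken across permutations at each k.
    """

    pan: np.ndarray
    core: np.ndarray
    n_permutations: int
    seed: int
    pan_median: np.ndarray = field(init=False)
    core_median: np.ndarray = field(init=False)

    def __post_init__(self):
        self.pan_median = np.median(self.pan, axis=0)
        self.core_median = np.median(self.core, axis=0)


def _translate(seq: str) -> str:
    protein = str(Seq(seq).translate(table=11))
    return protein.rstrip("*")


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _ungapped_identity(a: str, b: str, index_a: dict[str, list[int]], k: int):
    """Best ungapped identity/coverage between a and b over k-mer-seeded
    diagonals; identity is matches over the overlap, coverage is overlap over
    the shorter sequence."""
    offsets = set()
    for i in range(len(b) - k + 1):
        for j in index_a.get(b[i : i + k], ()):
            offsets.add(j - i)
    best = (0.0, 0.0)
    shorter = min(len(a), len(b))
    for off in offsets:
        lo_b = max(0, -off)
        hi_b = min(len(b), len(a) - off)
        overlap = hi_b - lo_b
        if overlap <= 0:
            continue
        matches = sum(
            1 for x in range(lo_b, hi_b) if b[x] == a[x + off]
        )
        identity = matches / overlap
        coverage = overlap / shorter
        if identity * coverage > best[0] * best[1]:
            best = (identity, coverage)
    return best


def cluster_genes(
    records: list[GeneRecord],
    identity_threshold: float = 0.9,
    coverage_threshold: float = 0.8,
    kmer: int = 8,
) -> ClusterTable:
    """Greedy single-linkage clustering on translated sequences.

    A documented stand-in for Markov clustering of all-vs-all alignments:
    genes are processed in decreasing protein length (ties by gene_id); a
    gene joins the first cluster whose representative (founder) shares at
    least ``identity_threshold`` amino-acid identity over at least
    ``coverage_threshold`` of the shorter sequence on an ungapped
    k-mer-seeded diagonal, otherwise it founds a new cluster.
    """
    for name, value in (
        ("identity_threshold", identity_threshold),
        ("coverage_threshold", coverage_threshold),
    ):
        if not 0 < value <= 1:
            raise ValidationError(f"{name} must lie in (0, 1], got {value}")
    proteins = {rec.gene_id: _translate(rec.sequence) for rec in records}
    order = sorted(records, key=lambda r: (-len(proteins[r.gene_id]), r.gene_id))
    reps: list[tuple[str, str, dict]] = []  # (cluster_id, protein, kmer index)
    clusters: dict[str, list[str]] = {}
    for rec in order:
        prot = proteins[rec.gene_id]
        joined = False
        for cid, rep_prot, rep_index in reps:
            identity, coverage = _ungapped_identity(rep_prot, prot, rep_index, kmer)
            if identity >= identity_threshold and coverage >= coverage_threshold:
                clusters[cid].append(rec.gene_id)
                joined = True
                break
        if not joined:
            cid = f"c{len(reps) + 1:05d}"
            reps.append((cid, prot, _kmer_index(prot, kmer)))
            clusters[cid] = [rec.gene_id]
    return ClusterTable(clusters=clusters)


def presence_counts(
    clusters: ClusterTable, strain_of: dict[str, str]
) -> PresenceProfile:
    """Distinct-strain presence count and per-strain paralog multiplicity."""
    presence, strains, paralogs = {}, {}, {}
    for cid, members in clusters.clusters.items():
        per_strain: dict[str, int] = {}
        for g in members:
            if g not in strain_of:
                raise ValidationError(f"gene {g!r} has no strain assignment")
            per_strain[strain_of[g]] = per_strain.get(strain_of[g], 0) + 1
        strains[cid] = set(per_strain)
        presence[cid] = len(per_strain)
        paralogs[cid] = per_strain
    return PresenceProfile(
        presence_count=presence, strains_present=strains, paralog_count=paralogs
    )


def default_bin_edges(n_strains: int) -> tuple[int, int, int, int]:
    """Upper bounds of the first four presence bins.

    With w = floor((n-2)/3) the bins are {1}, [2, 1+w], [2+w, 1+2w],
    [2+2w, n-1], {n}; any remainder is absorbed by the highly-shared bin.
    At n = 26 this gives 1 / 2-9 / 10-17 / 18-25 / 26.
    """
    if n_strains < 5:
        raise ValidationError(
            f"default bin edges need at least 5 strains, got {n_strains}"
        )
    w = (n_strains - 2) // 3
    return (1, 1 + w, 1 + 2 * w, n_strains - 1)


def partition_gene_sets(
    profile: PresenceProfile,
    n_strains: int,
    edges: tuple[int, int, int, int] | None = None,
    clusters: ClusterTable | None = None,
) -> GeneSetPartition:
    """Assign every cluster (and, when the ClusterTable is given, every gene)
    to one of the five presence classes."""
    edges = tuple(edges) if edges is not None else default_bin_edges(n_strains)
    if len(edges) != 4 or list(edges) != sorted(edges) or edges[0] != 1:
        raise ValidationError(f"bin edges {edges} are not 4 increasing bounds from 1")
    cluster_labels = {}
    for cid, count in profile.presence_count.items():
        if not 1 <= count <= n_strains:
            raise ValidationError(
                f"cluster {cid!r} presence {count} outside [1, {n_strains}]"
            )
        if count == n_strains:
            label = "core"
        elif count <= edges[0]:
            label = "strain_specific"
        elif count <= edges[1]:
            label = "lowly_shared"
        elif count <= edges[2]:
            label = "moderately_shared"
        else:
            label = "highly_shared"
        cluster_labels[cid] = label
    gene_labels = {}
    if clusters is not None:
        for cid, members in clusters.clusters.items():
            for g in members:
                gene_labels[g] = cluster_labels[cid]
    return GeneSetPartition(
        cluster_labels=cluster_labels,
        gene_labels=gene_labels,
        bin_edges=edges,
        n_strains=n_strains,
    )


def label_for_count(count: int, n_strains: int,
                    edges: tuple[int, int, int, int] | None = None) -> str:
    """Presence-class label for a single presence count."""
    profile = PresenceProfile(
        presence_count={"_": count}, strains_present={"_": set()}, paralog_count={"_": {}}
    )
    return partition_gene_sets(profile, n_strains, edges).cluster_labels["_"]


def select_representatives(
    clusters: ClusterTable, records: list[GeneRecord]
) -> ClusterTable:
    """Remove paralogs: per cluster keep at most one gene per strain — the
    longest CDS, ties broken by lexicographically smallest gene_id."""
    info = {r.gene_id: (r.strain_id, len(r.sequence)) for r in records}
    out = {}
    for cid, members in clusters.clusters.items():
        best: dict[str, str] = {}
        for g in members:
            if g not in info:
                raise ValidationError(f"gene {g!r} not found among records")
            strain, length = info[g]
            cur = best.get(strain)
            if cur is None or (-length, g) < (-info[cur][1], cur):
                best[strain] = g
        out[cid] = sorted(best.values(), key=members.index)
    return ClusterTable(clusters=out)


def pangenome_curve(
    profile: PresenceProfile,
    strains: list[str],
    n_permutations: int = 100,
    seed: int = 0,
) -> RarefactionCurve:
    """Pan (prefix union) and core (prefix intersection) cluster counts over
    seeded shuffles of the strain order."""
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    strains = list(strains)
    by_strain: dict[str, set[str]] = {s: set() for s in strains}
    for cid, present in profile.strains_present.items():
        for s in present:
            if s in by_strain:
                by_strain[s].add(cid)
    rng = np.random.default_rng(seed)
    n = len(strains)
    pan = np.zeros((n_permutations, n), dtype=np.int64)
    core = np.zeros((n_permutations, n), dtype=np.int64)
    for p in range(n_permutations):
        order = [strains[i] for i in rng.permutation(n)]
        union = set()
        inter: set[str] | None = None
        for k, s in enumerate(order):
            union |= by_strain[s]
            inter = by_strain[s].copy() if inter is None else inter & by_strain[s]
            pan[p, k] = len(union)
            core[p, k] = len(inter)
    return RarefactionCurve(pan=pan, core=core, n_permutations=n_permutations, seed=seed)
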