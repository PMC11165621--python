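"""Code-aware pangenome construction.

Proteins from all genomes are compared all-vs-all by global alignment and
clustered as connected components of the graph whose edges join pairs
above an amino-acid identity threshold with sufficient mutual coverage
(the semantics of greedy set-cover-free, transitive "cluster-mode 1"
protein clustering).  Because ORFs are translated under each genome's own
assigned genetic code before clustering, genomes using different
translation tables can share one pangenome — the capability standard
bacterial pangenome tools lack.

The identity graph is computed once (with a k-mer prefilter that must not
change results) and can be re-thresholded cheaply, which the taxonomy
stage uses to find the threshold at which an outlier genome first shares
a cluster with the rest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist

from .records import ProteinRecord

DEFAULT_IDENTITY = 70.0  # percent amino-acid identity
DEFAULT_COVERAGE = 0.8  # bidirectional aligned-span coverage

_aligner = PairwiseAligner(
    mode="global",
    substitution_matrix=substitution_matrices.load("BLOSUM62"),
    open_gap_score=-11.0,
    extend_gap_score=-1.0,
)


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> tuple[float, float, float]:
    """Global-alignment identity and mutual coverage of two proteins.

    Identity is matches over aligned columns (gap columns included);
    coverage of each sequence is its aligned span (first to last residue
    paired with the partner) divided by its length.  BLOSUM62 with affine
    gaps (open 11, extend 1).
    """
    sa = a.seq if isinstance(a, ProteinRecord) else a
    sb = b.seq if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty protein sequence")
    aln = _aligner.align(sa, sb)[0]
    counts = aln.counts()
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0, 0.0
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = max(b0[1] for b0 in blocks_b) - min(b0[0] for b0 in blocks_b)
    n_cols = counts.aligned + counts.internal_gaps
    identity = 100.0 * counts.identities / n_cols if n_cols else 0.0
    return identity, span_a / len(sa), span_b / len(sb)


@dataclass
class ProteinCluster:
    """One protein cluster (a connected component of the identity graph)."""

    cluster_id: str
    members: list[str]
    genomes: set[str]
    function_label: str = "unknown function"
    tie_flag: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    def is_core(self, genome_set: set[str]) -> bool:
        return genome_set <= self.genomes


def _kmer_candidates(proteins: list[ProteinRecord], k: int = 5,
                     min_shared: int = 2) -> set[tuple[int, int]]:
    """Pairs of protein indices sharing >= ``min_shared`` distinct aa k-mers.

    Two distinct shared 5-mers are expected even for remote homologs down
    to ~25 % identity over typical protein lengths, while unrelated pairs
    share two only by rare chance; the prefilter is asserted against
    unfiltered all-vs-all clustering in the test suite.
    """
    index: dict[str, list[int]] = {}
    for i, p in enumerate(proteins):
        for kmer in {p.seq[j : j + k] for j in range(len(p.seq) - k + 1)}:
            index.setdefault(kmer, []).append(i)
    from collections import Counter

    counts: Counter[tuple[int, int]] = Counter()
    for hits in index.values():
        if 1 < len(hits) <= 2000:
            counts.update(itertools.combinations(sorted(hits), 2))
    return {pair for pair, c in counts.items() if c >= min_shared}


class ProteinGraph:
    """All-vs-all protein identity graph, re-thresholdable after one pass.

    Alignments are computed for candidate pairs only (those sharing a
    5-mer when ``prefilter`` is on); edges below ``min_record_identity``
    are not stored.  ``clusters(threshold)`` then returns connected
    components at any identity threshold >= that floor.
    """

    def __init__(self, proteins: list[ProteinRecord], coverage_threshold: float = DEFAULT_COVERAGE,
                 prefilter: bool = True, min_record_identity: float = 15.0):
        if not proteins:
            raise ValueError("no proteins to cluster")
        ids = [p.id for p in proteins]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids")
        self.proteins = list(proteins)
        self.coverage_threshold = coverage_threshold
        self._by_id = {p.id: p for p in proteins}
        if prefilter:
            cand = _kmer_candidates(self.proteins)
        else:
            cand = set(itertools.combinations(range(len(self.proteins)), 2))
        rows = []
        for i, j in sorted(cand):
            la, lb = len(self.proteins[i].seq), len(self.proteins[j].seq)
            # identity <= len_short/len_long (matches <= len_short, columns >=
            # len_long), so extreme length mismatches cannot reach the floor
            if min(la, lb) / max(la, lb) * 100 < min_record_identity:
                continue
            ident, cov_a, cov_b = pairwise_identity(self.proteins[i], self.proteins[j])
            if ident >= min_record_identity and cov_a >= coverage_threshold and cov_b >= coverage_threshold:
                rows.append((self.proteins[i].id, self.proteins[j].id, ident, cov_a, cov_b))
        self.edges = pd.DataFrame(rows, columns=["a", "b", "identity", "cov_a", "cov_b"])

    def clusters(self, identity_threshold: float = DEFAULT_IDENTITY) -> list[ProteinCluster]:
        """Connected components at the given identity threshold.

        Cluster ids are deterministic: ordered by (size desc,
        lexicographically smallest member).
        """
        parent = {p.id: p.id for p in self.proteins}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        if len(self.edges):
            keep = self.edges[self.edges["identity"] >= identity_threshold]
            for a, b in zip(keep["a"], keep["b"]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        comps: dict[str, list[str]] = {}
        for p in self.proteins:
            comps.setdefault(find(p.id), []).append(p.id)
        ordered = sorted(comps.values(), key=lambda m: (-len(m), min(m)))
        out = []
        for i, members in enumerate(ordered, start=1):
            members = sorted(members)
            genomes = {self._by_id[m].source_genome for m in members}
            out.append(ProteinCluster(cluster_id=f"PC{i:05d}", members=members, genomes=genomes))
        return out


def cluster_proteins(proteins: list[ProteinRecord], identity_threshold: float = DEFAULT_IDENTITY,
                     coverage_threshold: float = DEFAULT_COVERAGE, prefilter: bool = True) -> list[ProteinCluster]:
    """One-shot clustering; see :class:`ProteinGraph` for details."""
    graph = ProteinGraph(proteins, coverage_threshold=coverage_threshold, prefilter=prefilter)
    return graph.clusters(identity_threshold)


@dataclass
class PangenomeMatrix:
    """Protein clusters x genomes presence-count matrix."""

    counts: pd.DataFrame  # rows: cluster ids, cols: genome ids
    clusters: list[ProteinCluster]
    identity_threshold: float
    coverage_threshold: float

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        return (self.counts >= 1).astype(int)


def presence_matrix(clusters: list[ProteinCluster], genome_ids: list[str],
                    protein_to_genome: dict[str, str] | None = None,
                    identity_threshold: float = DEFAULT_IDENTITY,
                    coverage_threshold: float = DEFAULT_COVERAGE) -> PangenomeMatrix:
    """Build the clusters-x-genomes count matrix from a clustering."""
    data = np.zeros((len(clusters), len(genome_ids)), dtype=int)
    col = {g: i for i, g in enumerate(genome_ids)}
    for r, cl in enumerate(clusters):
        for m in cl.members:
            g = protein_to_genome[m] if protein_to_genome else m.split("|")[0]
            if g in col:
                data[r, col[g]] += 1
    counts = pd.DataFrame(data, index=[c.cluster_id for c in clusters], columns=genome_ids)
    return PangenomeMatrix(counts=counts, clusters=clusters,
                           identity_threshold=identity_threshold,
                           coverage_threshold=coverage_threshold)


def core_clusters(matrix: PangenomeMatrix, genome_set: set[str] | list[str]) -> list[ProteinCluster]:
    """Clusters with at least one member in every genome of ``genome_set``."""
    genome_set = set(genome_set)
    if not genome_set:
        raise ValueError("genome_set must be non-empty")
    missing = genome_set - set(matrix.genome_ids)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    return [c for c in matrix.clusters if c.is_core(genome_set)]


def cluster_function(cluster: ProteinCluster, annotations: dict[str, str] | pd.Series) -> ProteinCluster:
    """Label a cluster by its most frequent member annotation.

    Missing annotations are ignored; with none at all the label is
    "unknown function".  Ties break lexicographically and set
    ``tie_flag``.
    """
    if isinstance(annotations, pd.Series):
        annotations = annotations.to_dict()
    labels = [annotations[m] for m in cluster.members if annotations.get(m) not in (None, "")]
    if not labels:
        cluster.function_label, cluster.tie_flag = "unknown function", False
        return cluster
    counts = pd.Series(labels).value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index)
    cluster.function_label = winners[0]
    cluster.tie_flag = len(winners) > 1
    return cluster


def presence_absence_dendrogram(matrix: PangenomeMatrix):
    """Average-linkage dendrogram of genomes on Jaccard distance.

    Genomes are ordered by id before linkage so ties break
    deterministically.  Returns a scikit-bio TreeNode.
    """
    from skbio import TreeNode

    pres = matrix.presence()
    ids = sorted(pres.columns)
    if len(ids) < 2:
        raise ValueError("need >=2 genomes for a dendrogram")
    X = pres[ids].T.values.astype(bool)
    dist = pdist(X, metric="jaccard")
    linkage = average(dist)
    tree = TreeNode.from_linkage_matrix(linkage, ids)
    for node in tree.traverse():
        if node.length is None or node.length < 0:
            node.length = 0.0
    return tree


def jaccard_distance(profile_a, profile_b) -> float:
    """Jaccard distance between two binary presence profiles."""
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(a, b).sum() / union
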