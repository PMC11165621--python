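"""Concatenated core-protein phylogeny at desk scale.

Per-cluster protein alignments are concatenated into one supermatrix per
family; pairwise Poisson-corrected distances feed a canonical
neighbor-joining tree, bootstrapped by column resampling and rooted at
the midpoint.  Distance-based NJ deliberately replaces model-fitted
maximum likelihood: the load-bearing output for rank demarcation is the
topology (which clades are sister), and NJ recovers the true topology
exactly whenever the distance matrix is additive, with deterministic
seeded bootstraps and second-scale runtimes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)


@dataclass
class Alignment:
    """Equal-length gapped amino-acid rows keyed by taxon id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(len(r) for r in self.rows)) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon ids in alignment")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace("-", "")


def progressive_align(seqs: dict[str, str] | list[tuple[str, str]]) -> Alignment:
    """Progressive multiple alignment (guide tree + profile merging).

    Deterministic for fixed input; a single sequence aligns to itself.
    """
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences to align")
    if any(not s for _, s in items):
        raise ValueError("empty sequence in alignment input")
    if len(items) == 1:
        return Alignment(ids=[items[0][0]], rows=[items[0][1]])
    proteins = [bseq.ProteinSequence(s) for _, s in items]
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    aln, order, tree, dists = balign.align_multiple(proteins, matrix, gap_penalty=(-11, -1))
    return Alignment(ids=[i for i, _ in items], rows=aln.get_gapped_sequences())


def sum_of_pairs(aln: Alignment, match: int = 1, mismatch: int = 0, gap: int = 0) -> float:
    """Simple sum-of-pairs column score (identity-based)."""
    score = 0.0
    arr = np.array([list(r) for r in aln.rows])
    for i in range(len(aln.rows)):
        for j in range(i + 1, len(aln.rows)):
            a, b = arr[i], arr[j]
            both = (a != "-") & (b != "-")
            score += match * np.sum((a == b) & both) + mismatch * np.sum((a != b) & both)
    return score


def concatenate(alignments: list[tuple[str, Alignment]],
                genome_of: dict[str, str],
                genomes: list[str] | None = None) -> tuple[Alignment, pd.DataFrame]:
    """Concatenate per-cluster alignments into a genome supermatrix.

    Each cluster alignment must hold at most one representative per
    genome; a genome absent from a cluster receives an all-gap block.
    ``genomes`` fixes the genome universe (a genome absent from every
    cluster is then an error); by default the universe is whatever the
    alignments cover.  Returns the concatenated alignment plus a
    partition table with 1-based inclusive block coordinates.
    """
    present = sorted({genome_of[pid] for _, aln in alignments for pid in aln.ids})
    genomes = sorted(genomes) if genomes is not None else present
    if not genomes:
        raise ValueError("no genomes in any alignment")
    parts = []
    blocks: dict[str, list[str]] = {g: [] for g in genomes}
    pos = 1
    for cluster_id, aln in alignments:
        per_genome: dict[str, str] = {}
        for pid, row in zip(aln.ids, aln.rows):
            g = genome_of[pid]
            if g in per_genome:
                raise ValueError(f"cluster {cluster_id}: multiple representatives for genome {g}")
            per_genome[g] = row
        width = aln.n_cols
        for g in genomes:
            blocks[g].append(per_genome.get(g, "-" * width))
        parts.append(dict(cluster_id=cluster_id, start=pos, end=pos + width - 1))
        pos += width
    rows = ["".join(blocks[g]) for g in genomes]
    empty = [g for g, r in zip(genomes, rows) if set(r) == {"-"}]
    if empty:
        raise ValueError(f"genomes absent from every cluster: {empty}")
    return Alignment(ids=genomes, rows=rows), pd.DataFrame(parts)


def distance_matrix(aln: Alignment, model: str = "poisson") -> pd.DataFrame:
    """Pairwise distances with pairwise gap deletion.

    p-distance is computed over columns where neither row is gapped;
    ``model="poisson"`` applies d = -ln(1 - p), with p clamped at 0.95
    (and a warning) to keep distances finite.  A pair with zero
    comparable columns is an error.
    """
    if len(aln.ids) < 2:
        raise ValueError(">=2 rows required")
    arr = _encode(aln.rows)
    D = _distances_from_array(arr, aln.ids, model)
    return pd.DataFrame(D, index=aln.ids, columns=aln.ids)


def _encode(rows: list[str]) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])


_GAP = ord("-")


def _distances_from_array(arr: np.ndarray, ids: list[str], model: str = "poisson") -> np.ndarray:
    if model not in ("poisson", "p"):
        raise ValueError(f"unknown distance model {model!r}")
    valid = arr != _GAP
    # pairwise comparable-column and mismatch counts in one broadcast
    both = valid[:, None, :] & valid[None, :, :]
    m = both.sum(axis=2)
    mism = ((arr[:, None, :] != arr[None, :, :]) & both).sum(axis=2)
    n = arr.shape[0]
    np.fill_diagonal(m, 1)
    if (m == 0).any():
        i, j = np.argwhere(m == 0)[0]
        raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
    p = mism / m
    np.fill_diagonal(p, 0.0)
    if model == "p":
        return p
    if (p >= 0.95).any():
        logger.warning("p-distances >= 0.95 clamped for %d pairs", int((p >= 0.95).sum() / 2))
        p = np.minimum(p, 0.95)
    return -np.log(1.0 - p)


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Canonical neighbor joining.

    Negative branch lengths are clamped to zero with the excess moved to
    the sibling edge, preserving the path length through the cherry.
    Returns an unrooted (trifurcating at the root) scikit-bio tree.
    """
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    ids = [str(c) for c in dist.columns]
    n = len(ids)
    if n < 2:
        raise ValueError(">=2 taxa required")
    nodes = [TreeNode(name=i) for i in ids]
    if n == 2:
        root = TreeNode()
        a, b = nodes
        a.length = float(D[0, 1])
        b.length = 0.0
        root.extend([a, b])
        return root
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the excess to the sibling edge
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = TreeNode()
        nodes[ai].length = float(li)
        nodes[aj].length = float(lj)
        parent.extend([nodes[ai], nodes[aj]])
        # distances from the new node to the rest
        newd = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D[ai, :] = newd
        D[:, ai] = newd
        D[ai, ai] = 0.0
        nodes[ai] = parent
        active.pop(j_)
    # terminal trifurcation (the canonical unrooted NJ root)
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = float(max(ln, 0.0))
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller/canonical leaf set) of a tree."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap(aln: Alignment, n_reps: int = 100, seed: int = 0,
              model: str = "poisson") -> TreeNode:
    """Column-resampling bootstrap over the distance + NJ pipeline.

    Builds the full-data NJ tree, then resamples alignment columns with
    replacement ``n_reps`` times and records, for every internal
    bipartition of the full tree, the percentage of replicate trees
    containing it (stored as internal node names).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(distance_matrix(aln, model))
    taxa = frozenset(aln.ids)
    counts: dict[frozenset[str], int] = {}
    node_key: dict[int, frozenset[str]] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            key = min(side, taxa - side, key=lambda s: (len(s), sorted(s)))
            node_key[id(node)] = key
            counts[key] = 0
    rng = np.random.default_rng(seed)
    arr = _encode(aln.rows)
    ncol = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        try:
            D = _distances_from_array(arr[:, cols], aln.ids, model)
            rep_tree = nj_tree(pd.DataFrame(D, index=aln.ids, columns=aln.ids))
        except ValueError:  # a replicate can lose all comparable columns for a pair
            continue
        rep_bip = _bipartitions(rep_tree, taxa)
        for key in counts:
            if key in rep_bip:
                counts[key] += 1
    for node in tree.non_tips(include_self=False):
        key = node_key.get(id(node))
        if key is not None:
            node.name = f"{100.0 * counts[key] / n_reps:g}"
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError(">=2 leaves required for midpoint rooting")
    if len(tips) == 2:
        # the midpoint bisects the single path between the two leaves
        a, b = tips
        total = a.distance(b)
        root = TreeNode()
        na, nb = TreeNode(name=a.name), TreeNode(name=b.name)
        na.length = nb.length = total / 2
        root.extend([na, nb])
        return root
    rooted = tree.root_at_midpoint()
    for node in rooted.traverse():
        if node.length is None:
            node.length = 0.0
    return rooted


def support_of_clade(tree: TreeNode, leaves: set[str]) -> float | None:
    """Bootstrap support of the clade with exactly these leaves, if present."""
    for node in tree.non_tips(include_self=True):
        tips = {t.name for t in node.tips()}
        if tips == set(leaves):
            try:
                return float(node.name) if node.name else None
            except (TypeError, ValueError):
                return None
    return None
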