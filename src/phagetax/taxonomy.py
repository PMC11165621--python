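"""Rank demarcation: similarity, pangenome and phylogeny into taxa.

Species and genera are single-linkage components of the intergenomic
similarity graph at the ICTV-conventional thresholds (>=95 % and >=70 %
intergenomic similarity S = ANI x AF); families are components of the
genome graph joined by sharing at least one protein cluster at the
pangenome identity threshold (70 %); subfamilies are the two root-child
clades of each family's midpoint-rooted core-protein tree, accepted only
with strong root-adjacent bootstrap support.  Partitions must nest
(species within genus within subfamily within family); a violation is a
hard error naming the offending genomes, never silently patched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ani import SimilarityMatrix
from .pangenome import PangenomeMatrix, ProteinGraph, core_clusters, presence_matrix
from .phylogeny import (Alignment, bootstrap, concatenate, midpoint_root,
                        progressive_align, support_of_clade)
from .records import ProteinRecord

logger = logging.getLogger(__name__)

SPECIES_THRESHOLD = 95.0
GENUS_THRESHOLD = 70.0
MIN_ROOT_SUPPORT = 95.0
RANK_ORDER = ("species", "genus", "subfamily", "family", "order")


def cluster_by_threshold(matrix: SimilarityMatrix | pd.DataFrame, threshold: float) -> dict[str, int]:
    """Single-linkage partition: components of the graph with S >= threshold.

    Near-threshold genomes join a group through intermediates, which is
    how borderline strains stay with their species.  Component indices
    are deterministic (ordered by smallest member id).
    """
    M = matrix.values if isinstance(matrix, SimilarityMatrix) else matrix
    ids = list(M.columns)
    if list(M.index) != ids:
        raise ValueError("similarity matrix must have identical row/column ids")
    A = np.asarray(M, dtype=float)
    if not np.allclose(A, A.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    adj = A >= threshold
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(adj, directed=False)
    return _canonical(ids, labels)


def _canonical(ids: list[str], labels) -> dict[str, int]:
    """Renumber components by their lexicographically smallest member."""
    groups: dict[int, list[str]] = {}
    for g, l in zip(ids, labels):
        groups.setdefault(int(l), []).append(g)
    ordered = sorted(groups.values(), key=lambda m: min(m))
    out: dict[str, int] = {}
    for k, members in enumerate(ordered, start=1):
        for g in members:
            out[g] = k
    return out


def genome_sharing_partition(matrix: PangenomeMatrix, genomes: list[str]) -> dict[str, int]:
    """Components of the genome graph with an edge iff >=1 shared cluster."""
    pres = matrix.presence()[genomes]
    X = pres.values.astype(bool)
    adj = (X.T @ X) >= 1  # genomes x genomes shared-cluster counts
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(adj, directed=False)
    return _canonical(genomes, labels)


def assign_family(matrix: PangenomeMatrix, genomes: list[str]) -> dict[str, int]:
    """Family partition from cluster sharing at the pangenome threshold.

    A genome sharing no cluster with any other becomes its own family
    (the signature of a deeply divergent proteome).
    """
    return genome_sharing_partition(matrix, genomes)


def outlier_connection_threshold(graph: ProteinGraph, genomes: list[str], outlier: str,
                                 thresholds: tuple[float, ...] = (65, 60, 55, 50, 45, 40, 35, 30, 25, 20)) -> float | None:
    """Highest clustering identity threshold at which ``outlier`` shares a cluster.

    Diagnostic for own-family genomes: reports how far the amino-acid
    identity threshold must be lowered before the outlier connects to the
    rest; None if it never connects on the grid.
    """
    others = [g for g in genomes if g != outlier]
    for thr in sorted(thresholds, reverse=True):
        clusters = graph.clusters(identity_threshold=thr)
        mat = presence_matrix(clusters, genomes, identity_threshold=thr,
                              coverage_threshold=graph.coverage_threshold)
        pres = mat.presence()
        shared = pres[pres[outlier] >= 1][others].sum(axis=1)
        if (shared >= 1).any():
            return float(thr)
    return None


def assign_subfamily(tree, family_members: list[str], min_support: float = MIN_ROOT_SUPPORT) -> dict[str, int]:
    """Subfamilies = the two root-child clades of the midpoint-rooted tree.

    Accepted only when the root-adjacent bipartition has bootstrap
    support >= ``min_support``; otherwise the family stays one subfamily
    and a warning is logged.  Families of one or two genomes are a single
    subfamily trivially.
    """
    if len(family_members) <= 2 or tree is None:
        return {g: 1 for g in sorted(family_members)}
    children = tree.children
    if len(children) != 2:
        logger.warning("family root is not bifurcating; keeping one subfamily")
        return {g: 1 for g in sorted(family_members)}
    sides = [{t.name for t in ch.tips()} if not ch.is_tip() else {ch.name} for ch in children]
    supports = [support_of_clade(tree, side) for side in sides if 1 < len(side) < len(family_members)]
    supports = [s for s in supports if s is not None]
    support = max(supports) if supports else None
    if support is None or support < min_support:
        logger.warning("root-adjacent support %s < %s; keeping one subfamily", support, min_support)
        return {g: 1 for g in sorted(family_members)}
    labels = {}
    for k, side in enumerate(sorted(sides, key=min)):
        for g in side:
            labels[g] = k + 1
    return labels


@dataclass
class TaxonomyAssignment:
    """Per-genome ranked labels with the evidence that produced them."""

    genome_id: str
    species: str
    genus: str
    subfamily: str
    family: str
    order: str
    evidence: dict[str, str] = field(default_factory=dict)


@dataclass
class FamilyPhylogeny:
    """Tree plus the supermatrix evidence it was built from."""

    tree: object  # midpoint-rooted skbio TreeNode with supports
    alignment: Alignment  # concatenated core-protein supermatrix (rows = genomes)
    partitions: pd.DataFrame  # cluster_id, start, end (1-based inclusive)


@dataclass
class TaxonomyResult:
    assignments: list[TaxonomyAssignment]
    table: pd.DataFrame  # long format
    family_trees: dict[str, FamilyPhylogeny]  # family label -> phylogeny bundle
    diagnostics: dict[str, object]

    def wide_table(self) -> pd.DataFrame:
        """Classification-table-shaped wide view: one column per species."""
        df = self.table
        rows = []
        for sp, grp in df.groupby("species"):
            first = grp.iloc[0]
            rows.append(dict(order=first["order"], family=first["family"],
                             subfamily=first["subfamily"], genus=first["genus"],
                             species=sp, strains=",".join(sorted(grp["genome_id"]))))
        out = pd.DataFrame(rows).sort_values(["family", "subfamily", "genus", "species"])
        return out.reset_index(drop=True)


def _check_nested(fine: dict[str, int], coarse: dict[str, int],
                  fine_rank: str, coarse_rank: str) -> None:
    by_group: dict[int, set[int]] = {}
    for g, f in fine.items():
        by_group.setdefault(f, set()).add(coarse[g])
    for f, cs in by_group.items():
        if len(cs) > 1:
            members = sorted(g for g, v in fine.items() if v == f)
            raise ValueError(
                f"nesting violation: {fine_rank} group {f} (members {members}) "
                f"spans multiple {coarse_rank} groups"
            )


def build_taxonomy(similarity: SimilarityMatrix, pangenome: PangenomeMatrix,
                   proteins: list[ProteinRecord], graph: ProteinGraph | None = None,
                   species_threshold: float = SPECIES_THRESHOLD,
                   genus_threshold: float = GENUS_THRESHOLD,
                   min_root_support: float = MIN_ROOT_SUPPORT,
                   bootstrap_reps: int = 100, seed: int = 0,
                   order_label: str = "order1",
                   name_map: dict[str, str] | None = None) -> TaxonomyResult:
    """Full rank assignment for one genome set.

    All genomes in one run are assumed to belong to one order (order-rank
    demarcation against outgroups is outside this pipeline's evidence).
    Labels are stable placeholders (``fam1``, ``gen2``, ``sp3``...)
    optionally renamed through ``name_map``.
    """
    genomes = similarity.genome_ids
    if sorted(genomes) != sorted(pangenome.genome_ids):
        raise ValueError("similarity matrix and pangenome cover different genomes")
    by_id = {p.id: p for p in proteins}

    species = cluster_by_threshold(similarity, species_threshold)
    genera = cluster_by_threshold(similarity, genus_threshold)
    families = assign_family(pangenome, genomes)

    # per-family core-protein phylogeny -> subfamilies
    fam_members: dict[int, list[str]] = {}
    for g, f in families.items():
        fam_members.setdefault(f, []).append(g)
    subfam: dict[str, int] = {}
    family_trees: dict[str, object] = {}
    support_notes: dict[int, float | None] = {}
    for f, members in sorted(fam_members.items()):
        tree = None
        if len(members) >= 3:
            phylo = family_tree(pangenome, by_id, members, bootstrap_reps=bootstrap_reps, seed=seed)
            family_trees[f"fam{f}"] = phylo
            tree = phylo.tree
        part = assign_subfamily(tree, members, min_support=min_root_support)
        for g, k in part.items():
            subfam[g] = (f, k)  # type: ignore[assignment]
    # renumber subfamilies globally, ordered by smallest member
    sub_groups: dict[tuple, list[str]] = {}
    for g, key in subfam.items():
        sub_groups.setdefault(key, []).append(g)
    subfamilies: dict[str, int] = {}
    for k, members in enumerate(sorted(sub_groups.values(), key=min), start=1):
        for g in members:
            subfamilies[g] = k

    _check_nested(species, genera, "species", "genus")
    _check_nested(genera, subfamilies, "genus", "subfamily")
    _check_nested(subfamilies, families, "subfamily", "family")

    def label(prefix: str, k: int) -> str:
        raw = f"{prefix}{k}"
        return name_map.get(raw, raw) if name_map else raw

    assignments = []
    rows = []
    for g in genomes:
        ev = {
            "species": f"S>={species_threshold:g} single-linkage",
            "genus": f"S>={genus_threshold:g} single-linkage",
            "subfamily": f"root bipartition, support>={min_root_support:g}",
            "family": f"shared cluster at {pangenome.identity_threshold:g}% identity",
        }
        a = TaxonomyAssignment(
            genome_id=g,
            species=label("sp", species[g]),
            genus=label("gen", genera[g]),
            subfamily=label("subfam", subfamilies[g]),
            family=label("fam", families[g]),
            order=order_label,
            evidence=ev,
        )
        assignments.append(a)
        rows.append(dict(genome_id=g, species=a.species, genus=a.genus,
                         subfamily=a.subfamily, family=a.family, order=a.order,
                         evidence="; ".join(f"{k}:{v}" for k, v in ev.items())))

    diagnostics: dict[str, object] = {}
    singleton_fams = [min(m) for f, m in fam_members.items() if len(m) == 1]
    if graph is not None and singleton_fams and len(genomes) > 1:
        for g in singleton_fams:
            diagnostics[f"connect_threshold:{g}"] = outlier_connection_threshold(graph, genomes, g)

    return TaxonomyResult(assignments=assignments, table=pd.DataFrame(rows),
                          family_trees=family_trees, diagnostics=diagnostics)


def family_tree(pangenome: PangenomeMatrix, proteins_by_id: dict[str, ProteinRecord],
                members: list[str], bootstrap_reps: int = 100, seed: int = 0) -> FamilyPhylogeny:
    """Midpoint-rooted bootstrapped NJ tree on a family's core proteins.

    One representative per genome and cluster (the longest member);
    clusters core to the family are aligned, concatenated and analysed
    under Poisson-corrected distances.
    """
    cores = core_clusters(pangenome, set(members))
    if not cores:
        raise ValueError(f"family {sorted(members)} has no core clusters; cannot build a tree")
    alignments: list[tuple[str, Alignment]] = []
    genome_of: dict[str, str] = {}
    for cl in cores:
        reps: dict[str, ProteinRecord] = {}
        for pid in cl.members:
            p = proteins_by_id[pid]
            g = p.source_genome
            if g not in members:
                continue
            if g not in reps or len(p.seq) > len(reps[g].seq):
                reps[g] = p
        seqs = [(p.id, p.seq) for p in sorted(reps.values(), key=lambda p: p.id)]
        for pid, _ in seqs:
            genome_of[pid] = proteins_by_id[pid].source_genome
        alignments.append((cl.cluster_id, progressive_align(seqs)))
    concat, parts = concatenate(alignments, genome_of, genomes=members)
    tree = bootstrap(concat, n_reps=bootstrap_reps, seed=seed)
    return FamilyPhylogeny(tree=midpoint_root(tree), alignment=concat, partitions=parts)
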