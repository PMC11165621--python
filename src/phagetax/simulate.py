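"""Synthetic megaphage-clade generator with full ground truth.

Simulates a clade of large phage genomes down a user-specified taxon tree:
an ancestral genome of codon-structured protein-coding genes separated by
intergenic spacers is evolved along each branch with per-site nucleotide
substitutions.  Substitutions inside genes are synonymous-biased (the
amino-acid sequence decays more slowly than the nucleotide sequence,
as in real coding DNA), never create stop codons, and change exactly the
drawn sites, so realised nucleotide divergence tracks the nominal
per-branch rate.  Gene gain (fresh random families on a branch, inserted
as a contiguous island) and per-leaf gene loss give the clade a pangenome
structure; an optional TAG recoding flag rewrites a fraction of glutamine
codons to TAG in designated taxa, emulating translation-table-15 phages.

Every output genome is traceable: the :class:`TruthTable` records taxonomy
labels per rank, the genetic code per genome, the gene-family layout of
every genome, expected pairwise divergence, and per-branch realised
substitution fractions.  Identical spec + seed give byte-identical FASTA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .records import GenomeRecord, revcomp

RANKS = ("family", "subfamily", "genus", "species")

_BASES = "ACGT"
_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODON_IDX = {c: i for i, c in enumerate(_CODONS)}
_STOPS = {"TAA", "TAG", "TGA"}
_T11 = CodonTable.unambiguous_dna_by_id[11].forward_table
_AA_OF = {c: _T11.get(c, "*") for c in _CODONS}
_AA_LIST = sorted(set(_T11.values()))
_AA_TO_CODONS = {aa: [c for c in _CODONS if _AA_OF[c] == aa] for aa in _AA_LIST}
_GLN_IDX = frozenset(_CODON_IDX[c] for c in ("CAA", "CAG"))
_TAG_IDX = _CODON_IDX["TAG"]

_SITE_SETS = [s for s in itertools.product((0, 1), repeat=3) if any(s)]


@lru_cache(maxsize=None)
def _variants(codon_idx: int, sites: tuple[int, int, int]) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Codons differing from ``codon_idx`` at exactly the flagged sites.

    Returns (all non-stop variants, synonymous non-stop variants).
    """
    codon = _CODONS[codon_idx]
    pools = [
        [b for b in _BASES if b != codon[i]] if sites[i] else [codon[i]] for i in range(3)
    ]
    allv, syn = [], []
    for combo in itertools.product(*pools):
        c = "".join(combo)
        if c in _STOPS:
            continue
        allv.append(_CODON_IDX[c])
        if _AA_OF[c] == _AA_OF[codon]:
            syn.append(_CODON_IDX[c])
    return tuple(allv), tuple(syn)


# ---------------------------------------------------------------------------
# Spec types


@dataclass
class TaxonNode:
    """One node of the taxon tree driving the simulation.

    ``branch`` is the expected substitutions/site on the edge above this
    node; ``rank`` labels the taxonomic rank this node defines (its name
    becomes the truth label for all leaves below).  ``n_accessory`` gene
    families are gained on the edge above and are present in all leaves
    below, minus per-leaf ``accessory_dropout``.  Leaves are nodes without
    children; their names become genome ids.
    """

    name: str
    branch: float = 0.0
    f_syn: float = 0.95
    rank: str | None = None
    n_accessory: int = 0
    accessory_dropout: float = 0.0
    recode: bool | None = None
    children: list["TaxonNode"] = field(default_factory=list)

    def leaves(self) -> list["TaxonNode"]:
        if not self.children:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]


@dataclass
class CladeSpec:
    """Full description of a simulated clade.

    ``n_core_families`` genes are planted in the common ancestor and kept
    in every genome (the universal core).  ``gc`` is the target genome
    molGC fraction; codon usage and spacer composition are biased to hit
    it.  ``recode_fraction`` is the fraction of ancestral glutamine codons
    flagged for TAG rewriting in recoded taxa.
    """

    tree: TaxonNode
    n_core_families: int
    gene_len_range: tuple[int, int] = (600, 1200)
    spacer_len_range: tuple[int, int] = (60, 180)
    gc: float = 0.27
    recode_fraction: float = 0.35
    recode_default: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core_families < 1:
            raise ValueError("n_core_families must be >= 1")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be a fraction in (0, 1)")
        if not 0 <= self.recode_fraction <= 1:
            raise ValueError("recode_fraction must be in [0, 1]")

    @classmethod
    def pair(cls, divergence: float, genome_length: int = 100_000,
             recode: bool = False, seed: int = 0, **kw) -> "CladeSpec":
        """Two genomes separated by ``divergence`` expected subs/site.

        The whole divergence sits on one branch so the realised pairwise
        difference is exactly binomial at the nominal rate (splitting it
        across both branches would let same-site hits partially cancel).
        """
        tree = TaxonNode("root", children=[
            TaxonNode("g1", branch=0.0),
            TaxonNode("g2", branch=divergence),
        ])
        return cls(tree=tree, n_core_families=_n_genes_for(genome_length, kw),
                   recode_default=recode, seed=seed, **kw)

    @classmethod
    def single(cls, recode: bool, genome_length: int = 55_000, seed: int = 0, **kw) -> "CladeSpec":
        """A lone genome, e.g. for genetic-code detection tests."""
        tree = TaxonNode("root", children=[TaxonNode("g1", branch=0.0)])
        return cls(tree=tree, n_core_families=_n_genes_for(genome_length, kw),
                   recode_default=recode, seed=seed, **kw)


def _n_genes_for(genome_length: int, kw: dict) -> int:
    if genome_length < 20_000:
        raise ValueError("genome_length must be >= 20000 nt")
    gene_mean = sum(kw.get("gene_len_range", (600, 1200))) / 2
    spacer_mean = sum(kw.get("spacer_len_range", (60, 180))) / 2
    n = int(genome_length / (gene_mean + spacer_mean))
    if n < 1:
        raise ValueError(f"cannot place any gene of mean length {gene_mean} in {genome_length} nt")
    return n


# ---------------------------------------------------------------------------
# Genome elements


@dataclass
class _Gene:
    family: str
    codons: np.ndarray  # codon indices incl. fixed start [0] and stop [-1]
    tag_flags: np.ndarray  # recode-eligible ancestral Gln positions
    strand: str

    def copy(self) -> "_Gene":
        return _Gene(self.family, self.codons.copy(), self.tag_flags.copy(), self.strand)


@dataclass
class _Spacer:
    bases: np.ndarray  # base indices 0-3

    def copy(self) -> "_Spacer":
        return _Spacer(self.bases.copy())


@dataclass
class TruthTable:
    """Ground truth accompanying a simulated clade."""

    taxonomy: pd.DataFrame  # genome_id + one column per rank
    table_id: dict[str, int]
    gene_families: pd.DataFrame  # genome_id, family_id, start, end, strand
    expected_divergence: pd.DataFrame  # square, expected subs/site between genomes
    branch_substitutions: pd.DataFrame  # node, expected, realised, n_sites
    proteins: dict[tuple[str, str], str]  # (genome_id, family_id) -> aa sequence


@dataclass
class SimulatedClade:
    genomes: list[GenomeRecord]
    truth: TruthTable


# ---------------------------------------------------------------------------
# Sequence generation helpers


def _solve_gc_bias(target: float, coding_fraction: float = 0.87) -> float:
    """Base bias g such that the expected genome GC hits ``target``.

    Codon usage weights synonyms by per-position base probabilities
    (g/2 for G/C, (1-g)/2 for A/T); spacers are sampled with the same g.
    Solved by bisection on the analytic expectation.
    """

    def coding_gc(g: float) -> float:
        tot = 0.0
        for aa in _AA_LIST:
            codons = _AA_TO_CODONS[aa]
            w = np.array([_codon_weight(c, g) for c in codons])
            w = w / w.sum()
            gc_counts = np.array([sum(b in "GC" for b in c) / 3 for c in codons])
            tot += float(w @ gc_counts)
        return tot / len(_AA_LIST)

    lo, hi = 0.01, 0.8
    for _ in range(60):
        mid = (lo + hi) / 2
        val = coding_fraction * coding_gc(mid) + (1 - coding_fraction) * mid
        if val < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _codon_weight(codon: str, g: float) -> float:
    w = 1.0
    for b in codon:
        w *= g / 2 if b in "GC" else (1 - g) / 2
    return w


class _GeneFactory:
    """Generates fresh random genes under the configured codon bias."""

    def __init__(self, spec: CladeSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.g = _solve_gc_bias(spec.gc)
        # per-aa synonym sampling distributions
        self.syn_probs = {}
        for aa in _AA_LIST:
            codons = _AA_TO_CODONS[aa]
            w = np.array([_codon_weight(c, self.g) for c in codons])
            self.syn_probs[aa] = (np.array([_CODON_IDX[c] for c in codons]), w / w.sum())
        self._kmer_guard: set[str] = set()

    def new_gene(self, family: str) -> _Gene:
        lo, hi = self.spec.gene_len_range
        n_codons = int(self.rng.integers(lo // 3, hi // 3 + 1))
        aas = self.rng.choice(len(_AA_LIST), size=n_codons - 2)
        body = np.empty(n_codons, dtype=np.int16)
        body[0] = _CODON_IDX["ATG"]
        for i, ai in enumerate(aas, start=1):
            idxs, probs = self.syn_probs[_AA_LIST[ai]]
            body[i] = idxs[self.rng.choice(len(idxs), p=probs)]
        body[-1] = _CODON_IDX["TAA" if self.rng.random() < 0.7 else "TGA"]
        aa_seq = "".join(_AA_OF[_CODONS[c]] for c in body[:-1])
        self._assert_novel(family, aa_seq)
        flags = np.zeros(n_codons, dtype=bool)
        gln = np.array([i for i in range(1, n_codons - 1) if body[i] in _GLN_IDX], dtype=int)
        if gln.size:
            flags[gln[self.rng.random(gln.size) < self.spec.recode_fraction]] = True
        strand = "+" if self.rng.random() < 0.5 else "-"
        return _Gene(family=family, codons=body, tag_flags=flags, strand=strand)

    def _assert_novel(self, family: str, aa_seq: str) -> None:
        # gained genes must not collide with existing families at high identity;
        # shared 12-mers are a cheap proxy asserted at generation time
        kmers = {aa_seq[i : i + 12] for i in range(0, len(aa_seq) - 12, 4)}
        if kmers & self._kmer_guard:
            raise RuntimeError(f"gained gene {family} collides with an existing family")
        self._kmer_guard |= kmers

    def new_spacer(self) -> _Spacer:
        lo, hi = self.spec.spacer_len_range
        n = int(self.rng.integers(lo, hi + 1))
        p = np.array([(1 - self.g) / 2, self.g / 2, self.g / 2, (1 - self.g) / 2])
        return _Spacer(self.rng.choice(4, size=n, p=p))


# ---------------------------------------------------------------------------
# Evolution


# Within genes, substitutions fall preferentially on third codon positions
# (purifying selection leaves mostly synonymous changes fixed); the weights
# keep the total per-codon rate at 3d while letting amino-acid identity decay
# much more slowly than nucleotide identity, as in real coding DNA.
_SITE_WEIGHTS = (0.10, 0.05, 0.85)


def _site_probs(d: float) -> np.ndarray:
    """Per-site hit probabilities summing to 3d, capped at 1 per site."""
    p = np.array([3 * d * w for w in _SITE_WEIGHTS])
    for _ in range(3):
        over = np.clip(p - 1.0, 0, None).sum()
        p = np.clip(p, 0, 1.0)
        free = p < 1.0
        if over <= 0 or not free.any():
            break
        p[free] += over / free.sum()
    return np.clip(p, 0, 1.0)


def _mutate_gene(gene: _Gene, d: float, f_syn: float, gc_weights: np.ndarray,
                 recode_fraction: float, rng: np.random.Generator) -> int:
    """Per-site substitutions on a gene's internal codons; returns #sites changed.

    Sites are hit with third-position-biased probabilities totalling 3d per
    codon; the codon is replaced by one differing at exactly the hit sites,
    synonymous with probability ``f_syn`` when a synonymous variant exists,
    and weighted by the genome's codon-composition bias so base composition
    is stationary.  Start and stop codons are held fixed so the gene stays
    callable, and stop codons are never created.  TAG-recoding flags stay
    stationary too: a codon newly mutated into glutamine is flagged with
    the recoding probability, and a codon leaving glutamine loses its flag,
    so deep divergence does not erode a clade's recoding signal.
    """
    n = len(gene.codons)
    if n <= 2 or d <= 0:
        return 0
    hits = rng.random((n - 2, 3)) < _site_probs(d)
    rows = np.nonzero(hits.any(axis=1))[0]
    changed = 0
    for r in rows:
        i = r + 1
        old = int(gene.codons[i])
        sites = tuple(int(x) for x in hits[r])
        allv, syn = _variants(old, sites)
        if not allv:
            continue
        pool = syn if (syn and rng.random() < f_syn) else allv
        w = gc_weights[list(pool)]
        new = pool[int(rng.choice(len(pool), p=w / w.sum()))]
        gene.codons[i] = new
        was_gln, is_gln = old in _GLN_IDX, new in _GLN_IDX
        if is_gln and not was_gln:
            gene.tag_flags[i] = rng.random() < recode_fraction
        elif not is_gln:
            gene.tag_flags[i] = False
        changed += sum(sites)
    return changed


def _mutate_spacer(sp: _Spacer, d: float, g: float, rng: np.random.Generator) -> int:
    hits = np.nonzero(rng.random(sp.bases.size) < d)[0]
    p_base = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    for h in hits:
        p = p_base.copy()
        p[sp.bases[h]] = 0.0
        sp.bases[h] = rng.choice(4, p=p / p.sum())
    return int(hits.size)


# ---------------------------------------------------------------------------
# Main driver


def simulate_clade(spec: CladeSpec) -> SimulatedClade:
    """Evolve a genome clade down ``spec.tree`` and return it with truth."""
    rng = np.random.default_rng(spec.seed)
    factory = _GeneFactory(spec, rng)

    # ancestral genome: spacer, gene, spacer, gene, ... spacer
    elements: list[_Gene | _Spacer] = [factory.new_spacer()]
    for k in range(spec.n_core_families):
        elements.append(factory.new_gene(f"core{k:04d}"))
        elements.append(factory.new_spacer())

    branch_log: list[dict] = []
    leaves: list[dict] = []
    fam_counter = itertools.count()

    gc_weights = np.array([_codon_weight(c, factory.g) for c in _CODONS])
    gc_weights[[_CODON_IDX[s] for s in _STOPS]] = 0.0

    def descend(node: TaxonNode, elems: list, labels: dict[str, str],
                dropout: dict[str, float], recode: bool, depth_from_root: float,
                loss_applied: bool) -> None:
        elems = [e.copy() for e in elems]
        # substitutions on the edge above this node
        n_sites = changed = 0
        for e in elems:
            if isinstance(e, _Gene):
                changed += _mutate_gene(e, node.branch, node.f_syn, gc_weights,
                                        spec.recode_fraction, rng)
                n_sites += 3 * (len(e.codons) - 2)
            else:
                changed += _mutate_spacer(e, node.branch, factory.g, rng)
                n_sites += e.bases.size
        if node.branch > 0:
            branch_log.append(dict(node=node.name, expected=node.branch,
                                   realised=changed / n_sites, n_sites=n_sites))
        # gene gain: a contiguous island of fresh families
        dropout = dict(dropout)
        if node.n_accessory:
            island: list[_Gene | _Spacer] = []
            for _ in range(node.n_accessory):
                fam = f"acc{next(fam_counter):04d}"
                island.append(factory.new_gene(fam))
                island.append(factory.new_spacer())
                dropout[fam] = node.accessory_dropout
            pos = 1 + 2 * int(rng.integers(0, (len(elems) - 1) // 2 + 1))
            elems[pos:pos] = island
        labels = dict(labels)
        if node.rank:
            labels[node.rank] = node.name
        if node.recode is not None:
            recode = node.recode
        depth = depth_from_root + node.branch
        # gene loss decisions are shared by everything below a species node
        # (strains of one species have identical gene content); trees without
        # a species rank apply loss at the leaves instead
        if not loss_applied and (node.rank == "species" or not node.children):
            elems = _apply_loss(elems, dropout, rng)
            loss_applied = True
        if node.children:
            for ch in node.children:
                descend(ch, elems, labels, dropout, recode, depth, loss_applied)
            return
        leaves.append(dict(node=node, elements=elems, labels=labels,
                           recode=recode, depth=depth))

    descend(spec.tree, elements, {}, {}, spec.recode_default, 0.0, False)

    genomes: list[GenomeRecord] = []
    fam_rows: list[dict] = []
    tax_rows: list[dict] = []
    table_id: dict[str, int] = {}
    proteins: dict[tuple[str, str], str] = {}
    for leaf in leaves:
        gid = leaf["node"].name
        parts: list[str] = []
        pos = 0
        for e in leaf["elements"]:
            if isinstance(e, _Spacer):
                s = "".join(_BASES[b] for b in e.bases)
                parts.append(s)
                pos += len(s)
            else:
                codons = e.codons.copy()
                if leaf["recode"]:
                    mask = e.tag_flags & np.isin(codons, list(_GLN_IDX))
                    codons[mask] = _TAG_IDX
                cds = "".join(_CODONS[c] for c in codons)
                start, end = pos, pos + len(cds)
                parts.append(cds if e.strand == "+" else revcomp(cds))
                fam_rows.append(dict(genome_id=gid, family_id=e.family,
                                     start=start, end=end, strand=e.strand))
                # protein truth translated with TAG read as Gln
                proteins[(gid, e.family)] = "".join(
                    "Q" if c == _TAG_IDX else _AA_OF[_CODONS[c]] for c in e.codons[:-1]
                )
                pos = end
        genomes.append(GenomeRecord(id=gid, seq="".join(parts)))
        table_id[gid] = 15 if leaf["recode"] else 11
        row = {"genome_id": gid}
        for rank in RANKS:
            row[rank] = leaf["labels"].get(rank, "all")
        tax_rows.append(row)

    ids = [g.id for g in genomes]
    depth = {lf["node"].name: lf["depth"] for lf in leaves}
    exp = pd.DataFrame(0.0, index=ids, columns=ids)
    # expected divergence = sum of branch lengths on the path (shared prefix removed)
    paths = _leaf_paths(spec.tree)
    for a, b in itertools.combinations(ids, 2):
        shared = sum(n.branch for n in _common_prefix(paths[a], paths[b]))
        div = depth[a] + depth[b] - 2 * shared
        exp.loc[a, b] = exp.loc[b, a] = div

    truth = TruthTable(
        taxonomy=pd.DataFrame(tax_rows),
        table_id=table_id,
        gene_families=pd.DataFrame(fam_rows),
        expected_divergence=exp,
        branch_substitutions=pd.DataFrame(branch_log),
        proteins=proteins,
    )
    return SimulatedClade(genomes=genomes, truth=truth)


def _apply_loss(elems: list, dropout: dict[str, float], rng: np.random.Generator) -> list:
    kept = []
    for e in elems:
        if isinstance(e, _Gene) and dropout.get(e.family, 0.0) > 0:
            if rng.random() < dropout[e.family]:
                continue
        kept.append(e)
    return kept


def _leaf_paths(tree: TaxonNode) -> dict[str, list[TaxonNode]]:
    out: dict[str, list[TaxonNode]] = {}

    def walk(node: TaxonNode, path: list[TaxonNode]) -> None:
        path = path + [node]
        if not node.children:
            out[node.name] = path
        for ch in node.children:
            walk(ch, path)

    walk(tree, [])
    return out


def _common_prefix(a: list, b: list) -> list:
    out = []
    for x, y in zip(a, b):
        if x is y:
            out.append(x)
        else:
            break
    return out


# ---------------------------------------------------------------------------
# The benchmark clade: a Lak-like 23-genome design


def lak_like_tree() -> TaxonNode:
    """Taxon tree emulating a Lak-megaphage-like clade.

    23 genomes: one 22-genome family split into two subfamilies (genera of
    11, 9 and 2 genomes; species sizes 4,1,1,1,2,2 / 9 / 2) plus one deeply
    divergent single-genome outlier family, all TAG-recoded.  Branch
    depths are chosen so intergenomic similarity lands >95 % within
    species, ~80 % across species within a genus, ~0 across genera, and so
    core-protein identity stays above the 70 % clustering threshold across
    the whole 22-genome family while the outlier's homologs fall to
    ~45-55 % identity (clusterable only at permissive thresholds).
    """
    b_strain, b_sp, b_gen, b_sf = 0.005, 0.03, 0.08, 0.04

    def species(name: str, strains: list[str]) -> TaxonNode:
        return TaxonNode(name, branch=b_sp, rank="species", n_accessory=3,
                         children=[TaxonNode(s, branch=b_strain) for s in strains])

    gen1 = TaxonNode("gen1", branch=b_gen, rank="genus", n_accessory=15,
                     children=[
                         species("sp1", ["G01", "G02", "G03", "G04"]),
                         species("sp2", ["G05"]),
                         species("sp3", ["G06"]),
                         species("sp4", ["G07"]),
                         species("sp5", ["G08", "G09"]),
                         species("sp6", ["G10", "G11"]),
                     ])
    gen2 = TaxonNode("gen2", branch=b_gen, rank="genus", n_accessory=15,
                     children=[species("sp7", [f"B{i:02d}" for i in range(1, 10)])])
    sfa = TaxonNode("sfA", branch=b_sf, rank="subfamily", n_accessory=14,
                    children=[gen1, gen2])
    gen3 = TaxonNode("gen3", branch=b_gen, rank="genus", n_accessory=15,
                     children=[species("sp8", ["H01", "H02"])])
    sfb = TaxonNode("sfB", branch=b_sf, rank="subfamily", n_accessory=14,
                    children=[gen3])
    fam1 = TaxonNode("fam1", branch=0.0, rank="family", n_accessory=12,
                     children=[sfa, sfb])
    outlier = TaxonNode("fam2", branch=0.45, f_syn=0.7, rank="family", n_accessory=35,
                        children=[TaxonNode("sfC", branch=0.0, rank="subfamily", children=[
                            TaxonNode("gen4", branch=0.0, rank="genus", children=[
                                species("sp9", ["S01"])])])])
    return TaxonNode("order", children=[fam1, outlier])


def lak_like_fixture(seed: int = 0) -> SimulatedClade:
    """The standard 23-genome benchmark clade at desk scale.

    Genome lengths are roughly one tenth of real Lak megaphages (~50 kb
    instead of ~500 kb) so the full pipeline runs in minutes; all genomes
    use the recoded (table 15) genetic code, AT-rich like real Lak phages.
    """
    spec = CladeSpec(tree=lak_like_tree(), n_core_families=8,
                     recode_default=True, seed=seed)
    return simulate_clade(spec)
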