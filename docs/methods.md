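# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `phagetax`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external analyses.

## Genetic-code detection

ORFs are predicted by a deterministic rule-based caller: in each of the six
frames, every stop-to-stop interval contributes the ORF running from its
first in-frame start codon (ATG/GTG/TTG) to the base before the stop, or to
the contig end. The minimum ORF length (default 90 nt, the conventional
minimum gene length of bacterial callers) is applied to the gene span
including the stop codon; reported coordinates exclude it. Contigs are
treated as linear (the intended inputs are genomes resolved to completion
with defined termini). Codons containing ambiguity codes translate to X and
are never starts or stops.

Because six-frame calling over-generates, ORFs are reduced by greedy
longest-first selection in which a candidate is kept only if it overlaps
every already-kept ORF by at most `max_overlap` nt (default 30, approximating
the limited gene overlap of real annotations). This guarantees the summed
ORF length cannot meaningfully exceed the genome length, making the coding
capacity CC = 100 × Σ ORF length / genome length a well-behaved statistic.

A genome is assigned translation table 15 when ΔCC = CC₁₅ − CC₁₁ ≥ 10
percentage points. The threshold sits between the two regimes the statistic
produces: genomes without TAG reassignment give ΔCC near 0 (measured
≈ 0–0.5 on simulated standard-code genomes, occasionally slightly negative
on real data), while TAG-recoded genomes give ΔCC well above 10 (≈ 12–14 on
the simulated clades here) because internal TAG codons fragment genes under
table 11 and the fragments restart only at the next in-frame start codon.

The caller is *not* a reimplementation of a trained gene model: it has no
RBS scoring, no coding statistics, and will call spurious short ORFs in
intergenic DNA. That is acceptable because its sole load-bearing output is
the coding-capacity differential, which depends on gene fragmentation, not
on exact gene boundaries.

## Pangenome construction

Proteins are compared by global alignment (BLOSUM62, gap open 11, extend 1 —
standard protein defaults). Identity is matches over aligned columns with
internal gap columns counted; coverage of each sequence is its aligned span
(first to last residue paired with the partner) over its length, so terminal
overhangs reduce coverage but not identity. Clusters are connected
components of the graph with an edge at identity ≥ 70 % and mutual coverage
≥ 0.8 (transitive, single-linkage semantics: one strong chain connects a
component even if some member pairs fall below threshold).

For speed, alignments are computed only for candidate pairs sharing at
least two distinct amino-acid 5-mers, plus a provably safe length-ratio
skip (identity cannot exceed shortest/longest length). The prefilter is
asserted equivalent to exhaustive all-vs-all union-find clustering in the
test suite. All pairwise identities above a 15 % recording floor are kept,
so the graph can be re-thresholded cheaply — this supports both the
core-count-vs-threshold monotonicity checks and the outlier diagnostic
(the highest threshold at which an isolated genome first shares a cluster).

## Intergenomic similarity

Each query genome is cut into consecutive non-overlapping 3 kb fragments
(terminal remainders shorter than half a fragment are dropped, longer ones
kept). A fragment is aligned end-to-end into the partner genome with
`edlib` (semi-global, gaps allowed); identity is 1 − edit distance /
fragment length. The forward strand is searched first and the reverse
complement only when the forward strand yields no qualifying match — a
fragment cannot have a true orthologous hit on both strands of the same
region, so this is an exact shortcut in practice. A fragment counts as an
orthologous match at ≥ 80 % identity.

ANI is the mean identity of matched fragments (0 with none), AF the matched
fraction, and S = ANI × AF. The two directions of a pair are averaged into
a symmetric matrix with diagonal 100; values below 0.01 % are reported as 0.
The 3 kb / 80 % defaults follow common fragment-ANI conventions. The edit
distance cap passed to the aligner is set ~25 % above the rejection bound so
unrelated fragments exit early without affecting any reported identity.

## Phylogeny

Per-cluster alignments use progressive MSA (pairwise-distance guide tree,
profile merging; provided by biotite, deterministic for fixed input) with
one representative per genome and cluster — the longest member, collapsing
paralogs. Alignments are concatenated into a genome supermatrix with
all-gap blocks for missing genomes and a recorded partition table.

Distances are Poisson-corrected p-distances, d = −ln(1 − p), with pairwise
gap deletion (complete deletion would discard most columns of a
concatenation containing all-gap blocks) and p clamped at 0.95 with a
warning. Trees are canonical neighbor joining ending in the standard
trifurcation; negative branch lengths are clamped to zero with the excess
moved to the sibling edge of the cherry. NJ is exact on additive matrices
(asserted against randomly generated trees) and agrees topologically with
an independent NJ implementation on random inputs.

Support values come from a seeded column-resampling bootstrap (default 100
replicates, configurable to 1000): the support of each internal bipartition
of the full-data tree is the percentage of replicate trees containing it.
Trees are midpoint-rooted. Distance-based NJ deliberately replaces
model-fitted maximum likelihood: the output that matters for rank
demarcation is the topology near the root, which NJ resolves with full
support on the simulated clades at a small fraction of the cost, and
deterministically.

## Rank demarcation

* **Species:** single-linkage components at S ≥ 95 (inclusive). Single
  linkage is deliberate: a strain slightly below threshold against one
  species member but above it against others stays in the species.
* **Genus:** same semantics at S ≥ 70.
* **Family:** components of the genome graph with an edge when two genomes
  share at least one protein cluster at the 70 % pangenome threshold. A
  genome sharing none is its own family; a diagnostic reports the highest
  clustering threshold at which it would connect.
* **Subfamily:** the two root-child clades of the family's midpoint-rooted
  core-protein tree, accepted when the root-adjacent bootstrap support is
  ≥ 95; otherwise the family remains one subfamily (logged). Families of
  one or two genomes are trivially one subfamily. No numeric similarity
  criterion separates subfamily from genus rank; the root-bipartition rule
  is this package's stated interpretation and is flagged in the evidence
  column of the output.
* **Order:** all genomes of one run are assumed one order; demarcating the
  order against outgroups requires proteome-scale comparisons outside this
  pipeline's evidence and is taken as an input label.

Nesting (species ⊆ genus ⊆ subfamily ⊆ family) is asserted; a violation is
a hard error naming the offending genomes. Labels are stable placeholders
(`sp1`, `gen2`, ...) numbered by each group's lexicographically smallest
member; scientific names are supplied by the user through a name map, never
inferred.

## Synthetic clade generator

The generator evolves an ancestral genome — alternating intergenic spacers
and codon-structured genes (ATG start, single TAA/TGA stop, no internal
stops) — down a user-specified taxon tree.

*Substitutions.* Per branch, each codon's sites are hit with probabilities
summing to 3d (d = expected substitutions/site) but concentrated on third
positions (weights 0.10/0.05/0.85). A hit codon is replaced by a codon
differing at exactly the hit sites, synonymous with probability `f_syn`
(default 0.95) when a synonymous variant exists, never a stop, and weighted
by the genome's base-composition bias so composition is stationary. This
makes amino-acid identity decay several-fold more slowly than nucleotide
identity, as in real coding DNA, while keeping realised nucleotide
divergence equal to the nominal rate (asserted per branch within three
standard errors). Spacers mutate site-wise with composition-biased
replacement. There is no rate heterogeneity across sites and no
recombination, and start/stop codons are held fixed — sufficient for
threshold-based demarcation testing, but real aligned-fraction and
identity distributions are broader than the simulated ones.

*Gene content.* Accessory gene families are gained on designated branches
as contiguous islands of fresh random genes (asserted not to collide with
existing families) and lost with a configurable per-family probability.
Loss decisions are made at species-rank nodes, so strains of one species
have identical gene content — without this, independent per-strain loss
would depress the aligned fraction between strains and blur the species
boundary, which real within-species pairs do not show. In trees without a
species rank, loss applies at the leaves.

*Recoding.* Each glutamine codon carries a TAG-rewriting flag with
probability `recode_fraction`; recoded leaves rewrite flagged positions
still holding CAA/CAG. Flags are inherited (TAG positions are concordant
within clades, as in real recoded lineages) and their density is kept
stationary under evolution: a codon mutating into glutamine is flagged
with the same probability and a codon leaving glutamine loses its flag,
so deep divergence does not erode a clade's recoding signal. The default
fraction is 0.35: at 300-codon genes with ~5 % glutamine this plants ~5
TAGs per gene and yields ΔCC ≈ 14–18 on ~50-gene genomes, with a worst
observed per-genome value of ≈ 12.5 across six benchmark-clade seeds —
comfortably above the 10-point calling threshold. (Smaller fractions were
evaluated during design and rejected: 0.15 gives ΔCC ≈ 8.3 ± 0.6, below
the threshold, because the six-frame caller re-initiates ORFs at the
first in-frame start after each TAG and thereby recovers roughly two
thirds of the fragmented coding length; 0.25 leaves individual genomes
within sampling reach of the threshold.)

*Composition.* Codon usage and spacer composition are biased toward a
target molGC (default 0.27 at the spec level, realised ≈ 29–31 % — the
AT-rich window of real gut megaphages); the bias parameter is solved by
bisection from the analytic GC expectation.

*Benchmark clade.* `lak_like_fixture` plants 23 genomes: a 22-genome family
(two subfamilies; genera of 11, 9 and 2; species of sizes 4,1,1,1,2,2 / 9 /
2) plus one deeply divergent single-genome family, all TAG-recoded, at
~50 kb — megaphage gene architecture at one-tenth length so the full
pipeline runs in about two minutes per seed on one CPU. Branch depths
(strain 0.005, species 0.03, genus 0.08, subfamily 0.04 substitutions/site;
outlier 0.45 with `f_syn` 0.7) were chosen once, by design-time calibration,
so that the observable bands fall on the correct sides of every demarcation
threshold with margin: within-species S ≈ 98–99, within-genus S ≈ 75–90,
cross-genus S ≈ 15–50, cross-subfamily core-protein identity ≈ 78–85 %
(above the 70 % clustering threshold), outlier identity ≈ 45–55 % (below
70 %, above 25 %). Genome lengths, gene lengths (600–1200 nt) and spacer
lengths (60–180 nt) match megaphage gene density (~1 gene/kb).

## Numerical and degenerate-input choices

* GC is computed over unambiguous bases only; >10 % ambiguity triggers a
  warning; an all-N sequence is an error.
* Identity of an empty protein is an error; clustering a single protein
  yields one singleton cluster.
* A genome shorter than half a fragment cannot be fragmented (error); a
  single genome fails the similarity stage with ">=2 genomes required".
* Ties: ORF selection breaks length ties by smaller start then forward
  strand; cluster ids order by size then smallest member; partition labels
  order by smallest member; dendrogram columns are sorted before linkage.
* All randomness (bootstrap, simulation) flows from explicit integer seeds;
  re-running a pipeline with the same config and inputs reproduces every
  numeric output exactly. Results are independent of `--threads`.

## Known limitations

* The ORF caller is rule-based; exact parity with trained gene callers is
  not claimed, so coding capacities on real genomes may differ by a few
  points from published values (the ΔCC contrast is robust to this).
* MMseqs2-style clustering is approximated by exact all-vs-all alignment
  components; cluster counts on real data are comparable, not identical.
* The similarity statistic uses query-side fragment totals per direction
  and then averages directions; other denominator conventions converge
  after pair averaging but can differ slightly for very different genome
  lengths.
* Maximum-likelihood phylogenetics, per-partition model selection and
  proteome-scale order demarcation are out of scope.
* The simulator has no indels within genes, no HGT and no rate
  heterogeneity; passing its tests demonstrates correct threshold logic
  and pipeline plumbing, not robustness to every property of real data.
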