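"""Alternative genetic-code detection via coding-capacity differentials.

Many huge gut phages repurpose the TAG stop codon to encode glutamine
(translation table 15).  Calling ORFs on such a genome with the standard
bacterial table 11 fragments most genes at internal TAG codons, so the
fraction of the genome covered by predicted ORFs ("coding capacity")
drops sharply.  The difference in coding capacity between table 15 and
table 11 (dCC = cc15 - cc11) is therefore a robust detector of TAG
reassignment: recoded genomes show a large positive dCC, standard-code
genomes a dCC near zero.

The ORF caller here is deliberately rule-based and deterministic: for
every stop-to-stop interval in each of the six frames it emits the ORF
from the first in-frame start codon to the stop.  That is sufficient for
the coding-capacity statistic; it does not attempt to reproduce a trained
gene model's exact calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

from .records import GenomeRecord, ProteinRecord, revcomp

START_CODONS = frozenset({"ATG", "GTG", "TTG"})

DEFAULT_MIN_ORF_LEN = 90  # nt, matching the usual minimum gene length of bacterial callers
DEFAULT_MAX_OVERLAP = 30  # nt of tolerated overlap between selected ORFs
DEFAULT_DELTA_THRESHOLD = 10.0  # percentage points of dCC calling table 15


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: codon map plus its stop and start codon sets."""

    table_id: int
    stops: frozenset[str]
    starts: frozenset[str]
    codon_to_aa: dict[str, str]

    @staticmethod
    @lru_cache(maxsize=None)
    def from_table(table_id: int) -> "GeneticCode":
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        return GeneticCode(
            table_id=table_id,
            stops=frozenset(tbl.stop_codons),
            starts=START_CODONS,
            codon_to_aa=dict(tbl.forward_table),
        )

    def translate_codon(self, codon: str) -> str:
        """Amino acid for a codon; ambiguous codons give 'X'."""
        return self.codon_to_aa.get(codon, "X")


TABLE11 = GeneticCode.from_table(11)
TABLE15 = GeneticCode.from_table(15)


@dataclass(frozen=True)
class Orf:
    """One open reading frame in forward-strand genome coordinates.

    ``start``/``end`` are 0-based half-open and exclude the stop codon;
    ``frame`` is the frame index (0-2) on the strand it was read from.
    """

    start: int
    end: int
    strand: str
    frame: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Orf") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class OrfSet:
    """Selected, non-redundant ORFs for one genome under one code."""

    genome_id: str
    table_id: int
    orfs: list[Orf]
    genome_length: int

    @property
    def coding_capacity(self) -> float:
        return 100.0 * sum(o.length_nt for o in self.orfs) / self.genome_length


@dataclass(frozen=True)
class CodeCall:
    """Per-genome genetic-code decision and its evidence."""

    genome_id: str
    cc11: float
    cc15: float
    threshold: float

    @property
    def delta(self) -> float:
        return self.cc15 - self.cc11

    @property
    def assigned_table(self) -> int:
        return 15 if self.delta >= self.threshold else 11


def _scan_strand(seq: str, code: GeneticCode, min_orf_len: int, strand: str, genome_len: int) -> list[Orf]:
    orfs: list[Orf] = []
    n = len(seq)
    stops = code.stops
    starts = code.starts
    for frame in range(3):
        start_pos = -1  # first start codon seen in the current stop-to-stop interval
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in stops:
                # the minimum length counts the stop codon (gene span), but
                # reported coordinates exclude it
                if start_pos >= 0 and pos + 3 - start_pos >= min_orf_len:
                    orfs.append(_mk_orf(start_pos, pos, strand, frame, genome_len))
                start_pos = -1
            elif start_pos < 0 and codon in starts:
                start_pos = pos
        # interval running off the contig end: ORF up to the last full codon
        last = frame + 3 * ((n - frame) // 3)
        if start_pos >= 0 and last - start_pos >= min_orf_len:
            orfs.append(_mk_orf(start_pos, last, strand, frame, genome_len))
    return orfs


def _mk_orf(s: int, e: int, strand: str, frame: int, genome_len: int) -> Orf:
    if strand == "+":
        return Orf(start=s, end=e, strand="+", frame=frame)
    # coordinates were on the reverse complement; map back to forward strand
    return Orf(start=genome_len - e, end=genome_len - s, strand="-", frame=frame)


def find_orfs(rec: GenomeRecord, code: GeneticCode, min_orf_len: int = DEFAULT_MIN_ORF_LEN) -> list[Orf]:
    """Six-frame ORF prediction on a linear contig.

    For each stop-to-stop interval in each frame, the ORF runs from the
    first in-frame start codon (ATG/GTG/TTG) to the base before the stop
    (or to the contig end).  Codons containing ambiguity codes are never
    starts or stops.
    """
    if min_orf_len < 3 or min_orf_len % 3:
        raise ValueError("min_orf_len must be >=3 and divisible by 3")
    n = len(rec.seq)
    out = _scan_strand(rec.seq, code, min_orf_len, "+", n)
    out += _scan_strand(revcomp(rec.seq), code, min_orf_len, "-", n)
    return out


def select_orfs(orfs: list[Orf], max_overlap: int = DEFAULT_MAX_OVERLAP) -> list[Orf]:
    """Greedy longest-first non-redundant ORF selection.

    An ORF is kept iff it overlaps every already-kept ORF by at most
    ``max_overlap`` nt, so summed ORF lengths cannot exceed the genome
    length (for max_overlap = 0).  Ties on length break by smaller start,
    then '+' strand.
    """
    ranked = sorted(orfs, key=lambda o: (-o.length_nt, o.start, 0 if o.strand == "+" else 1))
    kept: list[Orf] = []
    for cand in ranked:
        if all(cand.overlap(k) <= max_overlap for k in kept):
            kept.append(cand)
    kept.sort(key=lambda o: (o.start, o.end))
    return kept


def orf_set(rec: GenomeRecord, code: GeneticCode, min_orf_len: int = DEFAULT_MIN_ORF_LEN,
            max_overlap: int = DEFAULT_MAX_OVERLAP) -> OrfSet:
    """Predict, then greedily select, ORFs for one genome under one code."""
    selected = select_orfs(find_orfs(rec, code, min_orf_len), max_overlap)
    return OrfSet(genome_id=rec.id, table_id=code.table_id, orfs=selected, genome_length=rec.length)


def coding_capacity(rec: GenomeRecord, code: GeneticCode, min_orf_len: int = DEFAULT_MIN_ORF_LEN,
                    max_overlap: int = DEFAULT_MAX_OVERLAP) -> float:
    """Summed length of selected ORFs as a percentage of genome length."""
    return orf_set(rec, code, min_orf_len, max_overlap).coding_capacity


def call_code(rec: GenomeRecord, delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
              min_orf_len: int = DEFAULT_MIN_ORF_LEN, max_overlap: int = DEFAULT_MAX_OVERLAP) -> CodeCall:
    """Assign table 15 iff cc15 - cc11 >= delta_threshold, else table 11."""
    cc11 = coding_capacity(rec, TABLE11, min_orf_len, max_overlap)
    cc15 = coding_capacity(rec, TABLE15, min_orf_len, max_overlap)
    return CodeCall(genome_id=rec.id, cc11=cc11, cc15=cc15, threshold=delta_threshold)


def translate_orf(rec: GenomeRecord, orf: Orf, code: GeneticCode) -> str:
    """Protein sequence of an ORF (start codon translated as-is, no leading M fix)."""
    if orf.strand == "+":
        cds = rec.seq[orf.start : orf.end]
    else:
        cds = revcomp(rec.seq[orf.start : orf.end])
    return "".join(code.translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def proteome(rec: GenomeRecord, code: GeneticCode, min_orf_len: int = DEFAULT_MIN_ORF_LEN,
             max_overlap: int = DEFAULT_MAX_OVERLAP) -> list[ProteinRecord]:
    """Selected ORFs translated under ``code``, ids ``<genome>|<index>``."""
    oset = orf_set(rec, code, min_orf_len, max_overlap)
    prots = []
    for i, o in enumerate(oset.orfs, start=1):
        seq = translate_orf(rec, o, code)
        prots.append(
            ProteinRecord(
                id=f"{rec.id}|{i:04d}",
                seq=seq,
                source_genome=rec.id,
                coords=(o.start, o.end),
                strand=o.strand,
            )
        )
    return prots
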