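"""Core sequence record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeRecord:
    """One complete phage genome.

    ``id`` is the FASTA header token up to the first whitespace; the full
    header is kept as ``description``.  The sequence is uppercase DNA
    (U already mapped to T on input).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        from .io import gc_content

        return gc_content(self)


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein tied back to its source genome.

    ``coords`` are 0-based half-open genome coordinates of the encoding ORF
    on the forward strand; ``strand`` is '+' or '-'.
    """

    id: str
    seq: str
    source_genome: str = ""
    coords: tuple[int, int] = (0, 0)
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if "*" in self.seq:
            raise ValueError(f"protein {self.id!r}: internal stop symbol")

    def __len__(self) -> int:
        return len(self.seq)


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]
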