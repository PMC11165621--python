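"""FASTA input/output and per-genome descriptive statistics.

Reading is strict: duplicate ids and non-IUPAC characters are hard errors,
because every downstream stage keys on genome ids and assumes clean DNA.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GenomeRecord, ProteinRecord

logger = logging.getLogger(__name__)

_IUPAC_NT = set("ACGTRYSWKMBDHVN")
_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (possibly multi-record, multi-line) nucleotide FASTA.

    Sequences are uppercased and U is mapped to T.  Errors on an empty
    file, duplicate ids, or characters outside the IUPAC DNA alphabet.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        bad = set(seq) - _IUPAC_NT
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"record {rec.id!r}: non-IUPAC character {seq[pos]!r} at position {pos}"
            )
        records.append(GenomeRecord(id=rec.id, seq=seq, description=rec.description))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord | ProteinRecord], path: str | Path, width: int = 80) -> None:
    """Write records to FASTA, wrapping lines at ``width`` columns."""
    seqrecs = []
    for r in records:
        desc = getattr(r, "description", "") or ""
        # SeqIO prepends the id to the description on write
        desc = desc[len(r.id) :].strip() if desc.startswith(r.id) else desc
        seqrecs.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an amino-acid FASTA into ProteinRecords (no coordinates)."""
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"record {rec.id!r}: non-amino-acid characters {sorted(bad)}")
        out.append(ProteinRecord(id=rec.id, seq=seq))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def gc_content(rec: GenomeRecord) -> float:
    """molGC (%) over unambiguous bases only.

    N (and other ambiguity codes) are excluded from the denominator; a
    sequence with no unambiguous base has undefined GC and raises.
    A record with >10 % ambiguous bases triggers a log warning, since the
    statistic then describes only part of the assembly.
    """
    seq = rec.seq
    a, c, g, t = seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError(f"genome {rec.id!r}: GC undefined (no unambiguous bases)")
    frac_ambig = 1.0 - denom / len(seq)
    if frac_ambig > 0.10:
        logger.warning(
            "genome %s: %.1f%% ambiguous bases excluded from GC", rec.id, 100 * frac_ambig
        )
    return 100.0 * (g + c) / denom


def genome_summary(records: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Length / molGC summary table, one row per genome."""
    return pd.DataFrame(
        {
            "genome_id": [r.id for r in records],
            "length_bp": [r.length for r in records],
            "gc_percent": [round(gc_content(r), 2) for r in records],
        }
    )
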