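"""Fragment-based intergenomic similarity: S = ANI x aligned fraction.

The query genome is cut into consecutive non-overlapping fragments
(default 3 kb); each fragment is aligned against the full reference (both
strands) and counts as an orthologous match when its best alignment
reaches the identity floor (default 80 %).  ANI is the mean identity of
matched fragments, the aligned fraction (AF) is matched/total fragments,
and the intergenomic similarity S = ANI x AF penalises pairs that are
locally identical but share only part of their genomes.  The two
directions of a pair are averaged into a symmetric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .records import GenomeRecord, revcomp

DEFAULT_FRAGMENT_LEN = 3000  # nt
DEFAULT_MIN_IDENTITY = 80.0  # percent
REPORTING_FLOOR = 0.01  # percent; smaller S values are written as 0


def fragment_genome(rec: GenomeRecord, fragment_len: int = DEFAULT_FRAGMENT_LEN) -> list[str]:
    """Consecutive non-overlapping windows of ``fragment_len``.

    A terminal remainder shorter than half a fragment is dropped,
    otherwise kept as a short fragment.  A genome shorter than half a
    fragment cannot be fragmented at all and raises.
    """
    if fragment_len < 100:
        raise ValueError("fragment_len must be >= 100 nt")
    n = rec.length
    if n < fragment_len / 2:
        raise ValueError(
            f"genome {rec.id!r} ({n} nt) is shorter than half a fragment ({fragment_len} nt)"
        )
    frags = [rec.seq[i : i + fragment_len] for i in range(0, n - fragment_len + 1, fragment_len)]
    rem = n % fragment_len
    if rem >= fragment_len / 2:
        frags.append(rec.seq[n - rem :])
    if not frags:  # genome between flen/2 and flen: single short fragment
        frags = [rec.seq]
    return frags


def match_fragment(fragment: str, ref: GenomeRecord | str,
                   min_identity: float = DEFAULT_MIN_IDENTITY,
                   ref_rc: str | None = None) -> float | None:
    """Best-alignment identity of a fragment in a reference, or None.

    The fragment is aligned end-to-end into the reference (gaps allowed)
    and reported as an orthologous match iff the best identity reaches
    ``min_identity``.  The forward strand is searched first; the reverse
    complement only if the forward strand yields no match, since a
    fragment cannot have a qualifying orthologous hit on both strands of
    the same region.  Identity is 1 - edit distance over fragment length.
    """
    refseq = ref.seq if isinstance(ref, GenomeRecord) else ref
    qlen = len(fragment)
    # cap edit distance a little above the rejection threshold so clearly
    # unrelated fragments exit early
    k = int(qlen * (1 - min_identity / 100) * 1.25) + 10
    for target in (refseq, ref_rc if ref_rc is not None else revcomp(refseq)):
        res = edlib.align(fragment, target, mode="HW", task="distance", k=k)
        if res["editDistance"] < 0:
            continue
        identity = 100.0 * (1 - res["editDistance"] / qlen)
        if identity >= min_identity:
            return identity
    return None


@dataclass(frozen=True)
class PairSimilarity:
    """Directed fragment statistics for one (query, reference) pair."""

    query_id: str
    ref_id: str
    ani: float  # percent, over matched fragments (0 if none)
    af: float  # matched / total fragments
    n_fragments_total: int
    n_fragments_matched: int

    @property
    def s(self) -> float:
        return self.ani * self.af


def pair_similarity(query: GenomeRecord, ref: GenomeRecord,
                    fragment_len: int = DEFAULT_FRAGMENT_LEN,
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    _frags: list[str] | None = None,
                    _ref_rc: str | None = None) -> PairSimilarity:
    """One-directional fragment ANI/AF/S of ``query`` against ``ref``."""
    frags = _frags if _frags is not None else fragment_genome(query, fragment_len)
    ref_rc = _ref_rc if _ref_rc is not None else revcomp(ref.seq)
    idents = [m for m in (match_fragment(f, ref, min_identity, ref_rc=ref_rc) for f in frags)
              if m is not None]
    ani = float(np.mean(idents)) if idents else 0.0
    return PairSimilarity(query_id=query.id, ref_id=ref.id, ani=ani,
                          af=len(idents) / len(frags),
                          n_fragments_total=len(frags), n_fragments_matched=len(idents))


@dataclass
class SimilarityMatrix:
    """Symmetric genome x genome intergenomic-similarity matrix (percent)."""

    values: pd.DataFrame
    pairs: list[PairSimilarity]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(str)
        df.index = df.index.astype(str)
        return cls(values=df, pairs=[])


def similarity_matrix(genomes: list[GenomeRecord],
                      fragment_len: int = DEFAULT_FRAGMENT_LEN,
                      min_identity: float = DEFAULT_MIN_IDENTITY) -> SimilarityMatrix:
    """All-vs-all symmetrised intergenomic similarity.

    M[i,j] = (S(i->j) + S(j->i)) / 2, diagonal 100; values below the
    reporting floor (0.01 %) are written as 0.
    """
    if len(genomes) < 2:
        raise ValueError(">=2 genomes required for a similarity matrix")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    M = pd.DataFrame(100.0, index=ids, columns=ids)
    pairs: list[PairSimilarity] = []
    frags = {g.id: fragment_genome(g, fragment_len) for g in genomes}
    rc = {g.id: revcomp(g.seq) for g in genomes}
    for i, gi in enumerate(genomes):
        for gj in genomes[i + 1 :]:
            fwd = pair_similarity(gi, gj, fragment_len, min_identity,
                                  _frags=frags[gi.id], _ref_rc=rc[gj.id])
            rev = pair_similarity(gj, gi, fragment_len, min_identity,
                                  _frags=frags[gj.id], _ref_rc=rc[gi.id])
            pairs.extend([fwd, rev])
            s = (fwd.s + rev.s) / 2
            if s < REPORTING_FLOOR:
                s = 0.0
            M.loc[gi.id, gj.id] = M.loc[gj.id, gi.id] = s
    return SimilarityMatrix(values=M, pairs=pairs)
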