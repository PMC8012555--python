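"""Local protein alignment: the hit model and an internal search provider.

The interchange unit is the 15-column tabular hit (qseqid, stitle, pident,
qcovs, qlen, slen, length, mismatch, gapopen, qstart, qend, sstart, send,
evalue, bitscore) with 1-based inclusive coordinates, exactly the dialect an
external ``blastp -outfmt 6`` search emits.  Pipelines may consume such
tables directly; for self-contained runs this module also provides an
internal Smith-Waterman search so no external tool is required.

The internal aligner scores with BLOSUM62 and BLAST-convention affine gaps
(open 11, extend 1: a gap of length k costs 11 + k).  Bit scores use the
standard gapped Karlin-Altschul parameters for that scoring system
(lambda = 0.267, K = 0.041); the e-value is over the m*n search space of the
single query-subject pair, which is all the downstream 0.001 cutoff needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

#: BLAST-style affine gap costs: a gap of length k costs OPEN + k * EXTEND.
GAP_OPEN = 11
GAP_EXTEND = 1
_KA_LAMBDA = 0.267
_KA_K = 0.041


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local-alignment hit (tabular dialect row).

    ``subject_id`` is the first whitespace-delimited token of ``stitle``.
    All coordinates are 1-based inclusive; ``pident`` is the percent identity
    over the aligned columns (gaps included in the denominator) and ``qcovs``
    the percent of the query covered by the match.
    """

    query_id: str
    stitle: str
    pident: float
    qcovs: float
    qlen: int
    slen: int
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise AlignmentError(
                f"{self.query_id}: query coordinates "
                f"({self.qstart},{self.qend}) invalid for length {self.qlen}"
            )
        if not (1 <= self.sstart <= self.send <= self.slen):
            raise AlignmentError(
                f"{self.query_id}->{self.subject_id}: subject coordinates "
                f"({self.sstart},{self.send}) invalid for length {self.slen}"
            )
        if not 0 <= self.pident <= 100:
            raise AlignmentError(f"pident {self.pident} outside [0, 100]")

    @property
    def subject_id(self) -> str:
        return self.stitle.split()[0]


@lru_cache(maxsize=None)
def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython charges open_gap_score for the first gapped column and
    # extend_gap_score for each further one; BLAST's "open 11 extend 1"
    # charges 11 + k for a length-k gap, hence -(11 + 1) and -1.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def raw_score_to_bits(score: float) -> float:
    return (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)


def bits_to_evalue(bits: float, qlen: int, slen: int) -> float:
    return qlen * slen * 2.0 ** (-bits)


def local_align(
    query_seq: str,
    ref_seq: str,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns ``None`` when no positive-scoring local alignment exists (which
    for BLOSUM62 requires truly incompatible sequences).  Ties between
    co-optimal alignments are resolved deterministically by the alignment
    engine's fixed traceback order.
    """
    if not query_seq or not ref_seq:
        raise AlignmentError("local_align: empty sequence")
    query_seq = query_seq.upper()
    ref_seq = ref_seq.upper()
    alignments = _aligner().align(query_seq, ref_seq)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    counts = aln.counts()
    identities = counts.identities
    mismatches = counts.mismatches
    aln_len = aln.length
    gap_opens = 0
    for blocks in (qblocks, sblocks):
        for (prev_s, prev_e), (cur_s, cur_e) in zip(blocks, blocks[1:]):
            if cur_s > prev_e:
                gap_opens += 1
    qstart, qend = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
    sstart, send = int(sblocks[0][0]) + 1, int(sblocks[-1][1])
    bits = raw_score_to_bits(aln.score)
    return AlignmentHit(
        query_id=query_id,
        stitle=subject_id,
        pident=100.0 * identities / aln_len,
        qcovs=100.0 * (qend - qstart + 1) / len(query_seq),
        qlen=len(query_seq),
        slen=len(ref_seq),
        aln_len=int(aln_len),
        mismatches=int(mismatches),
        gap_opens=int(gap_opens),
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        evalue=bits_to_evalue(bits, len(query_seq), len(ref_seq)),
        bitscore=round(bits, 1),
    )
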