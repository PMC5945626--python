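"""Semi-global amplicon-read alignment and indel normalisation.

Reads are amplicon subsequences of the cDNA, so the alignment is semi-global:
the read is aligned end to end while the reference ends are free. Scoring is
affine (defaults: match +1, mismatch -2, gap open -5, gap extend -1 per base,
i.e. a length-L gap costs 5 + L). Before variant calling every indel is
shifted to its 3'-most equivalent position so that calls follow the HGVS
3' rule.

The dynamic programme itself is Biopython's PairwiseAligner configured for
this mode; this module owns the op-level representation, the deterministic
choice among co-optimal alignments, the 3'-shift normalisation and SAM
interchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pysam
from Bio import Align

from .reference_model import CodingTranscript

__all__ = [
    "AlnOp",
    "PairwiseAlignment",
    "ScoringParams",
    "align_read",
    "shift_indels_3prime",
    "import_sam",
    "export_sam",
]

log = logging.getLogger(__name__)

MATCH, MISMATCH, INSERTION, DELETION = "match", "mismatch", "insertion", "deletion"


@dataclass(frozen=True)
class ScoringParams:
    """Affine scoring; a gap of length L costs ``gap_open + L * gap_extend``."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlnOp:
    kind: str  # match | mismatch | insertion | deletion
    length: int
    seq: str = ""  # inserted (read) bases / deleted (ref) bases; "" for match/mismatch runs


@dataclass(frozen=True)
class PairwiseAlignment:
    """An alignment of one read against the cDNA.

    ``ref_interval`` is 1-based closed on the cDNA; ``ops`` run 5'->3' with no
    two adjacent ops of the same kind.
    """

    read_id: str
    ref_interval: tuple[int, int]
    ops: tuple[AlnOp, ...]
    score: float

    def ref_span(self) -> int:
        return sum(op.length for op in self.ops if op.kind in (MATCH, MISMATCH, DELETION))

    def read_length(self) -> int:
        return sum(op.length for op in self.ops if op.kind in (MATCH, MISMATCH, INSERTION))

    def read_sequence(self, transcript: CodingTranscript) -> str:
        """Reconstruct the aligned read by applying ops to the reference."""
        seq = transcript.sequence
        out: list[str] = []
        r = self.ref_interval[0] - 1  # 0-based cursor
        for op in self.ops:
            if op.kind in (MATCH,):
                out.append(seq[r : r + op.length])
                r += op.length
            elif op.kind == MISMATCH:
                out.append(op.seq)
                r += op.length
            elif op.kind == DELETION:
                r += op.length
            else:  # insertion
                out.append(op.seq)
        return "".join(out)


def _merge_ops(ops: list[AlnOp]) -> tuple[AlnOp, ...]:
    merged: list[AlnOp] = []
    for op in ops:
        if op.length == 0:
            continue
        if merged and merged[-1].kind == op.kind:
            prev = merged[-1]
            merged[-1] = AlnOp(op.kind, prev.length + op.length, prev.seq + op.seq)
        else:
            merged.append(op)
    return tuple(merged)


def _block_ops(ref_seq: str, read_seq: str) -> list[AlnOp]:
    """Split an aligned (gap-free) block into match/mismatch runs."""
    ops: list[AlnOp] = []
    i = 0
    n = len(ref_seq)
    while i < n:
        j = i
        is_match = ref_seq[i] == read_seq[i]
        while j < n and (ref_seq[j] == read_seq[j]) == is_match:
            j += 1
        ops.append(AlnOp(MATCH if is_match else MISMATCH, j - i, "" if is_match else read_seq[i:j]))
        i = j
    return ops


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # Biopython charges open_gap_score for the first gapped base, so the
    # first-base score is gap_open + gap_extend to realise open + L*extend.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    # free reference flanks: end gaps in the query row (reference bases not
    # covered by the read) score 0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def align_read(
    read: str,
    transcript: CodingTranscript,
    params: ScoringParams | None = None,
    read_id: str = "read",
) -> PairwiseAlignment:
    """Optimal semi-global alignment of a read to the cDNA.

    The read is global (end gaps penalised), the reference local (free end
    gaps). Deterministic: among co-optimal alignments the aligner's first
    enumerated path is taken and indel placement is then fixed by
    :func:`shift_indels_3prime` downstream.
    """
    params = params or ScoringParams()
    read = read.upper()
    if len(read) < 20:
        raise ValueError("read shorter than 20 nt")
    if set(read) - set("ACGTN"):
        raise ValueError("read contains non-ACGTN characters")
    if read.count("N") / len(read) > 0.5:
        log.warning("read %s rejected: >50%% N", read_id)
        raise ValueError("read is more than 50% N")

    aligner = _make_aligner(params)
    aln = next(iter(aligner.align(transcript.sequence, read)))
    ta, qa = aln.aligned  # 0-based half-open target/query blocks

    ops: list[AlnOp] = []
    if len(ta) == 0:
        raise ValueError("read did not align")
    ref_start = int(ta[0][0]) + 1
    # read bases before the first aligned block are an insertion at the start
    if qa[0][0] > 0:
        ops.append(AlnOp(INSERTION, int(qa[0][0]), read[: int(qa[0][0])]))
    prev_t, prev_q = None, None
    for (t0, t1), (q0, q1) in zip(ta, qa):
        if prev_t is not None:
            if t0 > prev_t:  # deletion first (preference), then insertion
                ops.append(AlnOp(DELETION, int(t0 - prev_t), transcript.sequence[prev_t:t0]))
            if q0 > prev_q:
                ops.append(AlnOp(INSERTION, int(q0 - prev_q), read[prev_q:q0]))
        ops.extend(_block_ops(transcript.sequence[t0:t1], read[q0:q1]))
        prev_t, prev_q = int(t1), int(q1)
    if prev_q < len(read):
        ops.append(AlnOp(INSERTION, len(read) - prev_q, read[prev_q:]))
    ref_end = int(ta[-1][1])

    return PairwiseAlignment(
        read_id=read_id,
        ref_interval=(ref_start, ref_end),
        ops=_merge_ops(ops),
        score=float(aln.score),
    )


def shift_indels_3prime(aln: PairwiseAlignment, transcript: CodingTranscript) -> PairwiseAlignment:
    """Place every indel at its 3'-most equivalent position.

    Score and implied read sequence are unchanged; idempotent. An indel can
    slide right one base whenever the base just past it equals its own first
    base (repeat context), consuming match length from the following op.
    """
    seq = transcript.sequence
    ops = list(aln.ops)
    changed = True
    while changed:
        changed = False
        # walk with a reference cursor
        r = aln.ref_interval[0] - 1  # 0-based index of next ref base
        i = 0
        while i < len(ops):
            op = ops[i]
            if op.kind in (MATCH, MISMATCH):
                r += op.length
                i += 1
                continue
            if op.kind == DELETION:
                nxt = ops[i + 1] if i + 1 < len(ops) else None
                if nxt is not None and nxt.kind == MATCH and nxt.length >= 1 and seq[r + op.length] == op.seq[0]:
                    # rotate deletion right by one
                    new_seq = op.seq[1:] + seq[r + op.length]
                    prev = ops[i - 1] if i > 0 else None
                    if prev is not None and prev.kind == MATCH:
                        ops[i - 1] = AlnOp(MATCH, prev.length + 1)
                    else:
                        ops.insert(i, AlnOp(MATCH, 1))
                        i += 1
                    ops[i] = AlnOp(DELETION, op.length, new_seq)
                    ops[i + 1] = AlnOp(MATCH, nxt.length - 1)
                    if ops[i + 1].length == 0:
                        del ops[i + 1]
                    changed = True
                    r += 1
                    i += 1
                    continue
                r += op.length
                i += 1
                continue
            if op.kind == INSERTION:
                nxt = ops[i + 1] if i + 1 < len(ops) else None
                if (
                    nxt is not None
                    and nxt.kind == MATCH
                    and nxt.length >= 1
                    and r < len(seq)
                    and op.seq[0] == seq[r]
                ):
                    new_seq = op.seq[1:] + op.seq[0]
                    prev = ops[i - 1] if i > 0 else None
                    if prev is not None and prev.kind == MATCH:
                        ops[i - 1] = AlnOp(MATCH, prev.length + 1)
                    else:
                        ops.insert(i, AlnOp(MATCH, 1))
                        i += 1
                    ops[i] = AlnOp(INSERTION, op.length, new_seq)
                    ops[i + 1] = AlnOp(MATCH, nxt.length - 1)
                    if ops[i + 1].length == 0:
                        del ops[i + 1]
                    changed = True
                    r += 1
                    i += 1
                    continue
                i += 1
                continue
    return replace(aln, ops=_merge_ops(ops))


# ---------------------------------------------------------------------------
# SAM interchange

_CIGAR_CONSUMES = {
    0: (True, True),   # M
    1: (True, False),  # I
    2: (False, True),  # D
    4: (True, False),  # S (soft clip, trimmed)
    7: (True, True),   # =
    8: (True, True),   # X
}


def import_sam(path: str | Path, transcript: CodingTranscript) -> list[PairwiseAlignment]:
    """Convert mapped SAM records to :class:`PairwiseAlignment`.

    Soft clips are trimmed; unmapped and secondary records are skipped (counts
    logged). The SAM reference name must match ``transcript.id``.
    """
    out: list[PairwiseAlignment] = []
    skipped_unmapped = skipped_secondary = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                skipped_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                skipped_secondary += 1
                continue
            if rec.reference_name != transcript.id:
                raise ValueError(
                    f"SAM reference {rec.reference_name!r} does not match transcript {transcript.id!r}"
                )
            ref_start = rec.reference_start + 1  # pysam is 0-based
            ops: list[AlnOp] = []
            query = rec.query_sequence or ""
            q = 0
            r = rec.reference_start  # 0-based
            for code, length in rec.cigartuples or []:
                if code not in _CIGAR_CONSUMES:
                    raise ValueError(f"unsupported CIGAR op code {code} in read {rec.query_name}")
                consumes_q, consumes_r = _CIGAR_CONSUMES[code]
                if code == 4:  # soft clip: trim
                    q += length
                elif code in (0, 7, 8):
                    ops.extend(_block_ops(transcript.sequence[r : r + length], query[q : q + length]))
                    q += length
                    r += length
                elif code == 1:
                    ops.append(AlnOp(INSERTION, length, query[q : q + length]))
                    q += length
                elif code == 2:
                    ops.append(AlnOp(DELETION, length, transcript.sequence[r : r + length]))
                    r += length
            out.append(
                PairwiseAlignment(
                    read_id=rec.query_name,
                    ref_interval=(ref_start, r),
                    ops=_merge_ops(ops),
                    score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                )
            )
    if skipped_unmapped or skipped_secondary:
        log.info("import_sam: skipped %d unmapped, %d secondary/supplementary", skipped_unmapped, skipped_secondary)
    return out


_KIND_TO_CIGAR = {MATCH: "=", MISMATCH: "X", INSERTION: "I", DELETION: "D"}


def export_sam(alignments: list[PairwiseAlignment], transcript: CodingTranscript, path: str | Path) -> None:
    """Write alignments as plain-text SAM with a header naming the transcript."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{transcript.id}\tLN:{len(transcript.sequence)}\n")
        for aln in alignments:
            cigar = "".join(f"{op.length}{_KIND_TO_CIGAR[op.kind]}" for op in aln.ops)
            seq = aln.read_sequence(transcript)
            fh.write(
                f"{aln.read_id}\t0\t{transcript.id}\t{aln.ref_interval[0]}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\tAS:i:{int(aln.score)}\n"
            )
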