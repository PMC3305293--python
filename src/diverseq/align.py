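"""Seed-and-extend read alignment against a transcript reference, and pileups.

The parameterisation mirrors a classic overlap assembler's knobs: a seed
(k-mer) length of 15, a percent-identity floor of 90, a mismatch penalty of
20, and a cap of 15 on any single gap.  Candidate loci come from exact
k-mer seed hits; each candidate window is then aligned with a local
affine-gap Smith-Waterman (Gotoh) dynamic program, so the reported score is
the true local-alignment optimum whenever the window covers it.

Coordinates are 0-based half-open internally; emitted text (SAM, reports)
is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .simulate import ReferenceTranscript, reverse_complement

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
GAP_CODE = 4  # pileup allele index for a gap (deleted base)
ALLELES = ("A", "C", "G", "T", "-")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


_ENC_MAP = np.zeros(128, dtype=np.int8)
for b, c in _CODE.items():
    _ENC_MAP[ord(b)] = c


def encode_seq(seq: str) -> np.ndarray:
    return _ENC_MAP[_encode(seq)]


@dataclass
class AlignParams:
    """Scoring and filtering parameters for read alignment."""

    k: int = 15
    min_identity: float = 0.90
    match_score: int = 10
    mismatch_penalty: int = 20
    gap_open: int = 20
    gap_extend: int = 5
    max_gap: int = 15
    seed_stride: int = 5
    min_gap_anchor: int = 5  # aligned run required beyond a terminal gap


@dataclass
class SeedIndex:
    """Exact k-mer index over the forward strand of every transcript."""

    k: int
    ids: list[str]
    lengths: list[int]
    _table: dict[str, list[tuple[int, int]]] = field(repr=False, default_factory=dict)

    def hits(self, kmer: str) -> list[tuple[int, int]]:
        """(transcript index, offset) occurrences of ``kmer``; [] if absent."""
        return self._table.get(kmer, [])


def build_index(reference: Sequence[ReferenceTranscript], k: int = 15) -> SeedIndex:
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    if any(len(t) < k for t in reference):
        raise ValueError("k exceeds the shortest transcript length")
    table: dict[str, list[tuple[int, int]]] = {}
    for ti, t in enumerate(reference):
        seq = t.sequence
        for off in range(len(seq) - k + 1):
            table.setdefault(seq[off : off + k], []).append((ti, off))
    return SeedIndex(k=k, ids=[t.id for t in reference], lengths=[len(t) for t in reference], _table=table)


@njit(cache=True)
def _gotoh_local(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Local affine-gap DP.  Returns (best, end_i, end_j, Hp, Dp, Ip).

    Pointer codes in Hp: 0 stop, 1 diagonal, 2 deletion (gap in read),
    3 insertion (gap in ref).  Dp/Ip: 1 = extend existing gap, 0 = open.
    A 1-base gap costs gap_open + gap_extend.
    """
    n, m = read.shape[0], ref.shape[0]
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), np.int64)
    D = np.full((n + 1, m + 1), NEG, np.int64)
    I = np.full((n + 1, m + 1), NEG, np.int64)
    Hp = np.zeros((n + 1, m + 1), np.int8)
    Dp = np.zeros((n + 1, m + 1), np.int8)
    Ip = np.zeros((n + 1, m + 1), np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d_open = H[i][j - 1] - gap_open - gap_extend
            d_ext = D[i][j - 1] - gap_extend
            if d_ext > d_open:
                D[i][j] = d_ext
                Dp[i][j] = 1
            else:
                D[i][j] = d_open
                Dp[i][j] = 0
            i_open = H[i - 1][j] - gap_open - gap_extend
            i_ext = I[i - 1][j] - gap_extend
            if i_ext > i_open:
                I[i][j] = i_ext
                Ip[i][j] = 1
            else:
                I[i][j] = i_open
                Ip[i][j] = 0
            s = match if read[i - 1] == ref[j - 1] else -mismatch
            diag = H[i - 1][j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if D[i][j] > h:
                h = D[i][j]
                p = 2
            if I[i][j] > h:
                h = I[i][j]
                p = 3
            H[i][j] = h
            Hp[i][j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, Hp, Dp, Ip


@dataclass(frozen=True)
class ReadAlignment:
    """A single best-hit local alignment of one read to one transcript."""

    read_id: str
    sample_id: str
    transcript_id: str
    start: int  # 0-based on the transcript
    strand: str  # '+' or '-'
    ops: tuple[tuple[str, int], ...]  # S/M/X/I/D run-length ops over the read
    identity: float
    score: int
    query: str  # read sequence in reference orientation

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must lie in [0, 1]")
        consumed = sum(n for op, n in self.ops if op in "SMXI")
        if consumed != len(self.query):
            raise ValueError("operations do not span the read")

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.ops if op in "MXD")

    @property
    def max_gap_run(self) -> int:
        runs = [n for op, n in self.ops if op in "ID"]
        return max(runs) if runs else 0


def _traceback(read: str, Hp, Dp, Ip, bi: int, bj: int) -> tuple[int, int, list[tuple[str, int]]]:
    """Walk pointers back from the best cell.

    Returns (read_start, ref_start, M/I/D ops without clips).
    """
    ops: list[tuple[str, int]] = []
    i, j = bi, bj

    def push(op: str):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    state = 0  # 0 in H, 2 in D, 3 in I
    while True:
        if state == 0:
            p = Hp[i][j]
            if p == 0:
                break
            if p == 1:
                push("M")  # match/mismatch split happens in _refine_ops
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            push("D")
            if Dp[i][j] == 0:
                state = 0
            j -= 1
        else:
            push("I")
            if Ip[i][j] == 0:
                state = 0
            i -= 1
    ops.reverse()
    return i, j, ops


def _refine_ops(read: str, ref_window: str, read_start: int, ref_start: int, ops: list[tuple[str, int]]):
    """Split M runs into match (M) / mismatch (X) and count matches."""
    out: list[tuple[str, int]] = []
    i, j = read_start, ref_start
    matches = 0

    def push(op: str, n: int = 1):
        if n == 0:
            return
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))

    for op, n in ops:
        if op == "M":
            for _ in range(n):
                if read[i] == ref_window[j]:
                    push("M")
                    matches += 1
                else:
                    push("X")
                i += 1
                j += 1
        elif op == "I":
            push("I", n)
            i += n
        else:
            push("D", n)
            j += n
    return out, matches


def _trim_dangling_gaps(
    ops: list[tuple[str, int]], min_anchor: int
) -> tuple[int, int, int, list[tuple[str, int]]]:
    """Trim terminal gaps anchored by fewer than ``min_anchor`` columns.

    A gap right at an alignment end held in place by only a couple of
    matching bases is almost always a placement artifact (e.g. a terminal
    mismatch re-expressed as gap + match when the next reference base
    happens to agree); such dangling segments are clipped.  Returns
    (extra leading read clip, extra trailing read clip, leading reference
    shift, trimmed ops).
    """
    lead = tail = ref_shift = 0
    changed = True
    while changed and ops:
        changed = False
        # trailing end
        i = len(ops) - 1
        anchor = 0
        while i >= 0 and ops[i][0] in "MX":
            anchor += ops[i][1]
            i -= 1
        if i >= 0 and ops[i][0] in "ID" and anchor < min_anchor:
            tail += sum(n for op, n in ops[i:] if op in "MXI")
            ops = ops[:i]
            changed = True
        # leading end
        i = 0
        anchor = 0
        while i < len(ops) and ops[i][0] in "MX":
            anchor += ops[i][1]
            i += 1
        if i < len(ops) and ops[i][0] in "ID" and anchor < min_anchor:
            lead += sum(n for op, n in ops[: i + 1] if op in "MXI")
            ref_shift += sum(n for op, n in ops[: i + 1] if op in "MXD")
            ops = ops[i + 1 :]
            changed = True
    return lead, tail, ref_shift, ops


def _align_window(seq: str, ref_window: str, params: AlignParams):
    """Local alignment of ``seq`` against a reference window.

    Returns (score, ref_start_in_window, ops_with_clips, identity) or None
    if the optimum is empty.  The score is the DP local optimum; the
    emitted operations additionally have dangling terminal gaps trimmed
    (see ``_trim_dangling_gaps``).
    """
    best, bi, bj, Hp, Dp, Ip = _gotoh_local(
        encode_seq(seq),
        encode_seq(ref_window),
        params.match_score,
        params.mismatch_penalty,
        params.gap_open,
        params.gap_extend,
    )
    if best <= 0:
        return None
    i0, j0, raw_ops = _traceback(seq, Hp, Dp, Ip, bi, bj)
    ops, matches = _refine_ops(seq, ref_window, i0, j0, raw_ops)
    lead, tail, ref_shift, ops = _trim_dangling_gaps(ops, params.min_gap_anchor)
    if not ops:
        return None
    i0 += lead
    j0 += ref_shift
    matches = 0
    i, j = i0, j0
    for op, n in ops:  # recount matches over the trimmed alignment
        if op == "M":
            matches += n
        if op in "MX":
            i += n
            j += n
        elif op == "I":
            i += n
        else:
            j += n
    columns = sum(n for op, n in ops)
    identity = matches / columns if columns else 0.0
    full: list[tuple[str, int]] = []
    if i0 > 0:
        full.append(("S", i0))
    full.extend(ops)
    if bi - tail < len(seq):
        full.append(("S", len(seq) - (bi - tail)))
    return int(best), j0, full, identity


def align_read(
    seq: str,
    index: SeedIndex,
    reference: Sequence[ReferenceTranscript],
    params: AlignParams | None = None,
    read_id: str = "",
    sample_id: str = "",
) -> ReadAlignment | None:
    """Best-hit alignment of one read over both strands, or None.

    Seeds are exact k-mer hits sampled every ``seed_stride`` bases; each
    cluster of nearby seed diagonals defines a reference window that is
    aligned in full.  The best candidate by score wins; exact ties break by
    (lowest transcript id, lowest start, '+' before '-').  The read is
    unaligned when the best identity falls below ``min_identity`` or any
    single gap exceeds ``max_gap``.
    """
    if params is None:
        params = AlignParams(k=index.k)
    if len(seq) == 0:
        raise ValueError("empty read")
    if len(seq) < index.k:
        return None
    pad = params.max_gap + 10
    candidates = []  # (score, tid, start, strand_rank, ops, identity, oriented_seq)
    for strand in "+-":
        oriented = seq if strand == "+" else reverse_complement(seq)
        diag_hits: dict[int, set[int]] = {}
        positions = list(range(0, len(oriented) - index.k + 1, params.seed_stride))
        if positions[-1] != len(oriented) - index.k:
            positions.append(len(oriented) - index.k)
        for qpos in positions:
            for ti, off in index.hits(oriented[qpos : qpos + index.k]):
                diag_hits.setdefault(ti, set()).add(off - qpos)
        for ti, diags in diag_hits.items():
            ds = sorted(diags)
            clusters: list[list[int]] = [[ds[0]]]
            for d in ds[1:]:
                if d - clusters[-1][-1] <= params.max_gap * 2:
                    clusters[-1].append(d)
                else:
                    clusters.append([d])
            tlen = index.lengths[ti]
            tseq = reference[ti].sequence
            for cl in clusters:
                w0 = max(0, cl[0] - pad)
                w1 = min(tlen, cl[-1] + len(oriented) + pad)
                res = _align_window(oriented, tseq[w0:w1], params)
                if res is None:
                    continue
                score, j0, ops, identity = res
                candidates.append(
                    (score, index.ids[ti], w0 + j0, 0 if strand == "+" else 1, ops, identity, oriented)
                )
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    score, tid, start, strand_rank, ops, identity, oriented = candidates[0]
    aln = ReadAlignment(
        read_id=read_id,
        sample_id=sample_id,
        transcript_id=tid,
        start=start,
        strand="+" if strand_rank == 0 else "-",
        ops=tuple(ops),
        identity=identity,
        score=score,
        query=oriented,
    )
    if aln.identity < params.min_identity or aln.max_gap_run > params.max_gap:
        return None
    return aln


def align_reads(
    reads: Iterable,
    index: SeedIndex,
    reference: Sequence[ReferenceTranscript],
    params: AlignParams | None = None,
    sample_id: str = "",
) -> list[ReadAlignment]:
    """Align a read set (SimulatedRead or (id, seq) pairs); best hits only."""
    out = []
    for r in reads:
        rid, seq = (r.id, r.sequence) if hasattr(r, "sequence") else r
        aln = align_read(seq, index, reference, params, read_id=rid, sample_id=sample_id)
        if aln is not None:
            out.append(aln)
    return out


# ---------------------------------------------------------------------------
# pileups


@dataclass(frozen=True)
class PileupColumn:
    """Per-site allele counts, per sample and pooled."""

    transcript_id: str
    position: int
    sample_counts: Mapping[str, np.ndarray]  # sample -> counts over A,C,G,T,-

    @property
    def counts(self) -> np.ndarray:
        total = np.zeros(5, dtype=np.int64)
        for c in self.sample_counts.values():
            total += c
        return total

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


class Pileup:
    """Dense per-transcript, per-sample allele counts built from alignments.

    Deleted reference positions contribute gap counts; insertions are kept
    aside (they do not occupy a reference column).
    """

    def __init__(self, reference: Sequence[ReferenceTranscript], samples: Sequence[str]):
        self.samples = list(samples)
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self.reference = {t.id: t for t in reference}
        self.counts = {
            t.id: np.zeros((len(t), len(self.samples), 5), dtype=np.int32) for t in reference
        }
        self.insertions: list[tuple[str, int, str, str]] = []  # (tid, pos, sample, bases)

    def add_alignment(self, aln: ReadAlignment) -> None:
        arr = self.counts.get(aln.transcript_id)
        if arr is None:
            raise ValueError(f"unknown transcript {aln.transcript_id}")
        si = self._sample_idx[aln.sample_id]
        i = 0  # read cursor
        j = aln.start  # reference cursor
        for op, n in aln.ops:
            if op == "S":
                i += n
            elif op in "MX":
                for _ in range(n):
                    if j >= arr.shape[0]:
                        raise ValueError("alignment extends past transcript end")
                    arr[j, si, _CODE[aln.query[i]]] += 1
                    i += 1
                    j += 1
            elif op == "I":
                self.insertions.append(
                    (aln.transcript_id, j, aln.sample_id, aln.query[i : i + n])
                )
                i += n
            elif op == "D":
                for _ in range(n):
                    if j >= arr.shape[0]:
                        raise ValueError("alignment extends past transcript end")
                    arr[j, si, GAP_CODE] += 1
                    j += 1

    def column(self, transcript_id: str, position: int) -> PileupColumn:
        arr = self.counts[transcript_id]
        return PileupColumn(
            transcript_id,
            position,
            {s: arr[position, i].astype(np.int64) for i, s in enumerate(self.samples)},
        )

    def iter_columns(self, min_depth: int = 1):
        for tid, arr in self.counts.items():
            depth = arr.sum(axis=(1, 2))
            for pos in np.nonzero(depth >= min_depth)[0]:
                yield self.column(tid, int(pos))


def build_pileup(
    alignments: Iterable[ReadAlignment],
    reference: Sequence[ReferenceTranscript],
    samples: Sequence[str],
) -> Pileup:
    pile = Pileup(reference, samples)
    for aln in alignments:
        pile.add_alignment(aln)
    return pile


# ---------------------------------------------------------------------------
# SAM output


def write_sam(
    alignments: Iterable[ReadAlignment],
    reference: Sequence[ReferenceTranscript],
    path,
) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t.id, "LN": len(t)} for t in reference],
    }
    tid_map = {t.id: i for i, t in enumerate(reference)}
    op_map = {"M": 0, "I": 1, "D": 2, "S": 4, "X": 8}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.query
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_id = tid_map[aln.transcript_id]
            seg.reference_start = aln.start
            seg.mapping_quality = 60
            # merge M/X to M for broad compatibility
            cigar = []
            for op, n in aln.ops:
                code = 0 if op in "MX" else op_map[op]
                if cigar and cigar[-1][0] == code:
                    cigar[-1] = (code, cigar[-1][1] + n)
                else:
                    cigar.append((code, n))
            seg.cigartuples = cigar
            seg.set_tag("AS", aln.score)
            seg.set_tag("RG", aln.sample_id)
            fh.write(seg)
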