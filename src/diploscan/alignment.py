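"""Pairwise alignment of the two phases: PAF parsing and a built-in anchor aligner.

The anchor aligner finds k-mers that occur exactly once in both sequences,
chains collinear anchors with a longest-increasing-subsequence pass, and
closes inter-anchor gaps with a global affine-gap alignment (so each indel
stays contiguous).  Large gaps are left as plain insertion/deletion CIGAR
ops after exact-match trimming of their flanks; gaps whose two sides align
in opposite orientation (>= 2 shared unique k-mers on the minus strand) are
emitted as separate minus-strand blocks, which downstream variant
extraction reports as inversions.
"""

from __future__ import annotations

import bisect
import logging
import os
import re

import edlib
import numpy as np

from .models import AlignmentBlock, revcomp

log = logging.getLogger(__name__)

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cg: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIG_RE.finditer(cg)]
    if not ops or sum(len(m.group(0)) for m in _CIG_RE.finditer(cg)) != len(cg):
        raise ValueError(f"malformed CIGAR: {cg!r}")
    return ops


def cigar_to_str(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


# ---------------------------------------------------------------- PAF


def read_paf(path: str | os.PathLike) -> list[AlignmentBlock]:
    """Parse PAF records carrying a cg:Z: CIGAR tag into alignment blocks.

    Records without a CIGAR are dropped (counted in a warning); malformed
    lines raise ValueError with the line number.
    """
    blocks: list[AlignmentBlock] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has <12 fields")
            try:
                qname, _qlen, qstart, qend, strand, tname, _tlen, tstart, tend = (
                    fields[0], int(fields[1]), int(fields[2]), int(fields[3]),
                    fields[4], fields[5], int(fields[6]), int(fields[7]),
                    int(fields[8]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            cg = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
            if cg is None:
                skipped += 1
                continue
            try:
                cigar = parse_cigar(cg)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            block = AlignmentBlock(tname, tstart, tend, qname, qstart, qend,
                                   strand, cigar)
            block.validate()
            blocks.append(block)
    if skipped:
        log.warning("read_paf: %d record(s) without cg tag skipped", skipped)
    return blocks


def write_paf(blocks: list[AlignmentBlock], path: str | os.PathLike,
              seq_lengths: dict[str, int] | None = None) -> None:
    seq_lengths = seq_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            matches = sum(n for op, n in b.cigar if op in "=M")
            alen = sum(n for op, n in b.cigar if op in "=XMID")
            fh.write(
                "\t".join(
                    map(str, [
                        b.query_name, seq_lengths.get(b.query_name, b.query_end),
                        b.query_start, b.query_end, b.strand,
                        b.ref_name, seq_lengths.get(b.ref_name, b.ref_end),
                        b.ref_start, b.ref_end, matches, alen, 60,
                        "cg:Z:" + cigar_to_str(b.cigar),
                    ])
                )
                + "\n"
            )


# ---------------------------------------------------------------- anchors

_BASE_CODE = np.full(256, 255, dtype=np.uint64)
for i, b in enumerate(b"ACGT"):
    _BASE_CODE[b] = i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers (2-bit packed); requires k <= 31."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    acc = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    for j in range(k):
        acc = acc * four + codes[j : j + n]
    return acc


def _unique_kmer_positions(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, idx, counts = np.unique(codes, return_index=True, return_counts=True)
    keep = counts == 1
    return vals[keep], idx[keep]


def shared_unique_anchors(seq_a: str, seq_b: str, k: int) -> np.ndarray:
    """(n, 2) array of (pos_a, pos_b) for k-mers unique in both sequences."""
    va, ia = _unique_kmer_positions(_kmer_codes(seq_a, k))
    vb, ib = _unique_kmer_positions(_kmer_codes(seq_b, k))
    common, ca, cb = np.intersect1d(va, vb, assume_unique=True,
                                    return_indices=True)
    if len(common) == 0:
        return np.empty((0, 2), dtype=np.int64)
    anchors = np.stack([ia[ca], ib[cb]], axis=1).astype(np.int64)
    return anchors[np.argsort(anchors[:, 0], kind="stable")]


def _lis_chain(anchors: np.ndarray) -> np.ndarray:
    """Longest strictly-increasing chain in both coordinates.

    Anchors are sorted by ref position (unique in both, so strictly
    increasing); patience LIS on the query positions, preferring the leftmost
    candidate on ties, yields a deterministic maximal chain.
    """
    n = len(anchors)
    if n == 0:
        return anchors
    qs = anchors[:, 1]
    tails: list[int] = []  # query pos of smallest tail per chain length
    tail_idx: list[int] = []
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        q = qs[i]
        j = bisect.bisect_left(tails, q)
        if j > 0:
            parent[i] = tail_idx[j - 1]
        if j == len(tails):
            tails.append(q)
            tail_idx.append(i)
        else:
            tails[j] = q
            tail_idx[j] = i
    chain = []
    i = tail_idx[-1]
    while i != -1:
        chain.append(i)
        i = parent[i]
    return anchors[np.array(chain[::-1], dtype=np.int64)]


def _trim_common(a: str, b: str) -> tuple[int, int, str, str]:
    """Trim the longest common prefix and suffix; returns (n_pre, n_suf, a', b')."""
    n = min(len(a), len(b))
    pre = 0
    while pre < n and a[pre] == b[pre]:
        pre += 1
    suf = 0
    while suf < n - pre and a[-1 - suf] == b[-1 - suf]:
        suf += 1
    return pre, suf, a[pre : len(a) - suf], b[pre : len(b) - suf]


def _append_op(cigar: list[tuple[str, int]], op: str, n: int) -> None:
    if n <= 0:
        return
    if cigar and cigar[-1][0] == op:
        cigar[-1] = (op, cigar[-1][1] + n)
    else:
        cigar.append((op, n))


def _edlib_ops(query: str, target: str) -> list[tuple[str, int]]:
    res = edlib.align(query, target, mode="NW", task="path")
    return [(op, n) for n, op in
            ((int(m.group(1)), m.group(2)) for m in _CIG_RE.finditer(res["cigar"]))]


_GAP_ALIGNER = None


def _gap_ops(query: str, target: str) -> list[tuple[str, int]]:
    """Global affine-gap alignment of a closed gap, as extended CIGAR ops.

    Affine penalties keep each indel contiguous (splitting a gap run around a
    coincidentally matching base costs an extra gap-open), so the emitted
    event set does not depend on arbitrary tie-breaking among unit-cost
    optimal paths.
    """
    global _GAP_ALIGNER
    if _GAP_ALIGNER is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -5
        a.extend_gap_score = -1
        _GAP_ALIGNER = a
    aln = _GAP_ALIGNER.align(target, query)[0]
    coords = aln.coordinates  # rows: target, query
    ops: list[tuple[str, int]] = []
    for i in range(coords.shape[1] - 1):
        t0, q0 = coords[0, i], coords[1, i]
        t1, q1 = coords[0, i + 1], coords[1, i + 1]
        if t1 > t0 and q1 > q0:
            run_op, run_n = None, 0
            for tt, qq in zip(range(t0, t1), range(q0, q1)):
                op = "=" if target[tt] == query[qq] else "X"
                if op == run_op:
                    run_n += 1
                else:
                    if run_op:
                        _append_op(ops, run_op, run_n)
                    run_op, run_n = op, 1
            if run_op:
                _append_op(ops, run_op, run_n)
        elif t1 > t0:
            _append_op(ops, "D", t1 - t0)
        elif q1 > q0:
            _append_op(ops, "I", q1 - q0)
    return ops


def _maybe_inversion(gap_r: str, gap_q: str, k: int, min_len: int = 40,
                     max_div: float = 0.1) -> list[tuple[str, int]] | None:
    """CIGAR of gap_q reverse-complemented onto gap_r, if the gap is an inversion."""
    if len(gap_r) < min_len or len(gap_q) < min_len:
        return None
    if not 0.8 <= len(gap_q) / len(gap_r) <= 1.25:
        return None
    rc = revcomp(gap_q)
    anchors = shared_unique_anchors(gap_r, rc, min(k, 15))
    if len(anchors) < 2:
        return None
    res = edlib.align(rc, gap_r, mode="NW", task="distance")
    if res["editDistance"] > max_div * max(len(gap_r), len(gap_q)):
        return None
    return _edlib_ops(rc, gap_r)


def anchor_align(
    seq_a: str,
    seq_b: str,
    k: int = 21,
    *,
    ref_name: str = "ref",
    query_name: str = "query",
    max_gap_close: int = 10_000,
    anchor_stride: int = 10,
) -> list[AlignmentBlock]:
    """Align two haplotype sequences of one chromosome (a = reference/phase-0).

    Returns plus-strand blocks with an exact (=/X/I/D) CIGAR; inverted
    segments are returned as separate minus-strand blocks between their
    plus-strand neighbours.  With no unique anchors in either orientation the
    result is an empty list.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")

    anchors_fwd = shared_unique_anchors(seq_a, seq_b, k)
    strand = "+"
    seq_q = seq_b
    if len(anchors_fwd) * 10 < len(seq_a) // max(k, 1):
        # weak forward signal: consider the reverse complement orientation
        anchors_rev = shared_unique_anchors(seq_a, revcomp(seq_b), k)
        if len(anchors_rev) > len(anchors_fwd):
            strand = "-"
            seq_q = revcomp(seq_b)
            anchors_fwd = anchors_rev
    if len(anchors_fwd) == 0:
        return []
    if anchor_stride > 1 and len(anchors_fwd) > 1000:
        anchors_fwd = anchors_fwd[::anchor_stride]
    chain = _lis_chain(anchors_fwd)

    blocks: list[AlignmentBlock] = []
    cigar: list[tuple[str, int]] = []
    # block start (r0, q0) and aligned-so-far cursors (r, q)
    r0, q0 = int(chain[0][0]), int(chain[0][1])
    # extend exact matches leftward of the first anchor
    while r0 > 0 and q0 > 0 and seq_a[r0 - 1] == seq_q[q0 - 1]:
        r0 -= 1
        q0 -= 1
    r, q = r0, q0

    def flush_block(r_end: int, q_end: int) -> None:
        nonlocal cigar, r0, q0
        if cigar and r_end > r0:
            blocks.append(
                AlignmentBlock(ref_name, r0, r_end, query_name, q0, q_end,
                               strand, cigar)
            )
        cigar = []
        r0, q0 = r_end, q_end

    def close_gap(gap_r: str, gap_q: str) -> None:
        """Append CIGAR ops for a gap starting at the cursors (r, q)."""
        nonlocal r, q
        pre, suf, mr, mq = _trim_common(gap_r, gap_q)
        _append_op(cigar, "=", pre)
        if mr or mq:
            if not mr:
                _append_op(cigar, "I", len(mq))
            elif not mq:
                _append_op(cigar, "D", len(mr))
            else:
                inv = _maybe_inversion(mr, mq, k)
                if inv is not None:
                    gr_s, gq_s = r + pre, q + pre
                    flush_block(gr_s, gq_s)
                    blocks.append(
                        AlignmentBlock(ref_name, gr_s, gr_s + len(mr),
                                       query_name, gq_s, gq_s + len(mq),
                                       "-" if strand == "+" else "+", inv)
                    )
                    flush_block(gr_s + len(mr), gq_s + len(mq))
                elif max(len(mr), len(mq)) <= max_gap_close:
                    for op, n in _gap_ops(mq, mr):
                        _append_op(cigar, op, n)
                else:
                    _append_op(cigar, "D", len(mr))
                    _append_op(cigar, "I", len(mq))
        _append_op(cigar, "=", suf)
        r += len(gap_r)
        q += len(gap_q)

    for ar, aq in chain:
        ar, aq = int(ar), int(aq)
        if ar < r or aq < q:
            # anchor overlaps already-aligned sequence; extend if on-diagonal
            if ar - aq == r - q and ar + k > r:
                _append_op(cigar, "=", ar + k - r)
                r, q = ar + k, aq + k
            continue
        if ar > r or aq > q:
            close_gap(seq_a[r:ar], seq_q[q:aq])
        _append_op(cigar, "=", k)
        r, q = ar + k, aq + k

    # extend exact matches rightward of the last anchor
    ext = 0
    while r + ext < len(seq_a) and q + ext < len(seq_q) \
            and seq_a[r + ext] == seq_q[q + ext]:
        ext += 1
    _append_op(cigar, "=", ext)
    r += ext
    q += ext
    rem_r, rem_q = len(seq_a) - r, len(seq_q) - q
    if rem_r and rem_q and max(rem_r, rem_q) <= max_gap_close:
        for op, n_ in _gap_ops(seq_q[q:], seq_a[r:]):
            _append_op(cigar, op, n_)
        r, q = len(seq_a), len(seq_q)
    flush_block(r, q)

    if strand == "-":
        # report query coordinates on the original (forward) strand
        L = len(seq_b)
        for b in blocks:
            b.query_start, b.query_end = L - b.query_end, L - b.query_start
    for b in blocks:
        b.validate()
    return blocks
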