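"""Local alignment of flank queries against a target genome.

The liftover procedure locates the orthologous position of a variant by
aligning its flank query (nominally 201 bases) against the whole target
genome and keeping high-scoring pairs (HSPs) that (a) contain the
variant position, (b) cover at least half of the nominal query, and
(c) have >= 90% identity across the HSP. Two search routes are provided:

* :func:`smith_waterman` -- an exhaustive affine-gap Smith-Waterman scan
  of the full dynamic-programming matrix, reporting every distinct local
  alignment above a score floor (Waterman-Eggert style: best alignment,
  mask its target span, repeat). This is the reference route; it is
  independent of any seeding heuristic.
* :func:`find_hsps` -- the production route: a BLAT-like seed-and-extend
  search that k-mer-indexes the target, gathers seed hits into candidate
  windows, and runs the same DP engine only inside those windows.

Both routes report HSPs in forward target coordinates with a strand
flag; minus-strand alignments are computed on the reverse-complemented
query. N bases never match anything (they count as mismatches).

Identity is gap-inclusive (matches / aligned columns, where columns
include gap columns), the stricter BLAST-style convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

from .genome_io import FlankQuery, GenomeSequence

__all__ = [
    "AlignParams",
    "HSP",
    "UniqueStatus",
    "TargetSeedIndex",
    "smith_waterman",
    "find_hsps",
    "hsp_identity",
    "filter_hsps",
    "unique_hsp",
    "write_hsps_tsv",
]

# Base encoding: A=0 C=1 G=2 T=3 N=4, masked=5. Codes >=4 never match.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)
_MASKED = np.uint8(5)
_DECODE = "ACGTN?"


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A0 C1 G2 T3, other=N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1].copy()


def revcomp(seq: str) -> str:
    return "".join(_DECODE[c] for c in revcomp_codes(encode(seq)))


@dataclass(frozen=True)
class AlignParams:
    """Scoring and acceptance parameters for flank alignment.

    A gap of length L is penalised ``gap_open_penalty + L * gap_extend_penalty``.
    ``min_query_cover`` is a fraction of the *nominal* query length
    (``2*flank + 1`` bases) even when the extracted flank was truncated at
    a contig end. ``min_score`` is the floor below which local alignments
    are not reported; it is far below anything that can pass the identity
    and coverage filters and merely bounds the search.
    """

    match_score: int = 1
    mismatch_penalty: int = 1
    gap_open_penalty: int = 1
    gap_extend_penalty: int = 1
    seed_k: int = 11
    min_identity: float = 0.90
    min_query_cover: float = 0.50
    flank: int = 100
    min_score: int = 40

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_query_cover <= 1:
            raise ValueError("min_query_cover must be in (0, 1]")
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")

    @property
    def nominal_query_length(self) -> int:
        return 2 * self.flank + 1


@dataclass(frozen=True)
class HSP:
    """A gapped local alignment between a flank query and the target genome.

    Coordinates are 0-based half-open. ``query_start``/``query_end`` are on
    the original (forward) query; target coordinates are always on the
    forward strand of the target. ``blocks`` are gapless segments
    ``(query_offset, target_offset, length)`` ordered by increasing query
    offset; on the minus strand a block maps query position ``q + i`` to
    target position ``t + (length - 1 - i)``.
    """

    query_start: int
    query_end: int
    target_contig: str
    target_start: int
    target_end: int
    strand: str  # "+" or "-"
    blocks: Tuple[Tuple[int, int, int], ...]
    matches: int
    mismatches: int
    gap_columns: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / (self.matches + self.mismatches + self.gap_columns)

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def hsp_identity(h: HSP) -> float:
    """Gap-inclusive identity: matches / (matches + mismatches + gap columns)."""
    return h.identity


class UniqueStatus(Enum):
    NO_HSP = "no_hsp"
    MULTIPLE_HSP = "multiple_hsp"


@njit(cache=True)
def _sw_kernel(q, t, match, mismatch, go, ge):  # pragma: no cover - jitted
    """Affine-gap Smith-Waterman fill with traceback pointers.

    Returns (best score, best i, best j, H-origin pointers, E-open flags,
    F-open flags). Ties in the cell maximum prefer diagonal over vertical
    over horizontal moves (fewer gap columns); among equal-score end
    cells the one with the larger i+j wins (prefer the longer alignment),
    then the first in row-major scan order.
    """
    n = q.shape[0]
    m = t.shape[0]
    NEG = np.int32(-(10 ** 9) // 2)
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    ptr = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    pe = np.zeros((n + 1, m + 1), np.uint8)  # 1 = extended from E
    pf = np.zeros((n + 1, m + 1), np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go - ge
            e_ext = E[i, j - 1] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
            else:
                E[i, j] = e_ext
                pe[i, j] = 1
            f_open = H[i - 1, j] - go - ge
            f_ext = F[i - 1, j] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
            else:
                F[i, j] = f_ext
                pf[i, j] = 1
            tj = t[j - 1]
            if qi == tj and qi < 4:
                d = H[i - 1, j - 1] + match
            else:
                d = H[i - 1, j - 1] - mismatch
            h = np.int32(0)
            p = np.uint8(0)
            if d >= h and d > 0:
                h = d
                p = np.uint8(1)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            H[i, j] = h
            ptr[i, j] = p
            if h > best or (h == best and h > 0 and i + j > bi + bj):
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr, pe, pf


# Alignment op codes used in tracebacks.
_OP_DIAG, _OP_GAPQ, _OP_GAPT = 0, 1, 2  # diag / gap-in-query / gap-in-target


def _traceback(ptr, pe, pf, bi: int, bj: int) -> Tuple[int, int, List[int]]:
    """Walk pointers back from the best cell; returns (qs, ts, ops forward)."""
    ops: List[int] = []
    i, j = bi, bj
    state = 0  # 0 = H, 2 = E, 3 = F
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                ops.append(_OP_DIAG)
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # gap in query: consumes target char j-1
            opened = pe[i, j] == 0
            ops.append(_OP_GAPQ)
            j -= 1
            if opened:
                state = 0
        else:  # gap in target: consumes query char i-1
            opened = pf[i, j] == 0
            ops.append(_OP_GAPT)
            i -= 1
            if opened:
                state = 0
    ops.reverse()
    return i, j, ops


def _hsp_from_alignment(
    q_codes: np.ndarray,
    t_codes: np.ndarray,
    qs: int,
    ts: int,
    ops: Sequence[int],
    score: int,
    strand: str,
    orig_query_len: int,
    contig: str,
    t_offset: int,
) -> HSP:
    """Build an HSP from a traceback, converting minus-strand coordinates.

    ``qs``/``ts`` and the ops are in the orientation of the alignment
    (reverse-complemented query for minus strand); the returned HSP uses
    original-query and forward-target coordinates.
    """
    blocks: List[Tuple[int, int, int]] = []
    matches = mismatches = gap_columns = 0
    qi, tj = qs, ts
    run_q = run_t = run_len = -1
    for op in ops:
        if op == _OP_DIAG:
            if run_len < 0:
                run_q, run_t, run_len = qi, tj, 0
            run_len += 1
            if q_codes[qi] == t_codes[tj] and q_codes[qi] < 4:
                matches += 1
            else:
                mismatches += 1
            qi += 1
            tj += 1
        else:
            if run_len > 0:
                blocks.append((run_q, run_t, run_len))
            run_len = -1
            gap_columns += 1
            if op == _OP_GAPQ:
                tj += 1
            else:
                qi += 1
    if run_len > 0:
        blocks.append((run_q, run_t, run_len))
    q_start, q_end = qs, qi
    t_start, t_end = ts, tj
    if strand == "-":
        # Alignment used revcomp(query); flip query coordinates back.
        L = orig_query_len
        q_start, q_end = L - qi, L - qs
        conv = []
        for (bq, bt, bl) in blocks:
            conv.append((L - (bq + bl), bt, bl))
        conv.reverse()
        blocks = conv
    blocks = [(bq, bt + t_offset, bl) for (bq, bt, bl) in blocks]
    return HSP(
        query_start=q_start,
        query_end=q_end,
        target_contig=contig,
        target_start=t_start + t_offset,
        target_end=t_end + t_offset,
        strand=strand,
        blocks=tuple(blocks),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gap_columns,
        score=int(score),
    )


def _local_alignments(
    q_codes: np.ndarray,
    t_codes: np.ndarray,
    params: AlignParams,
    contig: str,
    t_offset: int = 0,
    max_hits: int = 32,
) -> List[HSP]:
    """All distinct local alignments of the query against one target slice.

    Iteratively takes the best alignment over both strands, emits it,
    masks its target span, and repeats until the score drops below
    ``params.min_score``. Masked bases match nothing, so each emitted HSP
    occupies a distinct target locus.
    """
    t_work = t_codes.copy()
    rc_q = revcomp_codes(q_codes)
    out: List[HSP] = []
    args = (
        params.match_score,
        params.mismatch_penalty,
        params.gap_open_penalty,
        params.gap_extend_penalty,
    )
    for _ in range(max_hits):
        cands = []
        for rank, (strand, qq) in enumerate((("+", q_codes), ("-", rc_q))):
            score, bi, bj, ptr, pe, pf = _sw_kernel(qq, t_work, *args)
            if score >= params.min_score:
                qs, ts, ops = _traceback(ptr, pe, pf, bi, bj)
                hsp = _hsp_from_alignment(
                    qq, t_work, qs, ts, ops, score, strand,
                    len(q_codes), contig, t_offset,
                )
                cands.append((score, rank, hsp.target_start, hsp))
        if not cands:
            break
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        hsp = cands[0][3]
        out.append(hsp)
        t_work[hsp.target_start - t_offset : hsp.target_end - t_offset] = _MASKED
    return out


def smith_waterman(
    query: str, target: str, params: AlignParams, contig: str = "target"
) -> List[HSP]:
    """Exhaustive local alignment of ``query`` against ``target``.

    Fills the full affine-gap DP matrix over both strands and reports
    every distinct locally optimal alignment scoring at least
    ``params.min_score``. Deterministic: ties prefer fewer gap columns,
    then the plus strand, then the leftmost target start. Intended as the
    reference route for modest target sizes (the full matrix is
    materialised in memory).
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    return _local_alignments(encode(query), encode(target), params, contig)


class TargetSeedIndex:
    """Exact k-mer index of a target genome for seed lookup.

    K-mers containing N are not indexed (they cannot produce exact
    matches under the N-never-matches rule anyway).
    """

    def __init__(self, genome: GenomeSequence, k: int = 11):
        self.k = k
        self.genome = genome
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((name, i))

    def hits(self, seq: str) -> Dict[str, List[int]]:
        """Target positions (per contig) sharing a k-mer with ``seq``."""
        k = self.k
        out: Dict[str, List[int]] = {}
        for i in range(len(seq) - k + 1):
            for contig, pos in self._index.get(seq[i : i + k], ()):
                out.setdefault(contig, []).append(pos)
        return out


def _candidate_windows(
    positions: Sequence[int], contig_len: int, query_len: int, pad: int = 50
) -> List[Tuple[int, int]]:
    """Merge seed-hit positions into disjoint target windows for extension."""
    windows: List[Tuple[int, int]] = []
    for p in sorted(positions):
        lo = max(0, p - query_len - pad)
        hi = min(contig_len, p + query_len + pad)
        if windows and lo <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], hi))
        else:
            windows.append((lo, hi))
    return windows


def find_hsps(
    query: FlankQuery,
    target: GenomeSequence,
    params: AlignParams,
    index: Optional[TargetSeedIndex] = None,
) -> List[HSP]:
    """Seed-and-extend search for HSPs of a flank query in the target genome.

    Builds (or reuses) an exact k-mer index of the target, collects seed
    hits of the query and of its reverse complement, merges hits into
    candidate windows, and runs the exhaustive local aligner inside each
    window. Reuses a prebuilt :class:`TargetSeedIndex` when lifting many
    variants against the same genome.
    """
    if index is None:
        index = TargetSeedIndex(target, params.seed_k)
    elif index.k != params.seed_k:
        raise ValueError("index k does not match params.seed_k")
    q_seq = query.sequence
    q_codes = encode(q_seq)
    hit_positions: Dict[str, List[int]] = {}
    for seq in (q_seq, revcomp(q_seq)):
        for contig, positions in index.hits(seq).items():
            hit_positions.setdefault(contig, []).extend(positions)
    out: List[HSP] = []
    for contig, positions in hit_positions.items():
        contig_len = target.lengths[contig]
        contig_seq = target.contigs[contig]
        for lo, hi in _candidate_windows(positions, contig_len, len(q_seq)):
            out.extend(
                _local_alignments(
                    q_codes, encode(contig_seq[lo:hi]), params, contig, t_offset=lo
                )
            )
    out.sort(key=lambda h: (-h.score, h.target_contig, h.target_start))
    return out


def filter_hsps(
    hsps: Iterable[HSP], query: FlankQuery, params: AlignParams
) -> List[HSP]:
    """Apply the three HSP acceptance clauses.

    Retains HSPs that (a) contain the variant position within the aligned
    query span, (b) align at least ``min_query_cover`` of the nominal
    query length (fixed denominator of ``2*flank + 1`` bases, even for
    flanks truncated at contig ends), and (c) have gap-inclusive identity
    of at least ``min_identity``.
    """
    nominal = params.nominal_query_length
    out = []
    for h in hsps:
        if not h.query_start <= query.variant_offset < h.query_end:
            continue
        if h.query_span < params.min_query_cover * nominal:
            continue
        if h.identity < params.min_identity - 1e-12:
            continue
        out.append(h)
    return out


def unique_hsp(hsps: Sequence[HSP]) -> Union[HSP, UniqueStatus]:
    """Return the single surviving HSP, or the reason there is none.

    The corroboration procedure only trusts variants whose flank maps to
    exactly one place in the target genome; zero hits and multiple hits
    are both terminal statuses (multi-hit flanks typically indicate
    paralogous target regions).
    """
    if not hsps:
        return UniqueStatus.NO_HSP
    if len(hsps) > 1:
        return UniqueStatus.MULTIPLE_HSP
    return hsps[0]


def write_hsps_tsv(hsps: Iterable[HSP], path) -> None:
    """Write HSPs as a BLAST outfmt-6-like TSV for inspection."""
    cols = (
        "query_start\tquery_end\ttarget_contig\ttarget_start\ttarget_end"
        "\tstrand\tmatches\tmismatches\tgap_columns\tidentity\tscore\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for h in hsps:
            fh.write(
                f"{h.query_start}\t{h.query_end}\t{h.target_contig}"
                f"\t{h.target_start}\t{h.target_end}\t{h.strand}"
                f"\t{h.matches}\t{h.mismatches}\t{h.gap_columns}"
                f"\t{h.identity:.4f}\t{h.score}\n"
            )
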