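"""Pairwise protein alignment with Karlin–Altschul E-value estimation.

Affine-gap Smith–Waterman (local) and Needleman–Wunsch (global) alignment
with substitution-matrix scoring, BLOSUM62 with gap open 11 / extend 1 by
default, mirroring BLASTP-style homology evidence. The dynamic programming
itself is delegated to :class:`Bio.Align.PairwiseAligner`; this module owns
the statistics, the identity dialect, and the coordinate transfer that the
residue-rule classifiers build on.

Conventions (documented because downstream rules are sensitive to them):

* A gap of length L is penalised ``gap_open + (L - 1) * gap_extend``.
* Identity % = identical residue columns / alignment length **including
  internal gap columns**, × 100. ``X`` never counts as an identity.
* Residue numbering is 1-based; intervals are inclusive.
* E = K·m·n·exp(−λ·S) on the raw score S (no bit-score conversion), with
  published gapped BLOSUM62-11/1 constants λ=0.267, K=0.041 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS + "X")

#: Sentinel for a reference position with no aligned query residue.
UNMAPPED = None

DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


class AlignmentError(ValueError):
    """Raised on illegal sequences or parameters."""


@dataclass(frozen=True)
class AlignmentParams:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = DEFAULT_LAMBDA
    k: float = DEFAULT_K
    mode: str = "local"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise AlignmentError(
                f"require gap_open >= gap_extend >= 1, got "
                f"{self.gap_open}/{self.gap_extend}"
            )
        if self.lam <= 0 or self.k <= 0:
            raise AlignmentError("lambda and K must be positive")
        if self.mode not in ("local", "global"):
            raise AlignmentError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class TierThresholds:
    """E-value tiers deferring judgment on hit quality (no hard cutoff)."""

    strong: float = 1e-10
    weak: float = 1e-2

    def tier(self, evalue: float) -> str:
        if evalue <= self.strong:
            return "strong"
        if evalue <= self.weak:
            return "weak"
        return "marginal"


@dataclass
class PairwiseAlignment:
    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    raw_score: int
    identity_pct: float
    evalue: float
    #: ordered (query_pos | None, ref_pos | None), 1-based
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.columns

    @property
    def query_span(self) -> tuple[int, int] | None:
        pos = [q for q, _ in self.columns if q is not None]
        return (pos[0], pos[-1]) if pos else None

    @property
    def ref_span(self) -> tuple[int, int] | None:
        pos = [r for _, r in self.columns if r is not None]
        return (pos[0], pos[-1]) if pos else None


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    ref_id: str
    activity_symbol: str
    raw_score: int
    evalue: float
    identity_pct: float
    query_coverage_pct: float
    ref_coverage_pct: float
    tier: str


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


def matrix_score(name: str, a: str, b: str) -> int:
    return int(_matrix(name)[a, b])


def _check_sequence(seq: str, what: str) -> None:
    if not seq:
        raise AlignmentError(f"{what} sequence is empty")
    for i, ch in enumerate(seq, start=1):
        if ch not in _ALPHABET:
            raise AlignmentError(
                f"illegal character {ch!r} at position {i} of {what} sequence"
            )


def _aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _matrix(params.matrix_name)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = params.mode
    return aligner


def estimate_evalue(
    raw_score: float, m: int, n: int, params: AlignmentParams
) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S).

    m and n are the lengths of the query and of the searched space; the
    expectation is 0 for an empty search space.
    """
    if m < 0 or n < 0:
        raise AlignmentError("search-space lengths must be nonnegative")
    if m == 0 or n == 0:
        return 0.0
    return params.k * m * n * math.exp(-params.lam * raw_score)


def _empty_alignment(query_id: str, ref_id: str, m: int, n: int,
                     params: AlignmentParams) -> PairwiseAlignment:
    return PairwiseAlignment(
        query_id=query_id,
        ref_id=ref_id,
        aligned_query="",
        aligned_ref="",
        raw_score=0,
        identity_pct=0.0,
        evalue=estimate_evalue(0, m, n, params),
        columns=[],
    )


def pairwise_align(
    query: str,
    ref: str,
    params: AlignmentParams | None = None,
    query_id: str = "query",
    ref_id: str = "ref",
    search_space: tuple[int, int] | None = None,
) -> PairwiseAlignment:
    """Optimal pairwise alignment of two protein sequences.

    In local mode an all-negative score landscape yields the empty
    alignment with raw score 0. ``search_space`` overrides the (m, n) used
    for the E-value (defaults to the two sequence lengths).
    """
    params = params or AlignmentParams()
    _check_sequence(query, "query")
    _check_sequence(ref, "ref")
    m, n = search_space if search_space is not None else (len(query), len(ref))

    alignments = _aligner(params).align(query, ref)
    try:
        best = alignments[0]
    except IndexError:
        best = None
    if best is None or (params.mode == "local" and alignments.score <= 0):
        return _empty_alignment(query_id, ref_id, m, n, params)

    gapped_q, gapped_r = str(best[0]), str(best[1])
    qi = best.indices[0]  # 0-based residue index per column, -1 in gaps
    ri = best.indices[1]
    columns: list[tuple[int | None, int | None]] = [
        (
            int(q) + 1 if q >= 0 else None,
            int(r) + 1 if r >= 0 else None,
        )
        for q, r in zip(qi, ri)
    ]
    identical = sum(
        1
        for a, b in zip(gapped_q, gapped_r)
        if a == b and a != "-" and a != "X"
    )
    identity_pct = round(100.0 * identical / len(columns), 2) if columns else 0.0
    score = int(round(alignments.score))
    return PairwiseAlignment(
        query_id=query_id,
        ref_id=ref_id,
        aligned_query=gapped_q,
        aligned_ref=gapped_r,
        raw_score=score,
        identity_pct=identity_pct,
        evalue=estimate_evalue(score, m, n, params),
        columns=columns,
    )


def map_ref_position(aln: PairwiseAlignment, ref_pos: int, ref_len: int | None = None):
    """Query position (1-based) aligned to ``ref_pos``, or UNMAPPED.

    UNMAPPED is returned when ``ref_pos`` sits in a gap column or outside
    the (local) alignment. Positions outside the reference are rejected.
    """
    upper = ref_len
    if upper is None:
        rs = aln.ref_span
        upper = rs[1] if rs else 0
    if ref_pos < 1 or (upper and ref_pos > upper):
        raise AlignmentError(f"ref_pos {ref_pos} out of range 1..{upper}")
    for q, r in aln.columns:
        if r == ref_pos:
            return q  # None when the column pairs ref_pos with a gap
    return UNMAPPED


def map_query_position(aln: PairwiseAlignment, query_pos: int):
    """Inverse coordinate transfer (query → reference)."""
    for q, r in aln.columns:
        if q == query_pos:
            return r
    return UNMAPPED


def search_best_hit(
    query_set: Sequence[tuple[str, str]],
    ref: tuple[str, str],
    activity_symbol: str = "",
    params: AlignmentParams | None = None,
    tiers: TierThresholds | None = None,
) -> list[SearchHit]:
    """Rank every sequence of ``query_set`` against one reference protein.

    ``query_set`` is (id, sequence) pairs, ``ref`` an (id, sequence) pair.
    Hits are sorted by raw score descending, ties broken by E-value
    ascending then query id; the Karlin–Altschul n is the summed length of
    the searched set, so E-values scale with the proteome searched.
    """
    if not query_set:
        raise AlignmentError("empty query set")
    params = params or AlignmentParams()
    tiers = tiers or TierThresholds()
    ref_id, ref_seq = ref
    space = sum(len(s) for _, s in query_set)
    hits = []
    for qid, qseq in query_set:
        aln = pairwise_align(
            qseq, ref_seq, params, query_id=qid, ref_id=ref_id,
            search_space=(len(ref_seq), space),
        )
        qspan, rspan = aln.query_span, aln.ref_span
        qcov = 100.0 * (qspan[1] - qspan[0] + 1) / len(qseq) if qspan else 0.0
        rcov = 100.0 * (rspan[1] - rspan[0] + 1) / len(ref_seq) if rspan else 0.0
        hits.append(
            SearchHit(
                query_id=qid,
                ref_id=ref_id,
                activity_symbol=activity_symbol,
                raw_score=aln.raw_score,
                evalue=aln.evalue,
                identity_pct=aln.identity_pct,
                query_coverage_pct=round(qcov, 2),
                ref_coverage_pct=round(rcov, 2),
                tier=tiers.tier(aln.evalue),
            )
        )
    hits.sort(key=lambda h: (-h.raw_score, h.evalue, h.query_id))
    return hits
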