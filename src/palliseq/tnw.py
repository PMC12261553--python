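"""Temporal Needleman-Wunsch (TNW) global alignment of timed sequences.

Classic Needleman-Wunsch aligns two symbol sequences globally, scoring
matches, mismatches and gaps.  The temporal variant implemented here adds a
timing term: when two symbols match, the score is additionally rewarded by

    T_p * exp(-|g_A - g_B| / tau)

where g_A, g_B are the transition times (days since the previous event in
each sequence) of the matched elements.  Identical timing earns the full
bonus T_p; the bonus decays to zero as the timing discrepancy grows, with
characteristic scale tau.  Mismatches and gaps are scored exactly as in
classic NW, so with T_p = 0 the algorithm reduces to Needleman-Wunsch on
the symbol strings.

Raw global scores depend on sequence length, so pairwise comparison uses a
normalized similarity in (0, 1]:

    sim(A, B) = exp(score(A, B) - max(score(A, A), score(B, B)))

which is 1 exactly for self-comparison and strictly increasing in the raw
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .encode import PathwaySequence

__all__ = [
    "TNWParams",
    "AlignmentResult",
    "tnw_align",
    "brute_force_score",
    "normalized_similarity",
    "pairwise_similarity_matrix",
]


@dataclass(frozen=True)
class TNWParams:
    """Scoring constants for temporal alignment.

    match/mismatch are per aligned symbol pair; ``gap`` is subtracted per
    unaligned element; ``temporal_weight`` (T_p) bounds the timing bonus on
    matches; ``time_scale`` (tau, days) sets how fast the bonus decays with
    timing discrepancy.
    """

    match: float = 1.0
    mismatch: float = -1.1
    gap: float = 0.7
    temporal_weight: float = 0.25
    time_scale: float = 30.0

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap penalty must be > 0 (it is subtracted)")
        if self.temporal_weight < 0:
            raise ValueError("temporal_weight must be >= 0")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be > 0")
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")

    def pair_score(self, sym_a: str, gap_a: float, sym_b: str, gap_b: float) -> float:
        if sym_a == sym_b:
            return self.match + self.temporal_weight * math.exp(
                -abs(gap_a - gap_b) / self.time_scale
            )
        return self.mismatch


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one global alignment.

    ``aligned_pairs`` lists (i, j) element indices; ``None`` on either side
    marks a gap.  The pairs reconstruct the score exactly.
    """

    score: float
    aligned_pairs: tuple[tuple[int | None, int | None], ...]


def _seq_parts(seq: PathwaySequence | None) -> tuple[tuple[str, ...], tuple[int, ...]]:
    if seq is None:
        return (), ()
    return tuple(seq.events), tuple(seq.gaps)


def tnw_align(
    seqA: PathwaySequence | None,
    seqB: PathwaySequence | None,
    params: TNWParams = TNWParams(),
) -> AlignmentResult:
    """Optimal global temporal alignment via dynamic programming.

    The DP matrix follows M(0,0)=0, M(i,0)=-i*g, M(0,j)=-j*g and

        M(i,j) = max( M(i-1,j-1) + s(a_i, b_j) + timing bonus on match,
                      M(i-1,j) - g,
                      M(i,j-1) - g )

    Traceback prefers diagonal, then up (consume A), then left (consume B)
    on ties; the score itself is tie-invariant.  Two empty sequences align
    with score 0 and empty traceback.
    """
    ev_a, gp_a = _seq_parts(seqA)
    ev_b, gp_b = _seq_parts(seqB)
    n, m = len(ev_a), len(ev_b)
    g = params.gap

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        M[i][0] = -i * g
    for j in range(1, m + 1):
        M[0][j] = -j * g
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = M[i - 1][j - 1] + params.pair_score(
                ev_a[i - 1], gp_a[i - 1], ev_b[j - 1], gp_b[j - 1]
            )
            M[i][j] = max(diag, M[i - 1][j] - g, M[i][j - 1] - g)

    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = M[i - 1][j - 1] + params.pair_score(
                ev_a[i - 1], gp_a[i - 1], ev_b[j - 1], gp_b[j - 1]
            )
            if math.isclose(M[i][j], diag, rel_tol=0.0, abs_tol=1e-12):
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if i > 0 and math.isclose(M[i][j], M[i - 1][j] - g, abs_tol=1e-12):
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    return AlignmentResult(score=M[n][m], aligned_pairs=tuple(reversed(pairs)))


_BRUTE_FORCE_CAP = 8


def brute_force_score(
    seqA: PathwaySequence | None,
    seqB: PathwaySequence | None,
    params: TNWParams = TNWParams(),
) -> float:
    """Independent oracle: exhaustive maximum over all global alignments.

    Enumerates every monotone global alignment (each element aligned or
    gapped, order preserved) recursively and returns the best objective.
    Refuses inputs with combined length above 8.
    """
    ev_a, gp_a = _seq_parts(seqA)
    ev_b, gp_b = _seq_parts(seqB)
    if len(ev_a) + len(ev_b) > _BRUTE_FORCE_CAP:
        raise ValueError(
            f"brute_force_score limited to total length {_BRUTE_FORCE_CAP}"
        )

    def best(i: int, j: int) -> float:
        if i == len(ev_a) and j == len(ev_b):
            return 0.0
        options = []
        if i < len(ev_a) and j < len(ev_b):
            options.append(
                params.pair_score(ev_a[i], gp_a[i], ev_b[j], gp_b[j])
                + best(i + 1, j + 1)
            )
        if i < len(ev_a):
            options.append(-params.gap + best(i + 1, j))
        if j < len(ev_b):
            options.append(-params.gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def _self_score(seq: PathwaySequence, params: TNWParams) -> float:
    # DP on (A, A); equals len * (match + temporal_weight) whenever the
    # all-diagonal alignment is optimal, but stays exact for any params
    return tnw_align(seq, seq, params).score


def normalized_similarity(
    seqA: PathwaySequence,
    seqB: PathwaySequence,
    params: TNWParams = TNWParams(),
) -> float:
    """Length-normalized similarity in (0, 1]; 1 iff the raw score reaches
    the better of the two self-alignment scores."""
    if seqA is None or len(seqA) == 0 or seqB is None or len(seqB) == 0:
        raise ValueError("normalized_similarity requires non-empty sequences")
    score = tnw_align(seqA, seqB, params).score
    return math.exp(score - max(_self_score(seqA, params), _self_score(seqB, params)))


def pairwise_similarity_matrix(
    sequences: list[PathwaySequence],
    params: TNWParams = TNWParams(),
) -> pd.DataFrame:
    """Symmetric unit-diagonal similarity matrix over all sequence pairs.

    Computed from n(n-1)/2 alignments; indexed by individual id.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    for s in sequences:
        if len(s) == 0:
            raise ValueError(f"empty sequence for {s.individual_id}")
    ids = [s.individual_id for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids among sequences")

    self_scores = [_self_score(s, params) for s in sequences]
    n = len(sequences)
    S = np.eye(n)
    for i, j in combinations(range(n), 2):
        score = tnw_align(sequences[i], sequences[j], params).score
        S[i, j] = S[j, i] = math.exp(score - max(self_scores[i], self_scores[j]))
    return pd.DataFrame(S, index=ids, columns=ids)
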