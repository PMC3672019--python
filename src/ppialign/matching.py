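"""Extract a one-to-one node matching from a similarity matrix.

Three heuristics over the weighted bipartite graph encoded by X:

* :func:`greedy_match` — matrix form of the 1/2-approximation: take the
  globally heaviest entry, zero its row and column, repeat.  Guarantees
  at least half the optimal weight.
* :func:`auction_match` — buyers (rows) bid price increments for objects
  (columns); with integer weights and a fixed increment
  ``epsilon < 1/min(n)`` the result attains the optimal weight.
* :func:`adaptive_auction_match` — starts with a small epsilon and grows
  it whenever a bidding round assigns fewer than ``delta`` new buyers,
  trading optimality for speed, then fills any unmatched rows with
  :func:`complete_matching` to reach maximum cardinality.

:func:`brute_force_optimal` enumerates every injection at small sizes
and serves as the exact oracle in tests.

Fractional scores are integerized as ``round(x * scale)`` before an
auction runs (the optimality guarantee is stated for integer weights);
reported pair scores always come from the original matrix.  When the
matrix has more rows than columns it is transposed internally so buyers
are the smaller side, and results are mapped back.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import Matching

__all__ = [
    "AuctionState",
    "greedy_match",
    "auction_match",
    "adaptive_auction_match",
    "complete_matching",
    "brute_force_optimal",
]

DEFAULT_SCALE = 10**6
DEFAULT_GROWTH = 4.0

_BRUTE_GUARD = 9


def _as_matrix(X) -> np.ndarray:
    """Accept a raw array or a SimilarityMatrix-like object with .X."""
    M = getattr(X, "X", X)
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2:
        raise ValueError("similarity scores must form a 2-d matrix")
    return M


@dataclass
class AuctionState:
    """Final state of an auction run, kept for inspection and testing.

    ``price_history`` holds one snapshot of the price vector per bidding
    round; prices are non-decreasing over the run by construction.
    """

    prices: np.ndarray
    owner: np.ndarray
    epsilon: float
    C: float
    delta: int = 1
    rounds: int = 0
    bids: int = 0
    price_history: list = field(default_factory=list)


def greedy_match(X) -> Matching:
    """Matrix-based greedy 1/2-approximation.

    Repeatedly selects the maximum entry of a working copy of X, records
    the pair, and zeroes its row and column, until one dimension of the
    working matrix is all zero.  Only strictly positive entries produce
    pairs; ties break to the smallest row index, then smallest column.
    """
    M = _as_matrix(X)
    if not np.isfinite(M).all():
        raise ValueError("similarity matrix must be finite")
    if (M < 0).any():
        raise ValueError("similarity matrix must be non-negative")
    work = M.copy()
    pairs: list[tuple[int, int]] = []
    scores: list[float] = []
    limit = min(work.shape)
    while len(pairs) < limit:
        flat = np.argmax(work)  # first occurrence: smallest row, then column
        i, j = np.unravel_index(flat, work.shape)
        if work[i, j] <= 0:
            break
        pairs.append((int(i), int(j)))
        scores.append(float(M[i, j]))
        work[i, :] = 0.0
        work[:, j] = 0.0
    return Matching(pairs=pairs, scores=scores, method="greedy", shape=M.shape)


def _run_auction(W: np.ndarray, epsilon: float, *, growth: float | None,
                 delta: int, state: AuctionState) -> np.ndarray:
    """Gauss-Seidel bidding rounds on integerized weights W (rows bid).

    Returns ``owner`` (per-column row index, -1 if unowned).  A buyer
    whose best profit is no longer positive drops out permanently:
    prices never decrease, so its profits can never recover.  With
    ``growth`` set, epsilon multiplies by it after every round that
    assigns fewer than ``delta`` net new buyers (the adaptive variant);
    with ``growth=None`` epsilon stays fixed.
    """
    n_rows, n_cols = W.shape
    prices = state.prices
    owner = state.owner
    row_obj = np.full(n_rows, -1, dtype=np.int64)
    active = (W > 0).any(axis=1)
    eps = epsilon
    while True:
        snapshot = [i for i in range(n_rows) if active[i] and row_obj[i] < 0]
        if not snapshot:
            break
        assigned_before = int((row_obj >= 0).sum())
        for i in snapshot:
            if row_obj[i] >= 0:
                continue
            profits = W[i] - prices
            ji = int(np.argmax(profits))
            ui = profits[ji]
            if ui <= 0:
                active[i] = False
                continue
            if n_cols > 1:
                rest = np.delete(profits, ji)
                vi = float(rest.max())
            else:
                vi = 0.0
            prices[ji] += ui - vi + eps
            prev = int(owner[ji])
            owner[ji] = i
            row_obj[i] = ji
            if prev >= 0:
                row_obj[prev] = -1
            state.bids += 1
        state.rounds += 1
        state.price_history.append(prices.copy())
        newly = int((row_obj >= 0).sum()) - assigned_before
        if growth is not None and newly < delta:
            eps *= growth
    state.epsilon = eps
    return owner


def _auction_core(X, epsilon: float, scale: float, *, growth: float | None,
                  delta: int, method: str) -> tuple[Matching, AuctionState]:
    M = _as_matrix(X)
    if not np.isfinite(M).all():
        raise ValueError("similarity matrix must be finite")
    if (M < 0).any():
        raise ValueError("similarity matrix must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if scale < 1:
        raise ValueError("scale must be >= 1")
    transposed = M.shape[0] > M.shape[1]
    Mw = M.T if transposed else M
    W = np.rint(Mw * scale)
    state = AuctionState(prices=np.zeros(Mw.shape[1]),
                         owner=np.full(Mw.shape[1], -1, dtype=np.int64),
                         epsilon=epsilon, C=float(np.abs(W).max(initial=0.0)),
                         delta=delta)
    owner = _run_auction(W, epsilon, growth=growth, delta=delta, state=state)
    pairs = []
    for j in range(len(owner)):
        if owner[j] >= 0:
            i = int(owner[j])
            pairs.append((j, i) if transposed else (i, j))
    pairs.sort()
    scores = [float(M[i, j]) for i, j in pairs]
    matching = Matching(pairs=pairs, scores=scores, method=method, shape=M.shape)
    return matching, state


def auction_match(X, epsilon: float, scale: float = 1,
                  return_state: bool = False):
    """Auction with a fixed bidding increment.

    Each unassigned buyer bids ``u_i - v_i + epsilon`` on its most
    profitable object (``u_i`` best profit, ``v_i`` second best); the
    object goes to the bidder at the raised price, possibly unseating a
    previous owner.  Bidding stops when every buyer with a
    positive-profit object is assigned.  For integer weights and
    ``epsilon < 1/min(n)`` the assignment weight is optimal.
    """
    matching, state = _auction_core(X, epsilon, scale, growth=None, delta=1,
                                    method="auction")
    return (matching, state) if return_state else matching


def adaptive_auction_match(X, epsilon0: float | None = None,
                           growth: float = DEFAULT_GROWTH,
                           delta: int | None = None,
                           scale: float = DEFAULT_SCALE,
                           return_state: bool = False):
    """Auction with aggressive epsilon scaling plus greedy completion.

    ``epsilon0`` defaults to ``1/(min(n)+1)`` on the integerized problem,
    ``delta`` to ``max(1, ceil(0.01 * min(n)))``.  After every bidding
    round that assigns fewer than ``delta`` net new buyers, epsilon is
    multiplied by ``growth``; prices persist across phases.  The auction
    result is then padded by :func:`complete_matching`, so on an
    entrywise-positive matrix the output has cardinality ``min(n)``.
    """
    M = _as_matrix(X)
    n_min = min(M.shape)
    if epsilon0 is None:
        epsilon0 = 1.0 / (n_min + 1)
    if delta is None:
        delta = max(1, int(np.ceil(0.01 * n_min)))
    if growth <= 1:
        raise ValueError("growth must be > 1")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    matching, state = _auction_core(M, epsilon0, scale, growth=growth,
                                    delta=delta, method="adaptive-auction")
    completed = complete_matching(matching, M)
    completed.method = "adaptive-auction"
    return (completed, state) if return_state else completed


def complete_matching(partial: Matching, X) -> Matching:
    """Pad a matching to maximum cardinality.

    Unmatched rows, in ascending order, are paired with the first
    unmatched column; the added pairs contribute their (possibly zero)
    scores.  Idempotent, never decreases weight, and always reaches
    cardinality ``min(n_rows, n_cols)``.
    """
    M = _as_matrix(X)
    n_rows, n_cols = M.shape
    used_rows = {i for i, _ in partial.pairs}
    used_cols = {j for _, j in partial.pairs}
    pairs = list(partial.pairs)
    scores = list(partial.scores)
    free_cols = iter(j for j in range(n_cols) if j not in used_cols)
    for i in range(n_rows):
        if len(pairs) >= min(n_rows, n_cols):
            break
        if i in used_rows:
            continue
        j = next(free_cols)
        pairs.append((i, j))
        scores.append(float(M[i, j]))
    order = np.argsort([p[0] for p in pairs], kind="stable")
    pairs = [pairs[k] for k in order]
    scores = [scores[k] for k in order]
    return Matching(pairs=pairs, scores=scores, method=partial.method or "completed",
                    shape=M.shape, meta=dict(partial.meta))


def brute_force_optimal(X) -> Matching:
    """Exact maximum-weight full-cardinality matching by enumeration.

    Enumerates every injection of the smaller index set into the larger
    (guarded at ``min(n) <= 9``); the lexicographically smallest
    injection among ties is returned, making the result deterministic.
    Test oracle only — exponential in the smaller dimension.
    """
    M = _as_matrix(X)
    transposed = M.shape[0] > M.shape[1]
    W = M.T if transposed else M
    n_small, n_large = W.shape
    if n_small > _BRUTE_GUARD:
        raise ValueError(f"brute force guarded at min dimension {_BRUTE_GUARD}")
    rows = np.arange(n_small)
    # itertools yields injections in lexicographic order, so argmax on the
    # weight vector resolves ties to the lexicographically smallest one
    perms = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(n_large), n_small)),
        dtype=np.int64,
    ).reshape(-1, n_small)
    weights = W[rows, perms].sum(axis=1)
    best = perms[int(np.argmax(weights))]
    pairs = [(int(c), int(r)) if transposed else (int(r), int(c))
             for r, c in zip(rows, best)]
    pairs.sort()
    scores = [float(M[i, j]) for i, j in pairs]
    return Matching(pairs=pairs, scores=scores, method="brute-force", shape=M.shape)
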