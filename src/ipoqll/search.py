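"""Itemset search driven by the IPOQ-LL criterion.

Stepwise selection alternates backward elimination with forward
selection: after every removal the search may re-introduce previously
removed items when that strictly improves the best score recorded at the
larger size, which lets it recover from overly greedy eliminations.  The
recommended instrument is the itemset with the maximum IPOQ-LL along the
trajectory, but the best itemset of every visited size is retained so an
instrument length can also be fixed a priori.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from joblib import Parallel, delayed

from .containers import PenaltyConfig, ResponseMatrix
from .criterion import IPOQResult, score_split

log = logging.getLogger("ipoqll.search")

#: minimum improvement of a recorded best for a forward step to be accepted;
#: guards against remove/re-add cycles driven by optimizer noise
FORWARD_ACCEPT_TOL = 1e-6

#: largest survey size for which exhaustive enumeration is allowed
EXHAUSTIVE_LIMIT = 20


@dataclass
class SearchTrajectory:
    """Bookkeeping of one stepwise run.

    ``best_by_size`` maps included-set size to the best ``(itemset,
    ipoq_ll)`` seen at that size; ``move_log`` records each accepted move
    as ``(step, action, item_index, ipoq_ll)``; ``optimum`` is the
    overall IPOQ-LL maximizer (ties broken towards the smaller, i.e.
    shorter, instrument).
    """

    best_by_size: dict = field(default_factory=dict)
    move_log: list = field(default_factory=list)
    optimum: tuple = None

    def record(self, itemset, ipoq_ll) -> None:
        size = len(itemset)
        cur = self.best_by_size.get(size)
        if cur is None or ipoq_ll > cur[1]:
            self.best_by_size[size] = (tuple(sorted(itemset)), float(ipoq_ll))

    def finalize(self) -> None:
        best = max(self.best_by_size.items(), key=lambda kv: (kv[1][1], -kv[0]))
        self.optimum = best[1]


def _score_candidates(responses, candidates, penalties, warm, n_jobs, seed):
    """Score candidate itemsets (deterministic order, optionally parallel)."""
    if n_jobs == 1:
        return [score_split(responses, c, penalties, warm_start=warm, seed=seed)
                for c in candidates]
    return Parallel(n_jobs=n_jobs)(
        delayed(score_split)(responses, c, penalties, warm_start=warm, seed=seed)
        for c in candidates)


def _best(results) -> IPOQResult:
    """First strict maximizer; candidate order encodes the tie-break rule."""
    best = results[0]
    for r in results[1:]:
        if r.ipoq_ll > best.ipoq_ll:
            best = r
    return best


def one_step_backward(responses: ResponseMatrix, s_in, penalties: PenaltyConfig,
                      warm_start: IPOQResult | None = None, n_jobs: int = 1,
                      seed: int = 0) -> IPOQResult:
    """Best split among all with one item fewer than ``s_in``.

    All ``|s_in|`` single-removals are scored; ties go to removing the
    lowest item index (candidates are generated in that order and only a
    strictly higher score displaces the incumbent).
    """
    s_in = sorted(int(i) for i in s_in)
    if len(s_in) < 2:
        raise ValueError("backward elimination needs at least two included items")
    candidates = [[i for i in s_in if i != drop] for drop in s_in]
    return _best(_score_candidates(responses, candidates, penalties,
                                   warm_start, n_jobs, seed))


def one_step_forward(responses: ResponseMatrix, s_in, penalties: PenaltyConfig,
                     warm_start: IPOQResult | None = None, n_jobs: int = 1,
                     seed: int = 0) -> IPOQResult:
    """Best split among all with one more item than ``s_in``.

    Ties go to adding the lowest item index.
    """
    s_in = sorted(int(i) for i in s_in)
    s_out = sorted(set(range(responses.n_items)) - set(s_in))
    if not s_out:
        raise ValueError("forward selection needs a non-empty excluded set")
    candidates = [sorted(s_in + [add]) for add in s_out]
    return _best(_score_candidates(responses, candidates, penalties,
                                   warm_start, n_jobs, seed))


def stepwise_search(responses: ResponseMatrix, penalties: PenaltyConfig,
                    min_size: int = 1, seed: int = 0,
                    n_jobs: int = 1) -> SearchTrajectory:
    """Stepwise itemset selection from the full survey down to ``min_size``.

    Starting from all items, repeat: one backward step; then up to two
    forward steps, each accepted only if it strictly improves the recorded
    best at its size by more than ``FORWARD_ACCEPT_TOL`` (and does not
    revisit an itemset).  The full per-size record is returned; the
    stopping rule for the recommended instrument is the global IPOQ-LL
    maximum over the trajectory.
    """
    if responses.n_items < 2:
        raise ValueError("need at least two items to search")
    if not (1 <= min_size <= responses.n_items):
        raise ValueError("min_size must lie in 1..P")
    traj = SearchTrajectory()
    visited = set()
    step = 0

    current = score_split(responses, range(responses.n_items), penalties, seed=seed)
    traj.record(current.s_in, current.ipoq_ll)
    visited.add(frozenset(current.s_in))
    log.info("size %d: IPOQ-LL %.3f", len(current.s_in), current.ipoq_ll)

    while len(current.s_in) > min_size:
        nxt = one_step_backward(responses, current.s_in, penalties,
                                warm_start=current, n_jobs=n_jobs, seed=seed)
        removed = (set(current.s_in) - set(nxt.s_in)).pop()
        step += 1
        traj.move_log.append((step, "remove", removed, nxt.ipoq_ll))
        traj.record(nxt.s_in, nxt.ipoq_ll)
        visited.add(frozenset(nxt.s_in))
        current = nxt
        log.info("size %d: IPOQ-LL %.3f (removed item %d)",
                 len(current.s_in), current.ipoq_ll, removed)
        if len(current.s_in) <= min_size:
            break
        # forward recovery: re-admit an item if that beats the record at
        # the larger size, at most twice in a row
        for _ in range(2):
            if not current.s_out:
                break
            fwd = one_step_forward(responses, current.s_in, penalties,
                                   warm_start=current, n_jobs=n_jobs, seed=seed)
            size_f = len(fwd.s_in)
            recorded = traj.best_by_size.get(size_f, (None, -float("inf")))[1]
            if fwd.ipoq_ll <= recorded + FORWARD_ACCEPT_TOL or \
                    frozenset(fwd.s_in) in visited:
                break
            added = (set(fwd.s_in) - set(current.s_in)).pop()
            step += 1
            traj.move_log.append((step, "add", added, fwd.ipoq_ll))
            traj.record(fwd.s_in, fwd.ipoq_ll)
            visited.add(frozenset(fwd.s_in))
            current = fwd
            log.info("size %d: IPOQ-LL %.3f (re-added item %d)",
                     len(current.s_in), current.ipoq_ll, added)
    traj.finalize()
    return traj


def exhaustive_search(responses: ResponseMatrix, penalties: PenaltyConfig,
                      size: int | None = None, n_jobs: int = 1,
                      seed: int = 0) -> tuple:
    """Globally best itemset over all non-empty subsets (or all of ``size``).

    Enumerates ``2^P - 1`` subsets, so ``P`` is capped at
    ``EXHAUSTIVE_LIMIT``; beyond that use :func:`stepwise_search`.
    Returns ``(itemset, ipoq_ll)``.
    """
    p = responses.n_items
    if p > EXHAUSTIVE_LIMIT:
        raise ValueError(f"exhaustive search is limited to P <= {EXHAUSTIVE_LIMIT} "
                         "items; use stepwise_search for larger surveys")
    if size is not None and not (1 <= size <= p):
        raise ValueError("size must lie in 1..P")
    sizes = [size] if size is not None else range(1, p + 1)
    candidates = [list(c) for s in sizes for c in combinations(range(p), s)]
    results = _score_candidates(responses, candidates, penalties, None, n_jobs, seed)
    best = _best(results)
    return best.s_in, best.ipoq_ll


def best_subset_of_size(trajectory: SearchTrajectory, size: int) -> tuple:
    """The best itemset recorded at a given instrument length."""
    if size not in trajectory.best_by_size:
        raise KeyError(f"no itemset of size {size} was recorded by the search")
    return trajectory.best_by_size[size][0]
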