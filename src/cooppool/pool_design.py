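"""Construction and verification of covering pooling designs.

A covering design for parameters ``(n, k, t, lam)`` is a family of blocks
(subsets of the candidate index set ``{0..n-1}``, each of size at most
``k``) such that every ``t``-subset of candidates is contained in at least
``lam`` distinct blocks.  Blocks become the pools of the initial screen, so
the number of blocks equals the number of first-round experiments.

Two constructors are provided: a randomized greedy builder that fills block
positions by maximal marginal pair coverage (with restarts), and a swap
local search that repairs a fixed-size random family by single-element
exchanges.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Library",
    "PoolDesign",
    "SwapFailure",
    "count_combinations",
    "greedy_design",
    "swap_design",
    "verify_cover",
    "schonheim_bound",
]


@dataclass(frozen=True)
class Library:
    """A candidate library: a size and optional display labels."""

    n: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or self.n < 2:
            raise ValueError(f"library size must be an integer >= 2, got {self.n!r}")
        if self.labels is not None:
            if len(self.labels) != self.n:
                raise ValueError(
                    f"expected {self.n} labels, got {len(self.labels)}"
                )
            if len(set(self.labels)) != self.n:
                raise ValueError("labels must be unique")

    def label(self, index: int) -> str:
        if self.labels is None:
            return str(index)
        return self.labels[index]


@dataclass
class PoolDesign:
    """A family of candidate-index blocks with its covering parameters."""

    n: int
    k: int
    t: int
    lam: int
    blocks: list[frozenset[int]]

    def __post_init__(self) -> None:
        self.blocks = [frozenset(b) for b in self.blocks]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "t": self.t,
            "lam": self.lam,
            "blocks": [sorted(b) for b in self.blocks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoolDesign":
        return cls(
            n=int(d["n"]),
            k=int(d["k"]),
            t=int(d["t"]),
            lam=int(d["lam"]),
            blocks=[frozenset(int(i) for i in b) for b in d["blocks"]],
        )


@dataclass
class SwapFailure:
    """Returned by :func:`swap_design` when no complete design was found."""

    n: int
    k: int
    t: int
    lam: int
    n_blocks: int
    uncovered_count: int
    best_blocks: list[frozenset[int]] = field(default_factory=list)


def _check_int(name: str, value, minimum: int | None = None) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise ValueError(f"{name} must be an integer, got {value!r}")
    value = int(value)
    if minimum is not None and value < minimum:
        raise ValueError(f"{name} must be >= {minimum}, got {value}")
    return value


def count_combinations(n: int, t: int) -> int:
    """Number of unordered ``t``-subsets of an ``n``-element set, C(n, t)."""
    n = _check_int("n", n, 0)
    t = _check_int("t", t, 0)
    if t > n:
        raise ValueError(f"t must satisfy 0 <= t <= n, got t={t}, n={n}")
    return math.comb(n, t)


def schonheim_bound(n: int, k: int, t: int) -> int:
    """Recursive lower bound on the minimum block count of a covering design.

    ``C(n, k, t) >= ceil((n / k) * C(n - 1, k - 1, t - 1))`` with the base
    case ``C(n, k, 1) = ceil(n / k)``.
    """
    n = _check_int("n", n, 1)
    k = _check_int("k", k, 1)
    t = _check_int("t", t, 1)
    if not (t <= k <= n):
        raise ValueError(f"need t <= k <= n, got n={n}, k={k}, t={t}")
    if t == 1:
        return math.ceil(n / k)
    return math.ceil(n * schonheim_bound(n - 1, k - 1, t - 1) / k)


def verify_cover(design: PoolDesign) -> tuple[bool, list[tuple[int, ...]]]:
    """Certify a design: return ``(ok, uncovered)``.

    ``ok`` is True iff every ``t``-subset of ``{0..n-1}`` is contained in at
    least ``lam`` distinct blocks; ``uncovered`` lists the deficient
    ``t``-subsets (sorted tuples).
    """
    n, t, lam = design.n, design.t, design.lam
    if len(set(design.blocks)) != len(design.blocks):
        raise ValueError("design contains duplicate blocks")
    for b in design.blocks:
        if not all(0 <= i < n for i in b):
            raise ValueError(f"block {sorted(b)} has indices outside 0..{n - 1}")
        if len(b) > design.k:
            raise ValueError(f"block {sorted(b)} exceeds declared size k={design.k}")
    counts: dict[tuple[int, ...], int] = {}
    for b in design.blocks:
        for sub in itertools.combinations(sorted(b), t):
            counts[sub] = counts.get(sub, 0) + 1
    uncovered = [
        sub
        for sub in itertools.combinations(range(n), t)
        if counts.get(sub, 0) < lam
    ]
    return (not uncovered, uncovered)


# ---------------------------------------------------------------------------
# greedy construction


def _greedy_once_pairs(n: int, k: int, lam: int, rng: np.random.Generator) -> list[frozenset[int]]:
    # remaining[i, j]: how many more distinct blocks must still contain {i, j}
    remaining = np.full((n, n), lam, dtype=np.int32)
    np.fill_diagonal(remaining, 0)
    n_uncovered = count_combinations(n, 2) * lam
    blocks: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    def add_member(block: list[int], choice: int) -> int:
        covered = 0
        for m in block:
            if remaining[choice, m] > 0:
                remaining[choice, m] -= 1
                remaining[m, choice] -= 1
                covered += 1
        block.append(choice)
        return covered

    while n_uncovered > 0:
        snapshot = remaining.copy() if lam > 1 else None
        before = n_uncovered
        block: list[int] = []
        in_block = np.zeros(n, dtype=bool)
        while len(block) < k and n_uncovered > 0:
            if block:
                gain = (remaining[:, block] > 0).sum(axis=1)
            else:
                gain = np.zeros(n, dtype=np.int64)
            gain[in_block] = -1
            best = gain.max()
            finalists = np.flatnonzero(gain == best)
            if len(finalists) > 1:
                # stage 2: among max-gain candidates, most uncovered-pair incidence
                incidence = (remaining[finalists] > 0).sum(axis=1)
                finalists = finalists[incidence == incidence.max()]
            # stage 3: uniform random tie-break
            if len(finalists) > 1:
                choice = int(finalists[rng.integers(len(finalists))])
            else:
                choice = int(finalists[0])
            n_uncovered -= add_member(block, choice)
            in_block[choice] = True
        fb = frozenset(block)
        if fb in seen:
            # duplicate block (possible only for lam > 1): undo, then seed a
            # fresh block from a still-uncovered pair and fill randomly
            assert snapshot is not None
            remaining = snapshot.copy()
            n_uncovered = before
            placed = False
            for _attempt in range(200):
                ij = np.argwhere(np.triu(remaining, 1) > 0)
                a, b = (int(v) for v in ij[rng.integers(len(ij))])
                block = [a]
                add_count = add_member(block, b)
                n_uncovered -= add_count
                while len(block) < k:
                    pool = [c for c in range(n) if c not in block]
                    n_uncovered -= add_member(block, int(pool[rng.integers(len(pool))]))
                fb = frozenset(block)
                if fb not in seen:
                    placed = True
                    break
                remaining = snapshot.copy()
                n_uncovered = before
            if not placed:
                raise ValueError(
                    f"cannot reach coverage multiplicity lam={lam} without "
                    f"duplicate blocks for n={n}, k={k}"
                )
        blocks.append(fb)
        seen.add(fb)
    return blocks


def _coverage_counts(blocks: Iterable[frozenset[int]], t: int) -> dict[tuple[int, ...], int]:
    counts: dict[tuple[int, ...], int] = {}
    for b in blocks:
        for sub in itertools.combinations(sorted(b), t):
            counts[sub] = counts.get(sub, 0) + 1
    return counts


def _greedy_once_generic(
    n: int, k: int, t: int, lam: int, rng: np.random.Generator
) -> list[frozenset[int]]:
    # dict-based path for t >= 3; only exercised at small n
    remaining: dict[tuple[int, ...], int] = {
        sub: lam for sub in itertools.combinations(range(n), t)
    }
    n_uncovered = len(remaining) * lam
    blocks: list[frozenset[int]] = []

    def incidence(c: int) -> int:
        return sum(1 for sub, r in remaining.items() if r > 0 and c in sub)

    seen: set[frozenset[int]] = set()

    def cover(block: Sequence[int], choice: int, log: list) -> int:
        covered = 0
        if len(block) >= t - 1:
            for combo in itertools.combinations(sorted(block), t - 1):
                sub = tuple(sorted(combo + (choice,)))
                if remaining.get(sub, 0) > 0:
                    remaining[sub] -= 1
                    log.append(sub)
                    covered += 1
        return covered

    while n_uncovered > 0:
        block: list[int] = []
        log: list[tuple[int, ...]] = []
        while len(block) < k and n_uncovered > 0:
            gains = np.full(n, -1, dtype=np.int64)
            for c in range(n):
                if c in block:
                    continue
                g = 0
                if len(block) >= t - 1:
                    for combo in itertools.combinations(sorted(block), t - 1):
                        if c in combo:
                            continue
                        sub = tuple(sorted(combo + (c,)))
                        if remaining.get(sub, 0) > 0:
                            g += 1
                gains[c] = g
            best = gains.max()
            finalists = np.flatnonzero(gains == best)
            if len(finalists) > 1:
                inc = np.array([incidence(int(c)) for c in finalists])
                finalists = finalists[inc == inc.max()]
            if len(finalists) > 1:
                choice = int(finalists[rng.integers(len(finalists))])
            else:
                choice = int(finalists[0])
            n_uncovered -= cover(block, choice, log)
            block.append(choice)
        fb = frozenset(block)
        if not log or fb in seen:
            # stalled (t - 1 leading members complete no uncovered subset) or
            # duplicate block: undo, then seed from an uncovered t-subset
            for sub in log:
                remaining[sub] += 1
                n_uncovered += 1
            uncov = [sub for sub, r in remaining.items() if r > 0]
            seed_sub = uncov[int(rng.integers(len(uncov)))]
            block = list(seed_sub)
            log = []
            n_uncovered -= cover(block[:-1], block[-1], log)
            while len(block) < k:
                pool = [c for c in range(n) if c not in block]
                choice = pool[int(rng.integers(len(pool)))]
                n_uncovered -= cover(block, choice, log)
                block.append(choice)
            fb = frozenset(block)
            if fb in seen:
                raise ValueError(
                    f"cannot reach coverage multiplicity lam={lam} without "
                    f"duplicate blocks for n={n}, k={k}, t={t}"
                )
        blocks.append(fb)
        seen.add(fb)
    return blocks


def greedy_design(
    n: int,
    k: int,
    t: int = 2,
    lam: int = 1,
    restarts: int = 1000,
    seed: int | None = None,
) -> PoolDesign:
    """Build a covering design by randomized greedy construction.

    Each block position is filled by a three-stage rule: (1) keep the
    candidates whose addition covers the most still-uncovered ``t``-subsets,
    (2) among those, keep the candidates contained in the most uncovered
    ``t``-subsets overall, (3) pick uniformly at random among the remaining
    finalists.  Blocks are appended until every ``t``-subset is covered
    ``lam`` times; the final block may be shorter than ``k``.  The smallest
    design over ``restarts`` independent runs is returned (ties broken by
    first found).

    Parameters
    ----------
    n, k, t, lam
        Covering-design parameters: library size, maximum block size,
        coverage order (2 = pairs, 3 = triples), coverage multiplicity.
    restarts
        Number of independent greedy runs.
    seed
        Seed for the tie-break RNG; identical arguments give identical
        designs.
    """
    n = _check_int("n", n, 1)
    k = _check_int("k", k, 1)
    t = _check_int("t", t, 2)
    lam = _check_int("lam", lam, 1)
    restarts = _check_int("restarts", restarts, 1)
    if not (t <= k <= n):
        raise ValueError(f"need t <= k <= n, got n={n}, k={k}, t={t}")

    rng = np.random.default_rng(seed)
    best: list[frozenset[int]] | None = None
    for _ in range(restarts):
        if t == 2:
            blocks = _greedy_once_pairs(n, k, lam, rng)
        else:
            blocks = _greedy_once_generic(n, k, t, lam, rng)
        if best is None or len(blocks) < len(best):
            best = blocks
        if len(best) == schonheim_bound(n, k, t) and lam == 1:
            break
    assert best is not None
    design = PoolDesign(n=n, k=k, t=t, lam=lam, blocks=best)
    ok, uncovered = verify_cover(design)
    if not ok:  # pragma: no cover - construction guarantees coverage
        raise RuntimeError(f"greedy construction left {len(uncovered)} uncovered")
    return design


# ---------------------------------------------------------------------------
# swap local search


def _random_blocks(
    n: int, k: int, n_blocks: int, rng: np.random.Generator
) -> list[frozenset[int]]:
    blocks: set[frozenset[int]] = set()
    while len(blocks) < n_blocks:
        blocks.add(frozenset(int(i) for i in rng.choice(n, size=k, replace=False)))
    return list(blocks)


def _objective(blocks: Sequence[frozenset[int]], t: int, lam: int) -> int:
    counts = _coverage_counts(blocks, t)
    return sum(min(c, lam) for c in counts.values())


def swap_design(
    n: int,
    k: int,
    t: int = 2,
    lam: int = 1,
    n_blocks: int | None = None,
    max_iters: int = 2000,
    seed: int | None = None,
    restarts: int = 20,
) -> PoolDesign | SwapFailure:
    """Search for a covering design of exactly ``n_blocks`` size-``k`` blocks.

    Hill climbing on the total number of covered ``t``-subsets (counted up
    to multiplicity ``lam``): starting from distinct random blocks, the best
    strictly improving single-element swap is applied until coverage is
    complete or no swap improves; stalled runs restart from a fresh random
    family, up to ``restarts`` times.  When ``n_blocks`` is None the minimum
    feasible size is searched by bisection between the Schönheim bound and
    the greedy solution size.

    Returns a :class:`PoolDesign` on success, else a :class:`SwapFailure`
    carrying the remaining uncovered count of the best family seen.
    """
    n = _check_int("n", n, 1)
    k = _check_int("k", k, 1)
    t = _check_int("t", t, 2)
    lam = _check_int("lam", lam, 1)
    max_iters = _check_int("max_iters", max_iters, 1)
    if not (t <= k <= n):
        raise ValueError(f"need t <= k <= n, got n={n}, k={k}, t={t}")

    if n_blocks is None:
        lo = schonheim_bound(n, k, t)
        hi = greedy_design(n, k, t, lam, restarts=20, seed=seed).n_blocks
        best_design: PoolDesign | SwapFailure | None = None
        while lo < hi:
            mid = (lo + hi) // 2
            attempt = swap_design(n, k, t, lam, mid, max_iters, seed, restarts)
            if isinstance(attempt, PoolDesign):
                best_design, hi = attempt, mid
            else:
                lo = mid + 1
        if best_design is None:
            best_design = swap_design(n, k, t, lam, hi, max_iters, seed, restarts)
        return best_design

    n_blocks = _check_int("n_blocks", n_blocks, 1)
    target = count_combinations(n, t) * lam
    rng = np.random.default_rng(seed)
    best_score = -1
    best_blocks: list[frozenset[int]] = []

    for _ in range(max(1, restarts)):
        blocks = _random_blocks(n, k, n_blocks, rng)
        score = _objective(blocks, t, lam)
        for _ in range(max_iters):
            if score == target:
                break
            improving: list[tuple[int, int, int, int]] = []  # (score, bi, out, inn)
            block_set = set(blocks)
            for bi, block in enumerate(blocks):
                others = blocks[:bi] + blocks[bi + 1 :]
                base = _objective(others, t, lam)
                for out in block:
                    for inn in range(n):
                        if inn in block:
                            continue
                        cand = block - {out} | {inn}
                        if cand in block_set:
                            continue
                        cand_score = base + _marginal(cand, others, t, lam)
                        if cand_score > score:
                            improving.append((cand_score, bi, out, inn))
            if not improving:
                break
            top = max(s for s, *_ in improving)
            choices = [x for x in improving if x[0] == top]
            _, bi, out, inn = choices[int(rng.integers(len(choices)))]
            blocks[bi] = blocks[bi] - {out} | {inn}
            score = top
        if score > best_score:
            best_score, best_blocks = score, list(blocks)
        if best_score == target:
            break

    if best_score == target:
        design = PoolDesign(n=n, k=k, t=t, lam=lam, blocks=best_blocks)
        ok, _ = verify_cover(design)
        assert ok
        return design
    return SwapFailure(
        n=n,
        k=k,
        t=t,
        lam=lam,
        n_blocks=n_blocks,
        uncovered_count=target - best_score,
        best_blocks=best_blocks,
    )


def _marginal(block: frozenset[int], others: Sequence[frozenset[int]], t: int, lam: int) -> int:
    counts = _coverage_counts(others, t)
    gain = 0
    for sub in itertools.combinations(sorted(block), t):
        if counts.get(sub, 0) < lam:
            gain += 1
    return gain
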