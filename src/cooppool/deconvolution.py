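"""Deconvolution of positive pooled groups into active entities.

Two strategies are implemented:

* **Iterative sectioning** — a generalization of interval bisection: a
  positive set of size ``k`` is split into three overlapping subsets of
  size ``ceil(2k/3)`` built from a tripartition (each subset is the union
  of two parts), so that every pair of the parent lies in at least one
  subset.  Positive subsets are recursively subdivided until a pair is
  reached.  Logical implication from previous answers prunes redundant
  queries, and knowledge can be shared across groups.

* **One-step signature decoding** — a fixed family of subsets of the
  group chosen so that every pair has a distinct, non-empty pattern of
  containing subsets; a single round of subset measurements then
  identifies a lone active pair by its signature.

The oracle is an arbitrary ``set -> bool`` callback (an experiment, a
simulation, or a recorded outcome log).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "DeconvNode",
    "DeconvResult",
    "SignatureDesign",
    "AmbiguousDecode",
    "Knowledge",
    "schedule",
    "make_children",
    "run_iterative",
    "onestep_design",
    "onestep_decode",
    "expected_tests",
]

Pair = tuple[int, int]
Triple = tuple[int, int, int]


def schedule(k0: int) -> list[int]:
    """Subset-size cascade below a root group of size ``k0``.

    Sizes follow ``k_i = ceil(2 * k_{i-1} / 3)`` starting from the root
    size, stopping at 2 (a pair).  The root size itself is not included.

    >>> schedule(10)
    [7, 5, 4, 3, 2]
    """
    if not isinstance(k0, int) or isinstance(k0, bool) or k0 < 2:
        raise ValueError(f"k0 must be an integer >= 2, got {k0!r}")
    sizes: list[int] = []
    k = k0
    while k > 2:
        k = math.ceil(2 * k / 3)
        sizes.append(k)
    return sizes


def make_children(
    parent: Iterable[int], child_size: int, seed: int | None = None
) -> tuple[frozenset[int], frozenset[int], frozenset[int]]:
    """Split ``parent`` into three overlapping subsets covering all its pairs.

    The parent is tripartitioned into near-equal parts A, B, C (sizes
    differing by at most one); the children are the unions A∪B, B∪C and
    A∪C.  Any two parent members share a child, so every pair of the
    parent is contained in at least one child.  Each child has at most
    ``ceil(2|parent|/3)`` members, hence ``child_size`` must be at least
    that.
    """
    members = sorted(set(parent))
    p = len(members)
    if p < 3:
        raise ValueError(f"parent must have at least 3 members, got {p}")
    min_size = math.ceil(2 * p / 3)
    if not (2 <= child_size < p):
        raise ValueError(f"need 2 <= child_size < |parent|, got {child_size} vs {p}")
    if child_size < min_size:
        raise ValueError(
            f"child_size={child_size} below feasibility bound ceil(2*{p}/3)={min_size}"
        )
    rng = np.random.default_rng(seed)
    base, rem = divmod(p, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    rng.shuffle(sizes)
    cuts = np.cumsum(sizes)[:-1]
    parts = [frozenset(int(v) for v in x) for x in np.split(np.array(members), cuts)]
    order = rng.permutation(3)
    a, b, c = (parts[i] for i in order)
    return (frozenset(a | b), frozenset(b | c), frozenset(a | c))


# ---------------------------------------------------------------------------
# knowledge base shared by iterative runs


class Knowledge:
    """Confirmed and excluded entities accumulated across oracle queries.

    Pairs are always tracked; singletons and triples only when the
    corresponding detection flag is on.  A negative test of a set excludes
    every tracked entity fully contained in it.  Entities containing an
    already-confirmed smaller entity are *masked*: the assay cannot decide
    them, so they count as decided for exploration purposes.
    """

    def __init__(self, detect_singletons: bool = False, detect_triples: bool = False):
        self.detect_singletons = detect_singletons
        self.detect_triples = detect_triples
        self.confirmed_pairs: set[Pair] = set()
        self.confirmed_singletons: set[int] = set()
        self.confirmed_triples: set[Triple] = set()
        self.excluded_pairs: set[Pair] = set()
        self.excluded_singletons: set[int] = set()
        self.excluded_triples: set[Triple] = set()

    # -- entity bookkeeping -------------------------------------------------

    def exclude_set(self, members: frozenset[int]) -> None:
        """Record a negative test: every tracked entity inside is inactive."""
        s = sorted(members)
        self.excluded_pairs.update(itertools.combinations(s, 2))
        if self.detect_singletons:
            self.excluded_singletons.update(s)
        if self.detect_triples:
            self.excluded_triples.update(itertools.combinations(s, 3))

    def confirm_pair(self, a: int, b: int) -> None:
        self.confirmed_pairs.add((a, b) if a < b else (b, a))

    def confirm_singleton(self, a: int) -> None:
        self.confirmed_singletons.add(a)

    def confirm_triple(self, t: Sequence[int]) -> None:
        self.confirmed_triples.add(tuple(sorted(t)))

    # -- decision predicates ------------------------------------------------

    def pair_decided(self, p: Pair) -> bool:
        if p in self.confirmed_pairs or p in self.excluded_pairs:
            return True
        if self.detect_singletons and (
            p[0] in self.confirmed_singletons or p[1] in self.confirmed_singletons
        ):
            return True  # masked by a confirmed singleton
        return False

    def singleton_decided(self, a: int) -> bool:
        return a in self.confirmed_singletons or a in self.excluded_singletons

    def triple_decided(self, t: Triple) -> bool:
        if t in self.confirmed_triples or t in self.excluded_triples:
            return True
        for p in itertools.combinations(t, 2):
            if p in self.confirmed_pairs:
                return True  # masked by a confirmed pair
        if self.detect_singletons and any(a in self.confirmed_singletons for a in t):
            return True
        return False

    def undecided_entities(self, members: frozenset[int]) -> Iterator[tuple[int, ...]]:
        s = sorted(members)
        if self.detect_singletons:
            for a in s:
                if not self.singleton_decided(a):
                    yield (a,)
        for p in itertools.combinations(s, 2):
            if not self.pair_decided(p):
                yield p
        if self.detect_triples:
            for t in itertools.combinations(s, 3):
                if not self.triple_decided(t):
                    yield t

    def all_decided(self, members: frozenset[int]) -> bool:
        return next(self.undecided_entities(members), None) is None

    def contains_confirmed(self, members: frozenset[int]) -> bool:
        for p in self.confirmed_pairs:
            if p[0] in members and p[1] in members:
                return True
        if self.confirmed_singletons & members:
            return True
        for t in self.confirmed_triples:
            if members.issuperset(t):
                return True
        return False

    def undecided_within(self, parent: frozenset[int], child: frozenset[int]) -> bool:
        """True iff every undecided entity of ``parent`` lies inside ``child``."""
        for ent in self.undecided_entities(parent):
            if not child.issuperset(ent):
                return False
        return True


# ---------------------------------------------------------------------------
# iterative sectioning


@dataclass
class DeconvNode:
    """A node of the sectioning tree, kept for reporting and session logs."""

    members: frozenset[int]
    level: int
    status: str = "untested"  # tested-positive/-negative, implied-..., pruned
    children: list["DeconvNode"] = field(default_factory=list)


@dataclass
class DeconvResult:
    """Outcome of a deconvolution run on one positive group."""

    active_pairs: set[Pair]
    active_singletons: set[int]
    active_triples: set[Triple]
    unresolved: list[frozenset[int]]
    tests_used: int
    root: DeconvNode | None = None
    log: list[dict] = field(default_factory=list)


class _Stop(Exception):
    """Raised to unwind exploration once find_all is off and a hit is found."""


def run_iterative(
    group: Iterable[int],
    oracle: Callable[[frozenset[int]], bool],
    find_all: bool = False,
    detect_singletons: bool = False,
    detect_triples: bool = False,
    seed: int | None = None,
    knowledge: Knowledge | None = None,
    root_known_positive: bool = False,
    prune: bool = True,
) -> DeconvResult:
    """Resolve a positive group into active pairs/singletons/triples.

    The group is explored depth-first along the ``ceil(2k/3)`` sectioning
    cascade.  With ``prune`` on (default), sets whose outcome is logically
    implied by previous answers are not queried: a set containing a
    confirmed entity is implied-positive, a set all of whose entities have
    been excluded is implied-negative, and the last undecided child of a
    positive parent is implied-positive once its siblings have excluded
    everything else.  ``tests_used`` counts real oracle invocations only.

    With ``find_all`` the exploration continues until every tracked entity
    of the group is either confirmed or excluded; otherwise it stops at the
    first confirmed entity.  ``knowledge`` may carry state from previous
    groups so cross-group implication prunes repeated work.
    ``root_known_positive`` skips the initial query of the whole group
    (e.g. when it was already measured during the pooled screen).
    """
    members = frozenset(int(i) for i in group)
    if len(members) < 2:
        raise ValueError("group must have at least 2 members")
    know = knowledge if knowledge is not None else Knowledge(detect_singletons, detect_triples)
    know.detect_singletons = detect_singletons
    know.detect_triples = detect_triples
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    tests = 0
    pre_pairs = set(know.confirmed_pairs)
    pre_singles = set(know.confirmed_singletons)
    pre_triples = set(know.confirmed_triples)
    unresolved: list[frozenset[int]] = []

    def query(node: DeconvNode, force: bool = False) -> bool:
        nonlocal tests
        s = node.members
        if prune and not force:
            if know.contains_confirmed(s):
                node.status = "implied-positive"
                log.append({"set": sorted(s), "result": "+", "level": node.level, "implied": True})
                return True
            if know.all_decided(s):
                node.status = "implied-negative"
                log.append({"set": sorted(s), "result": "-", "level": node.level, "implied": True})
                return False
        try:
            ans = bool(oracle(s))
        except Exception:
            log.append({"set": sorted(s), "result": "aborted", "level": node.level, "implied": False})
            raise
        tests += 1
        log.append({"set": sorted(s), "result": "+" if ans else "-", "level": node.level, "implied": False})
        node.status = "tested-positive" if ans else "tested-negative"
        if not ans:
            know.exclude_set(s)
        return ans

    def found_hit() -> None:
        if not find_all:
            raise _Stop

    def handle_leaf(node: DeconvNode) -> None:
        # node is a positive pair
        a, b = sorted(node.members)
        if detect_singletons:
            na = DeconvNode(frozenset([a]), node.level + 1)
            nb = DeconvNode(frozenset([b]), node.level + 1)
            node.children += [na, nb]
            singles = []
            if know.singleton_decided(a):
                ra = a in know.confirmed_singletons
                na.status = "implied-positive" if ra else "implied-negative"
            else:
                ra = query(na)
                if ra:
                    know.confirm_singleton(a)
                else:
                    know.excluded_singletons.add(a)
            if know.singleton_decided(b):
                rb = b in know.confirmed_singletons
                nb.status = "implied-positive" if rb else "implied-negative"
            else:
                rb = query(nb)
                if rb:
                    know.confirm_singleton(b)
                else:
                    know.excluded_singletons.add(b)
            if ra or rb:
                found_hit()
                return
        know.confirm_pair(a, b)
        found_hit()

    def test_entity(ent: tuple[int, ...], parent: DeconvNode) -> None:
        """Directly query one undecided entity (pair, singleton or triple)."""
        es = frozenset(ent)
        en = DeconvNode(es, parent.level + 1)
        parent.children.append(en)
        if (
            prune
            and parent.status != "untested"
            and not know.contains_confirmed(parent.members)
            and know.undecided_within(parent.members, es)
        ):
            # the only remaining explanation of the positive parent
            en.status = "implied-positive"
            log.append({"set": sorted(es), "result": "+", "level": en.level, "implied": True})
            positive = True
        else:
            positive = query(en)
        if len(ent) == 1:
            if positive:
                know.confirm_singleton(ent[0])
                found_hit()
            else:
                know.excluded_singletons.add(ent[0])
        elif len(ent) == 2:
            if positive:
                handle_leaf(en)
            # negative query already excluded the pair
        else:
            if positive:
                know.confirm_triple(ent)
                found_hit()
            else:
                know.excluded_triples.add(tuple(sorted(ent)))

    def resolve(node: DeconvNode) -> None:
        """Explore a set known to be positive until its entities are decided."""
        s = node.members
        if len(s) == 2:
            handle_leaf(node)
            return
        if prune:
            # members no longer involved in any undecided entity cannot teach
            # us anything: shrink exploration to the involved subset
            involved: set[int] = set()
            for ent in know.undecided_entities(s):
                involved.update(ent)
            if len(involved) < len(s) and len(involved) >= 2:
                sub = DeconvNode(frozenset(involved), node.level + 1)
                node.children.append(sub)
                if not know.contains_confirmed(s):
                    # all undecided entities lie inside: implied positive
                    sub.status = "implied-positive"
                    log.append({"set": sorted(sub.members), "result": "+",
                                "level": sub.level, "implied": True})
                    resolve(sub)
                elif query(sub):
                    resolve(sub)
                if (
                    node.status in ("tested-positive", "known-positive")
                    and not know.contains_confirmed(s)
                    and know.all_decided(s)
                ):
                    unresolved.append(s)
                return
            # few enough undecided entities left: test them directly instead
            # of sectioning further
            undec = list(itertools.islice(know.undecided_entities(s), 5))
            if len(undec) <= 4:
                for ent in undec:
                    if len(ent) == 1 and know.singleton_decided(ent[0]):
                        continue
                    if len(ent) == 2 and know.pair_decided(ent):
                        continue
                    if len(ent) == 3 and know.triple_decided(ent):
                        continue
                    test_entity(ent, node)
                if (
                    node.status in ("tested-positive", "known-positive")
                    and not know.contains_confirmed(s)
                    and know.all_decided(s)
                ):
                    unresolved.append(s)
                return
        child_size = math.ceil(2 * len(s) / 3)
        kids = make_children(s, child_size, seed=int(rng.integers(2**31)))
        nodes = [DeconvNode(frozenset(kid), node.level + 1) for kid in kids]
        node.children += nodes
        order = list(rng.permutation(3))
        if prune:
            # query lighter children first: their negatives are cheap
            # exclusions and often leave the heaviest child implied-positive
            load = {
                idx: sum(1 for _ in itertools.islice(
                    know.undecided_entities(nodes[idx].members), 64))
                for idx in order
            }
            order.sort(key=lambda idx: load[idx])
        positives: list[DeconvNode] = []
        for idx in order:
            child = nodes[idx]
            if prune and know.all_decided(child.members):
                child.status = "pruned"
                continue
            if (
                prune
                and not know.contains_confirmed(s)
                and know.undecided_within(s, child.members)
            ):
                # the parent is positive and can only be explained by an
                # entity inside this child: implied positive, no query needed
                child.status = "implied-positive"
                log.append({"set": sorted(child.members), "result": "+",
                            "level": child.level, "implied": True})
                if find_all:
                    positives.append(child)
                else:
                    resolve(child)
                continue
            if query(child):
                if find_all:
                    positives.append(child)
                else:
                    resolve(child)
        # with find_all the whole level is measured before recursing, so
        # negative siblings prune inside the positive subtrees
        for child in positives:
            if prune and know.all_decided(child.members):
                continue
            resolve(child)
        if detect_triples:
            # triples spanning all three parts lie in no child; test directly
            for t in itertools.combinations(sorted(s), 3):
                if know.triple_decided(t):
                    continue
                ts = frozenset(t)
                if any(ts.issubset(c.members) for c in nodes):
                    continue
                tn = DeconvNode(ts, node.level + 1)
                node.children.append(tn)
                if query(tn):
                    know.confirm_triple(t)
                    found_hit()
                else:
                    know.excluded_triples.add(t)
        if (
            node.status in ("tested-positive", "known-positive")
            and not know.contains_confirmed(s)
            and know.all_decided(s)
        ):
            unresolved.append(s)

    root = DeconvNode(members, 0)
    try:
        if root_known_positive:
            root.status = "known-positive"
            resolve(root)
        else:
            if query(root):
                resolve(root)
    except _Stop:
        pass

    return DeconvResult(
        active_pairs={p for p in know.confirmed_pairs if members.issuperset(p)},
        active_singletons={a for a in know.confirmed_singletons if a in members},
        active_triples={t for t in know.confirmed_triples if members.issuperset(t)},
        unresolved=unresolved,
        tests_used=tests,
        root=root,
        log=log,
    )


def expected_tests(
    k0: int, n_sim: int = 500, seed: int | None = None
) -> float:
    """Monte-Carlo mean number of oracle calls to find one planted pair.

    A single active pair is placed uniformly in a group of size ``k0`` and
    :func:`run_iterative` is run with a noiseless membership oracle
    (``find_all`` off, no singleton disambiguation).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    group = frozenset(range(k0))
    total = 0
    for _ in range(n_sim):
        pair = frozenset(int(i) for i in rng.choice(k0, size=2, replace=False))
        oracle = lambda s, pair=pair: pair.issubset(s)
        res = run_iterative(group, oracle, find_all=False, seed=int(rng.integers(2**31)))
        total += res.tests_used
    return total / n_sim


# ---------------------------------------------------------------------------
# one-step (non-adaptive) signature deconvolution


@dataclass
class SignatureDesign:
    """Fixed subsets of a group with the pair -> positive-pattern map."""

    group_size: int
    subsets: list[frozenset[int]]
    signature_map: dict[Pair, frozenset[int]]

    def signature(self, a: int, b: int) -> frozenset[int]:
        return self.signature_map[(a, b) if a < b else (b, a)]

    def to_dict(self) -> dict:
        return {
            "group_size": self.group_size,
            "subsets": [sorted(s) for s in self.subsets],
        }

    @classmethod
    def from_subsets(
        cls, group_size: int, subsets: Sequence[Iterable[int]]
    ) -> "SignatureDesign":
        subs = [frozenset(int(i) for i in s) for s in subsets]
        sig = {
            p: frozenset(i for i, s in enumerate(subs) if s.issuperset(p))
            for p in itertools.combinations(range(group_size), 2)
        }
        return cls(group_size=group_size, subsets=subs, signature_map=sig)


@dataclass
class AmbiguousDecode:
    """Decoder output when no single pair's signature matches the pattern."""

    observed: frozenset[int]
    pair_explanations: list[frozenset[Pair]]
    singleton_explanations: list[int]

    @property
    def no_active_pair(self) -> bool:
        return not self.observed


def onestep_design(
    group_size: int,
    n_subsets: int = 8,
    subset_size: int = 7,
    seed: int | None = None,
    max_tries: int = 20000,
) -> SignatureDesign:
    """Search for subsets giving every pair a unique non-empty signature.

    Uniform random families of ``n_subsets`` subsets of size
    ``subset_size`` are drawn until one has all-distinct, non-empty pair
    signatures.  Raises if the parameters are provably infeasible (fewer
    non-empty subset patterns than pairs) or if ``max_tries`` random
    families all fail.
    """
    if subset_size >= group_size:
        raise ValueError("subset_size must be smaller than group_size")
    if subset_size < 2 or n_subsets < 1:
        raise ValueError("need subset_size >= 2 and n_subsets >= 1")
    n_pairs = math.comb(group_size, 2)
    if 2**n_subsets - 1 < n_pairs:
        raise ValueError(
            f"infeasible: {2**n_subsets - 1} non-empty patterns over "
            f"{n_subsets} subsets cannot distinguish {n_pairs} pairs"
        )
    rng = np.random.default_rng(seed)
    pair_idx = list(itertools.combinations(range(group_size), 2))
    for _ in range(max_tries):
        rows = [rng.choice(group_size, size=subset_size, replace=False) for _ in range(n_subsets)]
        # per-element bitmask over subsets; pair signature = AND of member masks
        masks = [0] * group_size
        for i, row in enumerate(rows):
            bit = 1 << i
            for e in row:
                masks[e] |= bit
        sigs = [masks[a] & masks[b] for a, b in pair_idx]
        if all(sigs) and len(set(sigs)) == len(sigs):
            return SignatureDesign.from_subsets(
                group_size, [frozenset(int(i) for i in row) for row in rows]
            )
    raise RuntimeError(
        f"no valid signature design found in {max_tries} tries for "
        f"group_size={group_size}, n_subsets={n_subsets}, subset_size={subset_size}"
    )


def onestep_decode(
    design: SignatureDesign,
    positive_subsets: Iterable[int],
    max_explanation_size: int = 3,
) -> Pair | AmbiguousDecode:
    """Invert a positive-subset pattern to an active pair, or explain it.

    An exact signature match returns the unique pair.  Otherwise an
    :class:`AmbiguousDecode` is returned listing (a) every set of up to
    ``max_explanation_size`` pairs whose signature union equals the
    observation (multi-hit hypotheses) and (b) every single candidate whose
    subset-membership pattern equals it (single-quencher hypotheses).
    """
    observed = frozenset(int(i) for i in positive_subsets)
    if not observed <= set(range(len(design.subsets))):
        raise ValueError("positive_subsets contains unknown subset indices")
    inverse = {sig: p for p, sig in design.signature_map.items()}
    if observed in inverse:
        return inverse[observed]

    # only pairs whose signature is contained in the observation can be active
    candidates = [
        p for p, sig in design.signature_map.items() if sig and sig <= observed
    ]
    pair_explanations: list[frozenset[Pair]] = []
    for r in range(2, max_explanation_size + 1):
        for combo in itertools.combinations(candidates, r):
            union: frozenset[int] = frozenset().union(*(design.signature_map[p] for p in combo))
            if union == observed:
                pair_explanations.append(frozenset(combo))
    singleton_explanations = [
        a
        for a in range(design.group_size)
        if frozenset(i for i, s in enumerate(design.subsets) if a in s) == observed
    ]
    return AmbiguousDecode(
        observed=observed,
        pair_explanations=pair_explanations,
        singleton_explanations=singleton_explanations,
    )
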