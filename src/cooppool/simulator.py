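"""End-to-end synthetic screening campaigns.

Plants cooperative entities in a library, builds a covering design, screens
every pool through the quenching model, deconvolves the positive pools with
the chosen strategy, and reports experiment counts and recovery metrics.
Three strategies are compared: adaptive iterative sectioning, non-adaptive
one-step signature decoding (with direct follow-up tests when the pattern
is ambiguous), and exhaustive parallel testing of all pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assay_model import QuenchModel, Readout, combined_background
from .deconvolution import Knowledge, Pair, Triple, onestep_design, run_iterative
from .pool_design import PoolDesign, count_combinations, greedy_design

__all__ = [
    "GroundTruth",
    "CampaignResult",
    "sample_truth",
    "screen_set",
    "run_campaign",
    "summarize",
]


@dataclass
class GroundTruth:
    """Planted active entities of a synthetic library."""

    n: int
    active_pairs: set[Pair] = field(default_factory=set)
    active_singletons: set[int] = field(default_factory=set)
    active_triples: set[Triple] = field(default_factory=set)
    quench_fraction: float = 1.0
    ksv: np.ndarray | None = None  # per-compound background Stern-Volmer products

    def __post_init__(self) -> None:
        universe = range(self.n)
        for p in self.active_pairs:
            if not all(i in universe for i in p):
                raise ValueError(f"pair {p} outside library of size {self.n}")
        for t in self.active_triples:
            if not all(i in universe for i in t):
                raise ValueError(f"triple {t} outside library of size {self.n}")
        if not all(a in universe for a in self.active_singletons):
            raise ValueError("singleton outside library")

    def entities(self) -> list[tuple[int, ...]]:
        return (
            [(a,) for a in sorted(self.active_singletons)]
            + sorted(self.active_pairs)
            + sorted(self.active_triples)
        )

    def active_in(self, members: frozenset[int]) -> bool:
        return any(members.issuperset(e) for e in self.entities())


@dataclass
class CampaignResult:
    """Counts and recovery sets of one simulated campaign."""

    strategy: str
    design_tests: int
    deconv_tests: int
    recovered_pairs: set[Pair]
    recovered_singletons: set[int]
    false_negatives: set[Pair]
    false_positives: set[Pair]
    unresolved: list[list[int]]
    group_log: list[dict] = field(default_factory=list)

    @property
    def total_tests(self) -> int:
        return self.design_tests + self.deconv_tests

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "design_tests": self.design_tests,
            "deconv_tests": self.deconv_tests,
            "total_tests": self.total_tests,
            "recovered_pairs": sorted(map(list, self.recovered_pairs)),
            "recovered_singletons": sorted(self.recovered_singletons),
            "false_negatives": sorted(map(list, self.false_negatives)),
            "false_positives": sorted(map(list, self.false_positives)),
            "unresolved": self.unresolved,
            "group_log": self.group_log,
        }


def sample_truth(
    n: int,
    n_pairs: int,
    n_singletons: int = 0,
    n_triples: int = 0,
    hub_bias: float = 0.0,
    seed: int | None = None,
    quench_fraction: float = 1.0,
    model: QuenchModel | None = None,
) -> GroundTruth:
    """Plant random active entities in a library of size ``n``.

    At ``hub_bias = 0`` pairs are sampled uniformly without replacement.
    At ``hub_bias > 0`` each pair includes, with that probability, a member
    of a small privileged hub set (three compounds), mimicking libraries in
    which a few compounds dominate cooperativity.  Per-compound background
    Stern-Volmer products are drawn from ``model`` when given.
    """
    if not (0.0 <= hub_bias <= 1.0):
        raise ValueError("hub_bias must be in [0, 1]")
    if n_pairs > count_combinations(n, 2):
        raise ValueError("more pairs requested than exist")
    if n_singletons > n or n_triples > count_combinations(n, 3):
        raise ValueError("infeasible entity counts")
    rng = np.random.default_rng(seed)
    hubs = [int(i) for i in rng.choice(n, size=min(3, n), replace=False)]
    pairs: set[Pair] = set()
    while len(pairs) < n_pairs:
        if hub_bias > 0 and rng.random() < hub_bias:
            a = hubs[int(rng.integers(len(hubs)))]
            b = int(rng.integers(n))
        else:
            a, b = (int(i) for i in rng.choice(n, size=2, replace=False))
        if a == b:
            continue
        pairs.add((a, b) if a < b else (b, a))
    in_pairs = {i for p in pairs for i in p}
    free = [i for i in range(n) if i not in in_pairs]
    if len(free) < n_singletons:
        raise ValueError("not enough candidates left for singletons")
    singles = {int(i) for i in rng.choice(free, size=n_singletons, replace=False)} if n_singletons else set()
    triples: set[Triple] = set()
    while len(triples) < n_triples:
        t = tuple(sorted(int(i) for i in rng.choice(n, size=3, replace=False)))
        triples.add(t)
    ksv = model.sample_ksv(n, rng) if model is not None else None
    return GroundTruth(
        n=n,
        active_pairs=pairs,
        active_singletons=singles,
        active_triples=triples,
        quench_fraction=quench_fraction,
        ksv=ksv,
    )


def screen_set(
    members: Iterable[int],
    truth: GroundTruth,
    model: QuenchModel,
    seed: int | None = None,
    set_id: str = "",
    rng: np.random.Generator | None = None,
) -> Readout:
    """Simulate one pooled measurement of ``members``.

    The background comes from the per-compound Stern-Volmer products of
    the members (zero when the truth carries none); if any planted entity
    lies fully inside the set, a further ``quench_fraction`` of the
    remaining emission is removed.  Additive Gaussian readout noise is then
    applied and the result clipped to [0, 100].
    """
    mem = frozenset(int(i) for i in members)
    if not all(0 <= i < truth.n for i in mem):
        raise ValueError("members outside library")
    if rng is None:
        rng = np.random.default_rng(seed)
    if truth.ksv is not None and len(mem):
        background = combined_background(truth.ksv[sorted(mem)])
    else:
        background = 0.0
    active = truth.quench_fraction if truth.active_in(mem) else 0.0
    quench = 100.0 * (1.0 - (1.0 - active) * (1.0 - background / 100.0))
    if model.readout_noise_sd > 0:
        quench += float(rng.normal(0.0, model.readout_noise_sd))
    quench = float(np.clip(quench, 0.0, 100.0))
    return Readout(set_id=set_id, quench_percent=quench, call=model.call(quench))


def _onestep_deconvolve(
    group: frozenset[int],
    oracle,
    know: Knowledge,
    rng: np.random.Generator,
    design_cache: dict | None = None,
) -> tuple[int, list[frozenset[int]]]:
    """One-step signature decoding of a positive group, with follow-ups.

    The group's subsets are measured in one round; negative subsets exclude
    their pairs.  If exactly one undecided pair remains consistent with the
    observed pattern it is confirmed without further tests; otherwise every
    consistent undecided pair is tested directly (the adaptive follow-up
    the ambiguous multi-hit and single-quencher groups require).
    """
    members = sorted(group)
    g = len(members)
    tests = 0
    unresolved: list[frozenset[int]] = []
    if g < 5:
        # too small for a signature family: test undecided pairs directly
        candidates = [p for p in itertools.combinations(members, 2) if not know.pair_decided(p)]
    else:
        if design_cache is not None and g in design_cache:
            design = design_cache[g]
        else:
            design = onestep_design(g, n_subsets=8, subset_size=g - 3, seed=int(rng.integers(2**31)))
            if design_cache is not None:
                design_cache[g] = design
        positive: set[int] = set()
        for i, sub in enumerate(design.subsets):
            sub_members = frozenset(members[j] for j in sub)
            tests += 1
            if oracle(sub_members):
                positive.add(i)
            else:
                know.exclude_set(sub_members)
        local = {
            p: frozenset(i for i, sub in enumerate(design.subsets) if sub.issuperset(p))
            for p in itertools.combinations(range(g), 2)
        }
        candidates = []
        for p, sig in local.items():
            gp = (members[p[0]], members[p[1]])
            if know.pair_decided(gp):
                continue
            if sig <= positive:
                candidates.append(gp)
    if len(candidates) == 1 and not know.contains_confirmed(group):
        # the group's positivity cannot be explained by anything already
        # confirmed, and only one consistent pair is left: it must be active
        know.confirm_pair(*candidates[0])
        return tests, unresolved
    for gp in candidates:
        if know.pair_decided(gp):
            continue
        tests += 1
        pair_set = frozenset(gp)
        if oracle(pair_set):
            know.confirm_pair(*gp)
        else:
            know.exclude_set(pair_set)
    if not know.contains_confirmed(group):
        unresolved.append(group)
    return tests, unresolved


def run_campaign(
    n: int,
    k: int,
    truth: GroundTruth,
    model: QuenchModel,
    strategy: str = "iterative",
    seed: int | None = None,
    design: PoolDesign | None = None,
    design_restarts: int = 5,
    share_knowledge: bool = True,
    find_all: bool = True,
    detect_singletons: bool = False,
) -> CampaignResult:
    """Run design -> screen -> deconvolve on a planted truth.

    A greedy covering design is built (or supplied), each block is screened
    through the quenching model, and every positive block is deconvolved
    with the chosen strategy.  With ``share_knowledge`` (default), entities
    confirmed or excluded in one group prune queries in later groups.  The
    ``parallel`` strategy skips pooling and tests all ``C(n, 2)`` pairs.
    """
    if strategy not in ("iterative", "onestep", "parallel"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    planted = set(truth.active_pairs)

    if strategy == "parallel":
        recovered: set[Pair] = set()
        for p in itertools.combinations(range(n), 2):
            r = screen_set(p, truth, model, rng=rng, set_id=f"pair-{p[0]}-{p[1]}")
            if r.call:
                recovered.add(p)
        # individually active compounds light up every pair containing them
        singles = {a for a in truth.active_singletons}
        pair_hits = {p for p in recovered if not (set(p) & singles)}
        return CampaignResult(
            strategy=strategy,
            design_tests=count_combinations(n, 2),
            deconv_tests=0,
            recovered_pairs=pair_hits,
            recovered_singletons=singles & {i for p in recovered for i in p},
            false_negatives=planted - pair_hits,
            false_positives=pair_hits - planted,
            unresolved=[],
        )

    if design is None:
        design = greedy_design(n, k, t=2, lam=1, restarts=design_restarts, seed=seed)
    readouts = [
        screen_set(b, truth, model, rng=rng, set_id=f"block-{i}")
        for i, b in enumerate(design.blocks)
    ]

    know = Knowledge(detect_singletons=detect_singletons)
    group_log: list[dict] = []
    deconv_tests = 0
    unresolved: list[list[int]] = []
    design_cache: dict = {}

    def oracle(s: frozenset[int]) -> bool:
        return screen_set(s, truth, model, rng=rng).call

    # negative blocks exclude everything inside them before deconvolution
    for block, r in zip(design.blocks, readouts):
        if not r.call:
            know.exclude_set(block)

    for block, r in zip(design.blocks, readouts):
        if not r.call:
            continue
        if not share_knowledge:
            local = Knowledge(detect_singletons=detect_singletons)
            for b2, r2 in zip(design.blocks, readouts):
                if not r2.call:
                    local.exclude_set(b2 & block)
            group_know = local
        else:
            group_know = know
        if group_know.all_decided(block) and group_know.contains_confirmed(block):
            group_log.append({"block": sorted(block), "tests": 0, "skipped": True})
            continue
        if strategy == "iterative":
            res = run_iterative(
                block,
                oracle,
                find_all=find_all,
                detect_singletons=detect_singletons,
                seed=int(rng.integers(2**31)),
                knowledge=group_know,
                root_known_positive=True,
            )
            tests, unres = res.tests_used, [sorted(u) for u in res.unresolved]
        else:
            tests, unres_sets = _onestep_deconvolve(block, oracle, group_know, rng, design_cache)
            unres = [sorted(u) for u in unres_sets]
        if share_knowledge is False:
            know.confirmed_pairs |= group_know.confirmed_pairs
            know.confirmed_singletons |= group_know.confirmed_singletons
        deconv_tests += tests
        unresolved.extend(unres)
        group_log.append({"block": sorted(block), "tests": tests, "skipped": False})

    recovered = set(know.confirmed_pairs)
    covered = {
        p
        for b in design.blocks
        for p in itertools.combinations(sorted(b), 2)
    }
    return CampaignResult(
        strategy=strategy,
        design_tests=design.n_blocks,
        deconv_tests=deconv_tests,
        recovered_pairs=recovered,
        recovered_singletons=set(know.confirmed_singletons),
        false_negatives=(planted & covered) - recovered,
        false_positives=recovered - planted,
        unresolved=unresolved,
        group_log=group_log,
    )


def summarize(results: Sequence[CampaignResult], truth_sizes: Sequence[int] | None = None):
    """Aggregate campaign replicates into a per-strategy metrics table."""
    import pandas as pd

    if not results:
        raise ValueError("results must be non-empty")
    rows = []
    for i, r in enumerate(results):
        planted = r.recovered_pairs | r.false_negatives
        n_planted = truth_sizes[i] if truth_sizes is not None else len(planted)
        rows.append(
            {
                "strategy": r.strategy,
                "total_tests": r.total_tests,
                "design_tests": r.design_tests,
                "deconv_tests": r.deconv_tests,
                "sensitivity": len(r.recovered_pairs & planted) / n_planted if n_planted else 1.0,
                "false_discoveries": len(r.false_positives),
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby("strategy")
        .agg(
            mean_total=("total_tests", "mean"),
            q25_total=("total_tests", lambda s: s.quantile(0.25)),
            q75_total=("total_tests", lambda s: s.quantile(0.75)),
            mean_sensitivity=("sensitivity", "mean"),
            mean_false_discoveries=("false_discoveries", "mean"),
            n=("total_tests", "size"),
        )
        .reset_index()
    )
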