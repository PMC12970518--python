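"""Phenomenological model of the luminescence-quenching readout.

Each inactive compound contributes a small background quenching channel,
parameterized by a dimensionless Stern-Volmer product at working
concentration; independent channels are additive, so a pool of inactive
compounds has quenching ``100 * (1 - 1 / (1 + sum KSV))``.  A planted
cooperative entity suppresses a further ``active_quench_fraction`` of the
remaining emission.  The hit threshold on the quenching percentage trades
the false-positive rate of large pools against the number of pools, which
is how the working group size is chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "QuenchModel",
    "Readout",
    "quench_percent",
    "combined_background",
    "false_positive_prob",
    "positive_group_prob",
    "expected_total_tests",
    "tradeoff_table",
]


@dataclass
class QuenchModel:
    """Parameters of the quenching readout and hit-calling threshold.

    ``background_ksv_log_mean`` / ``background_ksv_log_sd`` parameterize a
    log-normal distribution of per-compound background Stern-Volmer
    products (defaults give a group of ten inactives a few percent chance
    of crossing the 60% threshold).  ``active_quench_fraction`` is the
    fraction of remaining intensity removed by an active entity (1.0 =
    total extinction).  ``readout_noise_sd`` is additive Gaussian noise on
    the quenching percentage, in percentage points.
    """

    background_ksv_log_mean: float = math.log(0.03)
    background_ksv_log_sd: float = 1.0
    active_quench_fraction: float = 1.0
    readout_noise_sd: float = 0.0
    threshold: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.active_quench_fraction <= 1.0):
            raise ValueError("active_quench_fraction must be in [0, 1]")
        if not (0.0 < self.threshold < 100.0):
            raise ValueError("threshold must be in (0, 100)")
        if self.readout_noise_sd < 0:
            raise ValueError("readout_noise_sd must be >= 0")

    def sample_ksv(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.background_ksv_log_mean, self.background_ksv_log_sd, size)

    def call(self, quench: float) -> bool:
        return quench >= self.threshold

    def to_dict(self) -> dict:
        return {
            "background_ksv_log_mean": self.background_ksv_log_mean,
            "background_ksv_log_sd": self.background_ksv_log_sd,
            "active_quench_fraction": self.active_quench_fraction,
            "readout_noise_sd": self.readout_noise_sd,
            "threshold": self.threshold,
        }


@dataclass
class Readout:
    """One measured set: its quenching percentage and the threshold call."""

    set_id: str
    quench_percent: float
    call: bool


def quench_percent(intensity: float, reference_intensity: float) -> float:
    """Quenching percentage, ``100 * (1 - I / I_ref)``.

    Intensities above the reference are clipped to zero quenching.
    """
    if reference_intensity <= 0:
        raise ValueError("reference_intensity must be positive")
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    return 100.0 * max(0.0, 1.0 - intensity / reference_intensity)


def combined_background(ksv_values: Iterable[float]) -> float:
    """Background quenching percent of a pool of inactive compounds.

    Stern-Volmer channels are additive: ``100 * (1 - 1 / (1 + sum KSV))``.
    """
    vals = list(ksv_values)
    if any(v < 0 for v in vals):
        raise ValueError("Stern-Volmer products must be >= 0")
    total = float(sum(vals))
    return 100.0 * (1.0 - 1.0 / (1.0 + total))


def false_positive_prob(
    k: int, model: QuenchModel, n_sim: int = 100_000, seed: int | None = None
) -> float:
    """Monte-Carlo probability that ``k`` inactive compounds alone call positive."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if k == 0 and model.readout_noise_sd == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    ksv = model.sample_ksv((n_sim, k), rng) if k else np.zeros((n_sim, 1))
    quench = 100.0 * (1.0 - 1.0 / (1.0 + ksv.sum(axis=1)))
    if model.readout_noise_sd > 0:
        quench = quench + rng.normal(0.0, model.readout_noise_sd, n_sim)
    quench = np.clip(quench, 0.0, 100.0)
    return float(np.mean(quench >= model.threshold))


def positive_group_prob(p_pair: float, k: int) -> float:
    """Probability that a pool of ``k`` compounds contains an active pair.

    Assumes each of the ``C(k, 2)`` pairs is independently active with
    probability ``p_pair``: ``1 - (1 - p_pair)^C(k,2)``.
    """
    if not (0.0 <= p_pair <= 1.0):
        raise ValueError("p_pair must be in [0, 1]")
    if k < 0:
        raise ValueError("k must be >= 0")
    return 1.0 - (1.0 - p_pair) ** math.comb(k, 2)


def expected_total_tests(
    n: int,
    k: int,
    p_pair: float,
    deconv_cost_fn: Callable[[int], float],
    design_size_fn: Callable[[int, int], float],
) -> float:
    """Expected experiment count: initial screen plus follow-up deconvolution.

    ``design_size + design_size * P(positive pool) * E[deconvolution
    tests]`` — the quantity minimized when choosing the pool size ``k``.
    """
    size = design_size_fn(n, k)
    return size + size * positive_group_prob(p_pair, k) * deconv_cost_fn(k)


def tradeoff_table(
    n: int,
    ks: Sequence[int],
    p_pair: float,
    deconv_cost_fn: Callable[[int], float],
    design_size_fn: Callable[[int, int], float],
):
    """Tabulate the pool-size trade-off as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for k in ks:
        size = design_size_fn(n, k)
        p_pos = positive_group_prob(p_pair, k)
        deconv = deconv_cost_fn(k)
        rows.append(
            {
                "k": k,
                "design_size": size,
                "p_positive": p_pos,
                "expected_deconv": deconv,
                "expected_total": size + size * p_pos * deconv,
            }
        )
    return pd.DataFrame(rows)
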