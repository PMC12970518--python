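"""Reaction-versus-controls comparison of chromatographic peak tables.

Inputs are tabular peak lists (retention time in minutes, base-peak
intensity, optionally a unit-m/z spectrum vector); raw chromatograms and
vendor formats are out of scope.  A reaction peak is *matched* when a
control peak lies within the retention-time tolerance (and, when spectra
are available, the spectral cosine clears its threshold); matching is
greedy by retention-time distance with each control peak used at most
once.  Unmatched reaction peaks above an intensity floor are the candidate
new product peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakTable",
    "PeakDiffReport",
    "match_peaks",
    "batch_compare",
]


@dataclass(frozen=True)
class Peak:
    rt: float  # retention time, minutes
    intensity: float  # base-peak intensity counts
    spectrum: tuple[float, ...] | None = None  # intensities over unit m/z bins

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass
class PeakTable:
    """One run's peak list, sorted by retention time."""

    run_id: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.rt)

    @classmethod
    def from_arrays(
        cls,
        run_id: str,
        rt: Sequence[float],
        intensity: Sequence[float],
        spectra: Sequence[Sequence[float]] | None = None,
    ) -> "PeakTable":
        peaks = [
            Peak(
                rt=float(r),
                intensity=float(i),
                spectrum=tuple(float(x) for x in spectra[j]) if spectra is not None else None,
            )
            for j, (r, i) in enumerate(zip(rt, intensity))
        ]
        return cls(run_id=run_id, peaks=peaks)

    @classmethod
    def from_dataframe(cls, run_id: str, df: pd.DataFrame) -> "PeakTable":
        spec_cols = [c for c in df.columns if str(c).startswith("mz_bin_")]
        spectra = df[spec_cols].to_numpy() if spec_cols else None
        return cls.from_arrays(run_id, df["rt_min"], df["intensity"], spectra)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.peaks:
            row = {"run_id": self.run_id, "rt_min": p.rt, "intensity": p.intensity}
            if p.spectrum is not None:
                row.update({f"mz_bin_{i}": v for i, v in enumerate(p.spectrum)})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class PeakDiffReport:
    """Difference between one reaction run and its controls."""

    run_id: str
    new_peaks: list[Peak]
    matched_peaks: list[tuple[Peak, Peak, str]]  # (reaction, control, control run)
    disappeared_peaks: list[tuple[Peak, str]]
    faint_peaks: list[Peak] = field(default_factory=list)  # unmatched, below floor

    @property
    def n_new(self) -> int:
        return len(self.new_peaks)

    @property
    def top_new_intensity(self) -> float:
        return max((p.intensity for p in self.new_peaks), default=0.0)

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "new_peaks": [{"rt_min": p.rt, "intensity": p.intensity} for p in self.new_peaks],
            "matched_peaks": [
                {
                    "rt_min": rp.rt,
                    "intensity": rp.intensity,
                    "control_rt_min": cp.rt,
                    "control_run": run,
                }
                for rp, cp, run in self.matched_peaks
            ],
            "disappeared_peaks": [
                {"rt_min": p.rt, "intensity": p.intensity, "control_run": run}
                for p, run in self.disappeared_peaks
            ],
            "faint_peaks": [{"rt_min": p.rt, "intensity": p.intensity} for p in self.faint_peaks],
        }


def _cosine(a: Sequence[float], b: Sequence[float]) -> float:
    va, vb = np.asarray(a, float), np.asarray(b, float)
    m = max(len(va), len(vb))
    va = np.pad(va, (0, m - len(va)))
    vb = np.pad(vb, (0, m - len(vb)))
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def match_peaks(
    reaction: PeakTable,
    controls: Sequence[PeakTable],
    rt_tolerance: float = 0.05,
    intensity_floor_fraction: float = 0.05,
    spectrum_min_cosine: float | None = None,
) -> PeakDiffReport:
    """Compare one reaction run against its control runs.

    Candidate (reaction, control) peak matches within ``rt_tolerance``
    minutes (and with spectral cosine at least ``spectrum_min_cosine``,
    when both spectra are present and the threshold is set) are ranked by
    retention-time distance and assigned greedily; each peak on either
    side is used at most once.  Unmatched reaction peaks with intensity at
    least ``intensity_floor_fraction`` of the strongest reaction peak are
    reported as new; weaker ones as faint.  Unmatched control peaks are
    reported as disappeared.
    """
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be positive")
    if not (0.0 <= intensity_floor_fraction <= 1.0):
        raise ValueError("intensity_floor_fraction must be in [0, 1]")
    if not reaction.peaks:
        return PeakDiffReport(
            run_id=reaction.run_id,
            new_peaks=[],
            matched_peaks=[],
            disappeared_peaks=[
                (p, c.run_id) for c in controls for p in c.peaks
            ],
        )

    control_peaks: list[tuple[Peak, str]] = [
        (p, c.run_id) for c in controls for p in c.peaks
    ]
    candidates = []
    for ri, rp in enumerate(reaction.peaks):
        for ci, (cp, crun) in enumerate(control_peaks):
            d = abs(rp.rt - cp.rt)
            if d > rt_tolerance:
                continue
            if (
                spectrum_min_cosine is not None
                and rp.spectrum is not None
                and cp.spectrum is not None
                and _cosine(rp.spectrum, cp.spectrum) < spectrum_min_cosine
            ):
                continue
            candidates.append((d, rp.rt, cp.rt, crun, ri, ci))
    candidates.sort()

    matched: list[tuple[Peak, Peak, str]] = []
    used_r: set[int] = set()
    used_c: set[int] = set()
    for d, _, _, crun, ri, ci in candidates:
        if ri in used_r or ci in used_c:
            continue
        used_r.add(ri)
        used_c.add(ci)
        matched.append((reaction.peaks[ri], control_peaks[ci][0], crun))

    floor = intensity_floor_fraction * max(p.intensity for p in reaction.peaks)
    new_peaks, faint = [], []
    for ri, rp in enumerate(reaction.peaks):
        if ri in used_r:
            continue
        (new_peaks if rp.intensity >= floor else faint).append(rp)
    disappeared = [
        (cp, crun)
        for ci, (cp, crun) in enumerate(control_peaks)
        if ci not in used_c
    ]
    return PeakDiffReport(
        run_id=reaction.run_id,
        new_peaks=new_peaks,
        matched_peaks=matched,
        disappeared_peaks=disappeared,
        faint_peaks=faint,
    )


def batch_compare(
    grid: Mapping[tuple[str, str], str],
    control_map: Mapping[str, Sequence[str]],
    tables: Mapping[str, PeakTable],
    rt_tolerance: float = 0.05,
    intensity_floor_fraction: float = 0.05,
    spectrum_min_cosine: float | None = None,
) -> tuple[pd.DataFrame, dict[str, PeakDiffReport], dict[str, str]]:
    """Run :func:`match_peaks` over a (pair, acceptor) -> run grid.

    Returns a ranked hit table (most new peaks first, then strongest new
    peak), the per-run reports, and a per-run error map for cells whose
    controls are missing; the batch continues past individual failures.
    """
    rows = []
    reports: dict[str, PeakDiffReport] = {}
    errors: dict[str, str] = {}
    for (pair, acceptor), run in grid.items():
        try:
            if run not in tables:
                raise KeyError(f"missing peak table for run {run!r}")
            control_runs = control_map.get(run, [])
            if not control_runs:
                raise KeyError(f"no controls registered for run {run!r}")
            missing = [c for c in control_runs if c not in tables]
            if missing:
                raise KeyError(f"missing control tables {missing} for run {run!r}")
            report = match_peaks(
                tables[run],
                [tables[c] for c in control_runs],
                rt_tolerance=rt_tolerance,
                intensity_floor_fraction=intensity_floor_fraction,
                spectrum_min_cosine=spectrum_min_cosine,
            )
            reports[run] = report
            rows.append(
                {
                    "pair": pair,
                    "acceptor": acceptor,
                    "run": run,
                    "n_new_peaks": report.n_new,
                    "top_new_intensity": report.top_new_intensity,
                }
            )
        except KeyError as exc:
            errors[run] = str(exc)
    table = pd.DataFrame(
        rows, columns=["pair", "acceptor", "run", "n_new_peaks", "top_new_intensity"]
    )
    if len(table):
        table = table.sort_values(
            ["n_new_peaks", "top_new_intensity"], ascending=False, kind="stable"
        ).reset_index(drop=True)
    return table, reports, errors
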