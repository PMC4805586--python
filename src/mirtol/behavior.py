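"""Hot-plate %MPE scoring and tolerance trajectories.

Thermal antinociception is scored as the percent maximal possible
effect (%MPE).  With a latency cutoff at ``cutoff_factor`` times the
saline baseline (4x by default, protecting against tissue damage),

    %MPE = 100 * (min(test, cutoff_factor*baseline) - baseline)
               / ((cutoff_factor - 1) * baseline)

so a test latency at baseline scores 0 and a latency at the cutoff
scores 100.  Latencies below baseline give negative %MPE
(hyperalgesia) and are not clamped; only the upper cutoff clamps.

The baseline for each genotype on each injection day is the mean
latency of that genotype's saline-vehicle group on that day.
Analgesic tolerance appears as a decline of %MPE across repeated
identical injections; ``tolerance_trajectory`` summarizes it per
genotype as per-injection mean/sem and the first-minus-last delta.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import LatencyRecord, RunConfig

logger = logging.getLogger("mirtol")

__all__ = [
    "MPERecord",
    "ToleranceSummary",
    "compute_mpe",
    "baseline_from_saline",
    "mpe_records",
    "tolerance_trajectory",
    "compare_genotypes",
]


@dataclass(frozen=True)
class MPERecord:
    """%MPE for one morphine-treated animal on one injection day."""

    animal_id: str
    genotype: str
    injection_number: int
    mpe: float
    baseline_used: float
    clamped: bool


@dataclass(frozen=True)
class ToleranceSummary:
    """Per-genotype tolerance trajectory across injections.

    ``tolerance_delta`` is the first-injection mean %MPE minus the
    last-injection mean %MPE: positive when analgesia declines.
    """

    genotype: str
    injections: tuple[int, ...]
    mean_mpe: tuple[float, ...]
    sem_mpe: tuple[float, ...]
    n: tuple[int, ...]
    tolerance_delta: float


def compute_mpe(
    test_latency: float, baseline_latency: float, cutoff_factor: float = 4.0
) -> float:
    """Percent maximal possible effect of one test latency.

    Parameters
    ----------
    test_latency : float
        Observed paw-lick latency, seconds.
    baseline_latency : float
        Saline-group baseline latency for the same genotype and
        injection day, seconds.
    cutoff_factor : float
        Latency cutoff as a multiple of baseline (default 4).

    Returns
    -------
    float
        %MPE in percent; 0 at baseline, 100 at the cutoff, negative
        below baseline.  Latencies above the cutoff are clamped to 100.
    """
    if not (math.isfinite(baseline_latency) and baseline_latency > 0):
        raise ValueError(f"baseline latency must be > 0, got {baseline_latency}")
    if cutoff_factor <= 1:
        raise ValueError(f"cutoff_factor must exceed 1, got {cutoff_factor}")
    cutoff = cutoff_factor * baseline_latency
    clamped_latency = min(test_latency, cutoff)
    return 100.0 * (clamped_latency - baseline_latency) / (cutoff - baseline_latency)


def is_clamped(
    test_latency: float, baseline_latency: float, cutoff_factor: float = 4.0
) -> bool:
    return test_latency >= cutoff_factor * baseline_latency


def baseline_from_saline(
    records: Sequence[LatencyRecord], genotype: str, injection_number: int
) -> float:
    """Mean saline-group latency for one genotype on one injection day."""
    lat = [
        r.latency
        for r in records
        if r.treatment == "saline"
        and r.genotype == genotype
        and r.injection_number == injection_number
    ]
    n_other = sum(
        1 for r in records
        if r.treatment == "saline" and r.injection_number == injection_number
        and r.genotype != genotype
    )
    if n_other:
        logger.debug(
            "baseline_from_saline(%s, day %d): ignored %d saline record(s) "
            "from other genotypes", genotype, injection_number, n_other,
        )
    if not lat:
        raise ValueError(
            f"no saline records for genotype {genotype!r}, "
            f"injection {injection_number}"
        )
    return float(np.mean(lat))


def mpe_records(
    records: Sequence[LatencyRecord], config: RunConfig | None = None
) -> list[MPERecord]:
    """Score every morphine observation against its genotype/day saline baseline."""
    cf = (config or RunConfig()).cutoff_factor
    out: list[MPERecord] = []
    for r in records:
        if r.treatment != "morphine":
            continue
        base = baseline_from_saline(records, r.genotype, r.injection_number)
        out.append(
            MPERecord(
                animal_id=r.animal_id,
                genotype=r.genotype,
                injection_number=r.injection_number,
                mpe=compute_mpe(r.latency, base, cf),
                baseline_used=base,
                clamped=is_clamped(r.latency, base, cf),
            )
        )
    return out


def tolerance_trajectory(
    records: Sequence[LatencyRecord], config: RunConfig | None = None
) -> list[ToleranceSummary]:
    """Per-genotype per-injection mean/sem %MPE and first-minus-last delta.

    Output is deterministically ordered by genotype then injection
    number.  Requires at least two distinct injection days.
    """
    scored = mpe_records(records, config)
    if not scored:
        raise ValueError("no morphine records to score")
    days = sorted({m.injection_number for m in scored})
    if len(days) < 2:
        raise ValueError("tolerance requires at least two injection days")

    summaries: list[ToleranceSummary] = []
    for genotype in sorted({m.genotype for m in scored}):
        means, sems, ns, inj = [], [], [], []
        for day in days:
            vals = [m.mpe for m in scored
                    if m.genotype == genotype and m.injection_number == day]
            if not vals:
                continue
            inj.append(day)
            means.append(float(np.mean(vals)))
            sems.append(float(stats.sem(vals)) if len(vals) > 1 else 0.0)
            ns.append(len(vals))
        summaries.append(
            ToleranceSummary(
                genotype=genotype,
                injections=tuple(inj),
                mean_mpe=tuple(means),
                sem_mpe=tuple(sems),
                n=tuple(ns),
                tolerance_delta=means[0] - means[-1],
            )
        )
    return summaries


def compare_genotypes(
    records: Sequence[LatencyRecord],
    genotype_a: str,
    genotype_b: str,
    config: RunConfig | None = None,
) -> dict[int, tuple[float, float]]:
    """Plain two-group comparison of %MPE between genotypes per injection day.

    Returns ``{injection_number: (t, p)}`` from an equal-variance
    two-sample t test on the per-animal %MPE values of the two
    genotypes' morphine groups.
    """
    scored = mpe_records(records, config)
    out: dict[int, tuple[float, float]] = {}
    for day in sorted({m.injection_number for m in scored}):
        a = [m.mpe for m in scored if m.genotype == genotype_a and m.injection_number == day]
        b = [m.mpe for m in scored if m.genotype == genotype_b and m.injection_number == day]
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            out[day] = (float(t), float(p))
    return out
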