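"""Two-group differential expression on log2 matrices with BH-FDR control.

The per-feature test is the equal-variance two-sample t test on log2
intensities (with two groups this is the one-way ANOVA: F = t^2, same
p-value).  Multiple testing is controlled by the Benjamini-Hochberg
linear step-up procedure at level ``fdr_q`` (default 10%): sort
p-values ascending, find the largest k with p_(k) <= k*q/m, and reject
the k smallest.  Reported q-values are the usual step-up adjusted
p-values, q_(i) = min_{j>=i} m*p_(j)/j clipped at 1, so that
``significant`` is equivalent to ``q <= fdr_q``.

``strain_specific`` implements the cross-strain refinement: a feature
is retained when it is FDR-significant in the tolerance-susceptible
strain and shows no raw-significance evidence in the resistant strain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import ExpressionMatrix, RunConfig, SampleDesign

logger = logging.getLogger("mirtol")

__all__ = [
    "DiffExprRecord",
    "two_group_test",
    "bh_stepup",
    "call_de",
    "strain_specific",
    "de_frame",
    "read_de",
]

P_FLOOR = float(np.finfo(float).eps)


@dataclass(frozen=True)
class DiffExprRecord:
    """Per-feature differential-expression call."""

    feature_id: str
    log2fc: float        # mean(treated) - mean(control), log2 units
    statistic: float     # equal-variance t (F of the two-group ANOVA = t^2)
    p: float
    q: float = 1.0
    direction: str = "none"   # up / down / none
    significant: bool = False


def two_group_test(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    contrast: tuple[str, str] = ("morphine", "saline"),
    strain: str | None = None,
) -> list[DiffExprRecord]:
    """Per-feature equal-variance two-group test (no FDR yet).

    ``contrast`` is (treated, control); ``log2fc`` is the treated-mean
    minus control-mean difference on the log2 scale.  Features with
    zero variance in both groups get a floored p-value with a warning
    rather than being dropped.
    """
    treated_label, control_label = contrast
    treated_ids = design.samples_for(treated_label, strain)
    control_ids = design.samples_for(control_label, strain)
    if len(treated_ids) < 2 or len(control_ids) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(treated_ids)} {treated_label!r} "
            f"and {len(control_ids)} {control_label!r}"
            + (f" for strain {strain!r}" if strain else "")
        )
    overlap = set(treated_ids) & set(control_ids)
    if overlap:
        raise ValueError(f"groups not disjoint: {sorted(overlap)}")

    a = matrix.subset_samples(treated_ids).values
    b = matrix.subset_samples(control_ids).values
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    t = np.asarray(t, float)
    p = np.asarray(p, float)

    degenerate = (a.var(axis=1) == 0.0) & (b.var(axis=1) == 0.0)
    if degenerate.any():
        logger.warning(
            "%d feature(s) with zero within-group variance: p floored at %.3g",
            int(degenerate.sum()), P_FLOOR,
        )
        # identical groups (fc == 0) carry no evidence; unequal constant
        # groups are maximally inconsistent with the null
        p = np.where(degenerate, np.where(log2fc == 0.0, 1.0, P_FLOOR), p)
        replacement = np.zeros_like(t)
        nonzero = log2fc != 0.0
        replacement[nonzero] = np.sign(log2fc[nonzero]) * np.inf
        t = np.where(np.isfinite(t), t, replacement)
    p = np.clip(p, P_FLOOR, 1.0)

    return [
        DiffExprRecord(fid, float(fc), float(ti), float(pi))
        for fid, fc, ti, pi in zip(matrix.feature_ids, log2fc, t, p)
    ]


def bh_stepup(
    pvalues: Sequence[float], fdr_q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg linear step-up procedure.

    Returns ``(reject, qvalues)`` in the input order.  Rejections are
    the k* smallest p-values where k* = max{i : p_(i) <= i*q/m};
    q-values are the monotone step-up adjusted p-values
    ``q_(i) = min_{j >= i} m * p_(j) / j`` clipped at 1.  Ties keep
    input order (stable sort).
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    below = ps <= ranks * fdr_q / m
    k_star = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0

    q_sorted = np.minimum.accumulate((m * ps / ranks)[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)

    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    q = np.empty(m)
    q[order] = q_sorted
    return reject, q


def call_de(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    config: RunConfig | None = None,
    contrast: tuple[str, str] = ("morphine", "saline"),
    strain: str | None = None,
) -> list[DiffExprRecord]:
    """Differential-expression calling: two-group test + BH step-up.

    Significant records carry a direction from the sign of the log2
    fold change; non-significant records have direction ``"none"``.
    """
    config = config or RunConfig()
    records = two_group_test(matrix, design, contrast, strain)
    reject, q = bh_stepup([r.p for r in records], config.fdr_q)
    out = []
    for r, rej, qi in zip(records, reject, q):
        direction = "none"
        if rej:
            direction = "up" if r.log2fc > 0 else "down"
        out.append(
            DiffExprRecord(
                r.feature_id, r.log2fc, r.statistic, r.p,
                q=float(qi), direction=direction, significant=bool(rej),
            )
        )
    n_up = sum(1 for r in out if r.direction == "up")
    n_down = sum(1 for r in out if r.direction == "down")
    logger.info("call_de: %d/%d significant at q<=%.2g (%d up, %d down)",
                n_up + n_down, len(out), config.fdr_q, n_up, n_down)
    return out


def strain_specific(
    de_a: Sequence[DiffExprRecord],
    de_b: Sequence[DiffExprRecord],
    config: RunConfig | None = None,
) -> list[str]:
    """Features significant in strain A and flat in strain B.

    Retains feature ids that are FDR-significant in ``de_a``
    (q <= fdr_q) while showing no raw evidence in ``de_b``
    (p > alpha_raw).  Features absent from either list are excluded
    with a counted warning.  Duplicate feature ids (probe-level
    duplicates) are resolved per-index against the B-side by feature
    id: if any B record for that id is raw-significant the feature is
    dropped.
    """
    config = config or RunConfig()
    b_pvals: dict[str, list[float]] = {}
    for r in de_b:
        b_pvals.setdefault(r.feature_id, []).append(r.p)

    kept: list[str] = []
    n_missing = 0
    seen: set[str] = set()
    for r in de_a:
        if not r.significant:
            continue
        if r.feature_id not in b_pvals:
            n_missing += 1
            continue
        if all(p > config.alpha_raw for p in b_pvals[r.feature_id]):
            if r.feature_id not in seen:
                kept.append(r.feature_id)
                seen.add(r.feature_id)
    if n_missing:
        logger.warning("strain_specific: %d significant feature(s) missing from "
                       "comparison strain, excluded", n_missing)
    return kept


def de_frame(records: Sequence[DiffExprRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "statistic": [r.statistic for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "direction": [r.direction for r in records],
            "significant": [r.significant for r in records],
        }
    )


def read_de(path) -> list[DiffExprRecord]:
    """Read a DE output TSV back into records."""
    import pandas as pd

    from .core_io import _sniff_sep

    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    required = ["feature_id", "log2fc", "statistic", "p", "q", "direction", "significant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: DE table missing columns {missing}")
    return [
        DiffExprRecord(
            str(r.feature_id), float(r.log2fc), float(r.statistic), float(r.p),
            float(r.q), str(r.direction), bool(r.significant),
        )
        for r in df.itertuples(index=False)
    ]
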