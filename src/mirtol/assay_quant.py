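"""Small-assay quantification.

Three independent bench assays share this module:

* comparative-Ct (2^-ddCt) relative quantification of qRT-PCR, with a
  fixed amplification efficiency of 2 and a single reference gene;
* dual-luciferase reporter normalization (Renilla / firefly, expressed
  as percent of a control condition), averaging technical replicates
  within each biological replicate before between-replicate statistics;
* western-blot densitometry as target-to-actin band ratios with a
  plain equal-variance two-group comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import CtRecord

logger = logging.getLogger("mirtol")

__all__ = [
    "FoldChangeRecord",
    "LuciferaseWell",
    "DensitometryRecord",
    "ddct_fold",
    "ddct_from_records",
    "normalize_luciferase",
    "densitometry_ratio",
    "read_luciferase",
    "read_densitometry",
]


@dataclass(frozen=True)
class FoldChangeRecord:
    """Comparative-Ct result for one gene: fold = 2^-ddCt."""

    gene_id: str
    delta_ct_control: float
    delta_ct_treated: float
    ddct: float
    fold: float
    log2_fold: float


@dataclass(frozen=True)
class LuciferaseWell:
    """One dual-luciferase well; ``normalized`` is Renilla / firefly."""

    condition: str
    renilla: float
    firefly: float
    biological_rep: int = 1

    def __post_init__(self) -> None:
        if self.renilla < 0:
            raise ValueError(f"renilla RLU must be >= 0, got {self.renilla}")

    @property
    def normalized(self) -> float:
        return self.renilla / self.firefly


@dataclass(frozen=True)
class DensitometryRecord:
    """One western-blot lane: target and loading-control band intensities."""

    sample_id: str
    group: str
    target_band: float
    actin_band: float

    def __post_init__(self) -> None:
        if self.target_band < 0:
            raise ValueError(f"target band intensity must be >= 0, got {self.target_band}")

    @property
    def ratio(self) -> float:
        return self.target_band / self.actin_band


# ---------------------------------------------------------------------------
# comparative Ct
# ---------------------------------------------------------------------------

def ddct_fold(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
    gene_id: str = "",
) -> FoldChangeRecord:
    """Comparative-Ct relative quantification.

    dCt = Ct_target - Ct_reference within each condition;
    ddCt = dCt_treated - dCt_control; fold change = 2^-ddCt
    (log2 fold = -ddCt).  Amplification efficiency is fixed at 2.
    """
    for name, ct in (
        ("ct_target_treated", ct_target_treated),
        ("ct_ref_treated", ct_ref_treated),
        ("ct_target_control", ct_target_control),
        ("ct_ref_control", ct_ref_control),
    ):
        if not math.isfinite(ct):
            raise ValueError(f"{name} must be finite, got {ct}")
    d_control = ct_target_control - ct_ref_control
    d_treated = ct_target_treated - ct_ref_treated
    ddct = d_treated - d_control
    return FoldChangeRecord(
        gene_id=gene_id,
        delta_ct_control=d_control,
        delta_ct_treated=d_treated,
        ddct=ddct,
        fold=2.0 ** (-ddct),
        log2_fold=-ddct,
    )


def ddct_from_records(
    records: Sequence[CtRecord],
    gene_id: str,
    control_condition: str = "control",
    treated_condition: str = "treated",
) -> FoldChangeRecord:
    """Comparative-Ct fold change from per-sample Ct records.

    Within each sample, the target Ct is normalized to the mean of that
    sample's reference-gene Ct records; per-condition dCt is the mean
    across samples (biological replicates).
    """
    def condition_dct(condition: str) -> float:
        samples = sorted({r.sample_id for r in records if r.condition == condition})
        if not samples:
            raise ValueError(f"no Ct records for condition {condition!r}")
        dcts = []
        for s in samples:
            target = [r.ct for r in records
                      if r.sample_id == s and r.gene_id == gene_id and not r.is_reference]
            ref = [r.ct for r in records if r.sample_id == s and r.is_reference]
            if not target:
                continue
            if not ref:
                raise ValueError(f"sample {s!r} has no reference-gene Ct")
            dcts.append(float(np.mean(target)) - float(np.mean(ref)))
        if not dcts:
            raise ValueError(
                f"no target Ct records for gene {gene_id!r}, condition {condition!r}"
            )
        return float(np.mean(dcts))

    d_control = condition_dct(control_condition)
    d_treated = condition_dct(treated_condition)
    ddct = d_treated - d_control
    return FoldChangeRecord(gene_id, d_control, d_treated, ddct, 2.0 ** (-ddct), -ddct)


# ---------------------------------------------------------------------------
# dual luciferase
# ---------------------------------------------------------------------------

def normalize_luciferase(
    wells: Sequence[LuciferaseWell], control_condition: str
) -> dict[str, tuple[float, float]]:
    """Percent-of-control luciferase activity per condition.

    Each well's Renilla signal is normalized to its own firefly signal
    (wells with zero firefly are excluded with a warning).  Technical
    wells are averaged within each biological replicate first; the
    per-condition mean and SEM are then taken across biological
    replicates and expressed as percent of the control-condition mean.

    Returns ``{condition: (mean_percent, sem_percent)}``.
    """
    usable = []
    for w in wells:
        if w.firefly <= 0:
            logger.warning("luciferase well with non-positive firefly excluded "
                           "(condition %r)", w.condition)
            continue
        usable.append(w)
    if not any(w.condition == control_condition for w in usable):
        raise ValueError(f"control condition {control_condition!r} absent")

    # technical-first averaging: one value per (condition, biological_rep)
    bio_means: dict[str, list[float]] = {}
    for cond in sorted({w.condition for w in usable}):
        reps = sorted({w.biological_rep for w in usable if w.condition == cond})
        bio_means[cond] = [
            float(np.mean([w.normalized for w in usable
                           if w.condition == cond and w.biological_rep == rep]))
            for rep in reps
        ]

    control_mean = float(np.mean(bio_means[control_condition]))
    out: dict[str, tuple[float, float]] = {}
    for cond, vals in bio_means.items():
        pct = [100.0 * v / control_mean for v in vals]
        sem = float(stats.sem(pct)) if len(pct) > 1 else 0.0
        out[cond] = (float(np.mean(pct)), sem)
    return out


# ---------------------------------------------------------------------------
# densitometry
# ---------------------------------------------------------------------------

def densitometry_ratio(
    records: Sequence[DensitometryRecord],
) -> dict:
    """Group-wise target-to-actin ratios and a two-group comparison.

    Records with zero (or negative) loading-control band are excluded
    with a warning.  When exactly two groups are present, an
    equal-variance two-sample t test compares their per-sample ratios
    and the ratio of group means is reported (group order is
    alphabetical; ratio_of_means = second / first).

    Returns a dict with keys ``group_means``, ``group_sems``, ``n``,
    and, for two groups, ``ratio_of_means``, ``t``, ``p``.
    """
    usable = []
    for r in records:
        if r.actin_band <= 0:
            logger.warning("densitometry record %r excluded: non-positive actin band",
                           r.sample_id)
            continue
        usable.append(r)
    if not usable:
        raise ValueError("no usable densitometry records")

    groups = sorted({r.group for r in usable})
    ratios = {g: [r.ratio for r in usable if r.group == g] for g in groups}
    result: dict = {
        "group_means": {g: float(np.mean(v)) for g, v in ratios.items()},
        "group_sems": {g: (float(stats.sem(v)) if len(v) > 1 else 0.0)
                       for g, v in ratios.items()},
        "n": {g: len(v) for g, v in ratios.items()},
    }
    if len(groups) == 2:
        a, b = groups
        if min(len(ratios[a]), len(ratios[b])) >= 2:
            t, p = stats.ttest_ind(ratios[b], ratios[a], equal_var=True)
            result["t"], result["p"] = float(t), float(p)
        result["ratio_of_means"] = (
            result["group_means"][b] / result["group_means"][a]
        )
    else:
        logger.info("densitometry: %d group(s); two-group comparison skipped",
                    len(groups))
    return result


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_luciferase(path) -> list[LuciferaseWell]:
    """Read luciferase wells (condition, renilla, firefly[, biological_rep])."""
    import pandas as pd

    from .core_io import _sniff_sep

    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    required = ["condition", "renilla", "firefly"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: luciferase table missing columns {missing}")
    has_rep = "biological_rep" in df.columns
    return [
        LuciferaseWell(
            str(r.condition), float(r.renilla), float(r.firefly),
            int(r.biological_rep) if has_rep else 1,
        )
        for r in df.itertuples(index=False)
    ]


def read_densitometry(path) -> list[DensitometryRecord]:
    """Read densitometry lanes (sample_id, group, target_band, actin_band)."""
    import pandas as pd

    from .core_io import _sniff_sep

    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    required = ["sample_id", "group", "target_band", "actin_band"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: densitometry table missing columns {missing}")
    return [
        DensitometryRecord(
            str(r.sample_id), str(r.group), float(r.target_band), float(r.actin_band)
        )
        for r in df.itertuples(index=False)
    ]
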