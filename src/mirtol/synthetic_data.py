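"""Seeded generators emulating the study's inputs, with planted ground truth.

The generators emulate a two-strain (tolerance-susceptible vs
-resistant), two-treatment (saline vs chronic morphine) design:

* ``gen_expression`` — log2 miRNA and mRNA array matrices with planted
  differential miRNAs (effects drawn from the upper half of the fold
  range reported for chronic morphine, |log2FC| >= 2), planted
  repressive and activating miRNA->mRNA pairs whose target mRNAs shift
  by -gain*effect or +gain*effect, a prediction table mixing planted
  pairs with decoys spanning the mirSVR cutoff, and a "hub" miRNA
  (modeled on the many-target, large-effect miR-202-5p archetype)
  whose predicted targets concentrate among the planted DE mRNAs;
* ``gen_latencies`` — hot-plate latencies in which the analgesic
  effect of morphine decays geometrically across injections in the
  susceptible genotype (decay rate < 1) and not at all in the
  resistant genotype (decay rate 1);
* ``gen_ct`` — qRT-PCR threshold cycles constructed so the
  comparative-Ct method inverts exactly to the planted log2 folds at
  zero noise.

Every generator is a pure function of its spec (identical spec and
seed give identical output).  Planted truth is returned alongside the
data so recovery tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    CtRecord,
    ExpressionMatrix,
    LatencyRecord,
    RunConfig,
    SampleDesign,
    TargetPrediction,
    write_table,
)

__all__ = [
    "BehaviorSpec",
    "SynthSpec",
    "PlantedPair",
    "SynthTruth",
    "default_spec",
    "gen_expression",
    "gen_latencies",
    "gen_ct",
]

# upper half of the reported chronic-morphine log2 fold-change range;
# weaker reported effects (down to ~0.34) are below detection power at
# n = 4 per cell and 0.5 log2 noise (see docs/methods.md)
EFFECT_PALETTE = (4.38, 4.07, 3.46, 2.44, 2.21, 2.13)
UP_FRACTION = 0.70  # reported split: 33 up / 14 down

SUSCEPTIBLE = "susceptible"
RESISTANT = "resistant"


@dataclass(frozen=True)
class BehaviorSpec:
    """Hot-plate generator parameters (seconds unless noted).

    ``acute_effect`` is the added latency of the first morphine
    injection; an ED90-like dose takes %MPE to ~90, i.e. about
    0.9 * 3 * baseline above baseline at a 4x cutoff.
    ``decay_rate`` multiplies the drug effect per injection; 1.0 means
    no tolerance (the resistant genotype).
    """

    baseline_mean: float = 7.0
    baseline_sd: float = 0.8
    acute_effect: float = 19.0
    latency_noise_sd: float = 1.5
    decay_rate: Mapping[str, float] = field(
        default_factory=lambda: {SUSCEPTIBLE: 0.5, RESISTANT: 1.0}
    )
    n_animals: int = 8
    n_injections: int = 3

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        for g, r in self.decay_rate.items():
            if not 0.0 < r <= 1.0:
                raise ValueError(f"decay_rate[{g!r}] must be in (0, 1], got {r}")


@dataclass
class SynthSpec:
    """Full synthetic-study specification.

    ``planted_de_mirna`` maps miRNA id -> log2 effect (added to the
    morphine group of the susceptible strain).  ``planted_pairs`` is a
    list of (mirna_id, mrna_id, mode, gain) with mode ``"repress"``
    (target shifts by -gain*effect) or ``"activate"`` (+gain*effect).
    """

    rng_seed: int = 0
    n_per_cell: int = 4
    n_mirna: int = 780
    n_mrna: int = 1000
    planted_de_mirna: dict[str, float] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str, str, float]] = field(default_factory=list)
    hub_id: str | None = None
    hub_extra_predictions: int = 85
    per_mirna_predictions: int = 20
    noise_sd: float = 0.5
    decoy_prediction_count: int = 300
    above_cutoff_fraction: float = 0.10
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    ct_noise_sd: float = 0.2
    n_ct_samples: int = 6

    def __post_init__(self) -> None:
        for name in ("n_per_cell", "n_mirna", "n_mrna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        mirna_ids = set(self.mirna_ids())
        mrna_ids = set(self.mrna_ids())
        for mid in self.planted_de_mirna:
            if mid not in mirna_ids:
                raise ValueError(f"planted miRNA {mid!r} outside the id space")
        for mid, gid, mode, gain in self.planted_pairs:
            if mid not in mirna_ids:
                raise ValueError(f"planted pair references absent miRNA {mid!r}")
            if gid not in mrna_ids:
                raise ValueError(f"planted pair references absent mRNA {gid!r}")
            if mode not in ("repress", "activate"):
                raise ValueError(f"pair mode must be repress/activate, got {mode!r}")
            if mid not in self.planted_de_mirna:
                raise ValueError(f"planted pair references non-DE miRNA {mid!r}")

    def mirna_ids(self) -> list[str]:
        return [f"mir{i:04d}" for i in range(1, self.n_mirna + 1)]

    def mrna_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(1, self.n_mrna + 1)]


def default_spec(rng_seed: int = 0, planted: bool = True) -> SynthSpec:
    """The default synthetic study.

    Plants 47 differential miRNAs (matching the reported count) with
    log2 effects from :data:`EFFECT_PALETTE`, signed ~70% up / 30%
    down.  The first planted miRNA is the hub: effect +4.07 and 15
    repressive pairs into the planted DE mRNA set; the remaining 46
    miRNAs share 65 further planted pairs (~10% activating), for 80
    planted DE mRNAs in a universe of 1000.  With ``planted=False``
    returns a null study (no effects, decoy predictions only).
    """
    spec = SynthSpec(rng_seed=rng_seed)
    if not planted:
        return spec
    rng = np.random.default_rng([rng_seed, 101])
    mirna_ids = spec.mirna_ids()
    mrna_ids = spec.mrna_ids()

    n_planted = 47
    chosen = [mirna_ids[i] for i in rng.choice(spec.n_mirna, n_planted, replace=False)]
    hub = chosen[0]
    effects = {hub: 4.07}
    for mid in chosen[1:]:
        mag = float(rng.choice(EFFECT_PALETTE))
        sign = 1.0 if rng.random() < UP_FRACTION else -1.0
        effects[mid] = sign * mag

    target_idx = rng.choice(spec.n_mrna, 80, replace=False)
    targets = [mrna_ids[i] for i in target_idx]
    pairs: list[tuple[str, str, str, float]] = [
        (hub, g, "repress", 1.0) for g in targets[:15]
    ]
    others = chosen[1:]
    for j, g in enumerate(targets[15:]):
        mid = others[j % len(others)]
        mode = "activate" if rng.random() < 0.10 else "repress"
        pairs.append((mid, g, mode, 1.0))

    spec.planted_de_mirna = effects
    spec.planted_pairs = pairs
    spec.hub_id = hub
    spec.__post_init__()
    return spec


@dataclass(frozen=True)
class PlantedPair:
    """One planted miRNA->mRNA edge with its assigned prediction scores."""

    mirna_id: str
    mrna_id: str
    mode: str
    gain: float
    mirsvr: float
    phastcons: float
    passes_filter: bool
    expected_class: str
    mrna_log2fc: float


@dataclass
class SynthTruth:
    """Ground truth written alongside generated data."""

    planted_de_mirna: dict[str, float]
    planted_de_mrna: dict[str, float]
    pairs: list[PlantedPair]
    hub_id: str | None

    def mirna_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": list(self.planted_de_mirna),
             "log2fc": list(self.planted_de_mirna.values())}
        )

    def mrna_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": list(self.planted_de_mrna),
             "log2fc": list(self.planted_de_mrna.values())}
        )

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna_id": [p.mirna_id for p in self.pairs],
                "mrna_id": [p.mrna_id for p in self.pairs],
                "mode": [p.mode for p in self.pairs],
                "gain": [p.gain for p in self.pairs],
                "mirsvr": [p.mirsvr for p in self.pairs],
                "phastcons": [p.phastcons for p in self.pairs],
                "passes_filter": [p.passes_filter for p in self.pairs],
                "expected_class": [p.expected_class for p in self.pairs],
                "mrna_log2fc": [p.mrna_log2fc for p in self.pairs],
            }
        )

    def write(self, outdir: str | Path, config: RunConfig | None = None) -> None:
        outdir = Path(outdir)
        write_table(self.mirna_frame(), outdir / "truth_de_mirna.tsv", config)
        write_table(self.mrna_frame(), outdir / "truth_de_mrna.tsv", config)
        write_table(self.pairs_frame(), outdir / "truth_pairs.tsv", config)


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

def _design_frame(spec: SynthSpec) -> pd.DataFrame:
    rows = []
    for strain in (SUSCEPTIBLE, RESISTANT):
        for treatment in ("saline", "morphine"):
            for rep in range(1, spec.n_per_cell + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_{treatment}_{rep}",
                        "treatment": treatment,
                        "strain": strain,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def gen_expression(
    spec: SynthSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleDesign, list[TargetPrediction], SynthTruth]:
    """Generate miRNA and mRNA log2 matrices, design, predictions, truth.

    Baseline log2 levels are Normal(8, 1.5) per feature.  Planted
    miRNA effects are added to the morphine group of the susceptible
    strain only; each planted pair shifts its target mRNA by
    -gain*effect (repress) or +gain*effect (activate) in the same
    cell.  Gaussian noise (``noise_sd`` log2 units) is added
    everywhere.  The prediction table contains every planted pair
    (hub pairs scored in U(-1.5, -1.2), other planted pairs in
    U(-1.2, -0.12), with ``above_cutoff_fraction`` of the non-hub
    pairs deliberately scored above the mirSVR cutoff to exercise
    filtering), ``hub_extra_predictions`` passing decoy edges from the
    hub to non-planted mRNAs, and ``decoy_prediction_count`` random
    decoy edges with scores spanning the cutoff.
    """
    rng = np.random.default_rng([spec.rng_seed, 202])
    design = SampleDesign(_design_frame(spec))
    mirna_ids = spec.mirna_ids()
    mrna_ids = spec.mrna_ids()
    sample_ids = design.sample_ids
    is_effect_col = np.array(
        [
            (row.treatment == "morphine") and (row.strain == SUSCEPTIBLE)
            for row in design.frame.itertuples(index=False)
        ]
    )

    def build_matrix(ids: list[str], effects: Mapping[str, float], klass: str) -> ExpressionMatrix:
        base = rng.normal(8.0, 1.5, size=len(ids))
        values = np.tile(base[:, None], (1, len(sample_ids)))
        if effects:
            eff = np.array([effects.get(i, 0.0) for i in ids])
            values = values + np.outer(eff, is_effect_col.astype(float))
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        return ExpressionMatrix(np.array(ids), np.array(sample_ids), values, klass)

    mrna_effects: dict[str, float] = {}
    for mid, gid, mode, gain in spec.planted_pairs:
        effect = spec.planted_de_mirna[mid]
        shift = -gain * effect if mode == "repress" else gain * effect
        mrna_effects[gid] = mrna_effects.get(gid, 0.0) + shift

    mirna_matrix = build_matrix(mirna_ids, spec.planted_de_mirna, "miRNA")
    mrna_matrix = build_matrix(mrna_ids, mrna_effects, "mRNA")

    # --- prediction table -------------------------------------------------
    predictions: list[TargetPrediction] = []
    planted_records: list[PlantedPair] = []
    n_nonhub = sum(1 for p in spec.planted_pairs if p[0] != spec.hub_id)
    n_corrupt = int(round(spec.above_cutoff_fraction * n_nonhub))
    nonhub_positions = [i for i, p in enumerate(spec.planted_pairs) if p[0] != spec.hub_id]
    corrupt = set(
        rng.choice(nonhub_positions, size=n_corrupt, replace=False).tolist()
        if n_corrupt and nonhub_positions else []
    )
    for i, (mid, gid, mode, gain) in enumerate(spec.planted_pairs):
        if mid == spec.hub_id:
            score = float(rng.uniform(-1.5, -1.2))
        elif i in corrupt:
            score = float(rng.uniform(-0.09, -0.01))
        else:
            score = float(rng.uniform(-1.2, -0.12))
        pc = float(rng.uniform(0.6, 1.0))
        predictions.append(TargetPrediction(mid, gid, score, pc))
        planted_records.append(
            PlantedPair(
                mirna_id=mid, mrna_id=gid, mode=mode, gain=gain,
                mirsvr=score, phastcons=pc,
                passes_filter=score <= RunConfig().mirsvr_cutoff,
                expected_class=(
                    "negatively_correlated" if mode == "repress"
                    else "positively_correlated"
                ),
                mrna_log2fc=mrna_effects[gid],
            )
        )

    planted_pair_keys = {(m, g) for m, g, _, _ in spec.planted_pairs}
    planted_mrnas = set(mrna_effects)

    non_de = [g for g in mrna_ids if g not in planted_mrnas]
    if spec.hub_id is not None and spec.hub_extra_predictions and non_de:
        extra = rng.choice(len(non_de),
                           size=min(spec.hub_extra_predictions, len(non_de)),
                           replace=False)
        for j in extra:
            predictions.append(
                TargetPrediction(
                    spec.hub_id, non_de[j],
                    float(rng.uniform(-1.0, -0.15)),
                    float(rng.uniform(0.0, 1.0)),
                )
            )

    # every planted non-hub miRNA also carries a baseline of passing
    # decoy predictions to non-planted mRNAs: real target-prediction
    # tables list tens of targets per miRNA, so no miRNA's prediction
    # set collapses onto its planted pairs alone
    if spec.per_mirna_predictions and non_de:
        for mid in spec.planted_de_mirna:
            if mid == spec.hub_id:
                continue
            picks = rng.choice(len(non_de),
                               size=min(spec.per_mirna_predictions, len(non_de)),
                               replace=False)
            for j in picks:
                predictions.append(
                    TargetPrediction(
                        mid, non_de[j],
                        float(rng.uniform(-1.0, -0.15)),
                        float(rng.uniform(0.0, 1.0)),
                    )
                )

    n_decoys = 0
    while n_decoys < spec.decoy_prediction_count:
        mid = mirna_ids[int(rng.integers(spec.n_mirna))]
        gid = mrna_ids[int(rng.integers(spec.n_mrna))]
        if mid == spec.hub_id or (mid, gid) in planted_pair_keys:
            continue
        predictions.append(
            TargetPrediction(
                mid, gid, float(rng.uniform(-0.6, 0.0)), float(rng.uniform(0.0, 1.0))
            )
        )
        n_decoys += 1

    truth = SynthTruth(
        planted_de_mirna=dict(spec.planted_de_mirna),
        planted_de_mrna=mrna_effects,
        pairs=planted_records,
        hub_id=spec.hub_id,
    )
    return mirna_matrix, mrna_matrix, design, predictions, truth


# ---------------------------------------------------------------------------
# behavior generator
# ---------------------------------------------------------------------------

def gen_latencies(spec: SynthSpec, cutoff_factor: float = 4.0) -> list[LatencyRecord]:
    """Hot-plate latencies with genotype-specific tolerance development.

    Saline latencies are Normal(baseline_mean, baseline_sd) truncated
    positive.  The morphine latency at injection i is
    ``min(cutoff_factor * baseline_mean,
    baseline_draw + acute_effect * decay_rate**(i-1) + noise)``;
    the resistant genotype uses decay_rate 1 (no tolerance).
    """
    b = spec.behavior
    rng = np.random.default_rng([spec.rng_seed, 303])

    def positive_normal(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        for _ in range(100):
            x = rng.normal(mean, sd)
            if x > 0:
                return float(x)
        return max(float(x), 0.1)

    records: list[LatencyRecord] = []
    cutoff = cutoff_factor * b.baseline_mean
    for genotype, decay in b.decay_rate.items():
        for treatment in ("saline", "morphine"):
            for a in range(1, b.n_animals + 1):
                animal = f"{genotype}_{treatment}_{a}"
                for i in range(1, b.n_injections + 1):
                    if treatment == "saline":
                        lat = positive_normal(b.baseline_mean, b.baseline_sd)
                    else:
                        drug = b.acute_effect * decay ** (i - 1)
                        noise = rng.normal(0.0, b.latency_noise_sd) if b.latency_noise_sd else 0.0
                        lat = min(cutoff, positive_normal(b.baseline_mean, b.baseline_sd) + drug + noise)
                        lat = max(lat, 0.1)
                    records.append(
                        LatencyRecord(animal, genotype, treatment, i, lat)
                    )
    return records


# ---------------------------------------------------------------------------
# Ct generator
# ---------------------------------------------------------------------------

def gen_ct(
    spec: SynthSpec,
    planted_log2_folds: Mapping[str, float],
    reference_gene: str = "U6",
) -> list[CtRecord]:
    """qRT-PCR Ct records with planted log2 fold changes.

    Per sample, the reference gene's Ct is Normal(20, ct_noise_sd);
    each target gene's Ct is the sample's reference Ct plus a fixed
    per-gene offset, minus the planted log2 fold in treated samples
    only, plus measurement noise.  At zero noise the comparative-Ct
    method recovers fold = 2**planted exactly.
    """
    rng = np.random.default_rng([spec.rng_seed, 404])
    genes = list(planted_log2_folds)
    offsets = {g: float(rng.uniform(2.0, 8.0)) for g in genes}
    records: list[CtRecord] = []
    for condition in ("control", "treated"):
        for s in range(1, spec.n_ct_samples + 1):
            sample = f"{condition}_{s}"
            ref_ct = 20.0 + (rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0)
            records.append(CtRecord(sample, reference_gene, ref_ct, condition, True))
            for g in genes:
                ct = ref_ct + offsets[g]
                if condition == "treated":
                    ct -= planted_log2_folds[g]
                if spec.ct_noise_sd:
                    ct += rng.normal(0.0, spec.ct_noise_sd)
                records.append(CtRecord(sample, g, ct, condition, False))
    return records
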