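"""Domain types, delimited-text IO, and run configuration.

Every stage of the pipeline consumes and produces plain delimited text
(TSV preferred, CSV accepted).  The types here are deliberately thin:
expression data is a feature-by-sample matrix of normalized log2
intensities, predictions are (miRNA, mRNA) edges with mirSVR /
PhastCons scores, and behavioral / assay records are one observation
per row.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mirtol")

TREATMENTS = ("saline", "morphine")

__all__ = [
    "RunConfig",
    "SampleDesign",
    "ExpressionMatrix",
    "TargetPrediction",
    "LatencyRecord",
    "CtRecord",
    "read_expression",
    "read_predictions",
    "read_latencies",
    "read_ct",
    "write_table",
    "write_predictions",
    "write_latencies",
    "aggregate_sites",
    "build_id_index",
]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable thresholds shared across stages.

    Parameters
    ----------
    fdr_q : float
        Benjamini-Hochberg FDR level for differential-expression and
        over-targeting calls.  Default 0.10 (a 10% FDR).
    mirsvr_cutoff : float
        Keep predicted target sites with combined mirSVR score at or
        below this value ("good" sites score more negative).
    phastcons_cutoff : float
        Minimum PhastCons conservation for a prediction in strict mode.
    cutoff_factor : float
        Hot-plate latency cutoff as a multiple of the saline baseline;
        the %MPE denominator is ``(cutoff_factor - 1) * baseline``.
    rng_seed : int
        Seed recorded in output headers and used by simulation commands.
    alpha_raw : float
        Raw per-test significance level used where results are reported
        both raw and FDR-adjusted.
    strict_phastcons : bool
        If True, predictions must also pass ``phastcons_cutoff``;
        missing PhastCons then fails.  If False (default), filtering is
        on mirSVR alone and missing PhastCons passes.
    universe : str
        Over-targeting universe: ``"assay"`` (all mRNA features
        assayed) or ``"predicted"`` (only mRNAs with at least one
        score-filtered prediction).
    """

    fdr_q: float = 0.10
    mirsvr_cutoff: float = -0.10
    phastcons_cutoff: float = 0.57
    cutoff_factor: float = 4.0
    rng_seed: int = 0
    alpha_raw: float = 0.05
    strict_phastcons: bool = False
    universe: str = "assay"

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        if not 0.0 < self.alpha_raw < 1.0:
            raise ValueError(f"alpha_raw must be in (0, 1), got {self.alpha_raw}")
        if not 0.0 <= self.phastcons_cutoff <= 1.0:
            raise ValueError(
                f"phastcons_cutoff must be in [0, 1], got {self.phastcons_cutoff}"
            )
        if self.cutoff_factor <= 1.0:
            raise ValueError(
                f"cutoff_factor must exceed 1, got {self.cutoff_factor}"
            )
        if not math.isfinite(self.mirsvr_cutoff):
            raise ValueError("mirsvr_cutoff must be finite")
        if self.universe not in ("assay", "predicted"):
            raise ValueError(f"universe must be 'assay' or 'predicted', got {self.universe!r}")
        self.rng_seed = int(self.rng_seed)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.as_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    @property
    def config_hash(self) -> str:
        """Short stable digest of the configuration (for output headers)."""
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetPrediction:
    """A predicted miRNA -> mRNA edge with a (combined) mirSVR score.

    ``mirsvr`` is unitless and <= 0 for predicted sites; multiple sites
    on one 3'-UTR are summed into a combined pair score.  ``phastcons``
    is a conservation probability in [0, 1], or None when the source
    table did not provide one.
    """

    mirna_id: str
    mrna_id: str
    mirsvr: float
    phastcons: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.mirsvr):
            raise ValueError(f"mirsvr must be finite for {self.mirna_id}->{self.mrna_id}")
        if self.phastcons is not None and not 0.0 <= self.phastcons <= 1.0:
            raise ValueError(
                f"phastcons must be in [0, 1], got {self.phastcons} "
                f"for {self.mirna_id}->{self.mrna_id}"
            )


@dataclass(frozen=True)
class LatencyRecord:
    """One hot-plate observation: latency to paw lick, in seconds."""

    animal_id: str
    genotype: str
    treatment: str
    injection_number: int
    latency: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.injection_number < 1:
            raise ValueError("injection_number must be a positive integer")
        if not (math.isfinite(self.latency) and self.latency > 0):
            raise ValueError(
                f"latency must be a positive finite number of seconds, got {self.latency}"
            )


@dataclass(frozen=True)
class CtRecord:
    """One qRT-PCR threshold-cycle measurement."""

    sample_id: str
    gene_id: str
    ct: float
    condition: str
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"ct must be finite and > 0, got {self.ct}")


# ---------------------------------------------------------------------------
# sample design and expression matrix
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Sample annotation: one row per array sample.

    Columns: ``sample_id``, ``treatment`` (saline/morphine), ``strain``,
    ``replicate`` (positive integer within the treatment-by-strain cell).
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "treatment", "strain", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        f = self.frame.reset_index(drop=True).copy()
        f["sample_id"] = f["sample_id"].astype(str)
        f["treatment"] = f["treatment"].astype(str)
        f["strain"] = f["strain"].astype(str)
        f["replicate"] = f["replicate"].astype(int)
        if f["sample_id"].duplicated().any():
            dups = f.loc[f["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in design: {dups}")
        bad = sorted(set(f["treatment"]) - set(TREATMENTS))
        if bad:
            raise ValueError(f"unknown treatment labels in design: {bad}")
        if (f["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive")
        self.frame = f

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def samples_for(self, treatment: str, strain: str | None = None) -> list[str]:
        f = self.frame
        mask = f["treatment"] == treatment
        if strain is not None:
            mask &= f["strain"] == strain
        return f.loc[mask, "sample_id"].tolist()

    def cell_counts(self) -> pd.Series:
        return self.frame.groupby(["treatment", "strain"]).size()

    def require_replication(self, minimum: int = 2) -> None:
        """Raise unless every (treatment, strain) cell has >= ``minimum`` samples."""
        low = self.cell_counts()
        low = low[low < minimum]
        if len(low):
            raise ValueError(
                f"cells with fewer than {minimum} replicates: {low.to_dict()}"
            )

    @classmethod
    def read(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep=_sniff_sep(path), comment="#"))

    def write(self, path: str | Path, config: RunConfig | None = None) -> None:
        write_table(self.frame, path, config=config)


@dataclass
class ExpressionMatrix:
    """Normalized log2 intensities, features x samples.

    Feature ids MAY repeat (distinct probes can share a miRNA name, as
    when one miRNA appears in both the up- and down-regulated columns
    of an array report); sample ids must be unique.  All values must be
    finite.
    """

    feature_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    feature_class: str = "miRNA"

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=str)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_class not in ("miRNA", "mRNA"):
            raise ValueError(f"feature_class must be 'miRNA' or 'mRNA', got {self.feature_class!r}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            self.feature_ids.copy(),
            np.asarray(list(sample_ids), dtype=str),
            self.values[:, idx],
            self.feature_class,
        )

    def write(self, path: str | Path, config: RunConfig | None = None) -> None:
        df = self.to_frame()
        df.insert(0, "feature_id", df.index)
        write_table(df.reset_index(drop=True), path, config=config)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sniff_sep(path: str | Path) -> str:
    """Delimiter auto-detection: tab preferred, comma accepted."""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def read_expression(
    path: str | Path,
    design_path: str | Path,
    feature_class: str = "miRNA",
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Read a log2 expression table and its sample-design table.

    The expression file has a header row of sample ids and feature ids
    in the first column.  Matrix columns are re-ordered to match the
    design row order; a matrix column with no design row is a hard
    error, while design rows absent from the matrix are dropped with a
    logged warning.
    """
    design = SampleDesign.read(design_path)
    sep = _sniff_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = next(
            line for line in fh if not line.startswith("#")
        ).rstrip("\n").split(sep)
    raw_cols = header[1:]
    if len(set(raw_cols)) != len(raw_cols):
        dups = sorted({c for c in raw_cols if raw_cols.count(c) > 1})
        raise ValueError(f"{path}: duplicated sample column(s) {dups}")
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected feature-id column plus sample columns")
    feature_ids = df.iloc[:, 0].astype(str).to_numpy()
    data = df.iloc[:, 1:]

    values = np.empty(data.shape, dtype=float)
    for j, col in enumerate(data.columns):
        try:
            values[:, j] = pd.to_numeric(data[col], errors="raise").to_numpy(float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(data[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {data[col].iloc[row]!r} at "
                f"feature {feature_ids[row]!r}, sample {col!r}"
            ) from None

    design_ids = design.sample_ids
    unmatched = [c for c in data.columns if c not in design_ids]
    if unmatched:
        raise ValueError(f"{path}: sample column(s) {unmatched} not in design table")
    absent = [s for s in design_ids if s not in set(data.columns)]
    if absent:
        logger.warning("design samples absent from matrix, dropped: %s", absent)
        design = SampleDesign(design.frame[~design.frame["sample_id"].isin(absent)])
        design_ids = design.sample_ids

    order = [list(data.columns).index(s) for s in design_ids]
    matrix = ExpressionMatrix(
        feature_ids, np.asarray(design_ids, dtype=str), values[:, order], feature_class
    )
    return matrix, design


def aggregate_sites(rows: Iterable[TargetPrediction]) -> list[TargetPrediction]:
    """Collapse per-site rows to one record per (miRNA, mRNA) pair.

    mirSVR scores of multiple predicted sites on one 3'-UTR are summed
    into a combined pair score; PhastCons takes the maximum over sites
    (missing values ignored; all-missing stays missing).  Input order
    of first appearance is preserved.
    """
    combined: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for r in rows:
        key = (r.mirna_id, r.mrna_id)
        if key not in combined:
            combined[key] = [0.0, None]
            order.append(key)
        combined[key][0] += r.mirsvr
        if r.phastcons is not None:
            prev = combined[key][1]
            combined[key][1] = r.phastcons if prev is None else max(prev, r.phastcons)
    return [
        TargetPrediction(m, g, combined[(m, g)][0], combined[(m, g)][1])
        for m, g in order
    ]


def read_predictions(
    path: str | Path, aggregate: bool = True
) -> list[TargetPrediction]:
    """Read a target-prediction table (mirna_id, mrna_id, mirsvr[, phastcons]).

    One row per predicted site or per pair.  With ``aggregate=True``
    (default) site rows are combined per pair by summing mirSVR and
    taking the maximum PhastCons.  Positive mirSVR scores are kept with
    a warning (score semantics are decided upstream).
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    if df.empty:
        logger.warning("%s: empty prediction table", path)
        return []
    required = ["mirna_id", "mrna_id", "mirsvr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: prediction table missing columns {missing}")
    has_pc = "phastcons" in df.columns
    rows: list[TargetPrediction] = []
    n_positive = 0
    for rec in df.itertuples(index=False):
        mirsvr = float(getattr(rec, "mirsvr"))
        if mirsvr > 0:
            n_positive += 1
        pc = getattr(rec, "phastcons") if has_pc else None
        if pc is not None and (isinstance(pc, float) and math.isnan(pc)):
            pc = None
        rows.append(
            TargetPrediction(
                str(getattr(rec, "mirna_id")),
                str(getattr(rec, "mrna_id")),
                mirsvr,
                None if pc is None else float(pc),
            )
        )
    if n_positive:
        logger.warning(
            "%s: %d prediction row(s) with positive mirSVR kept as-is", path, n_positive
        )
    return aggregate_sites(rows) if aggregate else rows


def read_latencies(path: str | Path) -> list[LatencyRecord]:
    """Read hot-plate records (animal_id, genotype, treatment, injection_number, latency_s)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    required = ["animal_id", "genotype", "treatment", "injection_number", "latency_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: latency table missing columns {missing}")
    records = [
        LatencyRecord(
            str(r.animal_id), str(r.genotype), str(r.treatment),
            int(r.injection_number), float(r.latency_s),
        )
        for r in df.itertuples(index=False)
    ]
    _check_contiguous_injections(records)
    return records


def _check_contiguous_injections(records: Sequence[LatencyRecord]) -> None:
    by_animal: dict[str, list[int]] = {}
    for r in records:
        by_animal.setdefault(r.animal_id, []).append(r.injection_number)
    for animal, nums in by_animal.items():
        expected = list(range(1, max(nums) + 1))
        if sorted(nums) != expected:
            raise ValueError(
                f"injection numbers for animal {animal!r} not contiguous from 1: "
                f"{sorted(nums)}"
            )


def read_ct(path: str | Path) -> list[CtRecord]:
    """Read qRT-PCR Ct records (sample_id, gene_id, ct, condition, is_reference)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    required = ["sample_id", "gene_id", "ct", "condition", "is_reference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {missing}")
    records = [
        CtRecord(
            str(r.sample_id), str(r.gene_id), float(r.ct), str(r.condition),
            bool(r.is_reference) if not isinstance(r.is_reference, str)
            else r.is_reference.strip().lower() in ("1", "true", "yes"),
        )
        for r in df.itertuples(index=False)
    ]
    samples_with_ref = {r.sample_id for r in records if r.is_reference}
    without = sorted({r.sample_id for r in records} - samples_with_ref)
    if without:
        raise ValueError(f"{path}: sample(s) without a reference-gene record: {without}")
    return records


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write a DataFrame as TSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            s = config.rng_seed if seed is None else seed
            fh.write(f"# mirtol config_hash={config.config_hash} seed={s}\n")
        df.to_csv(fh, sep="\t", index=False)


def predictions_frame(preds: Sequence[TargetPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [p.mirna_id for p in preds],
            "mrna_id": [p.mrna_id for p in preds],
            "mirsvr": [p.mirsvr for p in preds],
            "phastcons": [p.phastcons for p in preds],
        }
    )


def write_predictions(
    preds: Sequence[TargetPrediction], path: str | Path,
    config: RunConfig | None = None,
) -> None:
    write_table(predictions_frame(preds), path, config=config)


def latencies_frame(records: Sequence[LatencyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "genotype": [r.genotype for r in records],
            "treatment": [r.treatment for r in records],
            "injection_number": [r.injection_number for r in records],
            "latency_s": [r.latency for r in records],
        }
    )


def write_latencies(
    records: Sequence[LatencyRecord], path: str | Path,
    config: RunConfig | None = None,
) -> None:
    write_table(latencies_frame(records), path, config=config)


def ct_frame(records: Sequence[CtRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "ct": [r.ct for r in records],
            "condition": [r.condition for r in records],
            "is_reference": [r.is_reference for r in records],
        }
    )


def write_ct(
    records: Sequence[CtRecord], path: str | Path, config: RunConfig | None = None
) -> None:
    write_table(ct_frame(records), path, config=config)


# ---------------------------------------------------------------------------
# id matching
# ---------------------------------------------------------------------------

def build_id_index(ids: Iterable[str]) -> dict[str, str]:
    """Map lower-cased id -> canonical (first-seen) spelling.

    Ids are case-preserved but matched case-insensitively; a case
    conflict (two spellings differing only by case) keeps the first
    spelling and logs a warning.
    """
    index: dict[str, str] = {}
    conflicts = []
    for s in ids:
        key = s.lower()
        if key in index:
            if index[key] != s:
                conflicts.append((index[key], s))
        else:
            index[key] = s
    if conflicts:
        logger.warning("case conflicts in feature ids (first spelling kept): %s",
                       conflicts[:5])
    return index
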