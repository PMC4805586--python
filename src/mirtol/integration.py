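"""miRNA-mRNA integration: expression pairing, over-targeting, prioritization.

This is the inferential core of the pipeline.  Given direction-called
differential-expression results for miRNAs and mRNAs and a
score-filtered target-prediction table, it

1. pairs each significant miRNA with its predicted, significant target
   mRNAs and classifies each edge by direction concordance
   (opposite-direction edges are consistent with canonical repression;
   same-direction edges capture activation, the miR-27a/Serpini1 case);
2. tests each significant miRNA for "over-targeting" — whether its
   predicted targets are over-represented among differentially
   expressed mRNAs — with a one-sided hypergeometric test over the
   assayed universe, BH-corrected across the tested miRNAs;
3. prioritizes candidate miRNAs by a deterministic rank-sum over the
   number of paired DE targets, the best (most negative) paired mirSVR
   score, and the over-targeting q-value, with strain-specificity and
   lexicographic id as tie-breakers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import RunConfig, TargetPrediction, build_id_index
from .diffexpr import DiffExprRecord, bh_stepup

logger = logging.getLogger("mirtol")

__all__ = [
    "PairingRecord",
    "OverTargetResult",
    "CandidateScore",
    "filter_predictions",
    "pair_expression",
    "hypergeom_upper_tail",
    "overtargeting_scan",
    "prioritize",
]


@dataclass(frozen=True)
class PairingRecord:
    """A classified miRNA-mRNA edge after the DE overlay."""

    mirna_id: str
    mrna_id: str
    mirna_direction: str    # up / down
    mrna_direction: str     # up / down
    mirna_log2fc: float
    mirsvr: float
    phastcons: float | None
    pairing_class: str      # negatively_correlated / positively_correlated


@dataclass(frozen=True)
class OverTargetResult:
    """Per-miRNA hypergeometric over-targeting counts and test.

    N: mRNA universe size; K: DE mRNAs in the universe; n: predicted
    targets of this miRNA in the universe; k: predicted targets that
    are DE.  ``p`` is the upper tail P(X >= k).
    """

    mirna_id: str
    N: int
    K: int
    n: int
    k: int
    p: float
    q: float = 1.0
    raw_significant: bool = False
    fdr_significant: bool = False


@dataclass(frozen=True)
class CandidateScore:
    """Prioritization summary for one candidate miRNA."""

    mirna_id: str
    n_paired_de_targets: int
    best_mirsvr: float
    hypergeom_q: float
    strain_specific: bool
    rank: int


# ---------------------------------------------------------------------------
# prediction filtering and expression pairing
# ---------------------------------------------------------------------------

def filter_predictions(
    predictions: Sequence[TargetPrediction], config: RunConfig
) -> list[TargetPrediction]:
    """Keep "good-score" predictions.

    A prediction passes when its combined mirSVR score is at or below
    ``config.mirsvr_cutoff``.  In strict mode the PhastCons score must
    also be present and at or above ``config.phastcons_cutoff``; in the
    default mode a missing PhastCons passes.
    """
    kept = []
    for p in predictions:
        if p.mirsvr > config.mirsvr_cutoff:
            continue
        if config.strict_phastcons and (
            p.phastcons is None or p.phastcons < config.phastcons_cutoff
        ):
            continue
        kept.append(p)
    return kept


def _significant_directions(
    de: Sequence[DiffExprRecord],
) -> dict[str, tuple[str, float]]:
    """feature_id -> (direction, log2fc) over significant records.

    With duplicate probes sharing a feature id, the record with the
    largest |log2fc| wins (deterministic; ties keep first appearance).
    """
    out: dict[str, tuple[str, float]] = {}
    for r in de:
        if not r.significant:
            continue
        if r.feature_id not in out or abs(r.log2fc) > abs(out[r.feature_id][1]):
            out[r.feature_id] = (r.direction, r.log2fc)
    return out


def pair_expression(
    de_mirna: Sequence[DiffExprRecord],
    de_mrna: Sequence[DiffExprRecord],
    predictions: Sequence[TargetPrediction],
    config: RunConfig | None = None,
) -> list[PairingRecord]:
    """Direction-based expression pairing of miRNAs and predicted targets.

    Keeps score-filtered predictions whose miRNA and mRNA are both
    significant, and classifies each edge as ``negatively_correlated``
    (directions differ) or ``positively_correlated`` (directions
    agree).  Ids are matched case-insensitively.  Output is sorted by
    miRNA id, then mirSVR ascending (most negative first).

    Predictions referencing features absent from either DE list are
    skipped silently (they are simply not significant); malformed
    references are counted in a single warning.
    """
    config = config or RunConfig()
    mirna_dir = _significant_directions(de_mirna)
    mrna_dir = _significant_directions(de_mrna)
    mirna_index = build_id_index(mirna_dir)
    mrna_index = build_id_index(mrna_dir)
    known_mirna = build_id_index(r.feature_id for r in de_mirna)
    known_mrna = build_id_index(r.feature_id for r in de_mrna)

    records: list[PairingRecord] = []
    n_unknown = 0
    for p in filter_predictions(predictions, config):
        mkey, gkey = p.mirna_id.lower(), p.mrna_id.lower()
        if mkey not in known_mirna or gkey not in known_mrna:
            n_unknown += 1
            continue
        if mkey not in mirna_index or gkey not in mrna_index:
            continue  # assayed but not significant
        mdir, mfc = mirna_dir[mirna_index[mkey]]
        gdir, _ = mrna_dir[mrna_index[gkey]]
        records.append(
            PairingRecord(
                mirna_id=mirna_index[mkey],
                mrna_id=mrna_index[gkey],
                mirna_direction=mdir,
                mrna_direction=gdir,
                mirna_log2fc=mfc,
                mirsvr=p.mirsvr,
                phastcons=p.phastcons,
                pairing_class=(
                    "negatively_correlated" if mdir != gdir
                    else "positively_correlated"
                ),
            )
        )
    if n_unknown:
        logger.warning("pair_expression: %d prediction(s) referenced features "
                       "absent from the DE lists; skipped", n_unknown)
    records.sort(key=lambda r: (r.mirna_id, r.mirsvr))
    return records


# ---------------------------------------------------------------------------
# hypergeometric over-targeting
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts marked items in a draw of ``n`` from a universe of ``N``
    containing ``K`` marked items:
    p = sum_{j=k}^{min(n,K)} C(K,j) C(N-K,n-j) / C(N,n).
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid counts: N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overtargeting_scan(
    de_mirna: Sequence[DiffExprRecord],
    de_mrna: Sequence[DiffExprRecord],
    predictions: Sequence[TargetPrediction],
    universe: Sequence[str] | None = None,
    config: RunConfig | None = None,
) -> list[OverTargetResult]:
    """One hypergeometric over-targeting test per significant miRNA.

    The universe defaults to all assayed mRNA features (every feature
    id in ``de_mrna``); with ``config.universe == "predicted"`` it is
    restricted to mRNAs carrying at least one score-filtered
    prediction.  For each significant miRNA, n counts its score-
    filtered predicted targets inside the universe and k those that are
    DE; miRNAs with n = 0 are excluded from testing with a log entry.
    BH step-up q-values are computed across the tested miRNAs; the
    ``raw_significant`` flag (p < alpha_raw) is reported separately
    from the FDR pass.
    """
    config = config or RunConfig()
    preds = filter_predictions(predictions, config)

    if universe is None:
        universe = [r.feature_id for r in de_mrna]
    uni_index = build_id_index(universe)
    if config.universe == "predicted" :
        predicted = {p.mrna_id.lower() for p in preds}
        uni_index = {key: v for key, v in uni_index.items() if key in predicted}
    N = len(uni_index)

    de_keys = {r.feature_id.lower() for r in de_mrna if r.significant}
    de_in_universe = de_keys & set(uni_index)
    K = len(de_in_universe)

    targets_by_mirna: dict[str, set[str]] = {}
    for p in preds:
        gkey = p.mrna_id.lower()
        if gkey in uni_index:
            targets_by_mirna.setdefault(p.mirna_id.lower(), set()).add(gkey)

    sig_mirna: list[str] = []
    seen = set()
    for r in de_mirna:
        if r.significant and r.feature_id.lower() not in seen:
            sig_mirna.append(r.feature_id)
            seen.add(r.feature_id.lower())

    rows: list[tuple[str, int, int]] = []
    n_untestable = 0
    for mid in sig_mirna:
        targets = targets_by_mirna.get(mid.lower(), set())
        if not targets:
            n_untestable += 1
            continue
        rows.append((mid, len(targets), len(targets & de_in_universe)))
    if n_untestable:
        logger.info("overtargeting_scan: %d significant miRNA(s) with no "
                    "in-universe predictions excluded", n_untestable)
    if not rows:
        return []

    pvals = [hypergeom_upper_tail(N, K, n, k) for _, n, k in rows]
    reject, qvals = bh_stepup(pvals, config.fdr_q)
    return [
        OverTargetResult(
            mirna_id=mid, N=N, K=K, n=n, k=k, p=p, q=float(q),
            raw_significant=bool(p < config.alpha_raw),
            fdr_significant=bool(rej),
        )
        for (mid, n, k), p, q, rej in zip(rows, pvals, qvals, reject)
    ]


# ---------------------------------------------------------------------------
# prioritization
# ---------------------------------------------------------------------------

def prioritize(
    pairings: Sequence[PairingRecord],
    overtarget_results: Sequence[OverTargetResult],
    strain_specific_ids: Sequence[str] = (),
    config: RunConfig | None = None,
) -> list[CandidateScore]:
    """Deterministic rank-sum prioritization of candidate miRNAs.

    Candidates are all miRNAs appearing in ``pairings`` or
    ``overtarget_results``.  Each is ranked (1 = best, average ranks on
    ties) on: number of paired DE targets (descending), best paired
    mirSVR score (ascending, most negative first), and over-targeting
    q-value (ascending).  Candidates are ordered by rank sum; residual
    ties are broken by the strain-specific flag (specific first), then
    lexicographic miRNA id.
    """
    per_mirna: dict[str, dict] = {}
    for pr in pairings:
        d = per_mirna.setdefault(
            pr.mirna_id, {"n_paired": 0, "best_mirsvr": np.inf, "q": 1.0}
        )
        d["n_paired"] += 1
        d["best_mirsvr"] = min(d["best_mirsvr"], pr.mirsvr)
    for ot in overtarget_results:
        d = per_mirna.setdefault(
            ot.mirna_id, {"n_paired": 0, "best_mirsvr": np.inf, "q": 1.0}
        )
        d["q"] = ot.q
    if not per_mirna:
        return []

    specific = {s.lower() for s in strain_specific_ids}
    ids = sorted(per_mirna)  # fixed base order => deterministic ranks
    n_paired = np.array([per_mirna[i]["n_paired"] for i in ids], float)
    best_svr = np.array(
        [per_mirna[i]["best_mirsvr"] for i in ids], float
    )
    # candidates with no pairing rank last on the score criterion
    best_svr[~np.isfinite(best_svr)] = np.inf
    qv = np.array([per_mirna[i]["q"] for i in ids], float)

    rank_sum = (
        stats.rankdata(-n_paired, method="average")
        + stats.rankdata(best_svr, method="average")
        + stats.rankdata(qv, method="average")
    )
    order = sorted(
        range(len(ids)),
        key=lambda i: (rank_sum[i], ids[i].lower() not in specific, ids[i]),
    )
    return [
        CandidateScore(
            mirna_id=ids[i],
            n_paired_de_targets=int(n_paired[i]),
            best_mirsvr=float(best_svr[i]) if np.isfinite(best_svr[i]) else float("nan"),
            hypergeom_q=float(qv[i]),
            strain_specific=ids[i].lower() in specific,
            rank=pos + 1,
        )
        for pos, i in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# tabular views (stage outputs mirror the published table columns)
# ---------------------------------------------------------------------------

def pairings_frame(records: Sequence[PairingRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "mirna_direction": [r.mirna_direction for r in records],
            "mirna_log2fc": [r.mirna_log2fc for r in records],
            "mrna_id": [r.mrna_id for r in records],
            "mirsvr": [r.mirsvr for r in records],
            "mrna_direction": [r.mrna_direction for r in records],
            "pairing_class": [r.pairing_class for r in records],
        }
    )


def read_pairings(path) -> list[PairingRecord]:
    import pandas as pd

    from .core_io import _sniff_sep

    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    return [
        PairingRecord(
            str(r.mirna_id), str(r.mrna_id), str(r.mirna_direction),
            str(r.mrna_direction), float(r.mirna_log2fc), float(r.mirsvr),
            None, str(r.pairing_class),
        )
        for r in df.itertuples(index=False)
    ]


def overtarget_frame(records: Sequence[OverTargetResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "N": [r.N for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "k": [r.k for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "raw_significant": [r.raw_significant for r in records],
            "fdr_significant": [r.fdr_significant for r in records],
        }
    )


def read_overtarget(path) -> list[OverTargetResult]:
    import pandas as pd

    from .core_io import _sniff_sep

    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    return [
        OverTargetResult(
            str(r.mirna_id), int(r.N), int(r.K), int(r.n), int(r.k),
            float(r.p), float(r.q), bool(r.raw_significant), bool(r.fdr_significant),
        )
        for r in df.itertuples(index=False)
    ]


def candidates_frame(records: Sequence[CandidateScore]):
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": [r.rank for r in records],
            "mirna_id": [r.mirna_id for r in records],
            "n_paired_de_targets": [r.n_paired_de_targets for r in records],
            "best_mirsvr": [r.best_mirsvr for r in records],
            "hypergeom_q": [r.hypergeom_q for r in records],
            "strain_specific": [r.strain_specific for r in records],
        }
    )
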