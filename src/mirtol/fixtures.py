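"""Packaged reference tables: the published differential-expression and
expression-pairing results, transcribed verbatim.

Three tables ship with the package:

* ``table1`` — the 47 chronic-morphine differential miRNAs in the
  tolerance-susceptible strain (log2 fold change; 33 up, 14 down).
  A miRNA name may legitimately appear in both directions: the
  starred / unstarred forms (e.g. miR-29b* up, miR-29b down) are
  distinct probes and are kept as distinct tokens.
* ``table2a`` — negatively correlated (opposite-direction)
  miRNA-mRNA expression pairings with combined mirSVR scores.
* ``table2b`` — positively correlated (same-direction) pairings.
  One row of the published miR-27a block was lost to a typesetting
  artifact; it is retained as a marker row with ``missing=True`` and
  excluded by default.

The published miR-27a log2 value differs in the third decimal between
the two pairing tables (-0.3690 vs -0.3670); each table is transcribed
as printed and no cross-table equality should be assumed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diffexpr import DiffExprRecord

__all__ = [
    "load_table1",
    "load_table2a",
    "load_table2b",
    "table1_records",
    "fixture_de_records",
    "fixture_predictions_frame",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("mirtol.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    """47 differential miRNAs: feature_id, log2fc, direction."""
    return _read("table1_de_mirna.tsv")


def load_table2a() -> pd.DataFrame:
    """Negatively correlated pairings (opposite-direction edges)."""
    return _read("table2a_negative_pairings.tsv")


def load_table2b(include_missing: bool = False) -> pd.DataFrame:
    """Positively correlated pairings (same-direction edges).

    With ``include_missing=True`` the lost-row marker of the miR-27a
    block is retained (its mRNA id and score are blank).
    """
    df = _read("table2b_positive_pairings.tsv")
    if not include_missing:
        df = df[~df["missing"]].reset_index(drop=True)
    return df


def table1_records() -> list[DiffExprRecord]:
    """Table-1 rows as pre-computed significant DE records (fixtures mode)."""
    return [
        DiffExprRecord(
            feature_id=r.feature_id,
            log2fc=float(r.log2fc),
            statistic=float("nan"),
            p=float("nan"),
            q=float("nan"),
            direction=r.direction,
            significant=True,
        )
        for r in load_table1().itertuples(index=False)
    ]


def fixture_de_records() -> tuple[list[DiffExprRecord], list[DiffExprRecord]]:
    """(miRNA, mRNA) DE records implied by the pairing tables.

    Directions are as printed; log2 fold changes are the printed miRNA
    values and +/-1 placeholders for mRNAs (the source mRNA data set
    is external to this package).  Used by the pipeline's fixtures
    mode to run the integration stages on published calls.
    """
    t2 = pd.concat([load_table2a(), load_table2b()], ignore_index=True)
    mirna: dict[str, DiffExprRecord] = {}
    mrna: dict[str, DiffExprRecord] = {}
    for r in t2.itertuples(index=False):
        if r.mirna_id not in mirna:
            mirna[r.mirna_id] = DiffExprRecord(
                feature_id=r.mirna_id,
                log2fc=float(r.mirna_log2),
                statistic=float("nan"),
                p=float("nan"),
                q=float("nan"),
                direction=r.mirna_direction,
                significant=True,
            )
        if r.mrna_id not in mrna:
            mrna[r.mrna_id] = DiffExprRecord(
                feature_id=r.mrna_id,
                log2fc=1.0 if r.mrna_direction == "up" else -1.0,
                statistic=float("nan"),
                p=float("nan"),
                q=float("nan"),
                direction=r.mrna_direction,
                significant=True,
            )
    return list(mirna.values()), list(mrna.values())


def fixture_predictions_frame() -> pd.DataFrame:
    """All printed pairings as a prediction table (mirna_id, mrna_id, mirsvr)."""
    t2 = pd.concat([load_table2a(), load_table2b()], ignore_index=True)
    return t2[["mirna_id", "mrna_id", "mirsvr"]].copy()
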