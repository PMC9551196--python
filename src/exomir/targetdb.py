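"""Multi-database miRNA-target evidence: confidence filtering and consensus voting.

Evidence tables carry one record per (database, miRNA, gene) claim with columns
``mirna, gene, db, type, score, conserved``; ``type`` is ``predicted`` or
``validated``. Confidence scores are p-value-like (smaller is better) and are
only meaningful for prediction databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

logger = logging.getLogger(__name__)

EVIDENCE_COLUMNS = ("mirna", "gene", "db", "type", "score", "conserved")


def _check_evidence(records: pd.DataFrame) -> None:
    missing = [c for c in EVIDENCE_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"evidence table missing column(s): {missing}")


def filter_prediction_evidence(
    records: pd.DataFrame,
    top_frac: float = 0.2,
    conserved_only_dbs: set[str] = frozenset(),
    per_db: bool = True,
) -> pd.DataFrame:
    """Keep only high-confidence prediction records; validated rows pass through.

    Within each prediction database the records at or below that database's
    ``top_frac`` score quantile are retained (boundary ties included).
    Per-database quantiles are the default because score scales are not
    comparable across databases; ``per_db=False`` applies one pooled cut.
    Records from ``conserved_only_dbs`` additionally require ``conserved``.
    """
    _check_evidence(records)
    if records.empty:
        return records.copy()
    pred = records[records["type"] == "predicted"].copy()
    valid = records[records["type"] == "validated"].copy()
    if pred["score"].isna().any():
        bad = pred.loc[pred["score"].isna(), "db"].unique()
        raise InputError(f"prediction records without scores in db(s): {list(bad)}")
    if not pred.empty:
        if per_db:
            thr = pred.groupby("db")["score"].transform(lambda s: s.quantile(top_frac))
        else:
            thr = pred["score"].quantile(top_frac)
        pred = pred[pred["score"] <= thr]
        drop = pred["db"].isin(conserved_only_dbs) & ~pred["conserved"].astype(bool)
        if drop.any():
            logger.info("dropping %d non-conserved records from conserved-only DBs",
                        int(drop.sum()))
        pred = pred[~drop]
    return pd.concat([pred, valid], ignore_index=True)


@dataclass
class ConsensusPairs:
    """Voted miRNA-gene pairs with per-pair database support counts."""

    table: pd.DataFrame  # columns: mirna, gene, n_pred_dbs, n_valid_dbs

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["mirna"], self.table["gene"]))

    def targets_of(self, mirnas) -> set[tuple[str, str]]:
        mask = self.table["mirna"].isin(set(mirnas))
        return set(zip(self.table.loc[mask, "mirna"], self.table.loc[mask, "gene"]))


def consensus_vote(
    records: pd.DataFrame, pred_min: int = 4, valid_min: int = 2
) -> ConsensusPairs:
    """Vote pairs in: >= pred_min prediction DBs OR >= valid_min validation DBs.

    Duplicate records for the same (pair, database) count once.
    """
    _check_evidence(records)
    if records.empty:
        return ConsensusPairs(pd.DataFrame(
            columns=["mirna", "gene", "n_pred_dbs", "n_valid_dbs"]))
    dedup = records.drop_duplicates(subset=["mirna", "gene", "db"])
    counts = (
        dedup.groupby(["mirna", "gene", "type"])["db"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=["predicted", "validated"], fill_value=0)
        .rename(columns={"predicted": "n_pred_dbs", "validated": "n_valid_dbs"})
        .reset_index()
    )
    keep = (counts["n_pred_dbs"] >= pred_min) | (counts["n_valid_dbs"] >= valid_min)
    out = counts[keep].sort_values(["mirna", "gene"]).reset_index(drop=True)
    out.columns.name = None
    return ConsensusPairs(out[["mirna", "gene", "n_pred_dbs", "n_valid_dbs"]])


def relevance_filter(
    genes, table: pd.DataFrame, min_score: float = 5.0
) -> set[str]:
    """Genes with phenotype-relevance score strictly above ``min_score`` and a
    direct association flag. Genes absent from the table are treated as not
    relevant (logged)."""
    if "gene" in table.columns:
        table = table.set_index("gene")
    genes = set(genes)
    absent = genes - set(table.index)
    if absent:
        logger.info("%d genes absent from relevance table", len(absent))
    present = sorted(genes & set(table.index))
    if not present:
        return set()
    sub = table.loc[present]
    keep = (sub["score"] > min_score) & sub["direct"].astype(bool)
    return set(np.asarray(present)[keep.to_numpy()])


def tf_annotate(genes, catalog: set[str]) -> dict[str, bool]:
    """Transcription-factor membership lookup against the supplied catalog."""
    catalog = set(catalog)
    return {g: g in catalog for g in genes}
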