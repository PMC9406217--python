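"""Classification and ranking of differential-expression records.

A DE table (gene_id, fold_change, log_fold_change, p, p_adj) is
partitioned into three statuses: *differential* (adjusted p <= alpha,
inclusive), *uninterpretable* (adjusted p missing; such rows are
excluded from every downstream stage), and *equal* (everything else).
Differential genes are split by direction of change and the top-k in
each direction, ranked by |log fold change|, are set aside for scoring.

Fold-change orientation: by convention fold change is stored as
parental over knockout line, so fold_change > 1 (lfc > 0) means the
gene is *down* in the knockout — the genes whose products a compound
panel would inhibit.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = ["classify_de", "top_ranked", "STATUSES"]

log = logging.getLogger(__name__)

STATUSES = ("differential", "equal", "uninterpretable")

_REQUIRED = ("gene_id", "fold_change", "log_fold_change", "p", "p_adj")


def classify_de(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign ``status`` and ``direction`` to every row of a DE table.

    Parameters
    ----------
    table:
        DataFrame with columns gene_id, fold_change, log_fold_change,
        p, p_adj. Missing values are NaN/empty. If one of fold_change /
        log_fold_change is absent it is derived from the other.
    alpha:
        Adjusted-p cutoff, boundary inclusive (p_adj <= alpha is
        differential).

    Returns a copy with ``status`` in {differential, equal,
    uninterpretable} and ``direction`` in {up, down, none}. The
    operation is idempotent.
    """
    df = table.copy()
    if "fold_change" not in df and "log_fold_change" in df:
        df["fold_change"] = np.exp2(df["log_fold_change"].astype(float))
    if "log_fold_change" not in df and "fold_change" in df:
        df["log_fold_change"] = np.log2(df["fold_change"].astype(float))
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"DE table lacks required columns: {missing_cols}")

    fc = df["fold_change"].astype(float)
    if (fc[fc.notna()] <= 0).any():
        bad = df.loc[fc.notna() & (fc <= 0), "gene_id"].tolist()[:5]
        raise ValueError(f"non-positive fold change for genes {bad}")

    padj = df["p_adj"].astype(float)
    uninterpretable = padj.isna()
    differential = ~uninterpretable & (padj <= alpha) & (fc != 1.0)

    status = np.where(uninterpretable, "uninterpretable",
                      np.where(differential, "differential", "equal"))
    direction = np.where(differential & (fc > 1.0), "up",
                         np.where(differential & (fc < 1.0), "down", "none"))
    df["status"] = status
    df["direction"] = direction

    counts = pd.Series(status).value_counts()
    log.info(
        "classified %d genes: %d differential, %d equal, %d uninterpretable "
        "(excluded downstream)", len(df),
        counts.get("differential", 0), counts.get("equal", 0),
        counts.get("uninterpretable", 0),
    )
    return df


def top_ranked(
    classified: pd.DataFrame,
    k: int = 100,
    direction: str = "up",
    metric: str = "log",
) -> pd.DataFrame:
    """Return the k most changed differential genes in one direction.

    Ranking is by |log fold change| descending (``metric="raw"`` ranks
    by |fold change - 1| instead); ties are broken by smaller adjusted
    p, then lexicographic gene_id, so the order is fully deterministic.
    If fewer than k genes qualify, all are returned with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if "status" not in classified.columns:
        raise ValueError("table is not classified; run classify_de first")
    pool = classified[(classified["status"] == "differential")
                      & (classified["direction"] == direction)].copy()
    if metric == "log":
        pool["_mag"] = pool["log_fold_change"].astype(float).abs()
    elif metric == "raw":
        pool["_mag"] = (pool["fold_change"].astype(float) - 1.0).abs()
    else:
        raise ValueError("metric must be 'log' or 'raw'")
    pool = pool.sort_values(
        by=["_mag", "p_adj", "gene_id"], ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_mag")
    if len(pool) < k:
        warnings.warn(
            f"only {len(pool)} {direction}-regulated genes available "
            f"(requested {k})", stacklevel=2)
    out = pool.head(k).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
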