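"""Fold-change signature calling and SAM annotation.

A probe enters the androgen/antiandrogen-response signature if, for at
least one (cell line, treatment), its three per-time-point averaged 2log
ratios all share one sign and all have magnitude >= 0.5 (ratio >= 1.42 or
<= 0.71).  Gene-level counts collapse probes by HUGO symbol when present
(e.g. three NDRG1 probes count once), otherwise by accession.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIGNATURE_COLUMNS = [
    "probe_id", "genbank_id", "symbol", "cytoband",
    "cell_line", "treatment", "direction", "mean_ratio",
]


def call_signature(
    averaged: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Apply the all-time-points fold-change rule to averaged ratio profiles.

    Parameters
    ----------
    averaged : DataFrame
        Columns probe_id, cell_line, treatment, time_h, M, complete (as
        produced by ``preprocess.average_replicates``).
    annotation : DataFrame, optional
        probe_id -> genbank_id / symbol / cytoband; merged onto the calls.
    threshold : float
        Magnitude every per-time-point mean must reach (inclusive).

    Returns one row per qualifying (probe, cell line, treatment) with the
    direction and the mean of the three per-time-point averages.  Incomplete
    profiles are skipped (logged).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    n_incomplete = 0
    rows = []
    for (pid, cl, tr), grp in averaged.groupby(
        ["probe_id", "cell_line", "treatment"], sort=True
    ):
        if "complete" in grp.columns and not grp["complete"].all():
            n_incomplete += 1
            continue
        m = grp.sort_values("time_h")["M"].to_numpy()
        if np.all(m >= threshold):
            direction = "up"
        elif np.all(m <= -threshold):
            direction = "down"
        else:
            continue
        rows.append({
            "probe_id": pid, "cell_line": cl, "treatment": tr,
            "direction": direction, "mean_ratio": float(m.mean()),
        })
    if n_incomplete:
        logger.info("skipped %d incomplete probe-condition profiles", n_incomplete)
    calls = pd.DataFrame(rows, columns=["probe_id", "cell_line", "treatment",
                                        "direction", "mean_ratio"])
    if annotation is not None and len(calls):
        ann_cols = [c for c in ("probe_id", "genbank_id", "symbol", "cytoband")
                    if c in annotation.columns]
        calls = calls.merge(annotation[ann_cols].drop_duplicates("probe_id"),
                            on="probe_id", how="left")
    for c in ("genbank_id", "symbol", "cytoband"):
        if c not in calls.columns:
            calls[c] = ""
    return calls[SIGNATURE_COLUMNS]


def gene_key(entries: pd.DataFrame) -> pd.Series:
    """Collapse key: HUGO symbol when present, else accession, else probe."""
    sym = entries.get("symbol", pd.Series("", index=entries.index)).fillna("").astype(str)
    gb = entries.get("genbank_id", pd.Series("", index=entries.index)).fillna("").astype(str)
    pid = entries.get("probe_id", pd.Series("", index=entries.index)).fillna("").astype(str)
    key = sym.where(sym.str.strip() != "", gb)
    return key.where(key.str.strip() != "", pid)


def summarize_signature_counts(entries: pd.DataFrame) -> pd.DataFrame:
    """Distinct-gene up/down counts per (cell line, treatment)."""
    if not len(entries):
        return pd.DataFrame(columns=["cell_line", "treatment", "direction", "n_genes"])
    df = entries.copy()
    df["gene"] = gene_key(df)
    counts = (
        df.groupby(["cell_line", "treatment", "direction"])["gene"]
        .nunique().reset_index(name="n_genes")
    )
    return counts


def annotate_signature_with_q(
    entries: pd.DataFrame,
    sam_results: dict,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Join per-condition SAM q-values onto signature entries.

    ``sam_results`` maps (cell_line, treatment) to (SamResult, probe_ids)
    as returned by ``sam.sam_by_condition``.  Entries without SAM coverage
    get NaN q; q is stored clipped to [0, 1] in ``sam_q`` with the raw
    value preserved in ``sam_q_raw``.  ``sam_significant`` flags q <=
    ``q_cutoff``.
    """
    out = entries.copy()
    out["sam_q_raw"] = np.nan
    for (cl, tr), (res, probes) in sam_results.items():
        if res.q is None:
            continue
        qmap = pd.Series(res.q, index=probes)
        mask = (out["cell_line"] == cl) & (out["treatment"] == tr)
        out.loc[mask, "sam_q_raw"] = out.loc[mask, "probe_id"].map(qmap).to_numpy()
    out["sam_q"] = out["sam_q_raw"].clip(0.0, 1.0)
    out["sam_significant"] = out["sam_q"] <= q_cutoff
    out.loc[out["sam_q"].isna(), "sam_significant"] = False
    return out


def write_signature(entries: pd.DataFrame, path) -> None:
    """Signature TSV mirroring the published table layout."""
    cols = [c for c in SIGNATURE_COLUMNS + ["sam_q", "sam_q_raw", "sam_significant"]
            if c in entries.columns]
    entries[cols].to_csv(path, sep="\t", index=False, float_format="%.4f")
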