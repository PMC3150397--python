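"""Cross-study concordance: link a signature to external gene-level tables,
apply presence filters, cluster the concordance matrix, and assign the four
progression clusters.

External study tables carry, per gene symbol, one signed value (a 2log
ratio or a +-1 direction call) for one published comparison: androgen
response in a cell line, tumor vs normal, metastasis vs primary, or
recurrent/therapy-resistant vs untreated disease.  Genes present in enough
studies are hierarchically clustered (distance = 1 - centered Pearson over
pairwise-complete columns, average linkage) and assigned a progression
cluster from their androgen direction and the consensus metastasis-vs-
primary direction:

    (androgen down, met up)   -> cluster 1
    (androgen down, met down) -> cluster 2
    (androgen up,   met down) -> cluster 3
    (androgen up,   met up)   -> cluster 4

Sign ties and no-data genes stay unassigned.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

COMPARISON_CLASSES = (
    "androgen_response", "tumor_vs_normal", "met_vs_primary",
    "resistant_or_recurrent",
)

MAX_CORRELATION_DISTANCE = 2.0


def harmonize_identifiers(
    tables: pd.DataFrame, alias_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Canonicalize symbols: upper-case, strip whitespace, apply aliases;
    duplicate symbols within one study are averaged with a warning."""
    out = tables.copy()
    bad = set(out["comparison_class"]) - set(COMPARISON_CLASSES)
    if bad:
        raise ValueError(f"unknown comparison class(es): {sorted(bad)}")
    out["symbol"] = out["symbol"].astype(str).str.strip().str.upper()
    if alias_map:
        canon = {str(k).strip().upper(): str(v).strip().upper()
                 for k, v in alias_map.items()}
        out["symbol"] = out["symbol"].map(lambda s: canon.get(s, s))
    dup = out.duplicated(["study_id", "symbol"], keep=False)
    if dup.any():
        logger.warning(
            "averaging %d duplicate (study, symbol) rows", int(dup.sum())
        )
        out = (
            out.groupby(["study_id", "comparison_class", "symbol"], as_index=False,
                        sort=False)["value"].mean()
        )
    return out


def presence_filter(
    genes: Sequence[str], tables: pd.DataFrame, min_present: int
) -> list[str]:
    """Genes with a non-missing value in at least ``min_present`` studies
    (order of the input list preserved)."""
    n_studies = tables["study_id"].nunique()
    if min_present > n_studies:
        raise ValueError(
            f"min_present={min_present} exceeds the {n_studies} available studies"
        )
    counts = tables.groupby("symbol")["study_id"].nunique()
    return [g for g in genes if counts.get(g, 0) >= min_present]


def build_concordance_matrix(
    genes: Sequence[str], tables: pd.DataFrame
) -> pd.DataFrame:
    """Genes x studies matrix of signed values; NaN marks missing data.
    Columns are ordered by comparison class then study id."""
    sub = tables[tables["symbol"].isin(set(genes))]
    mat = sub.pivot_table(index="symbol", columns="study_id", values="value")
    mat = mat.reindex([g for g in genes if g in mat.index])
    class_of = tables.drop_duplicates("study_id").set_index("study_id")[
        "comparison_class"]
    order = sorted(mat.columns,
                   key=lambda s: (COMPARISON_CLASSES.index(class_of[s]), s))
    return mat[order]


def correlation_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed distance: 1 - centered Pearson over pairwise-complete
    columns; undefined correlations (zero variance, <2 shared columns) get
    the maximum distance 2."""
    x = matrix.to_numpy(float)
    n = x.shape[0]
    d = np.empty(n * (n - 1) // 2)
    k = 0
    warned = False
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(x[i]) & np.isfinite(x[j])
            if both.sum() < 2:
                d[k] = MAX_CORRELATION_DISTANCE
                k += 1
                continue
            xi, xj = x[i, both], x[j, both]
            sdi, sdj = xi.std(), xj.std()
            if sdi == 0 or sdj == 0:
                if not warned:
                    logger.warning("zero-variance row(s); distance set to maximum")
                    warned = True
                d[k] = MAX_CORRELATION_DISTANCE
            else:
                r = np.mean((xi - xi.mean()) * (xj - xj.mean())) / (sdi * sdj)
                d[k] = 1.0 - r
            k += 1
    return d


def hierarchical_cluster(
    matrix: pd.DataFrame, method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerate rows of the concordance matrix.

    All-missing rows are excluded first.  Returns the scipy linkage matrix
    and the deterministic leaf order (labels).
    """
    keep = matrix.notna().any(axis=1)
    mat = matrix[keep]
    if len(mat) < 2:
        raise ValueError("need at least 2 rows with data to cluster")
    d = correlation_distance_matrix(mat)
    z = linkage(d, method=method)
    order = [mat.index[i] for i in leaves_list(z)]
    return z, order


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string of a scipy linkage tree with branch lengths."""
    tree = to_tree(z)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{node.dist:.6g}"
        left, right = rec(node.left), rec(node.right)
        return f"({left},{right}):{node.dist:.6g}"

    node = tree
    left, right = rec(node.left), rec(node.right)
    return f"({left},{right});"


def consensus_direction(values: Sequence[float], zero_band: float = 0.1) -> int:
    """Strict sign majority of non-missing entries; |value| < zero_band is
    treated as no direction.  Returns +1, -1 or 0 (tie / no data)."""
    v = np.asarray([x for x in values if np.isfinite(x)], float)
    pos = int(np.sum(v >= zero_band))
    neg = int(np.sum(v <= -zero_band))
    if pos > neg:
        return 1
    if neg > pos:
        return -1
    return 0


def assign_progression_cluster(
    androgen_dir: str, met_values: Sequence[float], zero_band: float = 0.1
) -> int | str:
    """Map (androgen direction, met-vs-primary consensus) to clusters 1-4."""
    if androgen_dir not in ("up", "down"):
        raise ValueError(f"androgen_dir must be 'up' or 'down', got {androgen_dir!r}")
    met = consensus_direction(met_values, zero_band=zero_band)
    if met == 0:
        return "unassigned"
    mapping = {("down", 1): 1, ("down", -1): 2, ("up", -1): 3, ("up", 1): 4}
    return mapping[(androgen_dir, met)]


def assign_progression_clusters(
    signature_directions: pd.Series,
    tables: pd.DataFrame,
    zero_band: float = 0.1,
) -> pd.DataFrame:
    """Cluster assignment for every gene with an androgen direction.

    ``signature_directions`` maps symbol -> 'up'/'down'; ``tables`` is a
    harmonized study table from which the met_vs_primary columns are used.
    """
    met = tables[tables["comparison_class"] == "met_vs_primary"]
    rows = []
    for gene, adir in signature_directions.items():
        vals = met.loc[met["symbol"] == gene, "value"].to_numpy()
        rows.append({
            "symbol": gene,
            "androgen_direction": adir,
            "cluster": assign_progression_cluster(adir, vals, zero_band=zero_band),
        })
    return pd.DataFrame(rows)


def export_cdt(matrix: pd.DataFrame, path, leaf_order: Sequence[str] | None = None) -> None:
    """Tab-delimited clustered-data-table style export for heat-map viewers."""
    mat = matrix.reindex(leaf_order) if leaf_order is not None else matrix
    out = mat.reset_index()
    out.insert(0, "GID", [f"GENE{i}X" for i in range(len(out))])
    out = out.rename(columns={out.columns[1]: "NAME"})
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
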