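"""Quantitative RT-PCR arm: standard curves, Ct-to-quantity conversion,
reference-gene normalization, and ordered-group comparisons.

Quantities are read off a per-gene standard curve fitted to a serial
dilution series (Ct regressed on log10 input quantity).  Expression is
normalized either to a single housekeeping reference (GAPDH) or to the
arithmetic mean of two references (PBGD + GAPDH) relative to a calibrator
sample.  Group differences use the two-sided Mann-Whitney test (exact for
small groups) and a post linear-trend test across ordered disease-stage
groups (ANOVA linear contrast with equally spaced scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: disease-stage groups of the tissue panel, in progression order
TISSUE_GROUPS = ("NAP", "LG-PC", "HG-PC", "LNmet", "HNPC", "HRPC")


@dataclass(frozen=True)
class StandardCurve:
    slope: float       # Ct per log10(quantity); < 0 for a valid curve
    intercept: float   # Ct at unit quantity
    r2: float
    efficiency: float  # 10^(-1/slope) - 1; 1.0 = perfect doubling

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")


def fit_standard_curve(
    log10_quantity: Sequence[float], ct: Sequence[float]
) -> StandardCurve:
    """Least-squares line of Ct on log10(quantity) from a dilution series.

    Requires >= 3 distinct dilution points; warns when the implied
    amplification efficiency is outside [0.8, 1.1].
    """
    x = np.asarray(log10_quantity, float)
    y = np.asarray(ct, float)
    if x.size != y.size:
        raise ValueError("log10_quantity and ct must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct dilution points")
    fit = stats.linregress(x, y)
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    if not (0.8 <= eff <= 1.1):
        logger.warning("amplification efficiency %.3f outside [0.8, 1.1]", eff)
    return StandardCurve(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2, efficiency=float(eff),
    )


def quantify_from_ct(ct, curve: StandardCurve):
    """Quantity = 10^((ct - intercept) / slope); accepts scalars or arrays."""
    ct = np.asarray(ct, float)
    q = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return float(q) if q.ndim == 0 else q


def collapse_replicate_wells(records: pd.DataFrame, curve_by_gene: Mapping[str, StandardCurve]) -> pd.DataFrame:
    """Convert well-level Cts to quantities and average replicate wells on
    the quantity scale, per (sample, gene)."""
    df = records.copy()
    df["quantity"] = [
        quantify_from_ct(ct, curve_by_gene[g]) for ct, g in zip(df["ct"], df["gene"])
    ]
    return (
        df.groupby(["sample_id", "group", "gene"], as_index=False, sort=False)
        ["quantity"].mean()
    )


def normalize_expression(
    target_qty: float,
    reference_qtys: Sequence[float],
    mode: str = "single_ref",
    calibrator_value: float | None = None,
    ref_combine: str = "arithmetic",
) -> float:
    """Normalized gene expression (n.g.e.).

    ``single_ref``: target / reference (one housekeeping gene).
    ``dual_ref_calibrated``: (target / mean of the two references) divided
    by ``calibrator_value`` — the same ratio computed on the calibrator
    sample — so the calibrator itself maps to 1.
    """
    refs = np.asarray(reference_qtys, float)
    if np.any(refs <= 0):
        raise ValueError(f"nonpositive reference quantity: {refs.tolist()}")
    if mode == "single_ref":
        return float(target_qty / refs[0])
    if mode == "dual_ref_calibrated":
        if calibrator_value is None or calibrator_value <= 0:
            raise ValueError("dual_ref_calibrated mode needs a positive calibrator_value")
        ref = float(np.mean(refs)) if ref_combine == "arithmetic" else float(
            stats.gmean(refs))
        return float((target_qty / ref) / calibrator_value)
    raise ValueError(f"unknown mode {mode!r}")


def linear_trend_test(groups: Sequence[Sequence[float]]) -> float:
    """Two-sided p for the linear contrast of group means with equally
    spaced scores (the ANOVA partition used as a post test for trend)."""
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([len(g) for g in groups])
    if np.any(ns < 2):
        raise ValueError("each group needs >= 2 observations for the trend test")
    means = np.array([np.mean(g) for g in groups])
    scores = np.arange(1, k + 1, dtype=float)
    c = scores - scores.mean()
    big_n = int(ns.sum())
    ss_within = sum(np.sum((np.asarray(g) - m) ** 2) for g, m in zip(groups, means))
    df_within = big_n - k
    if ss_within == 0:
        logger.warning("zero within-group variance; trend p reported as 0")
        return 0.0
    ms_within = ss_within / df_within
    contrast = float(np.sum(c * means))
    se = np.sqrt(ms_within * np.sum(c ** 2 / ns))
    t = contrast / se
    return float(2.0 * stats.t.sf(abs(t), df_within))


def jonckheere_terpstra(groups: Sequence[Sequence[float]]) -> float:
    """Nonparametric ordered-alternative test (normal approximation),
    offered as an alternative to the parametric trend contrast."""
    gs = [np.asarray(g, float) for g in groups]
    j = sum(
        np.sum(gs[a][:, None] < gs[b][None, :]) + 0.5 * np.sum(gs[a][:, None] == gs[b][None, :])
        for a, b in combinations(range(len(gs)), 2)
    )
    ns = np.array([g.size for g in gs])
    n = ns.sum()
    mean = (n ** 2 - np.sum(ns ** 2)) / 4.0
    var = (n ** 2 * (2 * n + 3) - np.sum(ns ** 2 * (2 * ns + 3))) / 72.0
    z = (j - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def compare_groups(
    values: pd.DataFrame,
    group_order: Sequence[str] = TISSUE_GROUPS,
    value_col: str = "quantity",
    exact_max_n: int = 8,
    trend: str = "linear_contrast",
) -> tuple[pd.DataFrame, dict]:
    """Pairwise Mann-Whitney two-sided p-values and an across-group trend p.

    Exact Mann-Whitney null distribution for small tie-free groups (both
    n <= ``exact_max_n``), normal approximation with tie correction
    otherwise.  Groups with fewer than 2 observations are skipped with a
    warning.  ``trend`` is 'linear_contrast' or 'jonckheere'.
    """
    present = [g for g in group_order if g in set(values["group"])]
    data = {g: values.loc[values["group"] == g, value_col].to_numpy(float)
            for g in present}
    rows = []
    for g1, g2 in combinations(present, 2):
        a, b = data[g1], data[g2]
        if a.size < 2 or b.size < 2:
            logger.warning("group %s or %s has < 2 observations; pair skipped", g1, g2)
            continue
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = ("exact" if a.size <= exact_max_n and b.size <= exact_max_n
                  and not ties else "asymptotic")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"group1": g1, "group2": g2, "n1": a.size, "n2": b.size,
                     "U": float(res.statistic), "p": float(res.pvalue),
                     "method": method})
    pairs = pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2", "U",
                                        "p", "method"])
    trend_groups = [data[g] for g in present if data[g].size >= 2]
    trend_report = {"groups": [g for g in present if data[g].size >= 2]}
    if len(trend_groups) >= 2:
        if trend == "jonckheere":
            trend_report["p"] = jonckheere_terpstra(trend_groups)
            trend_report["test"] = "jonckheere_terpstra"
        else:
            trend_report["p"] = linear_trend_test(trend_groups)
            trend_report["test"] = "linear_contrast"
    else:
        trend_report["p"] = np.nan
        trend_report["test"] = "skipped"
    return pairs, trend_report


def simulate_qpcr_panel(
    genes: Sequence[str] = ("ACSL3", "ENDOD1", "MCCC2"),
    group_sizes: Mapping[str, int] | None = None,
    trend_log2: Mapping[str, float] | None = None,
    noise_sd_log2: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic Ct tables with dilution series for the tissue-panel arm.

    Emulates the study's panel sizes (21 normal-adjacent, 52 low-grade, 21
    high-grade, 13 node metastases, plus hormone-naive/resistant primary
    groups) with per-gene log2 expression trends across progression stages;
    individual biological scatter dominates, as it did in the real panel.
    Returns (ct_records, dilution_series), both well-level TSV-ready.
    """
    rng = np.random.default_rng(seed)
    if group_sizes is None:
        group_sizes = {"NAP": 21, "LG-PC": 52, "HG-PC": 21, "LNmet": 13,
                       "HNPC": 12, "HRPC": 9}
    if trend_log2 is None:
        # down-regulation with progression for ACSL3/ENDOD1, biphasic MCCC2
        trend_log2 = {
            "ACSL3": -0.8, "ENDOD1": -1.0, "MCCC2": 0.0,
        }
    slope_true = -1.0 / np.log10(2.0)  # perfect doubling
    ct_rows, dil_rows = [], []
    all_genes = list(genes) + ["GAPDH", "PBGD"]
    for gene in all_genes:
        intercept = rng.uniform(30.0, 36.0)
        for lq in np.linspace(-3, 0, 7):
            ct = intercept + slope_true * lq + rng.normal(0, 0.1)
            dil_rows.append({"gene": gene, "log10_quantity": round(float(lq), 3),
                             "ct": round(float(ct), 3)})
        for gi, (group, n) in enumerate(group_sizes.items()):
            stage = gi / max(1, len(group_sizes) - 1)
            if gene in ("GAPDH", "PBGD"):
                mu = 0.0
            elif gene == "MCCC2":
                # biphasic: up in early-stage disease, back down late
                mu = 1.2 * np.sin(np.pi * stage)
            else:
                mu = trend_log2[gene] * stage
            for s in range(n):
                sample = f"{group}_{s+1:02d}"
                expr = 2.0 ** (mu + rng.normal(0, noise_sd_log2))
                for well in (1, 2):
                    ct = intercept + slope_true * np.log10(expr) + rng.normal(0, 0.15)
                    ct_rows.append({
                        "sample_id": sample, "group": group, "gene": gene,
                        "ct": round(float(ct), 3), "well": well,
                    })
    return (pd.DataFrame(ct_rows), pd.DataFrame(dil_rows))
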