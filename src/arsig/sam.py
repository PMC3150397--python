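"""One-class Significance Analysis of Microarrays (SAM) on pooled log-ratios.

Each gene contributes one vector of treated/vehicle 2log ratios (here the 6
values of one condition: 3 time points x 2 dye-swap replicates, pooled
because the time effect is negligible).  The statistic is

    d = mean(x) / (s + s0),   s = sd(x) / sqrt(n),

with the exchangeability factor s0 chosen from candidate percentiles of the
s distribution by minimizing the coefficient of variation of the median
absolute d across windows of s (the Tusher procedure).  The null is built
by sign-flip permutations of each gene's vector — exhaustive (2^n) when n
is small, otherwise sampled.  For a threshold delta, genes are called where
the sorted observed d departs from the permutation-expected order statistic
by more than delta; the false discovery rate at delta is

    FDR(delta) = pi0 * median over permutations of false calls / calls,

with pi0 = min(1, 2 * fraction of observed d inside the central permuted
quartiles).  A gene's q-value is the smallest FDR at which it is called,
made monotone in |d|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SamResult", "sam_statistics", "sam_permutation_fdr", "choose_s0"]


@dataclass
class SamResult:
    d: np.ndarray               # per-gene statistic
    s: np.ndarray               # per-gene standard error of the mean ratio
    xbar: np.ndarray            # per-gene mean ratio
    s0: float                   # exchangeability (fudge) factor
    n: int                      # values per gene
    q: np.ndarray | None = None
    pi0: float | None = None
    delta_table: pd.DataFrame | None = None
    genes: np.ndarray | None = field(default=None)  # optional labels

    def significant(self, q_cutoff: float = 0.05) -> np.ndarray:
        if self.q is None:
            raise ValueError("q-values not computed; run sam_permutation_fdr first")
        return self.q <= q_cutoff


def _d_stat(x: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = x.shape[1]
    xbar = x.mean(axis=1)
    s = x.std(axis=1, ddof=1) / np.sqrt(n)
    denom = s + s0
    if np.any(denom == 0):
        raise ValueError(
            "zero-variance gene with s0 = 0: d undefined; use a positive s0"
        )
    return xbar / denom, s, xbar


def choose_s0(
    xbar: np.ndarray,
    s: np.ndarray,
    percentiles: np.ndarray | None = None,
    n_windows: int = 20,
) -> float:
    """Tusher-style s0: the candidate percentile of s minimizing the
    coefficient of variation of MAD(d) across s-quantile windows."""
    if percentiles is None:
        percentiles = np.arange(0, 101, 5)
    cands = np.percentile(s, percentiles)
    # windows of genes by s quantile
    n_windows = max(2, min(n_windows, len(s) // 5)) if len(s) >= 10 else 2
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best_s0, best_cv = float(cands[-1]), np.inf
    for s0 in cands:
        if s0 == 0 and np.any(s == 0):
            continue
        d = xbar / (s + s0)
        mads = []
        for w in range(n_windows):
            dw = d[idx == w]
            if dw.size >= 2:
                med = np.median(dw)
                mads.append(np.median(np.abs(dw - med)) / 0.6745)
        mads = np.asarray(mads)
        if mads.size < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads, ddof=1) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_statistics(
    x: np.ndarray,
    s0: float | None = None,
    s0_percentiles: np.ndarray | None = None,
    genes: np.ndarray | None = None,
) -> SamResult:
    """Compute d, s and (unless given) the automatically selected s0.

    ``x`` is a (genes, values) matrix of pooled 2log ratios; every gene
    needs at least 2 finite values.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("x must be 2-D with >= 2 values per gene")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    n = x.shape[1]
    xbar = x.mean(axis=1)
    s = x.std(axis=1, ddof=1) / np.sqrt(n)
    if s0 is None:
        s0 = choose_s0(xbar, s, percentiles=s0_percentiles)
    d, s, xbar = _d_stat(x, float(s0))
    return SamResult(d=d, s=s, xbar=xbar, s0=float(s0), n=n,
                     genes=None if genes is None else np.asarray(genes))


def sign_flip_matrix(
    n: int, n_permutations: int | str, rng: np.random.Generator
) -> np.ndarray:
    """(B, n) matrix of +-1 sign vectors: all 2^n when exhaustive (or when a
    requested count covers them), otherwise sampled."""
    full = 2 ** n
    if n_permutations == "exhaustive" or (
        isinstance(n_permutations, (int, np.integer)) and n_permutations >= full
    ):
        bits = ((np.arange(full)[:, None] >> np.arange(n)) & 1)
        return 1.0 - 2.0 * bits
    b = int(n_permutations)
    return rng.choice([-1.0, 1.0], size=(b, n))


def _cuts(d_sorted: np.ndarray, dbar: np.ndarray, delta: float) -> tuple[float, float]:
    """SAM quantile-quantile cuts: smallest d whose excess over the expected
    order statistic reaches delta (upper), and the mirror image (lower)."""
    diff = d_sorted - dbar
    up = d_sorted[diff >= delta]
    cutup = float(up.min()) if up.size else np.inf
    down = d_sorted[-diff >= delta]
    cutlow = float(down.max()) if down.size else -np.inf
    return cutup, cutlow


def sam_permutation_fdr(
    x: np.ndarray,
    result: SamResult | None = None,
    n_permutations: int | str = "exhaustive",
    fdr_target: float = 0.05,
    seed: int | None = None,
    max_deltas: int = 200,
    deltas: np.ndarray | None = None,
) -> SamResult:
    """Attach permutation q-values and the delta table to a SAM result.

    The null is generated by sign-flipping each gene's pooled vector (the
    one-class null of no mean effect); the same s0 is reused for permuted
    statistics.  Raises on fewer than 10 requested permutations.  The delta
    grid defaults to the observed |d - expected order statistic| values
    (thinned to ``max_deltas``); pass ``deltas`` to evaluate a fixed grid.
    """
    x = np.asarray(x, dtype=float)
    if result is None:
        result = sam_statistics(x)
    if isinstance(n_permutations, (int, np.integer)) and n_permutations < 10:
        raise ValueError("n_permutations must be >= 10 (or 'exhaustive')")
    rng = np.random.default_rng(seed)
    n_genes, n = x.shape

    signs = sign_flip_matrix(n, n_permutations, rng)
    B = signs.shape[0]
    # permuted d fully recomputed per sign vector e: mean(e*x) changes and so
    # does sd(e*x); only the sum of squares is flip-invariant, which gives
    # var_e = (sum(x^2) - n*mean_e^2) / (n - 1)
    mean_perm = x @ signs.T / n                     # (genes, B)
    ssq = np.sum(x * x, axis=1)                     # (genes,)
    var_perm = (ssq[:, None] - n * mean_perm**2) / (n - 1)
    s_perm = np.sqrt(np.maximum(var_perm, 0.0)) / np.sqrt(n)
    d_perm = mean_perm / (s_perm + result.s0)       # (genes, B)
    d_perm_sorted = np.sort(d_perm, axis=0)
    dbar = d_perm_sorted.mean(axis=1)               # expected order statistics

    order = np.argsort(result.d, kind="stable")
    d_sorted = result.d[order]

    q25, q75 = np.percentile(d_perm, [25, 75])
    pi0 = min(1.0, 2.0 * float(np.mean((result.d > q25) & (result.d < q75))))

    if deltas is None:
        diffs = np.abs(d_sorted - dbar)
        deltas = np.unique(np.concatenate([[0.0], diffs]))
        if deltas.size > max_deltas:
            deltas = np.quantile(deltas, np.linspace(0, 1, max_deltas))
            deltas = np.unique(np.concatenate([[0.0], deltas]))
    else:
        deltas = np.sort(np.asarray(deltas, dtype=float))

    q = np.full(n_genes, 1.0)
    table = []
    for delta in deltas:
        cutup, cutlow = _cuts(d_sorted, dbar, float(delta))
        called = (result.d >= cutup) | (result.d <= cutlow)
        n_called = int(called.sum())
        if n_called == 0:
            table.append({"delta": float(delta), "genes_called": 0,
                          "median_false_called": 0.0, "FDR": 0.0})
            continue
        false_counts = ((d_perm >= cutup) | (d_perm <= cutlow)).sum(axis=0)
        med_false = float(np.median(false_counts))
        fdr = min(1.0, pi0 * med_false / n_called)
        table.append({"delta": float(delta), "genes_called": n_called,
                      "median_false_called": med_false, "FDR": fdr})
        q[called] = np.minimum(q[called], fdr)

    # enforce monotonicity: larger |d| never gets a larger q
    by_abs = np.argsort(-np.abs(result.d), kind="stable")
    q[by_abs] = np.maximum.accumulate(q[by_abs])
    q = np.clip(q, 0.0, 1.0)

    result.q = q
    result.pi0 = pi0
    result.delta_table = pd.DataFrame(table)
    return result


def sam_by_condition(
    ratios: pd.DataFrame,
    n_permutations: int | str = "exhaustive",
    seed: int | None = None,
    s0: float | None = None,
) -> dict[tuple[str, str], tuple[SamResult, np.ndarray]]:
    """Run one-class SAM per (cell line, treatment) on pooled per-replicate
    ratios (columns probe_id, cell_line, treatment, time_h, replicate, M).

    Only probes with all pooled values present enter each condition's run.
    Returns {(cell_line, treatment): (SamResult, probe_ids)}.
    """
    out: dict[tuple[str, str], tuple[SamResult, np.ndarray]] = {}
    for (cl, tr), grp in ratios.groupby(["cell_line", "treatment"], sort=True):
        mat = grp.pivot_table(
            index="probe_id", columns=["time_h", "replicate"], values="M"
        )
        mat = mat.dropna(axis=0)
        if mat.empty:
            continue
        res = sam_statistics(mat.to_numpy(), s0=s0, genes=mat.index.to_numpy())
        res = sam_permutation_fdr(
            mat.to_numpy(), res, n_permutations=n_permutations, seed=seed
        )
        out[(cl, tr)] = (res, mat.index.to_numpy())
    return out
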