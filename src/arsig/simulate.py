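"""Synthetic two-color androgen-stimulation experiments with planted truth.

The generator emulates the hybridization design of the PC346 panel: four
cell lines with distinct androgen-receptor (AR) states, stimulated with the
synthetic androgen R1881 (1 nM) or the antiandrogen hydroxyflutamide (OHF,
1 uM) against a time-matched vehicle control at 4, 8 and 16 h, two
biological replicates per condition hybridized in dye-swap.  PC346DCC
(vestigial AR) receives the R1881 arm only.  Each co-hybridized array
yields a spot table with Cy3/Cy5 intensities; intensity-dependent dye bias
and a censored low-intensity spot fraction are planted so the downstream
normalization and QC stages have something real to remove.

Every responsive probe's per-condition effect is recorded in a truth table,
which `evaluate_against_truth` scores signature calls against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CELL_LINES = ("PC346C", "PC346DCC", "PC346Flu1", "PC346Flu2")
TREATMENTS = ("R1881", "OHF")
TIME_POINTS_H = (4, 8, 16)

#: conditions actually hybridized: PC346DCC was stimulated with R1881 only
CONDITIONS = tuple(
    (cl, tr)
    for cl in CELL_LINES
    for tr in TREATMENTS
    if not (cl == "PC346DCC" and tr == "OHF")
)


def _default_r1881_multipliers() -> dict[str, float]:
    # Quantitative stand-ins for the panel's qualitative androgen response:
    # wild-type AR responds, vestigial AR (DCC) does not, AR overexpression
    # (Flu1) super-activates, the T877A mutant (Flu2) responds like wild type.
    return {"PC346C": 1.0, "PC346DCC": 0.0, "PC346Flu1": 2.5, "PC346Flu2": 1.0}


def _default_flut_agonism() -> dict[str, float]:
    # Only the T877A mutant receptor is activated by hydroxyflutamide,
    # and more weakly than by R1881.
    return {"PC346C": 0.0, "PC346DCC": 0.0, "PC346Flu1": 0.0, "PC346Flu2": 0.6}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    ``noise_sd`` is the standard deviation, in 2log units, of a single
    spot's observed log-ratio M; each channel receives independent noise of
    sd ``noise_sd / sqrt(2)``.  ``base_effect`` times the per-line
    multiplier gives the planted 2log effect of a responsive probe in that
    (cell line, treatment) arm.
    """

    n_probes: int = 2000
    n_subarrays: int = 4
    frac_responsive: float = 0.05
    base_effect: float = 1.0
    ar_response_multiplier: Mapping[str, float] = field(
        default_factory=_default_r1881_multipliers
    )
    flut_agonism: Mapping[str, float] = field(default_factory=_default_flut_agonism)
    dye_bias_amplitude: float = 0.3
    noise_sd: float = 0.25
    frac_low_intensity: float = 0.30
    frac_spot_dropout: float = 0.002
    frac_down: float = 0.3
    frac_control: float = 0.02
    time_multipliers: Sequence[float] = (1.0, 1.0, 1.0)
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    censored_baseline_mean: float = 6.0
    censored_baseline_sd: float = 0.5
    censor_responsive: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_probes", "n_subarrays"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("frac_responsive", "frac_low_intensity", "frac_spot_dropout",
                     "frac_down", "frac_control"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dye_bias_amplitude < 0:
            raise ValueError("dye_bias_amplitude must be >= 0")
        if len(self.time_multipliers) != len(TIME_POINTS_H):
            raise ValueError("time_multipliers must have one entry per time point")
        for m in (self.ar_response_multiplier, self.flut_agonism):
            missing = [cl for cl in CELL_LINES if cl not in m]
            if missing:
                raise ValueError(f"multiplier map missing cell lines: {missing}")
            neg = {k: v for k, v in m.items() if v < 0}
            if neg:
                raise ValueError(f"multipliers must be nonnegative: {neg}")

    def effect_multiplier(self, cell_line: str, treatment: str) -> float:
        if treatment == "R1881":
            return float(self.ar_response_multiplier[cell_line])
        return float(self.flut_agonism[cell_line])


def build_design() -> pd.DataFrame:
    """The hybridization design: one array per condition x time x replicate.

    Replicate 1 carries the stimulated sample in Cy3, replicate 2 is the
    dye-swap (stimulated in Cy5).
    """
    rows = []
    for cl, tr in CONDITIONS:
        for t in TIME_POINTS_H:
            for rep, orient in ((1, "stim_cy3"), (2, "stim_cy5")):
                rows.append({
                    "array_id": f"{cl}_{tr}_{t}h_r{rep}",
                    "cell_line": cl,
                    "treatment": tr,
                    "time_h": t,
                    "replicate": rep,
                    "dye_orientation": orient,
                })
    return pd.DataFrame(rows)


def generate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate spot tables for every array, the design table, and the truth.

    Returns
    -------
    spots : DataFrame
        One row per (array, spot): array_id, subarray_id, probe_id,
        genbank_id, symbol, control_flag, cy3, cy5.
    design : DataFrame
        Array annotations (cell line, treatment, time, replicate, dye
        orientation).
    truth : DataFrame
        Long table (probe_id, cell_line, treatment, true_effect) listing
        every responsive probe's planted 2log effect in each hybridized
        condition; probes absent from the table are all-zero by
        construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes

    probe_id = np.array([f"P{i:06d}" for i in range(n)])
    genbank = np.array([f"SYN{i:06d}" for i in range(n)])
    symbol = np.array([f"G{i:05d}" for i in range(n)])
    subarray = np.array([f"S{i % config.n_subarrays + 1}" for i in range(n)])

    n_control = int(round(config.frac_control * n))
    control = np.zeros(n, dtype=bool)
    if n_control:
        control[rng.choice(n, size=n_control, replace=False)] = True
        symbol = symbol.copy()
        symbol[control] = ""

    eligible = np.flatnonzero(~control)
    n_resp = int(round(config.frac_responsive * n))
    n_resp = min(n_resp, eligible.size)
    responsive = rng.choice(eligible, size=n_resp, replace=False)
    responsive.sort()
    sign = np.where(rng.random(n_resp) < config.frac_down, -1.0, 1.0)

    # Low-intensity censored probes: by default drawn outside the responsive
    # set so planted positives remain recoverable after the >50% rule.
    pool = eligible if config.censor_responsive else np.setdiff1d(eligible, responsive)
    n_low = min(int(round(config.frac_low_intensity * n)), pool.size)
    censored = rng.choice(pool, size=n_low, replace=False) if n_low else np.array([], int)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)
    if n_low:
        baseline[censored] = rng.normal(
            config.censored_baseline_mean, config.censored_baseline_sd, n_low
        )

    # Per-probe effect per condition (2log units), constant across time up
    # to the optional kinetics multipliers.
    effect = {}  # (cell_line, treatment) -> length-n vector
    truth_rows = []
    for cl, tr in CONDITIONS:
        e = np.zeros(n)
        e[responsive] = sign * config.base_effect * config.effect_multiplier(cl, tr)
        effect[(cl, tr)] = e
        for j, p in enumerate(responsive):
            truth_rows.append({
                "probe_id": probe_id[p],
                "cell_line": cl,
                "treatment": tr,
                "true_effect": e[p],
            })
    truth = pd.DataFrame(
        truth_rows, columns=["probe_id", "cell_line", "treatment", "true_effect"]
    )

    design = build_design()
    ch_sd = config.noise_sd / np.sqrt(2.0)
    bias = config.dye_bias_amplitude * np.sin(baseline)  # smooth in expected A
    tmult = dict(zip(TIME_POINTS_H, config.time_multipliers))

    tables = []
    for row in design.itertuples(index=False):
        e = effect[(row.cell_line, row.treatment)] * tmult[row.time_h]
        log_veh = baseline + rng.normal(0.0, ch_sd, n)
        log_stim = baseline + e + rng.normal(0.0, ch_sd, n)
        if row.dye_orientation == "stim_cy3":
            log_cy3, log_cy5 = log_stim, log_veh
        else:
            log_cy3, log_cy5 = log_veh, log_stim
        # dye bias is dye-linked: Cy3 reads high/low as a smooth function of
        # the spot's intensity regardless of which sample it carries
        cy3 = np.maximum(2.0 ** (log_cy3 + bias / 2.0), 0.0)
        cy5 = np.maximum(2.0 ** (log_cy5 - bias / 2.0), 0.0)
        if config.frac_spot_dropout > 0:
            drop = rng.random(n) < config.frac_spot_dropout
            n_drop = int(drop.sum())
            if n_drop:
                cy3[drop] = rng.uniform(20.0, 150.0, n_drop)
                cy5[drop] = rng.uniform(20.0, 150.0, n_drop)
        tables.append(pd.DataFrame({
            "array_id": row.array_id,
            "subarray_id": subarray,
            "probe_id": probe_id,
            "genbank_id": genbank,
            "symbol": symbol,
            "control_flag": control,
            "cy3": cy3,
            "cy5": cy5,
        }))

    spots = pd.concat(tables, ignore_index=True)
    return spots, design, truth


def probe_annotation(spots: pd.DataFrame) -> pd.DataFrame:
    """Per-probe genbank/symbol/control annotation from a spot table."""
    cols = ["probe_id", "genbank_id", "symbol", "control_flag"]
    return spots[cols].drop_duplicates("probe_id").reset_index(drop=True)


def evaluate_against_truth(
    signature: pd.DataFrame,
    truth: pd.DataFrame,
    probes: Sequence[str],
) -> pd.DataFrame:
    """Score signature calls against the planted truth, per condition.

    Parameters
    ----------
    signature : DataFrame
        Calls with columns probe_id, cell_line, treatment (extra columns
        ignored).  May be empty.
    truth : DataFrame
        As returned by :func:`generate_experiment`; probes absent from it
        count as all-zero.
    probes : sequence of str
        The full probe universe, needed for false-negative/TN counts.

    Returns
    -------
    DataFrame with one row per hybridized condition: tp, fp, fn, precision,
    recall and the false-discovery proportion FDP = FP / (FP + TP) (defined
    as 0 when there are no calls).
    """
    universe = set(probes)
    if len(signature):
        unknown = sorted(set(signature["probe_id"]) - universe)
        if unknown:
            raise ValueError(f"signature contains unknown probe ids: {unknown[:10]}")
    unknown_truth = sorted(set(truth["probe_id"]) - universe)
    if unknown_truth:
        raise ValueError(f"truth contains unknown probe ids: {unknown_truth[:10]}")

    rows = []
    for cl, tr in CONDITIONS:
        t = truth[(truth["cell_line"] == cl) & (truth["treatment"] == tr)]
        positives = set(t.loc[t["true_effect"] != 0.0, "probe_id"])
        if len(signature):
            called = set(
                signature.loc[
                    (signature["cell_line"] == cl) & (signature["treatment"] == tr),
                    "probe_id",
                ]
            )
        else:
            called = set()
        tp = len(called & positives)
        fp = len(called - positives)
        fn = len(positives - called)
        rows.append({
            "cell_line": cl,
            "treatment": tr,
            "n_true": len(positives),
            "n_called": len(called),
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / (tp + fp) if (tp + fp) else 0.0,
            "recall": tp / (tp + fn) if (tp + fn) else 0.0,
            "fdp": fp / (fp + tp) if (fp + tp) else 0.0,
        })
    return pd.DataFrame(rows)


def simulate_pooled_ratios(
    n_genes: int,
    n_responsive: int,
    effect: float,
    noise_sd: float,
    n_values: int = 6,
    frac_down: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly simulate per-gene pooled log-ratio vectors for SAM studies.

    Emulates the pooled one-class input (3 time points x 2 replicates = 6
    treated/control contrasts per gene) without the array layer.  Returns
    the (n_genes, n_values) matrix and the boolean responsive mask.
    """
    if n_responsive > n_genes:
        raise ValueError("n_responsive cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    mu = np.zeros(n_genes)
    resp = np.zeros(n_genes, dtype=bool)
    idx = rng.choice(n_genes, size=n_responsive, replace=False)
    resp[idx] = True
    sgn = np.where(rng.random(n_responsive) < frac_down, -1.0, 1.0)
    mu[idx] = sgn * effect
    x = mu[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_values))
    return x, resp


# ---------------------------------------------------------------------------
# Synthetic external "study pack" for the cross-database arm

def generate_study_pack(
    signature: pd.DataFrame,
    n_androgen: int = 5,
    n_tumor: int = 7,
    concordance: float = 0.85,
    frac_missing: float = 0.25,
    effect_scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate published gene-level study tables concordant with a signature.

    The real analysis linked the in-house signature to five published
    androgen-response databases and seven prostate-tumor progression
    databases; those tables are not redistributable, so this generates
    stand-ins: per study and gene, a signed 2log value agreeing with the
    gene's androgen direction with probability ``concordance`` and missing
    with probability ``frac_missing``.  Tumor studies are split across the
    progression comparison classes.

    ``signature`` needs columns ``symbol`` and ``direction`` (up/down); one
    row per gene is used (first occurrence wins).
    """
    rng = np.random.default_rng(seed)
    genes = signature.drop_duplicates("symbol")
    genes = genes[genes["symbol"].astype(str) != ""]
    tumor_classes = ["tumor_vs_normal", "met_vs_primary", "resistant_or_recurrent"]
    rows = []
    studies = [(f"AND{i+1:02d}", "androgen_response") for i in range(n_androgen)]
    studies += [(f"TUM{i+1:02d}", tumor_classes[i % len(tumor_classes)])
                for i in range(n_tumor)]
    for study_id, cls in studies:
        for g in genes.itertuples(index=False):
            if rng.random() < frac_missing:
                continue
            base = 1.0 if g.direction == "up" else -1.0
            if cls != "androgen_response":
                # progression studies: androgen-induced genes tend to fall
                # in metastatic/resistant disease, repressed genes to rise
                base = -base if cls != "tumor_vs_normal" else base
            agree = rng.random() < concordance
            val = (base if agree else -base) * effect_scale * rng.uniform(0.5, 1.5)
            rows.append({
                "study_id": study_id,
                "comparison_class": cls,
                "symbol": g.symbol,
                "value": round(float(val), 3),
            })
    return pd.DataFrame(rows, columns=["study_id", "comparison_class", "symbol", "value"])


# ---------------------------------------------------------------------------
# Disk round-trip

def write_experiment(
    outdir: str | Path,
    spots: pd.DataFrame,
    design: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> None:
    """Write spot/design/truth TSVs plus a JSON run manifest (no timestamps,
    so identical seeds give byte-identical trees)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spots.to_csv(outdir / "spots.tsv", sep="\t", index=False, float_format="%.6f")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6f")
    manifest = {"config": {k: (dict(v) if isinstance(v, Mapping) else
                                list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()}}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def read_experiment(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    spots = pd.read_csv(indir / "spots.tsv", sep="\t",
                        dtype={"subarray_id": str, "probe_id": str})
    spots["symbol"] = spots["symbol"].fillna("")
    design = pd.read_csv(indir / "design.tsv", sep="\t")
    truth = pd.read_csv(indir / "truth.tsv", sep="\t")
    return spots, design, truth
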