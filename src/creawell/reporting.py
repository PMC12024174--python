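"""End-to-end pipeline, table formatting and provenance.

Composes the stages simulate -> score -> analyze -> report. The report
reproduces the shapes of the study-style tables: per-variable descriptives
(N, mean, SD), a 13x13 correlation table with r/p/BF10 above the diagonal
and pairwise n below it, and the age-adjusted partial-correlation table with
the +/-0.040 stability screen. Display rounding follows the print
conventions: r to 3 dp, p to 3 dp with "<0.001" below, BF10 to 2 dp with
">100" above; every printed number is also stored at full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, scale_scoring, task_scoring
from .inference import BFSettings, CorrelationResult, PartialCorrelationResult
from .synthetic import CohortBundle, SimulationConfig, config_to_json, generate_cohort
from .variables import ANALYSIS_VARIABLES, VARIABLE_LABELS

__all__ = [
    "RunConfig",
    "ReportBundle",
    "score_bundle",
    "score_files",
    "descriptives",
    "results_frame",
    "partials_frame",
    "render_correlation_table",
    "scatter_plot",
    "run_pipeline",
]

log = logging.getLogger("creawell")


@dataclass
class RunConfig:
    """Everything one pipeline run needs: simulation, inference and I/O settings."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | Path = "creawell_out"
    bf_settings: BFSettings = field(default_factory=BFSettings)
    alpha: float = 0.05
    bf_threshold: float = 3.0
    covariate: str = "age"
    stability_tolerance: float = 0.040
    make_plots: bool = False
    synonyms: dict[str, str] | None = None


@dataclass
class ReportBundle:
    """All result tables of one run, at full stored precision."""

    scores: pd.DataFrame
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    correlation_table: pd.DataFrame
    partials: pd.DataFrame
    stability: pd.DataFrame
    provenance: dict


# --------------------------------------------------------------------------
# Scoring stage
# --------------------------------------------------------------------------

def score_bundle(bundle: CohortBundle, synonyms: dict[str, str] | None = None) -> pd.DataFrame:
    """Score a raw bundle into the participant x 13-variable analysis matrix.

    The age covariate is carried as an extra column. Participants absent from
    the AUT response table are missing on all three AUT indices; participants
    absent from the leisure table score 0 (no endorsed activities).
    """
    return _score_tables(
        demographics=bundle.demographics,
        aut_responses=bundle.aut_responses,
        okc=bundle.okc,
        leisure=bundle.leisure,
        swlsc=bundle.swlsc,
        spane=bundle.spane,
        mhcsf=bundle.mhcsf,
        spq=bundle.spq,
        synonyms=synonyms,
    )


def score_files(in_dir: str | Path, synonyms: dict[str, str] | None = None) -> pd.DataFrame:
    """Score raw CSVs written by the simulate stage (or supplied externally)."""
    p = Path(in_dir)
    return _score_tables(
        demographics=pd.read_csv(p / "demographics.csv"),
        aut_responses=pd.read_csv(p / "aut_responses.csv"),
        okc=pd.read_csv(p / "okc.csv"),
        leisure=pd.read_csv(p / "leisure.csv"),
        swlsc=pd.read_csv(p / "swlsc.csv", index_col="participant_id"),
        spane=pd.read_csv(p / "spane.csv", index_col="participant_id"),
        mhcsf=pd.read_csv(p / "mhcsf.csv", index_col="participant_id"),
        spq=pd.read_csv(p / "spq.csv", index_col="participant_id"),
        synonyms=synonyms,
    )


def _score_tables(
    demographics: pd.DataFrame,
    aut_responses: pd.DataFrame,
    okc: pd.DataFrame,
    leisure: pd.DataFrame,
    swlsc: pd.DataFrame,
    spane: pd.DataFrame,
    mhcsf: pd.DataFrame,
    spq: pd.DataFrame,
    synonyms: dict[str, str] | None = None,
) -> pd.DataFrame:
    roster = demographics["participant_id"].astype(str).tolist()
    out = pd.DataFrame(index=pd.Index(roster, name="participant_id"))
    out["age"] = demographics.set_index(demographics["participant_id"].astype(str))["age"]

    responders = sorted(aut_responses["participant_id"].astype(str).unique())
    responses = task_scoring.AUTResponseSet.from_frame(
        aut_responses, participants=responders, synonyms=synonyms
    )
    aut_scores = task_scoring.score_aut(responses)
    for col in aut_scores.columns:
        out[col] = aut_scores[col]

    okc_idx = okc.set_index(okc["participant_id"].astype(str))
    okc_vals = []
    for pid in roster:
        if pid not in okc_idx.index:
            okc_vals.append(np.nan)
            continue
        flags = okc_idx.loc[pid, ["four_limbs", "two_antennae", "tail"]]
        if flags.isna().any():
            okc_vals.append(np.nan)
        else:
            okc_vals.append(task_scoring.score_okc([int(v) for v in flags]))
    out["okc"] = okc_vals

    leisure_scores = task_scoring.score_leisure(leisure) if len(leisure) else None
    if leisure_scores is not None:
        out["creative_hobbies"] = leisure_scores["creative"].reindex(out.index).fillna(0.0)
    else:
        out["creative_hobbies"] = 0.0

    scales = scale_scoring.score_all_scales(swlsc, spane, mhcsf, spq)
    scales.index = scales.index.astype(str)
    for col in scales.columns:
        out[col] = scales[col]

    return out[["age", *ANALYSIS_VARIABLES]]


# --------------------------------------------------------------------------
# Report tables
# --------------------------------------------------------------------------

def descriptives(scores: pd.DataFrame) -> pd.DataFrame:
    """Per analysis variable: non-missing N, mean, and sample SD (n-1 divisor)."""
    if scores.empty:
        raise ValueError("empty score matrix")
    rows = []
    for var in ANALYSIS_VARIABLES:
        col = scores[var].astype(float)
        rows.append(
            {"variable": var, "label": VARIABLE_LABELS[var],
             "n": int(col.notna().sum()), "mean": float(col.mean()),
             "sd": float(col.std(ddof=1))}
        )
    return pd.DataFrame(rows)


def format_r(r: float) -> str:
    return "" if np.isnan(r) else f"{r:.3f}"


def format_p(p: float) -> str:
    if np.isnan(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_bf(bf: float) -> str:
    if np.isnan(bf):
        return ""
    return ">100" if bf > 100 else f"{bf:.2f}"


_STATUS_MARK = {"supported": "*", "partial_frequentist_only": "+", "none": ""}


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy full-precision table of all pairwise dual-inference results."""
    return pd.DataFrame(
        [
            {"var_x": res.pair[0], "var_y": res.pair[1], "r": res.r, "n": res.n,
             "p": res.p, "bf10": res.bf10, "evidence": res.evidence,
             "status": res.status, "flag": res.flag or ""}
            for res in results
        ]
    )


def partials_frame(partials: list[PartialCorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"var_x": part.pair[0], "var_y": part.pair[1], "covariate": part.covariate,
             "r_partial": part.r_partial, "n": part.n, "p": part.p,
             "zero_order_r": part.zero_order_r,
             "delta_from_zero_order": part.delta_from_zero_order,
             "flag": part.flag or ""}
            for part in partials
        ]
    )


def render_correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """13x13 display table: r (p, BF10) above the diagonal, pairwise n below.

    A trailing ``*`` marks pairs supported by both criteria, ``+`` pairs
    supported by the frequentist criterion only. Cells whose correlation is
    undefined are rendered as explicit blanks. Pure formatting — every value
    comes from the stored result set, nothing is recomputed.
    """
    expected = len(ANALYSIS_VARIABLES) * (len(ANALYSIS_VARIABLES) - 1) // 2
    if len(results) != expected:
        raise ValueError(f"need the full {expected}-pair result set")
    labels = [VARIABLE_LABELS[v] for v in ANALYSIS_VARIABLES]
    table = pd.DataFrame("", index=labels, columns=labels)
    np.fill_diagonal(table.values, "1")
    pos = {v: i for i, v in enumerate(ANALYSIS_VARIABLES)}
    for res in results:
        i, j = pos[res.pair[0]], pos[res.pair[1]]
        i, j = min(i, j), max(i, j)
        if np.isnan(res.r):
            cell = ""
        else:
            cell = (
                f"{format_r(res.r)}{_STATUS_MARK.get(res.status, '')} "
                f"(p={format_p(res.p)}, BF10={format_bf(res.bf10)})"
            )
        table.iloc[i, j] = cell
        table.iloc[j, i] = str(res.n)
    return table


def scatter_plot(scores: pd.DataFrame, var_x: str, var_y: str, path: str | Path) -> None:
    """Basic scatter plot of a pair with a least-squares fit line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = scores[var_x].astype(float)
    y = scores[var_y].astype(float)
    keep = x.notna() & y.notna()
    x, y = x[keep], y[keep]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, s=12, alpha=0.7)
    if len(x) >= 2 and x.std() > 0:
        b, a = np.polyfit(x, y, 1)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, a + b * grid, color="firebrick")
    ax.set_xlabel(VARIABLE_LABELS.get(var_x, var_x))
    ax.set_ylabel(VARIABLE_LABELS.get(var_y, var_y))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> ReportBundle:
    """simulate -> score -> analyze -> report, writing all artifacts to out_dir.

    Deterministic given the configuration (including its seed). Writes a
    provenance block recording the config hash, seed, thresholds and
    per-stage row counts alongside every output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    try:
        log.info("simulate: n=%d seed=%d", config.simulation.n_participants, config.simulation.seed)
        bundle = generate_cohort(config.simulation)
        raw_dir = out / "raw"
        bundle.write_csv(raw_dir)
        counts["participants"] = len(bundle.demographics)
        counts["aut_response_rows"] = len(bundle.aut_responses)
        counts["leisure_rows"] = len(bundle.leisure)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", exc) from exc

    try:
        scores = score_bundle(bundle, synonyms=config.synonyms)
        task_cols = ["aut_fluency", "aut_overall_originality", "aut_peak_originality",
                     "okc", "creative_hobbies"]
        scores[task_cols].to_csv(out / "task_scores.csv")
        scale_cols = ["life_satisfaction", "positive_affect", "negative_affect",
                      "mental_health", "spq_cognitive_perceptual", "spq_interpersonal",
                      "spq_disorganized", "spq_total"]
        scores[scale_cols].to_csv(out / "scale_scores.csv")
        scores.to_csv(out / "score_matrix.csv")
        counts["scored_participants"] = len(scores)
    except Exception as exc:
        raise StageError("score", exc) from exc

    try:
        results = inference.correlation_matrix(
            scores, settings=config.bf_settings,
            alpha=config.alpha, bf_threshold=config.bf_threshold,
        )
        partials = inference.partial_correlations_for_supported(
            scores, results, covariate=config.covariate
        )
        stability = inference.stability_screen(results, partials, config.stability_tolerance)
        counts["correlation_pairs"] = len(results)
        counts["supported_pairs"] = sum(r.status == "supported" for r in results)
        counts["partial_pairs"] = len(partials)
    except Exception as exc:
        raise StageError("analyze", exc) from exc

    try:
        desc = descriptives(scores)
        corr = results_frame(results)
        table = render_correlation_table(results)
        part = partials_frame(partials)
        desc.to_csv(out / "descriptives.csv", index=False)
        corr.to_csv(out / "correlations.csv", index=False)
        table.to_csv(out / "correlation_table.csv")
        part.to_csv(out / "partials.csv", index=False)
        stability.to_csv(out / "stability.csv", index=False)
        provenance = {
            "config_sha256": hashlib.sha256(config_to_json(config.simulation).encode()).hexdigest(),
            "seed": config.simulation.seed,
            "kappa": config.bf_settings.kappa,
            "alpha": config.alpha,
            "bf_threshold": config.bf_threshold,
            "covariate": config.covariate,
            "stability_tolerance": config.stability_tolerance,
            "row_counts": counts,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        if config.make_plots:
            for res in results:
                if res.status == "supported":
                    scatter_plot(scores, *res.pair, out / f"scatter_{res.pair[0]}__{res.pair[1]}.png")
    except Exception as exc:
        raise StageError("report", exc) from exc

    return ReportBundle(
        scores=scores, descriptives=desc, correlations=corr,
        correlation_table=table, partials=part, stability=stability,
        provenance=provenance,
    )
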