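"""Synthetic cohort generator for the creativity-wellbeing-schizotypy pipeline.

The study's raw data are tabular questionnaire and task records from a cohort
of ~76 adolescents and young adults in three age cohorts. This module
generates raw data of exactly that shape from a configurable latent model so
that every downstream stage (task scoring, scale scoring, dual inference,
reporting) can be exercised and validated end to end.

Generative model
----------------
One latent standard-normal vector per participant over the 13 analysis
variables, with correlation matrix ``repair_correlation_matrix(target_rho)``.
Observable layers on top of the latents:

* **Likert items** (SWLS-C, SPANE, MHC-SF, SPQ-BRU): item value =
  ``loading * latent + sqrt(1 - loading^2) * noise`` (marginally standard
  normal), discretized at per-scale-group cut-points. The cut-points are
  calibrated at configuration time (1-D root finding on the exact discretized
  mean) so each scored variable's population mean equals its target; defaults
  target the published cohort descriptives. The SPQ social-anxiety subscale,
  which belongs to none of the three reported factors, is driven by the SPQ
  total latent with the residual target mean so that the 32-item total
  calibrates exactly.
* **AUT responses**: per item, a response count drawn Poisson with rate
  ``fluency_rate * exp(s * latent_fluency - s^2/2)`` (mean exactly
  ``fluency_rate``), and that many distinct use tokens sampled without
  replacement from a Zipf-weighted per-item lexicon. A participant-specific
  Zipf exponent, tilted by the originality latents, makes rarer (tail) tokens
  more likely for participants high in originality, so "uses generated by 10%
  or less of the sample" is a nontrivial tail event.
* **OKC flags**: each of the three primed elements present with calibrated
  probability, probit-driven by the negated OKC latent (higher latent = fewer
  primed elements = higher reversed score).
* **Leisure**: per domain, an activity count Poisson-modulated by the
  creative-hobbies latent (creative domain only) and an i.i.d. frequency
  category per activity; the creative-domain rate is calibrated so the
  expected weighted score equals its target. Counts-times-weights gives the
  strong right skew seen in real leisure scores.
* **Missingness**: instrument-level missing-completely-at-random at
  configured per-instrument rates (whole instruments missing, never single
  items), emulating the pairwise-n pattern of the study's correlation table.

Randomness contract: one root seed; the seed sequence is split in a fixed,
documented order (demographics -> latents -> items -> AUT -> missingness,
with named substreams inside the items stage), so adding later stages never
perturbs earlier draws. Identical configs produce identical bundles.

Overall and peak originality are emergent properties of the lexicon mechanism
and are not mean-calibrated (no coherent target exists for a score bounded in
[0, 1)); all other analysis variables carry calibrated targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.correlation_tools import corr_clipped

from .variables import ANALYSIS_VARIABLES, AUT_ITEMS

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "SCALE_GROUPS",
    "DEFAULT_TARGET_RHO",
    "default_target_rho",
    "default_likert_thresholds",
    "repair_correlation_matrix",
    "generate_cohort",
    "attenuation_factors",
]

# --------------------------------------------------------------------------
# Scale-group definitions: which latent drives which item block, item counts,
# category codings and calibration targets (cohort descriptives).
# --------------------------------------------------------------------------

#: group -> (latent variable, n items, first category value, n categories,
#:           score type, target score mean, target score SD)
SCALE_GROUPS: dict[str, dict] = {
    "swlsc": dict(latent="life_satisfaction", n_items=5, first_cat=1, n_cats=5,
                  score="mean", mean=3.72, sd=0.81),
    "spane_pos": dict(latent="positive_affect", n_items=6, first_cat=1, n_cats=5,
                      score="sum", mean=22.04, sd=3.55),
    "spane_neg": dict(latent="negative_affect", n_items=6, first_cat=1, n_cats=5,
                      score="sum", mean=16.90, sd=4.30),
    "mhcsf": dict(latent="mental_health", n_items=14, first_cat=0, n_cats=6,
                  score="mean", mean=2.91, sd=0.72),
    "spq_cp": dict(latent="spq_cognitive_perceptual", n_items=15, first_cat=1, n_cats=5,
                   score="sum", mean=36.01, sd=8.79),
    "spq_int": dict(latent="spq_interpersonal", n_items=6, first_cat=1, n_cats=5,
                    score="sum", mean=14.81, sd=5.30),
    "spq_dis": dict(latent="spq_disorganized", n_items=7, first_cat=1, n_cats=5,
                    score="sum", mean=26.74, sd=6.06),
    # residual mean so the 32-item total calibrates to 91.49 exactly
    "spq_sa": dict(latent="spq_total", n_items=4, first_cat=1, n_cats=5,
                   score="sum", mean=13.93, sd=3.50),
}

#: age cohorts: (mean, sd, proportion, low, high, label) — cohort structure
#: of the emulated sample (n=76: 38/20/18; overall age 18.34 (1.83)).
DEFAULT_AGE_COHORTS: tuple[tuple, ...] = (
    (16.76, 0.28, 38 / 76, 16.0, 18.0, 1),
    (18.82, 0.39, 20 / 76, 18.0, 20.0, 2),
    (21.15, 0.44, 18 / 76, 20.0, 23.0, 3),
)

DEFAULT_GENDER_PROBS: dict[str, float] = {
    "female": 68 / 76, "male": 7 / 76, "nonbinary": 1 / 76,
}

#: instrument-level MCAR rates emulating the published pairwise-n pattern
#: (SPANE n=72, mental health n=75, SPQ n=72-75 out of 76).
DEFAULT_MISSING_RATES: dict[str, float] = {
    "aut": 0.0, "okc": 0.0, "leisure": 0.0,
    "swlsc": 0.0, "spane": 4 / 76, "mhcsf": 1 / 76, "spq": 4 / 76,
}

#: frequency-category sampling probabilities for leisure activities
#: (category order matches the days-per-week weights 0.5/1.5/3.5/5.5/7).
LEISURE_CATEGORIES: tuple[str, ...] = (
    "less than once", "1-2 days", "3-4 days", "5-6 days", "every day",
)
LEISURE_CATEGORY_PROBS: tuple[float, ...] = (0.25, 0.30, 0.20, 0.15, 0.10)
LEISURE_CATEGORY_WEIGHTS: tuple[float, ...] = (0.5, 1.5, 3.5, 5.5, 7.0)

#: expected activity counts for the non-focal leisure domains
_OTHER_DOMAIN_RATES = {"physical": 1.5, "socializing": 2.0, "sedentary": 3.0}

_CALIBRATION_TARGETS = {
    "aut_fluency": 4.91,
    "okc": 1.59,
    "creative_hobbies": 6.99,
    "life_satisfaction": 3.72,
    "positive_affect": 22.04,
    "negative_affect": 16.90,
    "mental_health": 2.91,
    "spq_cognitive_perceptual": 36.01,
    "spq_interpersonal": 14.81,
    "spq_disorganized": 26.74,
    "spq_total": 91.49,
}

# --------------------------------------------------------------------------
# Default latent correlation structure (published zero-order correlations,
# repaired to the nearest valid correlation matrix).
# --------------------------------------------------------------------------

_UPPER_TRI_RHO: tuple[tuple[float, ...], ...] = (
    (0.320, 0.704, 0.076, -0.111, 0.066, 0.228, -0.043, 0.299, 0.228, 0.125, 0.290, 0.298),
    (0.709, 0.086, 0.206, 0.146, 0.133, 0.212, 0.062, -0.043, -0.073, -0.046, -0.067),
    (0.062, 0.107, 0.144, 0.257, 0.120, 0.221, 0.040, -0.078, 0.152, 0.064),
    (0.040, 0.026, -0.069, -0.101, 0.097, 0.040, 0.000, 0.000, -0.008),
    (0.613, -0.334, 0.554, 0.140, -0.227, -0.400, -0.260, -0.387),
    (-0.327, 0.545, 0.163, -0.042, -0.386, -0.001, -0.124),
    (-0.400, 0.152, 0.552, 0.303, 0.295, 0.490),
    (0.067, -0.265, -0.450, -0.274, -0.406),
    (0.198, 0.177, 0.333, 0.238),
    (0.362, 0.556, 0.852),
    (0.362, 0.673),
    (0.793,),
)


def repair_correlation_matrix(candidate: np.ndarray) -> np.ndarray:
    """Nearest valid correlation matrix by eigenvalue clipping.

    A matrix assembled entry-wise from pairwise correlations need not be
    jointly positive semi-definite. Inputs must be square, symmetric, with
    unit diagonal and off-diagonals in (-1, 1); already-PSD inputs are
    returned unchanged, otherwise negative eigenvalues are clipped and the
    result rescaled back to unit diagonal.
    """
    m = np.asarray(candidate, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    off = m[~np.eye(m.shape[0], dtype=bool)]
    if off.size and (np.abs(off) >= 1.0).any():
        raise ValueError("off-diagonal correlations must lie in (-1, 1)")
    if np.linalg.eigvalsh(m).min() >= -1e-12:
        return m
    repaired = corr_clipped(m, threshold=1e-15)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


def default_target_rho() -> np.ndarray:
    """The published 13x13 zero-order correlation structure, PSD-repaired."""
    k = len(ANALYSIS_VARIABLES)
    m = np.eye(k)
    for i, row in enumerate(_UPPER_TRI_RHO):
        for j, v in enumerate(row, start=i + 1):
            m[i, j] = m[j, i] = v
    return repair_correlation_matrix(m)


DEFAULT_TARGET_RHO = default_target_rho()


def _discretized_mean(mu: float, sigma: float, first_cat: int, n_cats: int) -> float:
    cats = np.arange(first_cat, first_cat + n_cats)
    uppers = (cats[:-1] + 0.5 - mu) / sigma  # boundaries between categories
    cdf = np.concatenate([[0.0], stats.norm.cdf(uppers), [1.0]])
    return float((cats * np.diff(cdf)).sum())


def _group_thresholds(group: dict, item_loading: float) -> np.ndarray:
    """Calibrated cut-points on the standard-normal item scale for one group.

    The item is modelled as round-to-category of a normal with location mu
    and scale sigma; sigma is set from the target score SD under an
    exchangeable-items approximation, and mu is solved so the exact
    discretized item mean equals the target item mean.
    """
    k = group["n_items"]
    target_item_mean = group["mean"] if group["score"] == "mean" else group["mean"] / k
    inter_item = 0.8 * item_loading**2  # discretization-attenuated item correlation
    if group["score"] == "mean":
        sigma = group["sd"] * np.sqrt(k / (1.0 + (k - 1) * inter_item))
    else:
        sigma = group["sd"] / np.sqrt(k * (1.0 + (k - 1) * inter_item))
    sigma = float(np.clip(sigma, 0.5, 1.8))
    first, ncat = group["first_cat"], group["n_cats"]
    lo, hi = first - 4.0, first + ncat + 3.0
    mu = optimize.brentq(
        lambda m: _discretized_mean(m, sigma, first, ncat) - target_item_mean, lo, hi,
        xtol=1e-12,
    )
    cats = np.arange(first, first + ncat)
    return (cats[:-1] + 0.5 - mu) / sigma


def default_likert_thresholds(item_loading: float = 0.7) -> dict[str, np.ndarray]:
    """Calibrated per-scale-group cut-points for the default targets."""
    return {name: _group_thresholds(group, item_loading) for name, group in SCALE_GROUPS.items()}


@dataclass
class SimulationConfig:
    """Full specification of one synthetic cohort.

    Defaults reproduce the emulated study conditions: n=76, three age
    cohorts, the published correlation structure as latent targets, and
    calibrated score means. ``target_rho`` is the *latent* correlation
    matrix; discretization and task noise attenuate the scored correlations.
    Setting ``calibrate_scored_rho=True`` inflates the latent correlations by
    estimated attenuation factors so the *scored* correlations approach the
    targets (off by default).
    """

    n_participants: int = 76
    target_rho: np.ndarray = field(default_factory=default_target_rho)
    age_cohorts: tuple = DEFAULT_AGE_COHORTS
    gender_probs: dict = field(default_factory=lambda: dict(DEFAULT_GENDER_PROBS))
    likert_thresholds: dict = None  # filled from item_loading if omitted
    item_loading: float = 0.7
    okc_loading: float = 0.6
    okc_element_prob: float = (3.0 - 1.59) / 3.0  # per-element presence prob.
    lexicon_size_per_item: int = 60
    zipf_exponent: float = 1.1
    fluency_rate: float = 4.91
    fluency_dispersion: float = 0.17
    originality_tilt: float = 0.35
    hobby_target: float = 6.99
    hobby_dispersion: float = 0.5
    missing_rate_per_instrument: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    calibrate_scored_rho: bool = False
    seed: int = 0
    calibration_targets: dict = field(default_factory=lambda: dict(_CALIBRATION_TARGETS))

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        self.target_rho = np.asarray(self.target_rho, dtype=float)
        if self.target_rho.shape != (len(ANALYSIS_VARIABLES),) * 2:
            raise ValueError("target_rho must be 13x13 over the analysis variables")
        props = [c[2] for c in self.age_cohorts]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("age cohort proportions must sum to 1")
        if self.likert_thresholds is None:
            self.likert_thresholds = default_likert_thresholds(self.item_loading)
        for name, cuts in self.likert_thresholds.items():
            cuts = np.asarray(cuts, dtype=float)
            if not np.all(np.diff(cuts) > 0):
                raise ValueError(f"thresholds for {name!r} must be strictly increasing")
            self.likert_thresholds[name] = cuts
        for inst, rate in self.missing_rate_per_instrument.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missing rate for {inst!r} must be in [0, 1)")
        if self.zipf_exponent <= 0 or self.fluency_rate <= 0 or self.lexicon_size_per_item <= 0:
            raise ValueError("zipf_exponent, fluency_rate, lexicon_size_per_item must be positive")


@dataclass
class CohortBundle:
    """Raw dataset bundle: everything the scoring stages read."""

    demographics: pd.DataFrame
    aut_responses: pd.DataFrame
    swlsc: pd.DataFrame
    spane: pd.DataFrame
    mhcsf: pd.DataFrame
    spq: pd.DataFrame
    okc: pd.DataFrame
    leisure: pd.DataFrame
    latents: pd.DataFrame
    config: SimulationConfig

    _TABLES = ("demographics", "aut_responses", "swlsc", "spane", "mhcsf",
               "spq", "okc", "leisure")

    def write_csv(self, out_dir: str | Path) -> None:
        """Write every table in the CSV dialects the scoring stages read."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demographics.to_csv(out / "demographics.csv", index=False)
        self.aut_responses.to_csv(out / "aut_responses.csv", index=False)
        for name in ("swlsc", "spane", "mhcsf", "spq"):
            getattr(self, name).to_csv(out / f"{name}.csv")
        self.okc.to_csv(out / "okc.csv", index=False)
        self.leisure.to_csv(out / "leisure.csv", index=False)


def _simulate_demographics(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    pids = [f"P{i:05d}" for i in range(1, n + 1)]
    cohorts = rng.choice(len(config.age_cohorts), size=n, p=[c[2] for c in config.age_cohorts])
    means = np.array([config.age_cohorts[c][0] for c in cohorts])
    sds = np.array([config.age_cohorts[c][1] for c in cohorts])
    los = np.array([config.age_cohorts[c][3] for c in cohorts])
    his = np.array([config.age_cohorts[c][4] for c in cohorts])
    labels = np.array([config.age_cohorts[c][5] for c in cohorts])
    ages = np.clip(rng.normal(means, sds), los, his)
    genders = rng.choice(
        list(config.gender_probs), size=n, p=list(config.gender_probs.values())
    )
    return pd.DataFrame(
        {"participant_id": pids, "age": np.round(ages, 2),
         "cohort_label": labels, "gender": genders}
    )


def _simulate_items(
    latent: np.ndarray, cuts: np.ndarray, n_items: int, first_cat: int,
    loading: float, rng: np.random.Generator,
) -> np.ndarray:
    noise = rng.standard_normal((latent.size, n_items))
    u = loading * latent[:, None] + np.sqrt(1.0 - loading**2) * noise
    return first_cat + np.searchsorted(cuts, u.ravel()).reshape(u.shape)


def _simulate_aut(
    config: SimulationConfig,
    pids: list[str],
    lat: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(pids)
    s = config.fluency_dispersion
    rates = config.fluency_rate * np.exp(s * lat["aut_fluency"].to_numpy() - 0.5 * s * s)
    rho_op = float(
        config.target_rho[
            ANALYSIS_VARIABLES.index("aut_overall_originality"),
            ANALYSIS_VARIABLES.index("aut_peak_originality"),
        ]
    )
    denom = np.sqrt(max(2.0 * (1.0 + rho_op), 1e-6))
    tilt_latent = (
        lat["aut_overall_originality"].to_numpy() + lat["aut_peak_originality"].to_numpy()
    ) / denom
    exponents = config.zipf_exponent * np.exp(-config.originality_tilt * tilt_latent)
    v = config.lexicon_size_per_item
    log_rank = np.log(np.arange(1, v + 1))

    rows: list[tuple[str, str, str]] = []
    for item in AUT_ITEMS:
        counts = rng.poisson(rates)
        if counts.max() > v:
            raise ValueError(
                f"lexicon of {v} uses per item is smaller than a requested "
                f"response count of {counts.max()}"
            )
        # Gumbel top-k gives a weighted sample without replacement per row
        keys = -exponents[:, None] * log_rank[None, :] + rng.gumbel(size=(n, v))
        order = np.argsort(-keys, axis=1)
        for i, pid in enumerate(pids):
            for idx in order[i, : counts[i]]:
                rows.append((pid, item, f"{item}_use{idx + 1:02d}"))
    return pd.DataFrame(rows, columns=["participant_id", "item", "response_text"])


def _simulate_leisure(
    config: SimulationConfig,
    pids: list[str],
    hobby_latent: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    probs = np.asarray(LEISURE_CATEGORY_PROBS)
    expected_weight = float(np.dot(probs, LEISURE_CATEGORY_WEIGHTS))
    g = config.hobby_dispersion
    creative_rate = (
        config.hobby_target / expected_weight * np.exp(g * hobby_latent - 0.5 * g * g)
    )
    rows: list[tuple[str, str, str, str]] = []
    for domain in ("creative",) + tuple(_OTHER_DOMAIN_RATES):
        rates = creative_rate if domain == "creative" else np.full(len(pids), _OTHER_DOMAIN_RATES[domain])
        counts = rng.poisson(rates)
        for pid, k in zip(pids, counts):
            if k == 0:
                continue
            cats = rng.choice(len(LEISURE_CATEGORIES), size=k, p=probs)
            for a, c in enumerate(cats, start=1):
                rows.append((pid, domain, f"{domain}_activity{a:02d}", LEISURE_CATEGORIES[c]))
    return pd.DataFrame(rows, columns=["participant_id", "domain", "activity", "frequency"])


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a complete raw dataset bundle; deterministic given the config seed."""
    root = np.random.SeedSequence(config.seed)
    ss_demo, ss_latent, ss_items, ss_aut, ss_missing = root.spawn(5)
    # named substreams inside the item stage, so adding instruments later
    # never perturbs existing ones
    ss_scales, ss_okc, ss_leisure = ss_items.spawn(3)

    demo = _simulate_demographics(config, np.random.default_rng(ss_demo))
    pids = demo["participant_id"].tolist()
    n = config.n_participants

    rho = repair_correlation_matrix(config.target_rho)
    if config.calibrate_scored_rho:
        factors = attenuation_factors(config)
        f = np.array([factors[v] for v in ANALYSIS_VARIABLES])
        inflated = rho / np.outer(f, f)
        np.fill_diagonal(inflated, 1.0)
        rho = repair_correlation_matrix(np.clip(inflated, -0.99, 0.99))
    chol = np.linalg.cholesky(rho + 1e-12 * np.eye(rho.shape[0]))
    z = np.random.default_rng(ss_latent).standard_normal((n, rho.shape[0]))
    lat = pd.DataFrame(z @ chol.T, columns=list(ANALYSIS_VARIABLES), index=pids)

    rng_scales = np.random.default_rng(ss_scales)
    group_items: dict[str, np.ndarray] = {}
    for name, group in SCALE_GROUPS.items():  # fixed dict order = fixed draw order
        group_items[name] = _simulate_items(
            lat[group["latent"]].to_numpy(), config.likert_thresholds[name],
            group["n_items"], group["first_cat"], config.item_loading, rng_scales,
        )

    def _wide(groups: list[str]) -> pd.DataFrame:
        mat = np.concatenate([group_items[g] for g in groups], axis=1)
        cols = [f"item{i:02d}" for i in range(1, mat.shape[1] + 1)]
        out = pd.DataFrame(mat, columns=cols, index=pd.Index(pids, name="participant_id"))
        return out

    swlsc = _wide(["swlsc"])
    # SPANE positive items are 1,3,5,7,10,12: interleave the two 6-item blocks
    pos, neg = group_items["spane_pos"], group_items["spane_neg"]
    spane_mat = np.empty((n, 12), dtype=int)
    pos_slots = [0, 2, 4, 6, 9, 11]
    neg_slots = [1, 3, 5, 7, 8, 10]
    spane_mat[:, pos_slots] = pos
    spane_mat[:, neg_slots] = neg
    spane = pd.DataFrame(
        spane_mat, columns=[f"item{i:02d}" for i in range(1, 13)],
        index=pd.Index(pids, name="participant_id"),
    )
    mhcsf = _wide(["mhcsf"])
    spq = _wide(["spq_cp", "spq_sa", "spq_int", "spq_dis"])
    # reorder SPQ columns so the sequential default subscale map
    # (4 CP subscales, social anxiety, 2 interpersonal, 2 disorganized) holds:
    # generated blocks are cp(15), sa(4), int(6), dis(7) -> items 1..32 already
    # match the default map's ordering (cp:1-15, sa:16-19, int:20-25, dis:26-32).

    rng_okc = np.random.default_rng(ss_okc)
    tau = stats.norm.ppf(1.0 - config.okc_element_prob)
    a = config.okc_loading
    okc_noise = rng_okc.standard_normal((n, 3))
    okc_driver = -a * lat["okc"].to_numpy()[:, None] + np.sqrt(1 - a * a) * okc_noise
    okc_flags = (okc_driver > tau).astype(int)
    okc = pd.DataFrame(
        {"participant_id": pids,
         "four_limbs": okc_flags[:, 0],
         "two_antennae": okc_flags[:, 1],
         "tail": okc_flags[:, 2]}
    )

    leisure = _simulate_leisure(
        config, pids, lat["creative_hobbies"].to_numpy(), np.random.default_rng(ss_leisure)
    )
    aut = _simulate_aut(config, pids, lat, np.random.default_rng(ss_aut))

    rng_missing = np.random.default_rng(ss_missing)
    rates = config.missing_rate_per_instrument
    masks = {
        inst: rng_missing.random(n) < rates.get(inst, 0.0)
        for inst in ("aut", "okc", "leisure", "swlsc", "spane", "mhcsf", "spq")
    }
    scales = {"swlsc": swlsc, "spane": spane, "mhcsf": mhcsf, "spq": spq}
    for name, tbl in scales.items():
        tbl = tbl.astype(float)
        tbl.loc[masks[name], :] = np.nan
        scales[name] = tbl
    swlsc, spane, mhcsf, spq = (scales[k] for k in ("swlsc", "spane", "mhcsf", "spq"))
    if masks["aut"].any():
        dropped = {p for p, m in zip(pids, masks["aut"]) if m}
        aut = aut[~aut["participant_id"].isin(dropped)].reset_index(drop=True)
    if masks["okc"].any():
        flag_cols = ["four_limbs", "two_antennae", "tail"]
        okc[flag_cols] = okc[flag_cols].astype(float)
        okc.loc[masks["okc"], flag_cols] = np.nan
    if masks["leisure"].any():
        dropped = {p for p, m in zip(pids, masks["leisure"]) if m}
        leisure = leisure[~leisure["participant_id"].isin(dropped)].reset_index(drop=True)

    return CohortBundle(
        demographics=demo, aut_responses=aut, swlsc=swlsc, spane=spane,
        mhcsf=mhcsf, spq=spq, okc=okc, leisure=leisure, latents=lat, config=config,
    )


def attenuation_factors(config: SimulationConfig, n: int = 20000) -> dict[str, float]:
    """Estimated correlation between each scored variable and its own latent.

    Run once on an independent-latents cohort of size ``n`` (seed derived
    from the config seed); used by the optional scored-correlation
    calibration to inflate latent targets, and available as the
    attenuation-adjustment oracle for recovery checks.
    """
    from .reporting import score_bundle  # local import to avoid a cycle

    probe = SimulationConfig(
        n_participants=n,
        target_rho=np.eye(len(ANALYSIS_VARIABLES)),
        likert_thresholds=config.likert_thresholds,
        item_loading=config.item_loading,
        okc_loading=config.okc_loading,
        lexicon_size_per_item=config.lexicon_size_per_item,
        zipf_exponent=config.zipf_exponent,
        fluency_rate=config.fluency_rate,
        fluency_dispersion=config.fluency_dispersion,
        originality_tilt=config.originality_tilt,
        hobby_dispersion=config.hobby_dispersion,
        missing_rate_per_instrument={k: 0.0 for k in DEFAULT_MISSING_RATES},
        seed=(config.seed + 777) % (2**31),
    )
    bundle = generate_cohort(probe)
    scores = score_bundle(bundle)
    out = {}
    for v in ANALYSIS_VARIABLES:
        s = scores[v].to_numpy(dtype=float)
        l = bundle.latents[v].to_numpy()
        keep = ~np.isnan(s)
        corr = np.corrcoef(s[keep], l[keep])[0, 1] if keep.sum() > 2 and np.std(s[keep]) > 0 else 1.0
        out[v] = float(np.clip(abs(corr), 0.05, 1.0))
    return out


def config_to_json(config: SimulationConfig) -> str:
    """Canonical JSON echo of a configuration (provenance / hashing)."""
    d = {
        "n_participants": config.n_participants,
        "target_rho": np.asarray(config.target_rho).round(10).tolist(),
        "age_cohorts": [list(c) for c in config.age_cohorts],
        "gender_probs": config.gender_probs,
        "likert_thresholds": {k: np.asarray(v).tolist() for k, v in config.likert_thresholds.items()},
        "item_loading": config.item_loading,
        "okc_loading": config.okc_loading,
        "okc_element_prob": config.okc_element_prob,
        "lexicon_size_per_item": config.lexicon_size_per_item,
        "zipf_exponent": config.zipf_exponent,
        "fluency_rate": config.fluency_rate,
        "fluency_dispersion": config.fluency_dispersion,
        "originality_tilt": config.originality_tilt,
        "hobby_target": config.hobby_target,
        "hobby_dispersion": config.hobby_dispersion,
        "missing_rate_per_instrument": config.missing_rate_per_instrument,
        "calibrate_scored_rho": config.calibrate_scored_rho,
        "seed": config.seed,
    }
    return json.dumps(d, sort_keys=True)
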