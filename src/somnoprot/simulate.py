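"""Synthetic cohort, sleep-log, NPX and gene-set generator with ground truth.

The generator emulates the study conditions end to end so every pipeline
stage can be tested against a known truth:

* a cohort of 77 adults aged 80+ with covariates drawn at the published
  cohort moments (age 87.6 +/- 4.2 truncated at 80, 58.4% female,
  BMI 22.6 +/- 3.5, 4968.5 +/- 2846.7 daily steps, cystatin C
  1.2 +/- 0.3 mg/L, hypertension 37.7%, metabolic disease 10.4%,
  arrhythmia / heart failure 3.9%). For truncated variables the
  underlying normal parameters are solved so the *observed* moments
  match the targets;
* ~365 days of episode-level sleep logs per participant: one nocturnal
  main episode per day (participant-level mean TST 374.04 +/- 54.2 min)
  and zero or one secondary episode per day, driven by a per-participant
  zero-inflated-gamma propensity whose population mean daily secondary
  TST is 6.1 min (SD 7.8). The secondary-sleep latent is negatively
  coupled to the main-sleep level (the cohort's inverse main/secondary
  correlation); roughly 87% of participants (67/77) ever nap;
* an Olink-style NPX long table: 4 panels x 92 assays, a configurable
  number of proteins measured by two panels (368 assays / 355 distinct
  proteins by default), sporadic per-measurement QC warnings, and
  planted linear effects of the standardized secondary-sleep phenotype
  on a chosen set of signal assays;
* GMT gene sets with planted terms enriched in the signal proteins plus
  uniform decoy terms.

Episode stage minutes are partitioned as light/deep/REM/awake around
55/20/15/10% of the span with Dirichlet jitter (awake capped at 15%);
only the non-awake sum (TST) matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import PANELS, CovariateRow, GeneSet, SleepEpisode
from .phenotype import standardize

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_sleep_logs",
    "generate_npx",
    "generate_genesets",
    "simulate_study",
    "StudyBundle",
]

#: Covariate targets: observed cohort moments (means/SDs/prevalences).
DEFAULT_COVARIATE_MOMENTS = {
    "age": {"mean": 87.6, "sd": 4.2, "lower": 80.0},
    "female_fraction": 0.584,
    "bmi": {"mean": 22.6, "sd": 3.5, "lower": 0.0},
    "avg_steps": {"mean": 4968.5, "sd": 2846.7, "lower": 0.0},
    "cystatin_c": {"mean": 1.2, "sd": 0.3, "lower": 0.0},
    "hypertension": 0.377,
    "metabolic_disease": 0.104,
    "arrhythmia_hf": 0.039,
}

STAGE_PROPS = np.array([0.55, 0.20, 0.15, 0.10])  # light, deep, REM, awake
STAGE_CONC = 80.0  # Dirichlet concentration for stage jitter
MAX_AWAKE_FRAC = 0.15

#: nap span = 60 + Exp(mean 21) minutes capped at +180; with ~10% awake the
#: expected nap TST is ~0.9 * 81 min.
NAP_SPAN_EXTRA_MEAN = 21.0
NAP_SPAN_EXTRA_CAP = 180.0
NAP_MEAN_TST = 0.9 * (60.0 + NAP_SPAN_EXTRA_MEAN)

#: nap placement windows (probabilities over: post-wake early morning,
#: late morning, afternoon)
NAP_WINDOW_PROBS = {"early": 0.35, "late_morning": 0.10, "afternoon": 0.55}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator (defaults = the cohort)."""

    n_participants: int = 77
    n_days: int = 365
    seed: int = 0
    main_tst_mean: float = 374.04
    main_tst_sd: float = 54.2
    secondary_tst_mean: float = 6.1
    secondary_tst_sd: float = 7.8
    napper_fraction: float = 67 / 77
    n_assays: int = 368
    n_duplicate_proteins: int = 13  # 368 assays -> 355 distinct proteins
    n_signal_assays: int = 10
    effect_sizes: Sequence[float] | None = None  # NPX log2 per SD of outcome
    npx_noise_sd: float = 1.0
    npx_covariate_loading_sd: float = 0.15
    qc_warning_rate: float = 0.01
    covariate_moments: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MOMENTS)
    )
    main_secondary_corr: float = -0.3
    n_planted_terms: int = 2
    n_decoy_terms: int = 20
    planted_term_size: int = 10

    def __post_init__(self) -> None:
        for name in ("napper_fraction", "qc_warning_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("main_tst_sd", "secondary_tst_sd", "npx_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not -1.0 <= self.main_secondary_corr <= 0.0:
            raise ValueError("main_secondary_corr must lie in [-1, 0]")
        if self.n_signal_assays > self.n_assays:
            raise ValueError("n_signal_assays exceeds n_assays")
        if self.n_assays % len(PANELS) != 0:
            raise ValueError(f"n_assays must be divisible by {len(PANELS)} panels")
        if self.n_duplicate_proteins > self.n_assays // 2:
            raise ValueError("too many duplicated proteins")

    @property
    def planted_betas(self) -> np.ndarray:
        if self.effect_sizes is not None:
            base = np.asarray(list(self.effect_sizes), dtype=float)
            reps = -(-self.n_signal_assays // max(len(base), 1)) if len(base) else 1
            return np.tile(base, reps)[: self.n_signal_assays]
        signs = np.where(np.arange(self.n_signal_assays) % 2 == 0, 1.0, -1.0)
        return 0.6 * signs


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    signal_assay_ids: list[str] = field(default_factory=list)
    true_betas: dict[str, float] = field(default_factory=dict)
    true_participant_latent: dict[str, float] = field(default_factory=dict)
    true_main_mean: dict[str, float] = field(default_factory=dict)
    planted_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.true_betas) != set(self.signal_assay_ids):
            raise ValueError("true_betas keys must equal signal_assay_ids")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one global seed fans out to per-stage streams by a fixed offset
    return np.random.default_rng([config.seed, stage])


def _truncnorm_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose lower-truncated normal has the target moments."""
    a0 = (lower - mean) / sd
    if a0 < -6:  # truncation is immaterial
        return mean, sd

    def eqs(x):
        mu, log_sig = x
        sig = np.exp(log_sig)
        a = (lower - mu) / sig
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(eqs, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment match failed for {mean}, {sd}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_truncated(rng, n, mean, sd, lower) -> np.ndarray:
    mu, sig = _truncnorm_params(mean, sd, lower)
    a = (lower - mu) / sig
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sig, size=n, random_state=rng)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw the participant covariate table at the configured cohort moments."""
    if config.n_participants < 2:
        raise ValueError("need at least 2 participants")
    n = config.n_participants
    rng = _rng(config, 1)
    mom = config.covariate_moments
    pid = [f"P{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(index=pd.Index(pid, name="participant_id"))
    df["age"] = _draw_truncated(rng, n, **mom["age"])
    df["sex"] = (rng.random(n) < mom["female_fraction"]).astype(int)
    df["bmi"] = _draw_truncated(rng, n, **mom["bmi"])
    df["avg_steps"] = _draw_truncated(rng, n, **mom["avg_steps"])
    df["metabolic_disease"] = (rng.random(n) < mom["metabolic_disease"]).astype(int)
    df["hypertension"] = (rng.random(n) < mom["hypertension"]).astype(int)
    df["arrhythmia_hf"] = (rng.random(n) < mom["arrhythmia_hf"]).astype(int)
    df["cystatin_c"] = _draw_truncated(rng, n, **mom["cystatin_c"])
    return df


# ---------------------------------------------------------------------------
# sleep logs
# ---------------------------------------------------------------------------


def _partition_minutes(span: int, props: np.ndarray) -> list[int]:
    """Largest-remainder integer split of ``span`` by ``props`` (sums exactly)."""
    raw = span * props
    base = np.floor(raw).astype(int)
    short = span - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return [int(x) for x in base]


def _stage_split(rng, span: int) -> list[int]:
    props = rng.dirichlet(STAGE_CONC * STAGE_PROPS)
    while props[3] > MAX_AWAKE_FRAC:
        props = rng.dirichlet(STAGE_CONC * STAGE_PROPS)
    return _partition_minutes(span, props)


def _secondary_latents(config: SimulationConfig, rng, n: int):
    """Per-participant (main mean, target mean daily secondary TST).

    A bivariate-normal latent couples main sleep and nap propensity at
    ``main_secondary_corr``; the nap quantile is mapped through a
    zero-inflated gamma calibrated so the population mean/SD of mean
    daily secondary TST hit the configured 6.1 / 7.8 minutes.
    """
    u = rng.standard_normal(n)
    w = rng.standard_normal(n)
    rho = config.main_secondary_corr
    v = rho * u + np.sqrt(1.0 - rho * rho) * w
    main_mu = np.clip(
        config.main_tst_mean + config.main_tst_sd * u, 210.0, 560.0
    )
    f = config.napper_fraction
    if f <= 0.0 or config.secondary_tst_mean <= 0.0:
        return main_mu, np.zeros(n)
    mean_g = config.secondary_tst_mean / f
    var_total = config.secondary_tst_sd**2
    var_g = (var_total + config.secondary_tst_mean**2 - f * mean_g**2) / f
    if var_g <= 0:
        var_g = mean_g**2
    shape = mean_g**2 / var_g
    scale = var_g / mean_g
    q = stats.norm.cdf(v)
    m = np.zeros(n)
    napper = q >= 1.0 - f
    qn = np.clip((q[napper] - (1.0 - f)) / f, 1e-9, 1.0 - 1e-9)
    m[napper] = stats.gamma.ppf(qn, shape, scale=scale)
    return main_mu, m


def generate_sleep_logs(
    cohort: pd.DataFrame, config: SimulationConfig, *, start_date: date = date(2022, 11, 1)
) -> tuple[list[SleepEpisode], GroundTruth]:
    """Generate per-participant-day episodes plus the propensity ground truth.

    Each day gets one nocturnal main episode (wake ~06:30, TST near the
    participant mean) and, with the participant's nap propensity, at most
    one secondary episode of span >= 60 min placed post-wake, late
    morning, or in the afternoon.
    """
    if config.n_days < 1:
        raise ValueError("n_days must be >= 1")
    if cohort.empty:
        raise ValueError("cohort is empty")
    rng = _rng(config, 2)
    n = len(cohort)
    main_mu, sec_mean = _secondary_latents(config, rng, n)
    nap_p = np.minimum(sec_mean / NAP_MEAN_TST, 0.95)

    episodes: list[SleepEpisode] = []
    windows = list(NAP_WINDOW_PROBS)
    wprobs = np.array(list(NAP_WINDOW_PROBS.values()))
    for i, pid in enumerate(cohort.index):
        n_days = config.n_days
        wake_min = np.clip(
            np.rint(rng.normal(390.0, 35.0, n_days)), 280, 530
        ).astype(int)  # minutes after midnight: ~04:40-08:50
        tst = np.clip(rng.normal(main_mu[i], 25.0, n_days), 120.0, 560.0)
        span = np.rint(tst / 0.9).astype(int)
        nap_today = rng.random(n_days) < nap_p[i]
        nap_window = rng.choice(len(windows), size=n_days, p=wprobs)
        nap_extra = np.minimum(
            rng.exponential(NAP_SPAN_EXTRA_MEAN, n_days), NAP_SPAN_EXTRA_CAP
        )
        nap_span = (60 + np.rint(nap_extra)).astype(int)
        for d in range(n_days):
            day = start_date + timedelta(days=d + 1)
            wake = datetime.combine(day, time(0, 0)) + timedelta(minutes=int(wake_min[d]))
            start = wake - timedelta(minutes=int(span[d]))
            light, deep, rem, awake = _stage_split(rng, int(span[d]))
            episodes.append(
                SleepEpisode(pid, start, wake, light, deep, rem, awake)
            )
            if not nap_today[d]:
                continue
            w = windows[nap_window[d]]
            s = int(nap_span[d])
            if w == "early":
                nap_start = wake + timedelta(minutes=int(rng.integers(30, 121)))
            elif w == "late_morning":
                nap_start = datetime.combine(day, time(0, 0)) + timedelta(
                    minutes=int(rng.integers(570, 691))  # 09:30-11:30
                )
            else:  # afternoon: end by 18:00
                latest = 18 * 60 - s
                lo = 12 * 60 + 30
                nap_start = datetime.combine(day, time(0, 0)) + timedelta(
                    minutes=int(rng.integers(lo, max(lo + 1, latest + 1)))
                )
            if nap_start <= wake:
                nap_start = wake + timedelta(minutes=30)
            nl, nd_, nr, na = _stage_split(rng, s)
            episodes.append(
                SleepEpisode(
                    pid, nap_start, nap_start + timedelta(minutes=s), nl, nd_, nr, na
                )
            )
    truth = GroundTruth(
        true_participant_latent={p: float(sec_mean[i]) for i, p in enumerate(cohort.index)},
        true_main_mean={p: float(main_mu[i]) for i, p in enumerate(cohort.index)},
    )
    episodes.sort(key=lambda e: (e.participant_id, e.start))
    return episodes, truth


# ---------------------------------------------------------------------------
# NPX
# ---------------------------------------------------------------------------


def assay_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic assay metadata: assay_id, panel, protein_id.

    ``n_duplicate_proteins`` proteins are measured on two different
    panels, so distinct proteins = n_assays - n_duplicate_proteins.
    """
    per_panel = config.n_assays // len(PANELS)
    n_proteins = config.n_assays - config.n_duplicate_proteins
    proteins = [f"PROT{i + 1:04d}" for i in range(n_proteins)]
    slots = list(proteins)
    # duplicated proteins get a second assay slot; panel layout is
    # round-robin so the two assays of one protein land on different panels
    slots.extend(proteins[: config.n_duplicate_proteins])
    rows = []
    for j, prot in enumerate(slots):
        panel = PANELS[j // per_panel]
        rows.append({"assay_id": f"{panel}:{prot}", "panel": panel, "protein_id": prot})
    df = pd.DataFrame(rows).set_index("assay_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate protein landed twice on one panel; "
                         "reduce n_duplicate_proteins")
    return df


def generate_npx(
    cohort: pd.DataFrame,
    phenotypes: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format NPX records with planted protein-sleep effects.

    Signal assays receive ``npx = intercept + beta * z(secondary TST) +
    gamma . covariates + noise``; null assays have beta = 0. QC warnings
    are independent per measurement at ``qc_warning_rate``.
    """
    if not cohort.index.equals(phenotypes.index):
        missing = set(cohort.index) ^ set(phenotypes.index)
        raise ValueError(f"cohort/phenotype participant mismatch: {sorted(missing)[:5]}")
    rng = _rng(config, 3)
    assays = assay_table(config)
    n, p = len(cohort), len(assays)

    if "z_secondary" in phenotypes.columns and phenotypes["z_secondary"].notna().all():
        z = phenotypes["z_secondary"].to_numpy(dtype=float)
    else:
        z = standardize(phenotypes["avg_secondary_tst"].to_numpy(dtype=float))

    # standardized covariate block with small per-assay loadings
    C = np.column_stack(
        [
            standardize(cohort["age"].to_numpy(float)),
            cohort["sex"].to_numpy(float),
            standardize(cohort["bmi"].to_numpy(float)),
            standardize(cohort["avg_steps"].to_numpy(float)),
            cohort["metabolic_disease"].to_numpy(float),
            cohort["hypertension"].to_numpy(float),
            cohort["arrhythmia_hf"].to_numpy(float),
            standardize(cohort["cystatin_c"].to_numpy(float)),
        ]
    )
    gamma = rng.normal(0.0, config.npx_covariate_loading_sd, size=(C.shape[1], p))

    # plant effects on assays whose protein is measured once, so signal
    # proteins map one-to-one to assays
    unique_prot = assays["protein_id"].value_counts()
    candidates = [
        a for a in assays.index if unique_prot[assays.loc[a, "protein_id"]] == 1
    ]
    if config.n_signal_assays > len(candidates):
        raise ValueError("not enough single-assay proteins to plant signals")
    signal_ids = sorted(
        rng.choice(np.array(candidates), size=config.n_signal_assays, replace=False)
    )
    betas = np.zeros(p)
    planted = config.planted_betas
    for b, a in zip(planted, signal_ids):
        betas[assays.index.get_loc(a)] = b

    intercepts = rng.uniform(2.0, 10.0, size=p)
    noise = rng.normal(0.0, config.npx_noise_sd, size=(n, p))
    npx = intercepts + np.outer(z, betas) + C @ gamma + noise
    warn = rng.random((n, p)) < config.qc_warning_rate

    long = pd.DataFrame(
        {
            "SampleID": np.repeat(list(cohort.index), p),
            "Panel": np.tile(assays["panel"].to_numpy(), n),
            "Assay": np.tile(assays.index.to_numpy(), n),
            "Protein": np.tile(assays["protein_id"].to_numpy(), n),
            "NPX": npx.ravel(),
            "QC_Warning": np.where(warn.ravel(), "WARN", "PASS"),
        }
    )
    truth = GroundTruth(
        signal_assay_ids=list(signal_ids),
        true_betas={a: float(betas[assays.index.get_loc(a)]) for a in signal_ids},
    )
    return long, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def generate_genesets(
    ground_truth: GroundTruth, config: SimulationConfig
) -> tuple[list[GeneSet], GroundTruth]:
    """Planted enriched terms plus uniform decoys over the protein background.

    Each planted term contains at least 3 signal proteins plus filler
    proteins; cores are disjoint across planted terms (distinct
    biological processes share few genes), and decoys are drawn
    uniformly from the full background.
    """
    rng = _rng(config, 4)
    assays = assay_table(config)
    background = sorted(set(assays["protein_id"]))
    signal_proteins = sorted(
        {assays.loc[a, "protein_id"] for a in ground_truth.signal_assay_ids}
    )
    nonsignal = [g for g in background if g not in signal_proteins]
    sets: list[GeneSet] = []
    planted_ids = []
    if config.n_planted_terms > 0:
        per_term = len(signal_proteins) // config.n_planted_terms
        if per_term < 3:
            raise ValueError(
                "fewer than 3 signal proteins available for a planted term"
            )
        shuffled = list(rng.permutation(np.array(signal_proteins)))
    for t in range(config.n_planted_terms):
        core = shuffled[t * per_term : (t + 1) * per_term]
        n_fill = max(config.planted_term_size - len(core), 0)
        fill = rng.choice(np.array(nonsignal), size=n_fill, replace=False)
        tid = f"PLANTED{t + 1:02d}"
        sets.append(
            GeneSet(tid, f"planted enriched term {t + 1}",
                    frozenset(map(str, [*core, *fill])))
        )
        planted_ids.append(tid)
    for t in range(config.n_decoy_terms):
        hi = min(25, len(background))
        lo = min(10, hi)
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(np.array(background), size=size, replace=False)
        sets.append(
            GeneSet(f"DECOY{t + 1:03d}", f"decoy term {t + 1}",
                    frozenset(map(str, genes)))
        )
    ground_truth.planted_terms = planted_ids
    return sets, ground_truth


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    config: SimulationConfig
    cohort: pd.DataFrame
    episodes: list[SleepEpisode]
    phenotypes: pd.DataFrame
    npx_long: pd.DataFrame
    genesets: list[GeneSet]
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Cohort -> logs -> phenotypes -> NPX -> gene sets, with merged truth.

    Phenotypes are computed from the generated logs with the standard QC
    (days < 2 h dropped, participants < 90 days excluded) so planted NPX
    effects refer to exactly the phenotype the pipeline recomputes.
    """
    from .phenotype import (
        apply_qc,
        build_day_records,
        phenotypes_to_frame,
        standardize_phenotypes,
        summarize,
    )

    cohort = generate_cohort(config)
    episodes, truth_sleep = generate_sleep_logs(cohort, config)
    days = build_day_records(episodes)
    min_days = min(90, config.n_days)
    kept, _ = apply_qc(days, min_days=min_days)
    phen = summarize(kept)
    standardize_phenotypes(phen)
    phen_df = phenotypes_to_frame(phen)
    cohort = cohort.loc[phen_df.index]
    npx_long, truth = generate_npx(cohort, phen_df, config)
    gs_config = config
    if config.n_planted_terms > 0 and (
        len(truth.signal_assay_ids) // config.n_planted_terms < 3
    ):
        # nothing to plant terms around (e.g. a global-null simulation)
        from dataclasses import replace as _replace

        gs_config = _replace(config, n_planted_terms=0)
    genesets, truth = generate_genesets(truth, gs_config)
    truth.true_participant_latent = truth_sleep.true_participant_latent
    truth.true_main_mean = truth_sleep.true_main_mean
    return StudyBundle(
        config=config,
        cohort=cohort,
        episodes=episodes,
        phenotypes=phen_df,
        npx_long=npx_long,
        genesets=genesets,
        truth=truth,
    )
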