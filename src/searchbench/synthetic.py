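"""Synthetic trials and simulated participant behavior.

The generator emulates the statistical structure of a crowdsourced aerial
visual-search study so that every downstream stage (matching, metrics,
mixed-effects models, order analysis) can be exercised and validated without
external data:

* trials carry 1-25 ground-truth instances, with ~70% of trials holding only
  one or two targets (3-component count mixture);
* instance sides are log-normal with median ~66 px and mean ~125 px, heavily
  right-skewed like real aerial object scales;
* ordinal clarity ratings (1-5) are tied to instance size through a Gaussian
  copula with a configurable rank correlation (default 0.33);
* a participant selects each instance with a logistic probability driven by
  ln(area), distance from image center, target count (optionally clarity and
  color match), plus crossed worker and trial random intercepts;
* selected instances are clicked in a salience-weighted order (larger and
  color-matched instances earlier), with isotropic Gaussian click jitter;
* false positives arrive as a Poisson count whose rate decreases with the
  number of true targets, placed well away from any instance;
* timestamps follow log-normal first-click and inter-click distributions.

All randomness flows from a single seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import (COLOR_VOCABULARY, Selection, TargetInstance, Trial,
                         assign_order_indices)
from .matching import compute_match_threshold

__all__ = [
    "GeneratorConfig",
    "SimulatedCohort",
    "generate_trials",
    "simulate_selections",
    "simulate_ratings",
    "simulate_cohort",
    "SEARCH_CLASSES",
]

#: Object classes used for synthetic trials ("harbor"/"bridge" excluded by
#: the stimulus design).
SEARCH_CLASSES: tuple[str, ...] = (
    "baseball-diamond", "basketball-court", "ground-track-field",
    "helicopter", "large-vehicle", "plane", "roundabout", "ship",
    "small-vehicle", "soccer-ball-field", "storage-tank", "swimming-pool",
    "tennis-court",
)

_COUNT_BINS = ((1, 2), (3, 10), (11, 25))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Fixed-effect coefficients are on the logit scale with unstandardized
    predictors: ``log_area`` multiplies ln(area in px^2), ``dist_center``
    multiplies raw pixels, ``n_targets`` the raw target count, ``clarity``
    the 1-5 rating and ``color_match`` a 0/1 indicator. Defaults are the
    Experiment-1 preset; :meth:`experiment2` switches to the five-predictor
    variant.
    """

    n_participants: int = 20
    n_trials: int = 100
    seed: int = 0
    image_side: float = 800.0
    # trial composition
    count_weights: tuple[float, float, float] = (0.70, 0.27, 0.03)
    side_median: float = 66.0
    side_mean: float = 125.0
    aspect_sigma: float = 0.25
    clarity_size_rho: float = 0.33
    p_color_match: float = 0.40
    # selection model (logit scale)
    beta: dict = field(default_factory=lambda: {
        "intercept": -5.88, "log_area": 0.92,
        "dist_center": -0.001, "n_targets": -0.05,
    })
    var_worker: float = 0.95
    var_trial: float = 3.89
    # false-positive process: rate = max(0, fp_rate0 - fp_slope * n_targets)
    fp_rate0: float = 1.0
    fp_slope: float = 0.10
    fp_exclusion_factor: float = 1.5
    # selection-order salience weights (softmax on z(ln area) and color match)
    w_size: float = 0.25
    w_color: float = 1.0
    # click jitter sd as a fraction of the trial's mean instance side
    jitter_frac: float = 0.10
    # timing (log-normal medians/means, seconds)
    first_click_median: float = 5.03
    first_click_mean: float = 12.94
    inter_click_median: float = 1.02
    inter_click_mean: float = 1.97
    # rating response noise
    clarity_noise_sd: float = 0.0
    color_noise: float = 0.0

    @classmethod
    def experiment1(cls, **overrides) -> "GeneratorConfig":
        return cls(**overrides)

    @classmethod
    def experiment2(cls, **overrides) -> "GeneratorConfig":
        base = dict(
            beta={
                "intercept": -4.02, "clarity": 0.57, "color_match": 0.53,
                "dist_center": -0.003, "log_area": 0.55, "n_targets": -0.09,
            },
            var_worker=1.06, var_trial=2.81,
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if abs(sum(self.count_weights) - 1.0) > 1e-9:
            raise ValueError("count mixture weights must sum to 1")
        if any(w < 0 for w in self.count_weights):
            raise ValueError("count mixture weights must be non-negative")
        if self.side_mean <= self.side_median:
            raise ValueError(
                "infeasible log-normal calibration: mean side must exceed "
                f"median side (got mean {self.side_mean} <= median "
                f"{self.side_median})")
        if not 0.0 <= self.p_color_match <= 1.0:
            raise ValueError("p_color_match must be in [0, 1]")
        if self.var_worker < 0 or self.var_trial < 0:
            raise ValueError("random-intercept variances must be >= 0")
        if not -1.0 < self.clarity_size_rho < 1.0:
            raise ValueError("clarity_size_rho must be in (-1, 1)")

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal side distribution.

        median = exp(mu), mean = exp(mu + sigma^2/2).
        """
        mu = math.log(self.side_median)
        sigma = math.sqrt(2.0 * math.log(self.side_mean / self.side_median))
        return mu, sigma

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "count_weights" in d:
            d["count_weights"] = tuple(d["count_weights"])
        return cls(**d)


@dataclass
class SimulatedCohort:
    """A generated dataset plus the latent quantities that produced it."""

    trials: list[Trial]
    selections: list[Selection]
    worker_effects: pd.Series      # u_w by participant
    trial_effects: pd.Series       # u_t by trial
    latent: pd.DataFrame           # per (participant, trial, instance): p, selected
    config: GeneratorConfig


# -- clarity-size copula ------------------------------------------------------

_CLARITY_CUTS = stats.norm.ppf(np.arange(1, 5) / 5.0)  # equal quintile bins
_CLARITY_MIDRANK = np.arange(1, 6) / 5.0 - 0.1          # 0.1, 0.3, ..., 0.9


def _spearman_given_latent(r: float) -> float:
    """Population Spearman between a continuous margin and the 5-level
    discretization of a bivariate-normal pair with latent correlation r."""
    if r == 0.0:
        return 0.0
    # E[Phi(z1) 1{z2 <= b}] = P(z1 - z0 > 0 is wrong sign; use P(z0 < z1, z2 <= b)
    # with z0 independent: equals BVN CDF of (0, b) for (z0 - z1, z2) with
    # corr(z0 - z1, z2) = -r / sqrt(2).
    rho = -r / math.sqrt(2.0)
    cuts = np.concatenate([_CLARITY_CUTS, [8.0]])
    e_cum = np.array([
        stats.multivariate_normal.cdf(
            [0.0, b], mean=[0.0, 0.0], cov=[[2.0, rho * math.sqrt(2.0)],
                                            [rho * math.sqrt(2.0), 1.0]])
        for b in cuts
    ])
    # P(z0 < z1, z2 in bin) per bin, times midrank
    p_joint = np.diff(np.concatenate([[0.0], e_cum]))
    e_xy = float(p_joint @ _CLARITY_MIDRANK)
    cov = e_xy - 0.5 * 0.5
    var_x = 1.0 / 12.0
    var_y = float(np.sum(0.2 * (_CLARITY_MIDRANK - 0.5) ** 2))
    return cov / math.sqrt(var_x * var_y)


@lru_cache(maxsize=32)
def _latent_corr_for_spearman(rho_s: float) -> float:
    """Invert the copula: latent normal correlation giving target Spearman."""
    if rho_s == 0.0:
        return 0.0
    lo, hi = (-0.999, 0.0) if rho_s < 0 else (0.0, 0.999)
    return float(optimize.brentq(
        lambda r: _spearman_given_latent(r) - rho_s, lo, hi, xtol=1e-6))


# -- trial generation ---------------------------------------------------------

def _draw_target_count(config: GeneratorConfig, rng: np.random.Generator) -> int:
    comp = rng.choice(3, p=np.asarray(config.count_weights, dtype=float))
    lo, hi = _COUNT_BINS[comp]
    return min(int(rng.integers(lo, hi + 1)), 30)


def generate_trials(config: GeneratorConfig,
                    rng: np.random.Generator) -> list[Trial]:
    """Draw synthetic trials with calibrated size/count/clarity structure."""
    config.validate()
    mu, sigma = config.lognormal_params()
    latent_r = _latent_corr_for_spearman(config.clarity_size_rho)
    trials: list[Trial] = []
    for t in range(config.n_trials):
        tid = f"trial{t:04d}"
        n = _draw_target_count(config, rng)
        cls = str(rng.choice(SEARCH_CLASSES))
        template_color = str(rng.choice(COLOR_VOCABULARY))
        z1 = rng.standard_normal(n)
        side = np.exp(mu + sigma * z1)
        aspect = np.exp(rng.normal(0.0, config.aspect_sigma, n))
        width, height = side * aspect, side / aspect
        z2 = latent_r * z1 + math.sqrt(1.0 - latent_r ** 2) * rng.standard_normal(n)
        clarity = 1 + np.searchsorted(_CLARITY_CUTS, z2)
        match = rng.random(n) < config.p_color_match
        cx = rng.uniform(0.0, config.image_side, n)
        cy = rng.uniform(0.0, config.image_side, n)
        others = [c for c in COLOR_VOCABULARY if c != template_color]
        instances = [
            TargetInstance(
                instance_id=f"{tid}:{i}", trial_id=tid,
                cx=float(cx[i]), cy=float(cy[i]),
                width=float(width[i]), height=float(height[i]),
                class_label=cls,
                color_label=(template_color if match[i]
                             else str(rng.choice(others))),
                clarity=int(clarity[i]),
                color_match=int(match[i]),
            )
            for i in range(n)
        ]
        trials.append(Trial(
            trial_id=tid, search_class=cls, instances=instances,
            image_side=config.image_side,
            template_clarity=int(rng.integers(1, 6)),
            template_color=template_color,
        ))
    return trials


# -- behavior simulation ------------------------------------------------------

def _lognormal_draw(median: float, mean: float, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    mu = math.log(median)
    sigma = math.sqrt(max(2.0 * math.log(mean / median), 1e-12))
    return rng.lognormal(mu, sigma, size)


def _instance_logits(trial: Trial, config: GeneratorConfig) -> np.ndarray:
    b = config.beta
    half = trial.image_side / 2.0
    eta = np.full(trial.n_targets, b.get("intercept", 0.0))
    for i, inst in enumerate(trial.instances):
        eta[i] += b.get("log_area", 0.0) * math.log(inst.area)
        eta[i] += b.get("dist_center", 0.0) * math.hypot(inst.cx - half,
                                                         inst.cy - half)
        eta[i] += b.get("n_targets", 0.0) * trial.n_targets
        if "clarity" in b:
            eta[i] += b["clarity"] * (inst.clarity or 0)
        if "color_match" in b:
            eta[i] += b["color_match"] * (inst.color_match or 0)
    return eta


def _salience_order(trial: Trial, chosen: np.ndarray,
                    config: GeneratorConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Order chosen instance indices by noisy salience (Gumbel top-k)."""
    log_area = np.log([trial.instances[i].area for i in chosen])
    z = ((log_area - log_area.mean()) / log_area.std()
         if len(chosen) > 1 and log_area.std() > 0 else np.zeros(len(chosen)))
    m = np.array([trial.instances[i].color_match or 0 for i in chosen])
    score = config.w_size * z + config.w_color * m
    gumbel = rng.gumbel(size=len(chosen))
    return chosen[np.argsort(-(score + gumbel), kind="stable")]


def _place_false_positives(trial: Trial, k: int, config: GeneratorConfig,
                           rng: np.random.Generator) -> list[tuple[float, float]]:
    threshold = compute_match_threshold(trial.search_instances())
    min_dist = config.fp_exclusion_factor * threshold
    centers = np.array([[i.cx, i.cy] for i in trial.instances])
    points: list[tuple[float, float]] = []
    for _ in range(k):
        for _attempt in range(200):
            x = rng.uniform(0.0, trial.image_side)
            y = rng.uniform(0.0, trial.image_side)
            d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
            if d.min() >= min_dist:
                points.append((x, y))
                break
        # image too crowded to place an unambiguous FP: drop it
    return points


def simulate_selections(trials: list[Trial], config: GeneratorConfig,
                        rng: np.random.Generator) -> SimulatedCohort:
    """Simulate every participant on every trial.

    Returns the cohort with its latent random intercepts and per-instance
    selection probabilities, for self-consistency checks and parameter
    recovery.
    """
    config.validate()
    workers = [f"p{w:04d}" for w in range(config.n_participants)]
    u_w = pd.Series(rng.normal(0.0, math.sqrt(config.var_worker),
                               len(workers)), index=workers)
    u_t = pd.Series(rng.normal(0.0, math.sqrt(config.var_trial), len(trials)),
                    index=[t.trial_id for t in trials])
    base_logits = {t.trial_id: _instance_logits(t, config) for t in trials}
    mean_side = {t.trial_id: compute_match_threshold(t.search_instances())
                 for t in trials}

    selections: list[Selection] = []
    latent_rows = []
    for wid in workers:
        for trial in trials:
            eta = np.clip(base_logits[trial.trial_id] + u_w[wid]
                          + u_t[trial.trial_id], -35.0, 35.0)
            p = 1.0 / (1.0 + np.exp(-eta))
            sel_mask = rng.random(trial.n_targets) < p
            chosen = np.flatnonzero(sel_mask)
            ordered = (_salience_order(trial, chosen, config, rng)
                       if len(chosen) else chosen)
            jitter_sd = config.jitter_frac * mean_side[trial.trial_id]
            clicks: list[tuple[float, float]] = []
            for i in ordered:
                inst = trial.instances[i]
                x = float(np.clip(inst.cx + rng.normal(0.0, jitter_sd),
                                  0.0, trial.image_side))
                y = float(np.clip(inst.cy + rng.normal(0.0, jitter_sd),
                                  0.0, trial.image_side))
                clicks.append((x, y))
            lam = max(0.0, config.fp_rate0
                      - config.fp_slope * trial.n_targets)
            n_fp = int(rng.poisson(lam)) if lam > 0 else 0
            for pt in _place_false_positives(trial, n_fp, config, rng):
                pos = int(rng.integers(0, len(clicks) + 1))
                clicks.insert(pos, pt)
            if clicks:
                t0 = _lognormal_draw(config.first_click_median,
                                     config.first_click_mean, 1, rng)[0]
                gaps = _lognormal_draw(config.inter_click_median,
                                       config.inter_click_mean,
                                       len(clicks) - 1, rng)
                times = np.concatenate([[t0], t0 + np.cumsum(gaps)])
                for (x, y), t in zip(clicks, times):
                    selections.append(Selection(wid, trial.trial_id,
                                                x, y, float(t)))
            for i, inst in enumerate(trial.instances):
                latent_rows.append((wid, trial.trial_id, inst.instance_id,
                                    float(p[i]), bool(sel_mask[i])))
    latent = pd.DataFrame(latent_rows, columns=[
        "participant_id", "trial_id", "instance_id", "p", "selected"])
    return SimulatedCohort(trials=trials,
                           selections=assign_order_indices(selections),
                           worker_effects=u_w, trial_effects=u_t,
                           latent=latent, config=config)


def simulate_cohort(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Convenience wrapper: trials + behavior from one seeded generator."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trials = generate_trials(config, rng)
    return simulate_selections(trials, config, rng)


# -- ratings ------------------------------------------------------------------

def simulate_ratings(cohort: SimulatedCohort, config: GeneratorConfig,
                     rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Per-participant template and instance ratings with response noise.

    With ``clarity_noise_sd = 0`` the reported clarity equals the latent
    rating; with ``color_noise = 1`` color responses are uniform guesses
    over the 11-name color vocabulary.
    """
    vocab = list(COLOR_VOCABULARY)
    workers = list(cohort.worker_effects.index)
    trial_rows, inst_rows = [], []
    for wid in workers:
        for trial in cohort.trials:
            t_clar = trial.template_clarity or 3
            if config.clarity_noise_sd > 0:
                t_clar = int(np.clip(round(
                    t_clar + rng.normal(0.0, config.clarity_noise_sd)), 1, 5))
            t_color = trial.template_color or "unknown"
            if config.color_noise > 0 and rng.random() < config.color_noise:
                t_color = str(rng.choice(vocab))
            difficulty = int(rng.integers(1, 6))
            trial_rows.append((wid, trial.trial_id, t_clar, t_color,
                               difficulty))
            for inst in trial.instances:
                clar = inst.clarity or 3
                if config.clarity_noise_sd > 0:
                    clar = int(np.clip(round(
                        clar + rng.normal(0.0, config.clarity_noise_sd)), 1, 5))
                color = inst.color_label
                if config.color_noise > 0 and rng.random() < config.color_noise:
                    color = str(rng.choice(vocab))
                inst_rows.append((wid, trial.trial_id, inst.instance_id,
                                  clar, color, int(color == t_color)))
    return {
        "trial_ratings": pd.DataFrame(trial_rows, columns=[
            "participant_id", "trial_id", "template_clarity",
            "template_color", "difficulty"]),
        "instance_ratings": pd.DataFrame(inst_rows, columns=[
            "participant_id", "trial_id", "instance_id", "clarity",
            "color", "color_match"]),
    }
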