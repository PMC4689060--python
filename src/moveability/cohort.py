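"""Synthetic child cohort and accelerometer epoch series.

The cohort emulates the marginal structure of a 2–9.9-year-old study
sample: 75 % school-age (6–9.9 y) vs pre-school (2–<6 y), slightly more
girls, three parental-education (ISCED) categories, binary parental safety
concerns, a two-level season of assessment, and accelerometer weartime.
Habitual MVPA (min/day) is drawn from a gamma distribution with a
log-linear mean in the covariates and a per-child built-environment
exposure, so the downstream gamma log-link regression has a known truth to
recover.

Category counts are allocated exactly (largest-remainder rounding) and then
randomly paired with children, so printed shares match the configured
marginals while assignments stay random.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .city import DensityRaster, _sample_from_raster

__all__ = ["CohortConfig", "SyntheticTruth", "EpochConfig", "EpochSeries",
           "generate_cohort", "generate_epoch_counts", "simulate_screening",
           "apply_exclusions"]

#: covariate encoding used in the generative linear predictor; continuous
#: covariates are centered at typical values so the intercept is log of a
#: typical child's MVPA
AGE_CENTER = 6.0
WEARTIME_CENTER = 11.5


def default_true_beta() -> dict:
    """Log-scale generative coefficients (multiplicative effects ≈ a
    school-age basic model: season ×1.17, safety ×0.86, BMI ×0.95 ...)."""
    return {
        "intercept": math.log(60.0),
        "age": math.log(0.97),
        "bmi_z": math.log(0.95),
        "weartime": math.log(1.04),
        "season": math.log(1.17),
        "safety": math.log(0.86),
        "isced_low": math.log(0.95),
        "isced_high": math.log(1.01),
        "exposure": math.log(1.10),
    }


@dataclass
class CohortConfig:
    n_children: int = 400
    frac_school_age: float = 0.75
    frac_girls: float = 0.515
    # low/medium/high parental-education shares per age group
    isced_probs: dict = field(default_factory=lambda: {
        "school": (0.23, 0.56, 0.21), "pre_school": (0.13, 0.72, 0.15)})
    safety_prob: dict = field(default_factory=lambda: {"school": 0.353,
                                                       "pre_school": 0.47})
    season_spring_summer_prob: float = 0.29
    true_beta: dict = field(default_factory=default_true_beta)
    gamma_shape: float = 8.0
    weartime_mean_h: float = 11.5
    weartime_sd_h: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if self.n_children < 10:
            warnings.warn("n_children < 10 is too small for model-fitting "
                          "fixtures", stacklevel=2)
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        all_probs = [self.frac_school_age, self.frac_girls,
                     self.season_spring_summer_prob,
                     *self.safety_prob.values()]
        for probs in self.isced_probs.values():
            all_probs.extend(probs)
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("isced_probs must sum to 1 per age group")
        for p in all_probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Everything needed to recompute each child's linear predictor exactly."""

    true_beta: dict
    exposure: np.ndarray          # per-child true exposure
    linear_predictor: np.ndarray  # log μ per child
    gamma_shape: float
    seed: int
    density: DensityRaster | None = None
    layers: dict = field(default_factory=dict)


def _largest_remainder(n: int, probs) -> np.ndarray:
    """Integer allocation of n into categories matching probs exactly."""
    probs = np.asarray(probs, dtype=float)
    raw = probs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _exact_binary(n: int, p: float, rng) -> np.ndarray:
    k = int(round(p * n))
    out = np.zeros(n, dtype=int)
    out[:k] = 1
    rng.shuffle(out)
    return out


def _exact_categorical(n: int, probs, labels, rng) -> np.ndarray:
    counts = _largest_remainder(n, probs)
    out = np.repeat(labels, counts)
    rng.shuffle(out)
    return out


def generate_cohort(config: CohortConfig, density: DensityRaster | None = None,
                    truth_exposure_fn=None) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a cohort table and the generative truth behind it.

    Homes are sampled proportionally to residential density (uniform in the
    window if no raster is given); ``truth_exposure_fn(x, y)`` maps home
    coordinates to the true built-environment exposure entering the linear
    predictor (0 if omitted). MVPA is Gamma(shape ν) with
    log μ = Xβ using ``config.true_beta`` and centered continuous
    covariates (age − 6, weartime − 11.5).
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(0xC0C0,)))
    n = config.n_children

    n_school = int(round(config.frac_school_age * n))
    age_group = np.array(["school"] * n_school
                         + ["pre_school"] * (n - n_school))

    sex = np.empty(n, dtype=object)
    age = np.empty(n)
    safety = np.empty(n, dtype=int)
    for grp, lo, hi, mu, sd in (("school", 6.0, 9.9, 7.5, 0.8),
                                ("pre_school", 2.0, 5.999, 4.2, 0.85)):
        idx = np.flatnonzero(age_group == grp)
        if idx.size == 0:
            continue
        sex[idx] = _exact_categorical(
            idx.size, [config.frac_girls, 1 - config.frac_girls],
            np.array(["girl", "boy"], dtype=object), rng)
        age[idx] = np.clip(rng.normal(mu, sd, size=idx.size), lo, hi)
        safety[idx] = _exact_binary(idx.size, config.safety_prob[
            "school" if grp == "school" else "pre_school"], rng)

    isced = np.empty(n, dtype=object)
    for grp in ("school", "pre_school"):
        idx = np.flatnonzero(age_group == grp)
        if idx.size:
            isced[idx] = _exact_categorical(
                idx.size, config.isced_probs[grp],
                np.array(["low", "medium", "high"], dtype=object), rng)
    season = _exact_binary(n, config.season_spring_summer_prob, rng)
    bmi_z = rng.normal(0.3, 1.05, size=n)
    weartime = np.clip(rng.normal(config.weartime_mean_h, config.weartime_sd_h,
                                  size=n), 8.0, 16.0)

    if density is not None:
        homes = _sample_from_raster(n, density, rng)
    else:
        homes = rng.uniform(0, 1000, size=(n, 2))
    if truth_exposure_fn is not None:
        exposure = np.array([float(truth_exposure_fn(x, y)) for x, y in homes])
    else:
        exposure = np.zeros(n)

    b = config.true_beta
    eta = (b.get("intercept", math.log(60.0))
           + b.get("age", 0.0) * (age - AGE_CENTER)
           + b.get("bmi_z", 0.0) * bmi_z
           + b.get("weartime", 0.0) * (weartime - WEARTIME_CENTER)
           + b.get("season", 0.0) * season
           + b.get("safety", 0.0) * safety
           + b.get("isced_low", 0.0) * (isced == "low")
           + b.get("isced_high", 0.0) * (isced == "high")
           + b.get("exposure", 0.0) * exposure)
    mu = np.exp(eta)
    nu = config.gamma_shape
    mvpa = rng.gamma(shape=nu, scale=mu / nu)

    df = pd.DataFrame({
        "child_id": [f"c{i:04d}" for i in range(n)],
        "age_years": age,
        "sex": sex,
        "age_group": age_group,
        "bmi_z": bmi_z,
        "isced": isced,
        "safety_concerns": safety,
        "season": np.where(season == 1, "spring_summer", "autumn_winter"),
        "valid_weartime_h": weartime,
        "mvpa_min_per_day": mvpa,
        "home_x": homes[:, 0],
        "home_y": homes[:, 1],
        "true_exposure": exposure,
    })
    truth = SyntheticTruth(true_beta=dict(b), exposure=exposure,
                           linear_predictor=eta, gamma_shape=nu,
                           seed=config.seed, density=density)
    return df, truth


def simulate_screening(n_baseline: int = 448, n_rural: int = 24,
                       n_missing: int = 24, seed: int = 0) -> pd.DataFrame:
    """Baseline screening sample with the two study exclusion flags.

    Returns ``n_baseline`` children with valid accelerometry, of whom
    ``n_rural`` live in the rural peripheral area and a disjoint
    ``n_missing`` have missing questionnaire data. Marginals (age-group
    split, ISCED shares …) are pinned on the analysis sample — the children
    carrying neither flag — because that is the sample whose composition a
    study reports; the excluded children are drawn from the same
    distribution on top.
    """
    n_keep = n_baseline - n_rural - n_missing
    if n_keep < 1:
        raise ValueError("exclusions exceed the baseline sample")
    kept, _ = generate_cohort(CohortConfig(n_children=n_keep, seed=seed))
    extra, _ = generate_cohort(CohortConfig(n_children=n_rural + n_missing,
                                            seed=seed + 1))
    extra = extra.assign(child_id=[f"x{i:04d}" for i in range(len(extra))])
    kept["rural_peripheral"] = False
    kept["missing_questionnaire"] = False
    extra["rural_peripheral"] = [True] * n_rural + [False] * n_missing
    extra["missing_questionnaire"] = [False] * n_rural + [True] * n_missing
    df = pd.concat([kept, extra], ignore_index=True)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(0x5C2E,)))
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def apply_exclusions(screening: pd.DataFrame) -> pd.DataFrame:
    """Drop rural-peripheral children and those with missing questionnaires."""
    keep = ~(screening["rural_peripheral"] | screening["missing_questionnaire"])
    return screening[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# epoch-level accelerometer counts


@dataclass
class EpochConfig:
    """15-s epoch synthesis: diurnal wear window, injected non-wear bouts,
    MVPA epochs above the cut-off. ``noise='none'`` gives an exact,
    deterministic series for round-trip tests; ``'poisson'`` jitters counts
    and MVPA epoch placement while keeping the expected daily MVPA."""

    epoch_s: int = 15
    wear_start_hour: float = 7.0
    wear_end_hour: float = 21.0
    nonwear_bouts_min: tuple = (45.0,)
    mvpa_count: int = 700
    light_count: int = 100
    noise: str = "none"
    start_date: str = "2008-04-10"   # a Thursday: 4 days reach the weekend
    seed: int = 0


@dataclass
class EpochSeries:
    child_id: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"child_id": self.child_id,
                             "timestamp": self.timestamps,
                             "counts": self.counts})


def generate_epoch_counts(child_id: str, habitual_mvpa_min_per_day: float,
                          n_days: int, config: EpochConfig | None = None
                          ) -> EpochSeries:
    """Synthesize a 15-s epoch count series realizing a target habitual MVPA.

    Each day: zeros outside the wear window, configured non-wear bouts
    (zero runs) inside it, and MVPA-level counts on exactly (noise='none')
    or on average (noise='poisson') ``habitual × 4`` worn epochs; remaining
    worn epochs carry a light-activity count.
    """
    cfg = config or EpochConfig()
    per_day = 24 * 3600 // cfg.epoch_s
    w0 = int(cfg.wear_start_hour * 3600 / cfg.epoch_s)
    w1 = int(cfg.wear_end_hour * 3600 / cfg.epoch_s)
    bout_epochs = [int(round(b * 60 / cfg.epoch_s)) for b in cfg.nonwear_bouts_min]
    worn_per_day = (w1 - w0) - sum(bout_epochs)
    k_mvpa = habitual_mvpa_min_per_day * 60 / cfg.epoch_s
    if k_mvpa > worn_per_day:
        raise ValueError("habitual MVPA exceeds the daily wear window")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(0xE70C, sum(map(ord, child_id)) % 65536)))

    counts = np.zeros(n_days * per_day, dtype=int)
    for day in range(n_days):
        base = day * per_day
        worn = np.ones(per_day, dtype=bool)
        worn[:w0] = False
        worn[w1:] = False
        # non-wear bouts, placed mid-window so they never touch the
        # out-of-window zero runs
        pos = w0 + (w1 - w0) // 4
        for be in bout_epochs:
            worn[pos:pos + be] = False
            pos += be + 40  # ≥ 10 min of wear between bouts
        widx = np.flatnonzero(worn)
        if cfg.noise == "none":
            k = int(round(k_mvpa))
            mv = widx[:k]
            counts[base + widx] = cfg.light_count
            counts[base + mv] = cfg.mvpa_count
        else:
            p = k_mvpa / len(widx)
            is_mv = rng.random(len(widx)) < p
            light = rng.poisson(cfg.light_count, size=len(widx))
            light = np.minimum(light, 574)           # keep light below cut-off
            mv_counts = 575 + rng.poisson(cfg.mvpa_count - 575, size=len(widx))
            counts[base + widx] = np.where(is_mv, mv_counts, np.maximum(light, 1))
    t0 = pd.Timestamp(cfg.start_date)
    ts = t0 + pd.to_timedelta(np.arange(n_days * per_day) * cfg.epoch_s,
                              unit="s")
    return EpochSeries(child_id=child_id, timestamps=pd.DatetimeIndex(ts),
                       counts=counts)
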