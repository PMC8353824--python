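"""Synthetic cohorts with known ground truth.

Generates person-level cohorts (and optionally minute-level count streams)
with the statistical structure the analysis pipeline assumes:

* 4-part time-use compositions drawn logistic-normally — normal on ilr
  coordinates, inverse-ilr back to the simplex;
* wear time from a truncated normal (>= 600 min/day);
* behavior minutes = proportions x wear time, with MVPA rounded to whole
  minutes so that sub-half-minute MVPA becomes an exact (rounded) zero;
* survival from a Weibull baseline hazard with log-linear effects of the ilr
  coordinates and covariates, administratively censored uniformly over an
  accrual window.

The ``"whs-like"`` preset is moment-matched to a large cohort of older women
wearing hip accelerometers: behavior means near 14.7 / 63.6 / 222.0 / 591.3
min/day, wear 891 (SD 75) min/day, ~3% deaths over a mean 4.3 years of
follow-up and ~0.5% rounded-zero MVPA records.  Every draw is reproducible
from the single seed, and a ``TruthRecord`` table carries the pre-rounding
composition, linear predictor and uncensored event time for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .composition import PARTS, Composition, IlrBasis, close, ilr, pivot_basis
from .survival import CohortData

__all__ = [
    "GeneratorConfig",
    "whs_like_config",
    "generate_cohort",
    "true_hr",
    "generate_minute_streams",
]

# clr-scale log-hazard coefficients of the "whs-like" preset, order
# (MVPA, HLPA, LLPA, SB); derived once from published per-reallocation hazard
# ratios in older women (protective activity, harmful SB) and then frozen.
WHS_LIKE_CLR_EFFECTS = np.array([-0.10, -0.19, -0.26, 0.55])


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``beta_ilr`` is expressed in the pivot basis; use :func:`clr_to_ilr_beta`
    to convert a clr-scale effect vector.
    """

    n: int
    seed: int
    ilr_mean: np.ndarray
    ilr_cov: np.ndarray
    beta_ilr: np.ndarray
    wear_mean: float = 891.4
    wear_sd: float = 75.2
    wear_min: float = 600.0
    age_mean: float = 72.0
    age_sd: float = 5.7
    age_range: tuple[float, float] = (62.0, 101.0)
    smoker_prevalence: float = 0.035
    prevalent_cvd: float = 0.024
    prevalent_cancer: float = 0.119
    beta_age: float = 0.09
    beta_smoker: float = 0.5
    weibull_shape: float = 1.3
    weibull_scale: float = 160.0
    censor_low: float = 2.4
    censor_high: float = 6.2
    followup_cap: float = 6.5
    mvpa_rounding: bool = True
    reverse_causation: float = 0.0  # >0 links latent illness to low activity + death
    parts: tuple[str, ...] = PARTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "ilr_mean", np.asarray(self.ilr_mean, dtype=float))
        object.__setattr__(self, "ilr_cov", np.asarray(self.ilr_cov, dtype=float))
        object.__setattr__(self, "beta_ilr", np.asarray(self.beta_ilr, dtype=float))
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if self.weibull_shape <= 0:
            raise ValueError("Weibull shape must be positive")
        eig = np.linalg.eigvalsh(self.ilr_cov)
        if eig.min() <= 0:
            raise ValueError("ilr covariance must be positive definite")
        if not self.censor_low < self.censor_high <= self.followup_cap:
            raise ValueError("censoring window must be increasing and below the cap")

    @property
    def basis(self) -> IlrBasis:
        return pivot_basis(len(self.parts))


def clr_to_ilr_beta(gamma: np.ndarray, basis: IlrBasis) -> np.ndarray:
    """Convert a clr-scale (sum-zero) effect vector to ilr coordinates."""
    gamma = np.asarray(gamma, dtype=float)
    if abs(gamma.sum()) > 1e-9:
        raise ValueError("clr effects must sum to zero")
    return basis.matrix @ gamma


# "whs-like" preset moments, frozen from an offline moment-matching run
# (pilot draws iterated so minute-scale means track 14.7/63.6/222.0/591.3 and
# the rounded-zero MVPA fraction lands near 0.5%).
_WHS_ILR_MEAN = np.array([-2.6752183, -1.51911748, -0.70592632])
_WHS_ILR_COV = np.array(
    [
        [0.74478765, 0.08494911, 0.02105345],
        [0.08494911, 0.20539951, 0.02518447],
        [0.02105345, 0.02518447, 0.05260921],
    ]
)
_WHS_WEIBULL_SCALE = 72.0


def whs_like_config(n: int = 16676, seed: int = 0, **overrides) -> GeneratorConfig:
    """The calibrated "whs-like" preset (see module docstring)."""
    basis = pivot_basis(len(PARTS))
    cfg = GeneratorConfig(
        n=n,
        seed=seed,
        ilr_mean=_WHS_ILR_MEAN.copy(),
        ilr_cov=_WHS_ILR_COV.copy(),
        beta_ilr=clr_to_ilr_beta(WHS_LIKE_CLR_EFFECTS, basis),
        weibull_scale=_WHS_WEIBULL_SCALE,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _truncated_normal(
    rng: np.random.Generator, mean, sd, low, high, size
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _linear_predictor(
    cfg: GeneratorConfig, z: np.ndarray, age: np.ndarray, smoker: np.ndarray,
    ill: np.ndarray,
) -> np.ndarray:
    eta = (z - cfg.ilr_mean) @ cfg.beta_ilr
    eta += cfg.beta_age * (age - cfg.age_mean)
    eta += cfg.beta_smoker * smoker
    if cfg.reverse_causation > 0:
        eta += cfg.reverse_causation * ill
    return eta


def generate_cohort(cfg: GeneratorConfig) -> tuple[CohortData, pd.DataFrame]:
    """Draw a cohort and its ground-truth table.

    Returns ``(cohort, truth)`` where ``truth`` holds each subject's
    pre-rounding minutes, ilr coordinates, linear predictor and uncensored
    event time.  All randomness flows from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    basis = cfg.basis

    z = rng.multivariate_normal(cfg.ilr_mean, cfg.ilr_cov, size=n)

    ill = np.zeros(n)
    if cfg.reverse_causation > 0:
        # latent illness lowers activity and raises the death rate
        ill = (rng.random(n) < 0.05).astype(float)
        z[:, 0] -= 1.0 * ill

    logx = z @ basis.matrix  # clr-scale log abundances
    props = np.exp(logx - logx.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)

    wear = _truncated_normal(
        rng, cfg.wear_mean, cfg.wear_sd, cfg.wear_min, 1440.0, n
    )
    minutes = props * wear[:, None]
    minutes_true = minutes.copy()
    if cfg.mvpa_rounding:
        mvpa_idx = cfg.parts.index("MVPA")
        minutes[:, mvpa_idx] = np.round(minutes[:, mvpa_idx])

    age = _truncated_normal(
        rng, cfg.age_mean, cfg.age_sd, cfg.age_range[0], cfg.age_range[1], n
    )
    smoker = (rng.random(n) < cfg.smoker_prevalence).astype(int)
    cvd = (rng.random(n) < cfg.prevalent_cvd).astype(int)
    cancer = (rng.random(n) < cfg.prevalent_cancer).astype(int)

    eta = _linear_predictor(cfg, z, age, smoker, ill)
    # Weibull PH: S(t) = exp(-(t/scale)^shape * e^eta)
    e = rng.exponential(size=n)
    t_event = cfg.weibull_scale * (e * np.exp(-eta)) ** (1.0 / cfg.weibull_shape)
    t_censor = rng.uniform(cfg.censor_low, cfg.censor_high, size=n)
    t_censor = np.minimum(t_censor, cfg.followup_cap)
    event = (t_event <= t_censor).astype(int)
    follow_up = np.where(event == 1, t_event, t_censor)

    table = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "MVPA": minutes[:, 0],
            "HLPA": minutes[:, 1],
            "LLPA": minutes[:, 2],
            "SB": minutes[:, 3],
            "wear_minutes": wear,
            "age": age,
            "smoker": smoker,
            "prevalent_cvd": cvd,
            "prevalent_cancer": cancer,
            "follow_up": follow_up,
            "event": event,
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": table["subject_id"],
            "MVPA_true": minutes_true[:, 0],
            "HLPA_true": minutes_true[:, 1],
            "LLPA_true": minutes_true[:, 2],
            "SB_true": minutes_true[:, 3],
            "z1": z[:, 0],
            "z2": z[:, 1],
            "z3": z[:, 2],
            "linear_predictor": eta,
            "event_time": t_event,
            "ill": ill,
        }
    )
    # CohortData validates positivity, which rounded zeros violate by design;
    # hand back the raw frame and let callers run zero replacement first.
    return table, truth


def cohort_from_table(
    table: pd.DataFrame, covariates: tuple[str, ...] = ("age", "smoker")
) -> CohortData:
    """Wrap a generated (zero-free) table as analysis-ready CohortData."""
    return CohortData(table=table, covariates=covariates)


def true_hr(cfg: GeneratorConfig, comp: Composition, ref: Composition) -> float:
    """Generating-model hazard ratio of ``comp`` vs ``ref`` (covariates equal)."""
    d = ilr(comp, cfg.basis) - ilr(ref, cfg.basis)
    return float(np.exp(cfg.beta_ilr @ d))


# counts-per-minute sampling bands for minute-stream generation
_BANDS = {"SB": (1, 100), "LLPA": (101, 760), "HLPA": (761, 1951), "MVPA": (1952, 6000)}


def generate_minute_streams(
    cfg: GeneratorConfig, days_per_subject: int = 7
) -> tuple[list, pd.DataFrame]:
    """Per-minute count streams realizing the configured compositions.

    Each subject-day is a 1440-minute record: a wear block whose counts are
    drawn uniformly within each behavior's cut-point band (so classification
    recovers the intended minutes exactly), surrounded by zero-count non-wear
    bouts of >= 90 minutes.  Returns the series list and a truth table of the
    intended per-day behavior minutes.
    """
    from .accelerometer import MinuteSeries

    rng = np.random.default_rng(cfg.seed + 1)
    basis = cfg.basis
    z = rng.multivariate_normal(cfg.ilr_mean, cfg.ilr_cov, size=cfg.n)
    logx = z @ basis.matrix
    props = np.exp(logx - logx.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)

    series: list[MinuteSeries] = []
    rows: list[dict] = []
    for i in range(cfg.n):
        for day in range(1, days_per_subject + 1):
            wear = int(
                round(
                    _truncated_normal(
                        rng, cfg.wear_mean, cfg.wear_sd, cfg.wear_min, 1260.0, 1
                    )[0]
                )
            )
            # integer behavior minutes by largest remainder, summing to wear
            raw = props[i] * wear
            mins = np.floor(raw).astype(int)
            short = wear - mins.sum()
            order = np.argsort(-(raw - mins), kind="stable")
            mins[order[:short]] += 1

            counts = np.concatenate(
                [
                    rng.integers(_BANDS[p][0], _BANDS[p][1] + 1, size=m)
                    for p, m in zip(cfg.parts, mins)
                ]
            )
            rng.shuffle(counts)
            nonwear = 1440 - wear
            pre = int(rng.integers(90, nonwear - 90 + 1)) if nonwear >= 180 else nonwear
            day_counts = np.concatenate(
                [np.zeros(pre, np.int64), counts, np.zeros(nonwear - pre, np.int64)]
            )
            series.append(MinuteSeries(i + 1, day, day_counts))
            rows.append(
                {
                    "subject_id": i + 1,
                    "day_index": day,
                    "wear_minutes": wear,
                    **{p: int(m) for p, m in zip(cfg.parts, mins)},
                }
            )
    return series, pd.DataFrame(rows)
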