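"""Compositional Cox proportional-hazards modelling.

The exposure is a 4-part time-use composition (MVPA, HLPA, LLPA, SB as
proportions of accelerometer wear time).  The composition enters the Cox
model through its D-1 = 3 isometric log-ratio coordinates, jointly with
ordinary covariates:

    h(t | x, c) = h0(t) * exp( beta_ilr . ilr(x) + beta_cov . c )

The hazard ratio of a composition ``x`` against a referent ``r`` (covariates
held equal) is

    HR = exp( beta_ilr . (ilr(x) - ilr(r)) )

with a Wald interval from the ilr block of the variance-covariance matrix.
Because any two orthonormal ilr bases differ by a rotation of the coordinate
space, HR predictions are invariant to the choice of basis; that invariance
is the model's central correctness property and is exercised by the tests.

Partial-likelihood maximization (Efron tie handling), the Schoenfeld-residual
proportional-hazards test and martingale residuals are delegated to
``lifelines``.  A standard (non-compositional) Cox model on raw behavior
minutes, with one behavior left out, is provided as the comparator: there the
log HR of reallocating t minutes from the omitted behavior to behavior j is
t * beta_j, exactly linear in t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

from .composition import (
    PARTS,
    Composition,
    IlrBasis,
    close,
    compositional_mean,
    ilr,
    ilr_array,
    pivot_basis,
)

__all__ = [
    "CohortData",
    "CoxModel",
    "HREstimate",
    "fit_compositional_cox",
    "predict_hr",
    "referent_composition",
    "schoenfeld_test",
    "martingale_residuals",
    "fit_standard_cox",
    "StandardCoxModel",
]

ILR_COLS = ("z1", "z2", "z3")
_Z = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class CohortData:
    """Person-level analysis table.

    ``table`` must contain the four behavior columns (minutes/day, strictly
    positive after zero imputation), ``wear_minutes``, ``follow_up`` (years)
    and ``event`` (0/1), plus any covariate columns named in ``covariates``.
    """

    table: pd.DataFrame
    covariates: tuple[str, ...] = ()
    parts: tuple[str, ...] = PARTS

    def __post_init__(self) -> None:
        df = self.table
        needed = set(self.parts) | {"wear_minutes", "follow_up", "event"}
        needed |= set(self.covariates)
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
        if (df["follow_up"] <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be coded 0/1")
        if (df[list(self.parts)] <= 0).to_numpy().any():
            raise ValueError(
                "behavior minutes must be strictly positive; run zero replacement first"
            )

    @property
    def n(self) -> int:
        return len(self.table)

    def proportions(self) -> np.ndarray:
        mins = self.table[list(self.parts)].to_numpy(dtype=float)
        return mins / mins.sum(axis=1, keepdims=True)

    def mean_wear(self) -> float:
        return float(self.table["wear_minutes"].mean())


@dataclass(frozen=True)
class HREstimate:
    """A hazard ratio with its 95% Wald confidence interval."""

    hr: float
    lo: float
    hi: float
    se_log_hr: float

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.hr <= self.hi):
            raise ValueError("CI bounds must bracket the HR and be positive")
        if self.se_log_hr < 0:
            raise ValueError("standard error must be non-negative")


@dataclass(frozen=True)
class CoxModel:
    """A fitted compositional Cox model."""

    beta: pd.Series
    vcov: pd.DataFrame
    basis: IlrBasis
    log_likelihood: float
    n: int
    n_events: int
    covariates: tuple[str, ...]
    fitter: CoxPHFitter = field(repr=False)

    @property
    def beta_ilr(self) -> np.ndarray:
        return self.beta[list(ILR_COLS)].to_numpy(dtype=float)

    @property
    def vcov_ilr(self) -> np.ndarray:
        return self.vcov.loc[list(ILR_COLS), list(ILR_COLS)].to_numpy(dtype=float)

    def report(self) -> str:
        """Plain-text key-value summary of the fit."""
        lines = [
            f"n\t{self.n}",
            f"n_events\t{self.n_events}",
            f"log_partial_likelihood\t{self.log_likelihood:.6f}",
            f"basis\t{self.basis.description}",
        ]
        for name in self.beta.index:
            se = np.sqrt(self.vcov.loc[name, name])
            lines.append(f"beta[{name}]\t{self.beta[name]:.6f}\tse\t{se:.6f}")
        return "\n".join(lines)


def _ilr_frame(cohort: CohortData, basis: IlrBasis) -> pd.DataFrame:
    z = ilr_array(cohort.proportions(), basis)
    df = pd.DataFrame(z, columns=list(ILR_COLS), index=cohort.table.index)
    for c in cohort.covariates:
        df[c] = cohort.table[c].to_numpy(dtype=float)
    df["follow_up"] = cohort.table["follow_up"].to_numpy(dtype=float)
    df["event"] = cohort.table["event"].to_numpy(dtype=int)
    return df


def fit_compositional_cox(
    cohort: CohortData,
    basis: IlrBasis | None = None,
    *,
    wear_covariate: bool = False,
) -> CoxModel:
    """Maximize the Cox partial likelihood over ilr coordinates + covariates.

    Efron tie handling; Newton-Raphson run to a tight step tolerance so that
    refits under rotated bases agree to near machine precision.
    """
    basis = basis if basis is not None else pivot_basis(len(cohort.parts))
    n_events = int(cohort.table["event"].sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events to fit, got {n_events}")
    df = _ilr_frame(cohort, basis)
    if wear_covariate:
        df["wear_minutes"] = cohort.table["wear_minutes"].to_numpy(dtype=float)
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(
        df,
        duration_col="follow_up",
        event_col="event",
        fit_options={"precision": 1e-11, "max_steps": 500},
    )
    vcov = cph.variance_matrix_
    if not np.all(np.linalg.eigvalsh(vcov.to_numpy()) > -1e-10):
        raise RuntimeError("singular information matrix: variance estimate not PSD")
    return CoxModel(
        beta=cph.params_,
        vcov=vcov,
        basis=basis,
        log_likelihood=float(cph.log_likelihood_),
        n=cohort.n,
        n_events=n_events,
        covariates=cohort.covariates,
        fitter=cph,
    )


def predict_hr(model: CoxModel, comp: Composition, ref: Composition) -> HREstimate:
    """Hazard ratio of ``comp`` vs ``ref`` with a 95% Wald interval.

    Covariates cancel (held equal); only the ilr block of the fit enters.
    """
    if abs(comp.total - ref.total) > 1e-6 * max(1.0, ref.total):
        raise ValueError(
            f"composition totals differ ({comp.total} vs {ref.total}); "
            "close them to a common scale first"
        )
    d = ilr(comp, model.basis) - ilr(ref, model.basis)
    log_hr = float(model.beta_ilr @ d)
    var = float(d @ model.vcov_ilr @ d)
    se = np.sqrt(max(var, 0.0))
    return HREstimate(
        hr=float(np.exp(log_hr)),
        lo=float(np.exp(log_hr - _Z * se)),
        hi=float(np.exp(log_hr + _Z * se)),
        se_log_hr=float(se),
    )


def referent_composition(
    cohort: CohortData,
    quartile_metric: str = "total_activity_proportion",
    in_minutes: bool = False,
) -> Composition:
    """Compositional mean of the least-active quartile of the cohort.

    ``quartile_metric`` options:

    * ``"total_activity_proportion"`` (default) — share of wear time spent in
      any activity (MVPA + HLPA + LLPA over wear);
    * ``"mvpa_proportion"`` — MVPA share of wear time alone.

    The lowest-ranked quarter of subjects (stable order on ties) defines the
    referent.  Returned as proportions, or as minutes/day at the cohort mean
    wear time when ``in_minutes`` is set.
    """
    props = cohort.proportions()
    sb_idx = cohort.parts.index("SB")
    if quartile_metric == "total_activity_proportion":
        metric = 1.0 - props[:, sb_idx]
    elif quartile_metric == "mvpa_proportion":
        metric = props[:, cohort.parts.index("MVPA")]
    else:
        raise ValueError(f"unknown quartile metric {quartile_metric!r}")
    k = max(1, cohort.n // 4)
    order = np.argsort(metric, kind="stable")
    rows = props[order[:k]]
    total = cohort.mean_wear() if in_minutes else 1.0
    return compositional_mean(rows, total=total, parts=cohort.parts)


def schoenfeld_test(
    model: CoxModel, cohort: CohortData, time_transform: str = "km"
) -> pd.DataFrame:
    """Proportional-hazards test from scaled Schoenfeld residuals.

    Returns a frame with one row per coefficient plus a ``global`` row,
    columns ``chi2``, ``df``, ``p``.
    """
    if cohort.table["event"].sum() < 3:
        raise ValueError("need at least 3 events for the Schoenfeld test")
    df = _ilr_frame(cohort, model.basis)
    if "wear_minutes" in model.beta.index:
        df["wear_minutes"] = cohort.table["wear_minutes"].to_numpy(dtype=float)
    res = proportional_hazard_test(model.fitter, df, time_transform=time_transform)
    stats = res.summary["test_statistic"]
    pvals = res.summary["p"]
    rows = {
        str(name): {"chi2": float(stats[name]), "df": 1, "p": float(pvals[name])}
        for name in stats.index
    }
    global_chi2 = float(stats.sum())
    k = len(stats)
    from scipy.stats import chi2 as chi2_dist

    rows["global"] = {
        "chi2": global_chi2,
        "df": k,
        "p": float(chi2_dist.sf(global_chi2, k)),
    }
    return pd.DataFrame(rows).T


def martingale_residuals(model: CoxModel, cohort: CohortData) -> pd.DataFrame:
    """Per-subject martingale residuals with raw behavior minutes attached.

    The residual is the event indicator minus the estimated cumulative hazard
    at exit; plotted against untransformed minutes these diagnose functional
    form, which is how the curvilinear dose-response shows up before any
    compositional transformation.
    """
    df = _ilr_frame(cohort, model.basis)
    if "wear_minutes" in model.beta.index:
        df["wear_minutes"] = cohort.table["wear_minutes"].to_numpy(dtype=float)
    res = model.fitter.compute_residuals(df, kind="martingale")
    out = res[["martingale"]].copy()
    out = out.join(cohort.table[list(cohort.parts)])
    return out


@dataclass(frozen=True)
class StandardCoxModel:
    """Non-compositional comparator: Cox on raw minutes with one part dropped.

    Coefficients are per-minute log hazard ratios for increasing a retained
    behavior at the expense of the dropped one (total time held fixed through
    the wear-time covariate).
    """

    beta: pd.Series
    vcov: pd.DataFrame
    drop_part: str
    log_likelihood: float
    n: int
    n_events: int
    fitter: CoxPHFitter = field(repr=False)

    def reallocation_hr(self, to_part: str, minutes: float) -> HREstimate:
        """HR of moving ``minutes`` from the dropped behavior to ``to_part``.

        Exactly log-linear in ``minutes`` by construction.
        """
        if to_part == self.drop_part:
            raise ValueError("destination equals the omitted behavior")
        b = float(self.beta[to_part])
        se1 = float(np.sqrt(self.vcov.loc[to_part, to_part]))
        log_hr = minutes * b
        se = abs(minutes) * se1
        return HREstimate(
            hr=float(np.exp(log_hr)),
            lo=float(np.exp(log_hr - _Z * se)),
            hi=float(np.exp(log_hr + _Z * se)),
            se_log_hr=se,
        )


def fit_standard_cox(
    cohort: CohortData,
    drop_part: str = "SB",
    *,
    wear_covariate: bool = True,
) -> StandardCoxModel:
    """Fit the standard Cox comparator on raw behavior minutes.

    All behaviors but ``drop_part`` enter in minutes/day, so each coefficient
    estimates the effect of one more minute of that behavior at the expense of
    the omitted behavior.  Wear minutes are adjusted for by default.
    """
    n_events = int(cohort.table["event"].sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events to fit, got {n_events}")
    keep = [p for p in cohort.parts if p != drop_part]
    df = cohort.table[keep + list(cohort.covariates)].astype(float).copy()
    if wear_covariate:
        df["wear_minutes"] = cohort.table["wear_minutes"].to_numpy(dtype=float)
    df["follow_up"] = cohort.table["follow_up"].to_numpy(dtype=float)
    df["event"] = cohort.table["event"].to_numpy(dtype=int)
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(
        df,
        duration_col="follow_up",
        event_col="event",
        fit_options={"precision": 1e-11, "max_steps": 500},
    )
    return StandardCoxModel(
        beta=cph.params_,
        vcov=cph.variance_matrix_,
        drop_part=drop_part,
        log_likelihood=float(cph.log_likelihood_),
        n=cohort.n,
        n_events=n_events,
        fitter=cph,
    )
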