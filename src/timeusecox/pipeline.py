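"""End-to-end orchestration: cohort table -> imputation -> models -> analyses.

This is the programmatic counterpart of the command-line interface: each
function takes and returns plain tables or fitted model objects so stages can
be run, inspected and persisted independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import PARTS, Composition, close
from .reallocation import (
    build_scenarios,
    compare_models,
    evaluate_scenarios,
    pairwise_curves,
    scenarios_frame,
    single_behavior_curves,
    ternary_hr_grid,
)
from .survival import (
    CohortData,
    fit_compositional_cox,
    fit_standard_cox,
    martingale_residuals,
    predict_hr,
    referent_composition,
    schoenfeld_test,
)
from .zeros import ZeroPattern, lr_em_impute, multiplicative_replace

__all__ = [
    "impute_cohort_zeros",
    "apply_sensitivity_filter",
    "run_analysis",
    "AnalysisResult",
]

SENSITIVITY_FILTERS = ("none", "exclude-2y", "exclude-prevalent", "all")


def impute_cohort_zeros(
    table: pd.DataFrame,
    method: str = "lrem",
    parts: tuple[str, ...] = PARTS,
) -> pd.DataFrame:
    """Replace rounded MVPA zeros in a person-level minutes table.

    The detection limit is one recordable minute per day of wear, i.e.
    ``1 / wear_minutes`` in proportion units.  Rows are converted to
    proportions, imputed (lrEM by default, ``method="multiplicative"`` for
    the fallback), and mapped back to minutes at each subject's wear time.
    """
    mins = table[list(parts)].to_numpy(dtype=float)
    if (mins > 0).all():
        return table.copy()
    wear = table["wear_minutes"].to_numpy(dtype=float)
    props = mins / mins.sum(axis=1, keepdims=True)
    dl = np.broadcast_to((1.0 / wear)[:, None], props.shape)
    pattern = ZeroPattern(props, dl, parts=parts)
    if method == "lrem":
        imputed = lr_em_impute(pattern)
    elif method == "multiplicative":
        imputed = multiplicative_replace(pattern)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    out = table.copy()
    out[list(parts)] = imputed * mins.sum(axis=1, keepdims=True)
    return out


def apply_sensitivity_filter(table: pd.DataFrame, which: str) -> pd.DataFrame:
    """Row-predicate exclusions mirroring the reverse-causation checks.

    ``exclude-2y`` drops follow-up < 2 years; ``exclude-prevalent`` drops
    prevalent cardiovascular disease or cancer; ``all`` applies both.
    """
    if which not in SENSITIVITY_FILTERS:
        raise ValueError(f"unknown sensitivity filter {which!r}")
    out = table
    if which in ("exclude-2y", "all"):
        out = out[out["follow_up"] >= 2.0]
    if which in ("exclude-prevalent", "all"):
        for col in ("prevalent_cvd", "prevalent_cancer"):
            if col in out.columns:
                out = out[out[col] == 0]
    return out.reset_index(drop=True)


@dataclass
class AnalysisResult:
    """All artifacts of one end-to-end run."""

    cohort: CohortData
    model: object
    std_model: object
    referent: Composition  # minutes/day at cohort mean wear
    curves: dict
    pairwise: dict
    scenarios: pd.DataFrame
    comparison: pd.DataFrame
    schoenfeld: pd.DataFrame
    ternary: dict | None = None


def run_analysis(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "smoker"),
    *,
    basis=None,
    quartile_metric: str = "total_activity_proportion",
    sensitivity: str = "none",
    imputation: str = "lrem",
    curve_step: float = 5.0,
    ternary_resolution: int = 0,
) -> AnalysisResult:
    """Run the full analysis on a person-level minutes table.

    Produces the single-behavior curves, the four SB-pairwise curves, the
    predefined scenarios, the standard-vs-compositional 30-minute comparison
    and the proportional-hazards diagnostics.  ``curve_step`` sets the grid
    spacing in minutes.
    """
    table = apply_sensitivity_filter(table, sensitivity)
    table = impute_cohort_zeros(table, method=imputation)
    cohort = CohortData(table=table, covariates=covariates)

    model = fit_compositional_cox(cohort, basis=basis)
    std_model = fit_standard_cox(cohort, drop_part="SB")
    ref = referent_composition(cohort, quartile_metric, in_minutes=True)

    curves = {}
    for part in cohort.parts:
        lo = max(1.0, 0.25 * ref[part])
        hi = min(ref.total - 1.0, 4.0 * ref[part] + 60.0)
        grid = np.arange(lo, hi, curve_step)
        if ref[part] > lo:  # make sure the curve passes through the referent
            grid = np.unique(np.append(grid, ref[part]))
        curves[part] = single_behavior_curves(model, ref, part, grid)

    pairwise = {}
    for to_part in ("MVPA", "HLPA", "LLPA"):
        deltas = np.arange(curve_step, min(120.0, ref["SB"] - 1.0), curve_step)
        pairwise[to_part] = pairwise_curves(model, ref, "SB", to_part, deltas)

    scen = evaluate_scenarios(model, ref, build_scenarios(ref, cohort))
    comparison = compare_models(model, std_model, ref, delta=30.0, from_part="SB")
    sch = schoenfeld_test(model, cohort)

    result = AnalysisResult(
        cohort=cohort,
        model=model,
        std_model=std_model,
        referent=ref,
        curves=curves,
        pairwise=pairwise,
        scenarios=scenarios_frame(scen),
        comparison=comparison,
        schoenfeld=sch,
    )
    if ternary_resolution >= 2:
        result.ternary = {
            part: ternary_hr_grid(model, ref, part, resolution=ternary_resolution)
            for part in cohort.parts
        }
    return result
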