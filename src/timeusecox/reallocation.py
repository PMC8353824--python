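"""Time-reallocation hazard-ratio analyses.

Everything here is a thin composition of two primitives — a substitution
constructor from :mod:`timeusecox.composition` and
:func:`timeusecox.survival.predict_hr` — evaluated over grids of reallocated
minutes:

* single-behavior dose-response curves (vary one behavior, shrink the others
  proportionally);
* pairwise reallocation curves (move minutes between two behaviors, hold the
  other two fixed);
* predefined time-use scenarios, including the guideline-meeting
  reallocation (+22 min/day of MVPA from SB) and light-activity combinations;
* ternary HR grids over the 3-part sub-simplex with one behavior fixed;
* the standard-vs-compositional model comparison for 30-minute reallocations
  out of SB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import (
    Composition,
    close,
    compositional_mean,
    pairwise_substitution,
    proportional_substitution,
)
from .survival import (
    CohortData,
    CoxModel,
    HREstimate,
    StandardCoxModel,
    predict_hr,
)

__all__ = [
    "ReallocationCurve",
    "TernaryGrid",
    "Scenario",
    "single_behavior_curves",
    "pairwise_curves",
    "build_scenarios",
    "evaluate_scenarios",
    "ternary_hr_grid",
    "compare_models",
]


@dataclass(frozen=True)
class ReallocationCurve:
    """HR estimates along a grid of reallocated minutes."""

    scenario: str
    grid: np.ndarray
    estimates: tuple[HREstimate, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", g)
        if len(g) != len(self.estimates):
            raise ValueError("grid and estimates differ in length")
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "minutes": self.grid,
                "hr": [e.hr for e in self.estimates],
                "lo": [e.lo for e in self.estimates],
                "hi": [e.hi for e in self.estimates],
            }
        )


@dataclass(frozen=True)
class TernaryGrid:
    """HR estimates over the sub-simplex of three behaviors, one held fixed."""

    fixed_part: str
    fixed_proportion: float
    free_parts: tuple[str, str, str]
    nodes: np.ndarray  # (m, 3) proportions of the free parts (sum to 1 - fixed)
    estimates: tuple[HREstimate, ...]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.nodes, columns=list(self.free_parts))
        df["hr"] = [e.hr for e in self.estimates]
        df["lo"] = [e.lo for e in self.estimates]
        df["hi"] = [e.hi for e in self.estimates]
        return df


@dataclass(frozen=True)
class Scenario:
    """A named target composition compared against the referent."""

    name: str
    target: Composition
    estimate: HREstimate | None = None


def single_behavior_curves(
    model: CoxModel,
    ref: Composition,
    part: str,
    value_grid: np.ndarray,
) -> ReallocationCurve:
    """Vary one behavior over ``value_grid`` minutes, others proportionally."""
    grid = np.asarray(value_grid, dtype=float)
    if np.any((grid <= 0) | (grid >= ref.total)):
        raise ValueError("grid values must lie strictly inside (0, total)")
    ests = tuple(
        predict_hr(model, proportional_substitution(ref, part, v), ref) for v in grid
    )
    return ReallocationCurve(f"{part} (proportional)", grid, ests)


def pairwise_curves(
    model: CoxModel,
    ref: Composition,
    from_part: str,
    to_part: str,
    delta_grid: np.ndarray,
) -> ReallocationCurve:
    """Move ``delta`` minutes from one behavior to another along a grid."""
    grid = np.asarray(delta_grid, dtype=float)
    if np.any(grid >= ref[from_part]):
        raise ValueError(
            f"cannot reallocate more than the {ref[from_part]:.4g} min "
            f"available in {from_part}"
        )
    ests = tuple(
        predict_hr(model, pairwise_substitution(ref, from_part, to_part, d), ref)
        for d in grid
    )
    return ReallocationCurve(f"{from_part}->{to_part}", grid, ests)


# published reallocation amounts for the predefined scenarios (min/day)
GUIDELINE_MVPA_DELTA = 22.0  # (a): SB -> MVPA, 150 min/week
SB_TO_LLPA_DELTA = 120.0  # (b)
SB_TO_HLPA_DELTA = 60.0  # (c)
COMBO_HLPA_DELTA = 90.0  # (e)
COMBO_LLPA_DELTA = 120.0  # (e)
GUIDELINE_MVPA_MIN_PER_DAY = 150.0 / 7.0  # guideline threshold for scenario (d)


def build_scenarios(
    ref: Composition, cohort: CohortData | None = None
) -> list[Scenario]:
    """The five predefined time-use scenarios, constructed from the referent.

    (a) move 22 min/day from SB to MVPA (meets the 150 min/week guideline);
    (b) move 120 min/day from SB to LLPA;
    (c) move 60 min/day from SB to HLPA;
    (d) the mean composition of guideline-meeting subjects (requires a
        cohort; closed to the referent's total);
    (e) move 90 min/day from SB to HLPA plus 120 min/day from SB to LLPA,
        MVPA unchanged.
    """
    out = [
        Scenario(
            "a: SB->MVPA 22 min (guidelines)",
            pairwise_substitution(ref, "SB", "MVPA", GUIDELINE_MVPA_DELTA),
        ),
        Scenario(
            "b: SB->LLPA 120 min",
            pairwise_substitution(ref, "SB", "LLPA", SB_TO_LLPA_DELTA),
        ),
        Scenario(
            "c: SB->HLPA 60 min",
            pairwise_substitution(ref, "SB", "HLPA", SB_TO_HLPA_DELTA),
        ),
    ]
    if cohort is not None:
        meet = cohort.table["MVPA"] >= GUIDELINE_MVPA_MIN_PER_DAY
        if meet.any():
            mat = cohort.proportions()[meet.to_numpy()]
            out.append(
                Scenario(
                    "d: guideline-meeters mean",
                    compositional_mean(mat, total=ref.total, parts=ref.parts),
                )
            )
    e = pairwise_substitution(ref, "SB", "HLPA", COMBO_HLPA_DELTA)
    e = pairwise_substitution(e, "SB", "LLPA", COMBO_LLPA_DELTA)
    out.append(Scenario("e: SB->HLPA 90 + SB->LLPA 120", e))
    return out


def evaluate_scenarios(
    model: CoxModel, ref: Composition, scenarios: list[Scenario]
) -> list[Scenario]:
    """Attach an HR estimate vs the referent to each scenario."""
    out = []
    for sc in scenarios:
        if abs(sc.target.total - ref.total) > 1e-6 * max(1.0, ref.total):
            raise ValueError(
                f"scenario {sc.name!r} total {sc.target.total} does not match "
                f"the referent total {ref.total}"
            )
        out.append(Scenario(sc.name, sc.target, predict_hr(model, sc.target, ref)))
    return out


def scenarios_frame(scenarios: list[Scenario]) -> pd.DataFrame:
    rows = []
    for sc in scenarios:
        row = {"scenario": sc.name, **sc.target.as_dict()}
        if sc.estimate is not None:
            row.update(hr=sc.estimate.hr, lo=sc.estimate.lo, hi=sc.estimate.hi)
        rows.append(row)
    return pd.DataFrame(rows)


def ternary_hr_grid(
    model: CoxModel,
    ref: Composition,
    fixed_part: str,
    resolution: int = 100,
    floor: float | None = None,
) -> TernaryGrid:
    """HRs over a barycentric lattice of the three free behaviors.

    The fixed behavior keeps its referent proportion; lattice nodes split the
    remaining share among the other three.  Nodes with any free part below
    ``floor`` (default: one minute at the referent total) are excluded since
    log-ratios diverge at zero.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    free = tuple(p for p in ref.parts if p != fixed_part)
    fixed_prop = ref[fixed_part] / ref.total
    budget = ref.total - ref[fixed_part]
    if floor is None:
        floor = 1.0 if ref.total > 2 else 1.0 / ref.total  # one minute either way

    nodes = []
    ests = []
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            k = resolution - i - j
            vals = np.array([i, j, k], dtype=float) / resolution * budget
            if np.any(vals < floor):
                continue
            full = {fixed_part: ref[fixed_part]}
            full.update(dict(zip(free, vals)))
            comp = Composition(
                np.array([full[p] for p in ref.parts]),
                total=ref.total,
                parts=ref.parts,
            )
            nodes.append(vals)
            ests.append(predict_hr(model, comp, ref))
    return TernaryGrid(
        fixed_part=fixed_part,
        fixed_proportion=fixed_prop,
        free_parts=free,
        nodes=np.asarray(nodes),
        estimates=tuple(ests),
    )


def compare_models(
    comp_model: CoxModel,
    std_model: StandardCoxModel,
    ref: Composition,
    delta: float = 30.0,
    from_part: str = "SB",
) -> pd.DataFrame:
    """Standard vs compositional HRs for a fixed reallocation out of one part.

    Returns a tidy frame: destination behavior x model, with HR and CI.
    """
    if std_model.drop_part != from_part:
        raise ValueError(
            f"standard model omitted {std_model.drop_part!r}; it can only price "
            f"reallocations out of that behavior, not {from_part!r}"
        )
    rows = []
    for to_part in (p for p in ref.parts if p != from_part):
        comp_est = predict_hr(
            comp_model, pairwise_substitution(ref, from_part, to_part, delta), ref
        )
        std_est = std_model.reallocation_hr(to_part, delta)
        rows.append(
            {
                "to_part": to_part,
                "model": "compositional",
                "hr": comp_est.hr,
                "lo": comp_est.lo,
                "hi": comp_est.hi,
            }
        )
        rows.append(
            {
                "to_part": to_part,
                "model": "standard",
                "hr": std_est.hr,
                "lo": std_est.lo,
                "hi": std_est.hi,
            }
        )
    return pd.DataFrame(rows)
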