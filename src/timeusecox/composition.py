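"""Compositional algebra for time-use data.

A day of waking time is treated as a composition: the minutes spent in
moderate-to-vigorous physical activity (MVPA), higher-light physical activity
(HLPA), lower-light physical activity (LLPA) and sedentary behavior (SB) carry
only relative information once wear time is factored out.  This module
provides closure, isometric log-ratio (ilr) coordinates, compositional
(geometric) means, and the two substitution constructors used by the
reallocation analyses:

* proportional substitution — set one behavior to a new value and rescale the
  others by a common factor so the total is preserved;
* pairwise substitution — move minutes from one behavior to another, leaving
  the remaining behaviors untouched.

Everything is written for a general number of parts D but the package uses
D = 4 with the fixed order ``(MVPA, HLPA, LLPA, SB)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: canonical part order used throughout the package
PARTS: tuple[str, ...] = ("MVPA", "HLPA", "LLPA", "SB")

__all__ = [
    "PARTS",
    "Composition",
    "IlrBasis",
    "pivot_basis",
    "close",
    "ilr",
    "ilr_inverse",
    "compositional_mean",
    "proportional_substitution",
    "pairwise_substitution",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """A strictly positive composition with labelled parts.

    Parameters
    ----------
    values : array of float
        Strictly positive part values summing to ``total``.
    total : float
        The constant-sum scale: 1.0 for proportions of wear time, or
        minutes per day.
    parts : tuple of str
        Part labels, default ``(MVPA, HLPA, LLPA, SB)``.
    """

    values: np.ndarray
    total: float = 1.0
    parts: tuple[str, ...] = PARTS

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) != len(self.parts):
            raise ValueError(
                f"expected {len(self.parts)} part values, got shape {vals.shape}"
            )
        bad = np.nonzero(vals <= 0)[0]
        if bad.size:
            raise ValueError(
                f"non-positive part {self.parts[bad[0]]!r} = {vals[bad[0]]}; "
                "zeros must be imputed before constructing a Composition"
            )
        if self.total <= 0:
            raise ValueError(f"total must be positive, got {self.total}")
        if abs(vals.sum() - self.total) > _REL_TOL * max(1.0, abs(self.total)):
            raise ValueError(
                f"values sum to {vals.sum()}, not the stated total {self.total}"
            )

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.parts.index(part)])

    def proportions(self) -> np.ndarray:
        return self.values / self.total

    def rescale(self, total: float) -> "Composition":
        """Re-close to a different constant sum (no relative information changes)."""
        return close(self.values, total, self.parts)

    def as_dict(self) -> dict[str, float]:
        return {p: float(v) for p, v in zip(self.parts, self.values)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{p}={v:.4g}" for p, v in zip(self.parts, self.values))
        return f"Composition({body}; total={self.total:.6g})"


def close(
    values: Iterable[float], total: float = 1.0, parts: tuple[str, ...] = PARTS
) -> Composition:
    """Close a positive part vector to a constant sum.

    Raises ``ValueError`` naming the offending part if any value is <= 0.
    """
    vals = np.asarray(list(values), dtype=float)
    if len(vals) != len(parts):
        raise ValueError(f"expected {len(parts)} values, got {len(vals)}")
    bad = np.nonzero(vals <= 0)[0]
    if bad.size:
        raise ValueError(f"part {parts[bad[0]]!r} is non-positive ({vals[bad[0]]})")
    if total <= 0:
        raise ValueError("total must be positive")
    return Composition(vals * (total / vals.sum()), total=total, parts=parts)


@dataclass(frozen=True)
class IlrBasis:
    """An orthonormal ilr contrast matrix of shape (D-1, D).

    Rows are orthonormal and each row is orthogonal to the all-ones vector,
    so coordinates ``z = B @ log(x)`` are invariant to the closure constant.
    """

    matrix: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        mat = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", mat)
        d1, d = mat.shape
        if d1 != d - 1:
            raise ValueError(f"contrast matrix must be (D-1, D), got {mat.shape}")
        if not np.allclose(mat @ mat.T, np.eye(d1), atol=1e-10):
            raise ValueError("basis rows are not orthonormal")
        if not np.allclose(mat @ np.ones(d), 0.0, atol=1e-10):
            raise ValueError("basis rows must be orthogonal to the ones vector")

    @property
    def n_parts(self) -> int:
        return self.matrix.shape[1]

    def rotate(self, q: np.ndarray, description: str = "rotated") -> "IlrBasis":
        """Another valid basis: left-multiply the contrasts by an orthogonal Q."""
        q = np.asarray(q, dtype=float)
        return IlrBasis(q @ self.matrix, description=description)


def pivot_basis(n_parts: int = len(PARTS)) -> IlrBasis:
    """Pivot (sequential binary partition) ilr basis.

    Coordinate k isolates part k against the geometric mean of the parts after
    it: z_k = sqrt((D-k)/(D-k+1)) * ln( x_k / gmean(x_{k+1}, ..., x_D) ).
    For the canonical order this reads MVPA vs the rest, then HLPA vs
    (LLPA, SB), then LLPA vs SB.
    """
    d = n_parts
    mat = np.zeros((d - 1, d))
    for k in range(d - 1):
        r = d - k - 1  # parts remaining after the pivot
        coef = np.sqrt(r / (r + 1))
        mat[k, k] = coef
        mat[k, k + 1 :] = -coef / r
    return IlrBasis(mat, description="pivot: each part vs geometric mean of later parts")


def ilr(comp: Composition, basis: IlrBasis | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates of a composition (scale-invariant)."""
    basis = basis if basis is not None else pivot_basis(len(comp.parts))
    if basis.n_parts != len(comp.parts):
        raise ValueError("basis dimension does not match the composition")
    return basis.matrix @ np.log(comp.values)


def ilr_array(matrix: np.ndarray, basis: IlrBasis | None = None) -> np.ndarray:
    """Row-wise ilr of an (n, D) strictly positive array."""
    x = np.asarray(matrix, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive entries")
    basis = basis if basis is not None else pivot_basis(x.shape[1])
    return np.log(x) @ basis.matrix.T


def ilr_inverse(
    coords: Sequence[float],
    basis: IlrBasis | None = None,
    total: float = 1.0,
    parts: tuple[str, ...] = PARTS,
) -> Composition:
    """Map ilr coordinates back to a composition closed to ``total``."""
    z = np.asarray(coords, dtype=float)
    basis = basis if basis is not None else pivot_basis(len(parts))
    logx = basis.matrix.T @ z
    vals = np.exp(logx - logx.max())  # guard overflow; closure removes the shift
    return close(vals, total, parts)


def compositional_mean(
    rows: Sequence[Composition] | np.ndarray,
    total: float = 1.0,
    parts: tuple[str, ...] = PARTS,
) -> Composition:
    """Closed vector of per-part geometric means (the compositional center).

    Accepts a sequence of ``Composition`` or an (n, D) positive array; each
    row's own total is irrelevant (the center is scale-invariant).
    """
    if isinstance(rows, np.ndarray):
        mat = np.asarray(rows, dtype=float)
    else:
        rows = list(rows)
        if not rows:
            raise ValueError("cannot average an empty set of compositions")
        parts = rows[0].parts
        mat = np.vstack([c.values for c in rows])
    if mat.size == 0:
        raise ValueError("cannot average an empty set of compositions")
    if np.any(mat <= 0):
        raise ValueError("compositional mean requires strictly positive parts")
    center = np.exp(np.mean(np.log(mat), axis=0))
    return close(center, total, parts)


def proportional_substitution(
    ref: Composition, part: str, new_value: float
) -> Composition:
    """Set one behavior to ``new_value``, rescaling the others proportionally.

    The ratios among the untouched behaviors are preserved and the total is
    unchanged — the "increase one behavior at the proportional expense of all
    others" construction behind the single-behavior dose-response curves.
    """
    idx = ref.parts.index(part)
    if not 0 < new_value < ref.total:
        raise ValueError(
            f"new value for {part} must lie strictly between 0 and the total "
            f"{ref.total}, got {new_value}"
        )
    vals = ref.values.copy()
    remainder_old = ref.total - vals[idx]
    remainder_new = ref.total - new_value
    vals[idx] = new_value
    others = np.arange(len(vals)) != idx
    vals[others] *= remainder_new / remainder_old
    return Composition(vals, total=ref.total, parts=ref.parts)


def pairwise_substitution(
    ref: Composition, from_part: str, to_part: str, delta: float
) -> Composition:
    """Move ``delta`` minutes from one behavior to another, others untouched."""
    if from_part == to_part:
        raise ValueError("from_part and to_part must differ")
    i = ref.parts.index(from_part)
    j = ref.parts.index(to_part)
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if delta >= ref.values[i]:
        raise ValueError(
            f"cannot move {delta} min out of {from_part} "
            f"({ref.values[i]:.4g} min available)"
        )
    vals = ref.values.copy()
    vals[i] -= delta
    vals[j] += delta
    return Composition(vals, total=ref.total, parts=ref.parts)
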