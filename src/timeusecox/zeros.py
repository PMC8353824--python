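"""Rounded-zero replacement for time-use compositions.

A subject who accrued no whole minute of MVPA has a *rounded* zero: the true
proportion is positive but below the detection limit (DL) of one recordable
minute per day of wear.  Log-ratio methods cannot accept zeros, so these are
imputed before analysis.

Two methods are provided:

* :func:`lr_em_impute` — the log-ratio EM algorithm for rounded zeros: model
  the additive log-ratio (alr) coordinates, taken against a zero-free
  reference part, as multivariate normal; iterate between estimating the
  normal parameters from the completed data and replacing each censored entry
  by its conditional expectation truncated above at the alr-transformed DL.
* :func:`multiplicative_replace` — the simple multiplicative rule (zero ->
  0.65 * DL, observed parts of the row rescaled), used as a fallback and as a
  cross-check on the EM result.

Both leave the ratios among a row's observed parts untouched and preserve the
row closure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .composition import PARTS

__all__ = ["ZeroPattern", "lr_em_impute", "multiplicative_replace"]


@dataclass(frozen=True)
class ZeroPattern:
    """A proportion matrix with rounded zeros and per-entry detection limits.

    Parameters
    ----------
    data : (n, D) array
        Row-closed proportions; zeros mark censored entries.
    detection_limit : (n, D) or (D,) or scalar
        Detection limit in proportion units for each entry (e.g. 1 minute /
        the subject's wear minutes for count data at minute resolution).
    parts : part labels.
    """

    data: np.ndarray
    detection_limit: np.ndarray
    parts: tuple[str, ...] = PARTS

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.data, dtype=float))
        dl = np.broadcast_to(
            np.asarray(self.detection_limit, dtype=float), x.shape
        ).copy()
        object.__setattr__(self, "data", x)
        object.__setattr__(self, "detection_limit", dl)
        if np.any(x < 0):
            raise ValueError("proportions must be non-negative")
        if np.any(dl <= 0):
            raise ValueError("detection limits must be positive")
        if not np.allclose(x.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows must be closed to 1")
        if np.any(np.all(x == 0, axis=1)):
            raise ValueError("every row needs at least one observed part")

    @property
    def zero_mask(self) -> np.ndarray:
        return self.data == 0


def _reclose_rows(x: np.ndarray, imputed: np.ndarray) -> np.ndarray:
    """Rescale each row's observed parts so the row sums to 1 again.

    ``imputed`` marks entries whose values are kept as-is; the remaining
    (observed) entries of the row are scaled by a common factor, preserving
    their mutual ratios.
    """
    out = x.copy()
    imp_total = np.where(imputed, out, 0.0).sum(axis=1)
    if np.any(imp_total >= 1.0):
        raise ValueError("imputed values fill an entire row; detection limit too large")
    obs_total = np.where(~imputed, out, 0.0).sum(axis=1)
    scale = (1.0 - imp_total) / obs_total
    touched = imputed.any(axis=1)  # rows without imputations stay bit-identical
    resc = ~imputed & touched[:, None]
    out[resc] *= np.broadcast_to(scale[:, None], out.shape)[resc]
    return out


def multiplicative_replace(pattern: ZeroPattern, fraction: float = 0.65) -> np.ndarray:
    """Replace each zero by ``fraction * DL`` and re-close the row."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    x = pattern.data.copy()
    mask = pattern.zero_mask
    if not mask.any():
        return x
    x[mask] = fraction * pattern.detection_limit[mask]
    return _reclose_rows(x, mask)


def lr_em_impute(
    pattern: ZeroPattern,
    tol: float = 1e-4,
    max_iter: int = 100,
    reference_part: str = "SB",
) -> np.ndarray:
    """Impute rounded zeros by EM on additive log-ratio coordinates.

    The alr transform is taken against ``reference_part``, which must be
    zero-free across the matrix.  At each iteration the mean and covariance of
    the completed alr matrix are estimated, and every censored coordinate is
    replaced by its normal conditional expectation given the row's observed
    coordinates, truncated above at the alr-transformed detection limit
    psi = log(DL / x_ref).  Iteration stops when the largest absolute change
    in any imputed alr value falls below ``tol``.

    Returns the imputed proportion matrix; rows re-close to 1 and every
    imputed value lies strictly in (0, DL).
    """
    x = pattern.data
    mask = pattern.zero_mask
    if not mask.any():
        return x.copy()

    parts = list(pattern.parts)
    ref = parts.index(reference_part)
    if mask[:, ref].any():
        raise ValueError(
            f"alr reference part {reference_part!r} has zeros; pick a zero-free part"
        )
    d = x.shape[1]
    coord_cols = [j for j in range(d) if j != ref]

    with np.errstate(divide="ignore"):
        y = np.log(x[:, coord_cols]) - np.log(x[:, [ref]])
    cmask = mask[:, coord_cols]
    psi = np.log(pattern.detection_limit[:, coord_cols]) - np.log(x[:, [ref]])

    # start from the multiplicative rule
    y[cmask] = np.log(0.65) + psi[cmask]

    rows_c, cols_c = np.nonzero(cmask)
    last = y[rows_c, cols_c].copy()
    converged = False
    trace: list[float] = []
    for _ in range(max_iter):
        mu = y.mean(axis=0)
        sigma = np.cov(y, rowvar=False)
        sigma = np.atleast_2d(sigma) + 1e-12 * np.eye(d - 1)
        for i, j in zip(rows_c, cols_c):
            obs = [k for k in range(d - 1) if not cmask[i, k]]
            if obs:
                s_oo = sigma[np.ix_(obs, obs)]
                s_jo = sigma[j, obs]
                w = np.linalg.solve(s_oo, y[i, obs] - mu[obs])
                m_cond = mu[j] + s_jo @ w
                v_cond = sigma[j, j] - s_jo @ np.linalg.solve(s_oo, s_jo)
            else:
                m_cond, v_cond = mu[j], sigma[j, j]
            s = np.sqrt(max(v_cond, 1e-12))
            alpha = (psi[i, j] - m_cond) / s
            # E[Y | Y < psi] for Y ~ N(m_cond, s^2)
            y[i, j] = m_cond - s * norm.pdf(alpha) / max(norm.cdf(alpha), 1e-300)
            y[i, j] = min(y[i, j], psi[i, j] - 1e-12)
        change = float(np.max(np.abs(y[rows_c, cols_c] - last)))
        trace.append(change)
        last = y[rows_c, cols_c].copy()
        if change < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"lrEM did not converge in {max_iter} iterations; "
            f"last changes: {['%.3g' % t for t in trace[-5:]]}"
        )

    out = x.copy()
    out[mask] = np.exp(y[rows_c, cols_c]) * x[rows_c, ref]
    return _reclose_rows(out, mask)
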