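"""Second-order Taylor regression of the LR->HR patch mapping.

The blur-inverting mapping f from a smoothed patch to its sharp
counterpart is expanded to second order around the reference patch p_s:

    q_hat = p + f1 o (q_s - p_s) + 1/2 f2 o (q_s - p_s) o (q_s - p_s)

with o the element-wise product and f1, f2 the element-wise first and
second derivative vectors of f at p_s.  The derivatives are fitted by
weighted least squares over K similar training pairs {(p_i,s, p_i, w_i)}:
each pair contributes, per pixel j, one observation

    p_i[j] - p[j]  ~  f1[j] * d_ij + f2[j] * (1/2 d_ij^2),   d_ij = p_i,s[j] - p_s[j],

weighted by w_i.  The stacked system y = X b (X holding diagonal blocks
[diag(d_i), 1/2 diag(d_i o d_i)]) therefore decouples into n independent
2x2 weighted problems — the solver exploits that, and a dense full-matrix
solve is kept alongside as a cross-check.  The 1/2 is folded into X, so
the solution vector b is literally (f1, f2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import Patch, TrainingPair

__all__ = [
    "DerivativeEstimate",
    "RegressionSystem",
    "required_equations",
    "assemble_wls_system",
    "solve_derivatives",
    "solve_derivatives_full",
    "predict_patch",
]

logger = logging.getLogger(__name__)

#: default ridge, as a fraction of the mean normal-matrix diagonal per pixel
DEFAULT_RIDGE = 1e-6


@dataclass
class DerivativeEstimate:
    """Element-wise first and second derivatives of the patch mapping."""

    f1: np.ndarray
    f2: np.ndarray

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=np.float64).ravel()
        self.f2 = np.asarray(self.f2, dtype=np.float64).ravel()
        if self.f1.shape != self.f2.shape:
            raise ValueError("f1 and f2 must have equal length")
        if not (np.all(np.isfinite(self.f1)) and np.all(np.isfinite(self.f2))):
            raise ValueError("derivative estimates must be finite")


@dataclass
class RegressionSystem:
    """The weighted-least-squares system in decoupled (per-pixel) storage.

    ``deltas[i] = p_i,s - p_s`` and ``responses[i] = p_i - p`` are (K, n);
    ``weights`` is (K,) strictly positive.  Dense ``y`` (K*n,), ``X``
    (K*n, 2n) and the diagonal of ``W`` are materialised on demand for the
    full-matrix route.
    """

    deltas: np.ndarray
    responses: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.deltas = np.atleast_2d(np.asarray(self.deltas, dtype=np.float64))
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=np.float64))
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if self.deltas.shape != self.responses.shape:
            raise ValueError("deltas and responses must share their shape")
        if self.weights.shape != (self.deltas.shape[0],):
            raise ValueError("one weight per training pair required")
        if not np.all(self.weights > 0):
            raise ValueError("weights must be strictly positive")

    @property
    def n_pairs(self) -> int:
        return self.deltas.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.deltas.shape[1]

    @property
    def y(self) -> np.ndarray:
        return self.responses.ravel()

    @property
    def X(self) -> np.ndarray:
        K, n = self.deltas.shape
        X = np.zeros((K * n, 2 * n))
        rows = np.arange(n)
        for i in range(K):
            X[i * n + rows, rows] = self.deltas[i]
            X[i * n + rows, n + rows] = 0.5 * self.deltas[i] ** 2
        return X

    @property
    def W_diag(self) -> np.ndarray:
        return np.repeat(self.weights, self.n_pixels)


def required_equations(r: int) -> int:
    """Number of unknown derivative coefficients for patch radius r.

    A (2r+1) x (2r+1) patch has n = (2r+1)^2 pixels, each carrying one
    first- and one second-derivative coefficient: 2 * (2r+1)^2 in total
    (50 for the default r=2).  The training set should hold more equations
    than this for a well-posed full-rank fit.
    """
    if int(r) != r or r < 1:
        raise ValueError(f"patch radius must be an integer >= 1, got {r}")
    return 2 * (2 * int(r) + 1) ** 2


def _patch_values(p) -> np.ndarray:
    return p.values if isinstance(p, Patch) else np.asarray(p, dtype=np.float64).ravel()


def assemble_wls_system(p, p_s, pairs: list[TrainingPair]) -> RegressionSystem:
    """Build the WLS system from a reference pair (p_s, p) and its training set."""
    p = _patch_values(p)
    ps = _patch_values(p_s)
    if p.shape != ps.shape:
        raise ValueError("p and p_s must have equal length")
    if len(pairs) < 1:
        raise ValueError("at least one training pair is required")
    n = p.size
    deltas = np.empty((len(pairs), n))
    responses = np.empty((len(pairs), n))
    weights = np.empty(len(pairs))
    for i, pair in enumerate(pairs):
        lr = _patch_values(pair.lr_patch)
        hr = _patch_values(pair.hr_patch)
        if lr.size != n or hr.size != n:
            raise ValueError("training patch size disagrees with the reference")
        deltas[i] = lr - ps
        responses[i] = hr - p
        weights[i] = pair.weight
    return RegressionSystem(deltas, responses, weights)


def _solve_pixelwise(
    deltas: np.ndarray,
    responses: np.ndarray,
    weights: np.ndarray,
    ridge: float,
    ridge_floor: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """n independent 2x2 weighted normal-equation solves, vectorized over pixels.

    Per pixel j the regressors are g1 = d_j and g2 = 1/2 d_j^2 over the K
    pairs.  ``ridge`` scales a per-pixel Tikhonov term: lambda_j =
    ridge * mean(diag of the 2x2 normal matrix) + ridge_floor.  The
    absolute floor shrinks derivatives toward zero exactly where the
    offsets carry too little energy to determine them — the estimate then
    degrades gracefully into the zeroth-order patch copy q_hat = p rather
    than extrapolating noise.  A fully degenerate pixel (all offsets zero,
    or a numerically singular system) returns 0, 0.
    """
    w = weights[:, None]
    g1 = deltas
    g2 = 0.5 * deltas**2
    s11 = np.sum(w * g1 * g1, axis=0)
    s12 = np.sum(w * g1 * g2, axis=0)
    s22 = np.sum(w * g2 * g2, axis=0)
    b1 = np.sum(w * g1 * responses, axis=0)
    b2 = np.sum(w * g2 * responses, axis=0)
    lam = ridge * 0.5 * (s11 + s22) + ridge_floor
    a11 = s11 + lam
    a22 = s22 + lam
    det = a11 * a22 - s12 * s12
    scale = np.maximum(a11 * a22, s12 * s12)
    ok = det > np.finfo(float).tiny + 1e-14 * scale
    det_safe = np.where(ok, det, 1.0)
    f1 = np.where(ok, (a22 * b1 - s12 * b2) / det_safe, 0.0)
    f2 = np.where(ok, (a11 * b2 - s12 * b1) / det_safe, 0.0)
    return f1, f2


def solve_derivatives(
    sys: RegressionSystem, ridge: float = DEFAULT_RIDGE, ridge_floor: float = 0.0
) -> DerivativeEstimate:
    """Closed-form WLS solution, via the per-pixel decoupled 2x2 systems."""
    if ridge < 0 or ridge_floor < 0:
        raise ValueError("ridge terms must be >= 0")
    f1, f2 = _solve_pixelwise(sys.deltas, sys.responses, sys.weights, ridge, ridge_floor)
    return DerivativeEstimate(f1, f2)


def solve_derivatives_full(
    sys: RegressionSystem, ridge: float = DEFAULT_RIDGE, ridge_floor: float = 0.0
) -> DerivativeEstimate:
    """Dense full-matrix solve of b = (X^T W X + L)^-1 X^T W y.

    Uses the same per-pixel ridge construction as :func:`solve_derivatives`
    (L diagonal, lambda_j on both coefficients of pixel j); kept as an
    independent route for equivalence checks and debugging.  Requires the
    regularized normal matrix to be nonsingular.
    """
    if ridge < 0 or ridge_floor < 0:
        raise ValueError("ridge terms must be >= 0")
    X = sys.X
    Wd = sys.W_diag
    y = sys.y
    n = sys.n_pixels
    A = X.T @ (Wd[:, None] * X)
    diag = np.diagonal(A)
    lam = ridge * 0.5 * (diag[:n] + diag[n:]) + ridge_floor
    A = A + np.diag(np.concatenate([lam, lam]))
    b = X.T @ (Wd * y)
    sol = np.linalg.solve(A, b)
    return DerivativeEstimate(sol[:n], sol[n:])


def predict_patch(p, p_s, q_s, est: DerivativeEstimate):
    """Second-order Taylor prediction of the HR patch q_hat.

    ``q_hat = p + f1 o (q_s - p_s) + 1/2 f2 o (q_s - p_s)^2``; no intensity
    clipping is applied here.  Returns a :class:`Patch` at q_s's location
    when q_s is a Patch, else a plain vector.
    """
    pv = _patch_values(p)
    psv = _patch_values(p_s)
    qsv = _patch_values(q_s)
    if not (pv.shape == psv.shape == qsv.shape == est.f1.shape):
        raise ValueError("patch and derivative lengths disagree")
    d = qsv - psv
    qhat = pv + est.f1 * d + 0.5 * est.f2 * d * d
    if isinstance(q_s, Patch):
        return Patch(qhat, center=q_s.center, slice_index=q_s.slice_index, source="Z")
    return qhat
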