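"""Patch descriptors and similarity search.

Local structure of an image patch is summarised by its *region covariance
descriptor*: the 3x3 covariance, over the patch window, of the per-pixel
feature vector ``f_i = (I_i, dI/dx, dI/dy)``.  Two descriptors C1, C2 are
compared on the manifold of SPD matrices through their generalized
eigenvalues ``lambda_j``:

    d^2(C1, C2) = sum_j ln^2 lambda_j ,      w = exp(-d^2) in (0, 1],

which is symmetric, equals 1 iff the descriptors coincide, and is invariant
to a global intensity scaling (both covariances scale by c^2, leaving the
eigenvalue pencil untouched).  The module provides the descriptor math, a
windowed best-match search for a reference patch, and the collection of the
J most similar training patches per slice across a band of neighbouring
slices — the raw material of the local regression.

The exhaustive window searches are served by a per-slice :class:`SliceIndex`
that precomputes all patch vectors and all descriptors with box-filtered
moment maps, so a search touches only gathered arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import linalg as sla
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "Patch",
    "CovDescriptor",
    "TrainingPair",
    "SliceIndex",
    "feature_maps",
    "region_covariance",
    "covariance_weight",
    "patch_from_slice",
    "find_reference_patch",
    "collect_training_pairs",
]

logger = logging.getLogger(__name__)

#: ridge added to the descriptor diagonal; sized for intensities on [0, 1]
COV_EPS = 1e-8

#: floor keeping similarity weights strictly positive after exp underflow
_W_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """A vectorized s x s patch (row-major), s = 2r+1 odd.

    ``center`` is the (row, col) of the central pixel in the *unpadded*
    source slice; ``slice_index`` locates the slice along axis 0 of the
    source volume; ``source`` names that volume (e.g. "I", "I_s", "Z_s").
    """

    values: np.ndarray
    center: tuple[int, int]
    slice_index: int
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        s = int(round(np.sqrt(self.values.size)))
        if s * s != self.values.size or s < 3 or s % 2 == 0:
            raise ValueError(
                f"patch length {self.values.size} is not an odd square >= 9"
            )
        self.center = (int(self.center[0]), int(self.center[1]))

    @property
    def size(self) -> int:
        """Side length s."""
        return int(round(np.sqrt(self.values.size)))

    @property
    def radius(self) -> int:
        return (self.size - 1) // 2


@dataclass
class CovDescriptor:
    """3x3 region covariance of (intensity, dI/dx, dI/dy) features."""

    C: np.ndarray
    regularized: bool = True

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.shape != (3, 3):
            raise ValueError(f"descriptor must be 3x3, got {self.C.shape}")
        if not np.allclose(self.C, self.C.T, atol=1e-12):
            raise ValueError("descriptor must be symmetric")


@dataclass
class TrainingPair:
    """An (LR, HR) patch pair sharing a center, with its similarity weight."""

    lr_patch: Patch
    hr_patch: Patch
    weight: float

    def __post_init__(self) -> None:
        if self.lr_patch.center != self.hr_patch.center:
            raise ValueError("lr/hr patches must share their center")
        if self.lr_patch.slice_index != self.hr_patch.slice_index:
            raise ValueError("lr/hr patches must share their slice index")
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")


# ---------------------------------------------------------------------------
# feature maps and descriptors
# ---------------------------------------------------------------------------

def feature_maps(img2d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel features of a 2-D slice: (intensity, dI/dx, dI/dy).

    Gradients are central differences in the interior and one-sided at the
    borders; x runs along columns (horizontal), y along rows (vertical).
    """
    img2d = np.asarray(img2d, dtype=np.float64)
    if img2d.ndim != 2 or img2d.shape[0] < 3 or img2d.shape[1] < 3:
        raise ValueError(f"slice must be at least 3x3, got shape {img2d.shape}")
    gy, gx = np.gradient(img2d)
    return img2d, gx, gy


def region_covariance(
    maps: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: tuple[int, int],
    r: int,
    eps: float = COV_EPS,
) -> CovDescriptor:
    """Covariance of the P = (2r+1)^2 feature points in the window at ``center``.

    ``C = (1/P) sum_i (f_i - mu)(f_i - mu)^T + eps*I``; the eps ridge keeps
    the descriptor positive definite even on constant patches (whose raw
    covariance is the zero matrix).  Pass ``eps=0`` for the raw descriptor.
    """
    row, col = center
    h, w = maps[0].shape
    if not (r <= row < h - r and r <= col < w - r):
        raise IndexError(f"window of radius {r} at {center} exceeds maps {maps[0].shape}")
    feats = np.stack(
        [m[row - r : row + r + 1, col - r : col + r + 1].ravel() for m in maps]
    )  # (3, P)
    mu = feats.mean(axis=1, keepdims=True)
    centered = feats - mu
    C = centered @ centered.T / feats.shape[1]
    if eps:
        C = C + eps * np.eye(3)
    return CovDescriptor(C, regularized=bool(eps))


def _as_cov_array(C) -> np.ndarray:
    return C.C if isinstance(C, CovDescriptor) else np.asarray(C, dtype=np.float64)


def covariance_weight(C1, C2) -> float:
    """Similarity weight ``exp(-sum_j ln^2 lambda_j)`` of two descriptors.

    The three lambda_j are the generalized eigenvalues of the pencil
    (C1, C2).  Identical descriptors give exactly 1; the weight is symmetric
    and always strictly positive.  Raises on non-positive-definite input.
    """
    A, B = _as_cov_array(C1), _as_cov_array(C2)
    for M, name in ((A, "C1"), (B, "C2")):
        try:
            np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            raise ValueError(f"{name} is not positive definite") from None
    if np.array_equal(A, B):
        return 1.0
    lam = sla.eigh(A, B, eigvals_only=True)
    d2 = float(np.sum(np.log(np.clip(lam, 1e-12, None)) ** 2))
    return max(float(np.exp(-d2)), _W_FLOOR)


# ---------------------------------------------------------------------------
# vectorized pencil eigenvalues (3x3 symmetric, Cardano closed form)
# ---------------------------------------------------------------------------

def _eigvalsh3(A: np.ndarray) -> np.ndarray:
    """Eigenvalues of a stack of symmetric 3x3 matrices, closed form."""
    a = A[..., 0, 0]
    b = A[..., 1, 1]
    c = A[..., 2, 2]
    d = A[..., 0, 1]
    e = A[..., 1, 2]
    f = A[..., 0, 2]
    q = (a + b + c) / 3.0
    p1 = d * d + e * e + f * f
    p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * p1
    p = np.sqrt(np.maximum(p2, 0.0) / 6.0)
    near_scalar = p2 <= 1e-30 * np.maximum(q * q, 1.0)
    psafe = np.where(near_scalar, 1.0, p)
    aq, bq, cq = (a - q) / psafe, (b - q) / psafe, (c - q) / psafe
    dn, en, fn = d / psafe, e / psafe, f / psafe
    detB = (
        aq * (bq * cq - en * en)
        - dn * (dn * cq - en * fn)
        + fn * (dn * en - bq * fn)
    )
    phi = np.arccos(np.clip(detB / 2.0, -1.0, 1.0)) / 3.0
    lam1 = q + 2.0 * p * np.cos(phi)
    lam3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    lam2 = 3.0 * q - lam1 - lam3
    out = np.stack([lam3, lam2, lam1], axis=-1)
    if np.any(near_scalar):
        out = np.where(near_scalar[..., None], q[..., None], out)
    return out


def _pencil_d2(covs: np.ndarray, ref_cov: np.ndarray) -> np.ndarray:
    """``sum_j ln^2 lambda_j`` of the pencils (covs[i], ref_cov), vectorized.

    Whitens by the Cholesky factor of the reference: the generalized
    eigenvalues of (C, R) are the ordinary eigenvalues of L^-1 C L^-T with
    R = L L^T.
    """
    L = np.linalg.cholesky(ref_cov)
    Linv = sla.solve_triangular(L, np.eye(3), lower=True)
    A = Linv @ covs @ Linv.T
    lam = np.clip(_eigvalsh3(A), 1e-12, None)
    return np.sum(np.log(lam) ** 2, axis=-1)


# ---------------------------------------------------------------------------
# per-slice search index
# ---------------------------------------------------------------------------

class SliceIndex:
    """Precomputed patches and descriptors for every pixel of one 2-D slice.

    The slice is mirror-padded by the patch radius, so every original pixel
    is a valid patch center.  Descriptors are assembled from box-filtered
    first and second moments of the padded feature maps, identical (up to
    float round-off) to per-window summation.
    """

    def __init__(self, img2d: np.ndarray, r: int, eps: float = COV_EPS):
        img2d = np.asarray(img2d, dtype=np.float64)
        if img2d.ndim != 2:
            raise ValueError("SliceIndex expects a 2-D slice")
        if r < 1:
            raise ValueError(f"patch radius must be >= 1, got {r}")
        self.r = int(r)
        s = 2 * self.r + 1
        self.size = s
        self.shape = img2d.shape
        h, w = img2d.shape

        padded = np.pad(img2d, self.r, mode="reflect")
        self.padded = padded
        feats = np.stack(feature_maps(padded))  # (3, h+2r, w+2r)

        # first/second moments over s x s windows; only the fully-inside
        # region [r : r+h, r : r+w] (= original pixel centers) is read.
        mu = np.empty((3, h, w))
        sec = np.empty((3, 3, h, w))
        for k in range(3):
            mu[k] = ndimage.uniform_filter(feats[k], s, mode="constant")[
                self.r : self.r + h, self.r : self.r + w
            ]
        for k in range(3):
            for l in range(k, 3):
                m2 = ndimage.uniform_filter(feats[k] * feats[l], s, mode="constant")[
                    self.r : self.r + h, self.r : self.r + w
                ]
                sec[k, l] = sec[l, k] = m2
        covs = sec - mu[:, None] * mu[None, :]
        covs = np.moveaxis(covs, (0, 1), (2, 3))  # (h, w, 3, 3)
        covs = 0.5 * (covs + np.swapaxes(covs, -1, -2))
        if eps:
            covs[..., np.arange(3), np.arange(3)] += eps
        self.covs = covs
        #: (h, w, s, s) view of all patches, indexed by original center
        self.patches = sliding_window_view(padded, (s, s))

    def window(self, center: tuple[int, int], v: int):
        """Row/col slice bounds of the radius-v candidate window at ``center``."""
        row, col = center
        h, w = self.shape
        r0, r1 = max(0, row - v), min(h, row + v + 1)
        c0, c1 = max(0, col - v), min(w, col + v + 1)
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"empty search window at {center} (radius {v})")
        return r0, r1, c0, c1

    def best_in_window(self, center, v: int, ref_cov: np.ndarray):
        """Most-similar patch center in the window; ties -> smallest (row, col)."""
        r0, r1, c0, c1 = self.window(center, v)
        covs = self.covs[r0:r1, c0:c1].reshape(-1, 3, 3)
        d2 = _pencil_d2(covs, ref_cov)
        k = int(np.argmin(d2))  # row-major first occurrence = lexicographic
        ncols = c1 - c0
        weight = max(float(np.exp(-d2[k])), _W_FLOOR)
        return (r0 + k // ncols, c0 + k % ncols), weight

    def topj_in_window(self, center, v: int, J: int, ref_cov: np.ndarray):
        """The J most-similar centers in the window, by descending weight.

        Exact ties are ordered by (row, col); if the window holds fewer than
        J candidates all of them are returned.
        """
        r0, r1, c0, c1 = self.window(center, v)
        covs = self.covs[r0:r1, c0:c1].reshape(-1, 3, 3)
        d2 = _pencil_d2(covs, ref_cov)
        ncols = c1 - c0
        rows = r0 + np.arange(d2.size) // ncols
        cols = c0 + np.arange(d2.size) % ncols
        order = np.lexsort((cols, rows, d2))[: min(J, d2.size)]
        weights = np.maximum(np.exp(-d2[order]), _W_FLOOR)
        return rows[order], cols[order], weights


# ---------------------------------------------------------------------------
# public search operations
# ---------------------------------------------------------------------------

def patch_from_slice(
    img2d: np.ndarray,
    center: tuple[int, int],
    r: int,
    slice_index: int = 0,
    source: str = "",
) -> Patch:
    """Cut the s x s patch centred at ``center`` from a mirror-padded slice."""
    img2d = np.asarray(img2d, dtype=np.float64)
    row, col = center
    h, w = img2d.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"center {center} outside slice of shape {img2d.shape}")
    padded = np.pad(img2d, r, mode="reflect")
    window = padded[row : row + 2 * r + 1, col : col + 2 * r + 1]
    return Patch(window.ravel(), center=(row, col), slice_index=slice_index, source=source)


def _to_index(img2d, r: int) -> SliceIndex:
    return img2d if isinstance(img2d, SliceIndex) else SliceIndex(img2d, r)


def _patch_level_cov(patch: Patch) -> np.ndarray:
    """Descriptor of a free-standing patch, from its own s x s values."""
    img = patch.values.reshape(patch.size, patch.size)
    return region_covariance(feature_maps(img), (patch.radius, patch.radius), patch.radius).C


def find_reference_patch(
    q_s: Patch,
    I_s_slice,
    center_lr: tuple[int, int],
    v: int,
    r: int,
    q_cov=None,
) -> tuple[Patch, float]:
    """Best-matching reference patch p_s for the query q_s.

    Scans every candidate center in the radius-``v`` window around
    ``center_lr`` on the given slice (a 2-D array or prebuilt
    :class:`SliceIndex`) and returns the one whose region covariance is
    most similar to the query's, together with the similarity weight.
    Exact ties go to the lexicographically smallest (row, col).

    ``q_cov`` is the query's descriptor; when omitted it is computed from
    the patch's own values (gradients one-sided at the patch border).  The
    reconstruction pipeline passes the descriptor taken from the query's
    full source slice instead.
    """
    idx = _to_index(I_s_slice, r)
    if idx.r != r:
        raise ValueError("patch radius disagrees with the prebuilt index")
    ref = _as_cov_array(q_cov) if q_cov is not None else _patch_level_cov(q_s)
    (row, col), weight = idx.best_in_window(center_lr, v, ref)
    p_s = Patch(
        idx.patches[row, col].ravel(),
        center=(row, col),
        slice_index=q_s.slice_index,
        source="I_s",
    )
    return p_s, weight


def collect_training_pairs(
    p_s: Patch,
    I: Volume3D,
    I_s: Volume3D,
    v: int,
    p_slices: int,
    J: int,
    r: int,
) -> list[TrainingPair]:
    """Gather the training set {(p_i,s, p_i, w_i)} for the regression at p_s.

    For each of the ``p_slices`` slices centred on p_s's slice (clipped at
    the volume ends), the ``J`` patches of I_s most similar to p_s inside
    the radius-``v`` window around p_s's center are taken; each is paired
    with the same-center patch of I.  The result is sorted by descending
    weight and holds at most ``p_slices * J`` pairs.
    """
    if p_slices < 1 or p_slices % 2 == 0:
        raise ValueError(f"p_slices must be odd >= 1, got {p_slices}")
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    nz = I_s.data.shape[0]
    z0 = p_s.slice_index
    if not 0 <= z0 < nz:
        raise IndexError(f"slice index {z0} outside volume of {nz} slices")
    half = p_slices // 2
    z_lo, z_hi = max(0, z0 - half), min(nz, z0 + half + 1)

    ref_idx = SliceIndex(I_s.data[z0], r)
    ref_cov = ref_idx.covs[p_s.center]

    pairs: list[TrainingPair] = []
    for z in range(z_lo, z_hi):
        idx = ref_idx if z == z0 else SliceIndex(I_s.data[z], r)
        rows, cols, weights = idx.topj_in_window(p_s.center, v, J, ref_cov)
        if rows.size < J:
            logger.info(
                "slice %d: window holds only %d candidates (< J=%d)", z, rows.size, J
            )
        hr_padded = np.pad(I.data[z], r, mode="reflect")
        hr_windows = sliding_window_view(hr_padded, (idx.size, idx.size))
        for row, col, w in zip(rows, cols, weights):
            lr = Patch(idx.patches[row, col].ravel(), (row, col), z, source="I_s")
            hr = Patch(hr_windows[row, col].ravel(), (row, col), z, source="I")
            pairs.append(TrainingPair(lr, hr, float(w)))
    pairs.sort(key=lambda t: -t.weight)
    return pairs
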