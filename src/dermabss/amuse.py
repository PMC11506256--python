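"""Step 1: second-order ICA (AMUSE) on the Red and Infra-Red mixtures.

Above ~620 nm the hemoglobin absorption is negligible, so the Red and IR
log-absorbance mixtures contain only melanin and shading.  Melanin depends
on melanocyte density while shading depends on surface geometry, so the two
maps are modeled as mutually uncorrelated; both are spatially autocorrelated,
which makes a single lagged covariance sufficient for separation (AMUSE):
whiten the two mixtures with the zero-lag covariance, then diagonalize the
symmetrized lag-v covariance of the whitened data.  The rotation is unique up
to permutation and sign as long as the two whitened lagged eigenvalues differ
(the identifiability condition); their gap is reported as a diagnostic.

The recovered components are labeled afterwards: shading is concentrated at
the image border, melanin in the lesion, so the component whose absolute
values load more on the outer frame is the shading map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .optical_model import SourceSet

logger = logging.getLogger(__name__)


@dataclass
class UnmixingResult:
    """Two-channel unmixing estimate.

    ``Y = U @ X34`` exactly (non-centered); ``Y_centered`` is its centered
    version.  ``eigen_gap`` is the absolute difference of the two whitened
    lagged-covariance eigenvalues — a small gap means the identifiability
    condition is weak and the rotation is poorly determined.
    """

    U: np.ndarray            # (2, 2)
    Y: np.ndarray            # (2, N) non-centered estimates
    Y_centered: np.ndarray   # (2, N)
    eigen_gap: float
    eigenvalues: np.ndarray  # (2,)


def amuse_unmix(X34: np.ndarray, lag: int = 1,
                gap_warn: float = 1e-3) -> UnmixingResult:
    """Separate two mixtures by whitening + lagged-covariance rotation.

    Parameters
    ----------
    X34
        Array of shape ``(2, N)``: the Red and IR mixtures, flattened
        row-major.  Non-centered; centering is internal.
    lag
        Pixel offset used for the lagged covariance, ``1 <= lag < N``.
        The default of one raster step (horizontal neighbor) exploits the
        spatial smoothness of skin maps.
    gap_warn
        Relative eigenvalue-gap threshold below which an identifiability
        warning is emitted.

    Raises
    ------
    ValueError
        If the mixtures are collinear (rank-deficient covariance).
    """
    X34 = np.asarray(X34, dtype=float)
    if X34.ndim != 2 or X34.shape[0] != 2:
        raise ValueError("X34 must have shape (2, N)")
    N = X34.shape[1]
    if not 1 <= lag < N:
        raise ValueError(f"lag must satisfy 1 <= lag < {N}")

    Xc = X34 - X34.mean(axis=1, keepdims=True)
    C0 = (Xc @ Xc.T) / N
    w, E = np.linalg.eigh(C0)
    if w.min() <= 1e-12 * max(w.max(), 1e-300):
        raise ValueError("mixtures collinear: zero-lag covariance is rank deficient")
    W = (E / np.sqrt(w)).T          # whitening: W C0 W^T = I
    Z = W @ Xc
    Cv = (Z[:, lag:] @ Z[:, :-lag].T) / (N - lag)
    Cs = 0.5 * (Cv + Cv.T)
    lam, V = np.linalg.eigh(Cs)
    gap = float(abs(lam[1] - lam[0]))
    if gap < gap_warn * max(1.0, float(np.abs(lam).max())):
        warnings.warn(
            "identifiability condition weak: lagged-covariance eigenvalues "
            f"nearly equal (gap={gap:.3e}); separation unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    U = V.T @ W
    Y = U @ X34
    logger.debug("amuse_unmix: eigenvalues=%s gap=%.3e", lam, gap)
    return UnmixingResult(U=U, Y=Y, Y_centered=U @ Xc, eigen_gap=gap,
                          eigenvalues=lam)


def label_melanin_shading(result: UnmixingResult, shape: tuple,
                          border_fraction: float = 0.1):
    """Resolve sign and permutation of the two AMUSE components.

    Sign: each component is flipped so its spatial mean is non-negative
    (chromophore/shading maps are predominantly non-negative up to a positive
    scale).  Permutation: shading loads on the image border, so the component
    with the larger border score — mean absolute centered value over the
    outer ``border_fraction`` frame divided by the same over the central
    complement — is labeled shading; the other is melanin.

    Returns
    -------
    (SourceSet, dict)
        A partial :class:`~dermabss.optical_model.SourceSet` with melanin and
        shading filled, and a diagnostics dict with the border scores.
    """
    H, W = shape
    if result.Y.shape[1] != H * W:
        raise ValueError("shape does not match the number of samples")
    bh = max(1, int(round(border_fraction * H)))
    bw = max(1, int(round(border_fraction * W)))
    border = np.zeros((H, W), dtype=bool)
    border[:bh, :] = border[-bh:, :] = True
    border[:, :bw] = border[:, -bw:] = True
    border = border.ravel()

    Y = result.Y.copy()
    Yc = result.Y_centered.copy()
    scores = np.empty(2)
    for j in range(2):
        if Y[j].mean() < 0:
            Y[j] = -Y[j]
            Yc[j] = -Yc[j]
        a = np.abs(Yc[j])
        center_mean = a[~border].mean()
        scores[j] = a[border].mean() / max(center_mean, 1e-300)
    if abs(scores[0] - scores[1]) <= 1e-9:
        raise ValueError("labeling ambiguous; inspect manually "
                         f"(border scores {scores[0]:.6g}, {scores[1]:.6g})")
    shading_idx = int(np.argmax(scores))
    melanin_idx = 1 - shading_idx
    logger.debug("label_melanin_shading: border scores=%s shading=component %d",
                 scores, shading_idx)
    sources = SourceSet(oxy=None, deoxy=None,
                        melanin=Y[melanin_idx], shading=Y[shading_idx],
                        shape=tuple(shape))
    return sources, {"border_scores": scores, "shading_component": shading_idx}
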