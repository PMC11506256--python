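"""Multispectral image container and the Beer–Lambert log-absorbance transform.

A registered four-band reflectance image (Blue, Green, Red, Infra-Red) of
diffusely reflecting skin follows the Lambert–Beer law: each band is the
camera gain times the illuminant times ``exp(-2 * sum_j mu_j * l_j * C_j)``,
where the ``C_j`` are the pixelwise concentrations of oxyhemoglobin,
deoxyhemoglobin and melanin, and a fourth multiplicative shading term
accounts for surface geometry.  Taking the negative log turns the image into
a linear mixture of four non-negative source maps; subtracting the per-band
minimum removes the gain/illuminant constant whenever at least one pixel has
(approximately) zero concentrations for every source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical band order used throughout the package.
BAND_LABELS = ("blue", "green", "red", "ir")

#: Canonical source order: oxyhemoglobin, deoxyhemoglobin, melanin, shading.
SOURCE_LABELS = ("oxy", "deoxy", "melanin", "shading")


@dataclass
class MultispectralImage:
    """Four co-registered reflectance bands on one pixel grid.

    Parameters
    ----------
    bands
        Array of shape ``(4, H, W)`` with non-negative reflectance values in
        arbitrary linear units.
    band_labels
        Labels identifying each band.  If they are a permutation of
        :data:`BAND_LABELS`, the bands are reordered into canonical
        Blue/Green/Red/IR order on construction, so band files may be
        supplied in any order as long as they are labeled.
    """

    bands: np.ndarray
    band_labels: tuple = BAND_LABELS

    def __post_init__(self):
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3 or self.bands.shape[0] != 4:
            raise ValueError(
                f"expected 4 bands of identical shape, got array of shape "
                f"{self.bands.shape}"
            )
        labels = tuple(str(b).lower() for b in self.band_labels)
        if len(labels) != 4:
            raise ValueError("band_labels must name exactly 4 bands")
        if labels != BAND_LABELS:
            if sorted(labels) != sorted(BAND_LABELS):
                raise ValueError(
                    f"band_labels {labels} are not a permutation of {BAND_LABELS}"
                )
            order = [labels.index(b) for b in BAND_LABELS]
            self.bands = self.bands[order]
        self.band_labels = BAND_LABELS
        if np.any(self.bands < 0):
            raise ValueError("reflectance values must be non-negative")

    @property
    def height(self) -> int:
        return self.bands.shape[1]

    @property
    def width(self) -> int:
        return self.bands.shape[2]

    @property
    def shape(self) -> tuple:
        return self.bands.shape[1:]

    def band(self, label: str) -> np.ndarray:
        return self.bands[BAND_LABELS.index(label.lower())]


@dataclass
class AbsorbanceMixtures:
    """The four log-absorbance mixtures ``X_i(u)``, flattened row-major.

    ``X_i(u) = -log(Id_i(u)) - min_u(-log(Id_i(u)))``; each row of ``X`` has
    minimum exactly zero by construction, and ``offsets`` holds the
    subtracted per-band constants (the estimates of the gain/illuminant
    term ``n_i``).
    """

    X: np.ndarray              # (4, H*W)
    offsets: np.ndarray        # (4,)
    shape: tuple               # (H, W)

    def unflatten(self, i: int) -> np.ndarray:
        return self.X[i].reshape(self.shape)


@dataclass
class SourceSet:
    """Four source maps: oxy (j=1), deoxy (j=2), melanin (j=3), shading (j=4).

    Maps are stored flattened in row-major raster order.  Each map is known
    only up to a positive scale factor (``scale_indeterminate``); maps from
    the first three separation steps may contain negative values, while
    NMF-refined maps are non-negative (``nonnegative``).
    """

    oxy: np.ndarray | None
    deoxy: np.ndarray | None
    melanin: np.ndarray | None
    shading: np.ndarray | None
    shape: tuple
    scale_indeterminate: bool = True
    nonnegative: bool = False

    def __getitem__(self, name: str) -> np.ndarray:
        m = getattr(self, name)
        if m is None:
            raise KeyError(f"source map {name!r} is absent from this SourceSet")
        return m

    @property
    def labels(self) -> tuple:
        return tuple(s for s in SOURCE_LABELS if getattr(self, s) is not None)

    def as_matrix(self) -> np.ndarray:
        """Stack the present maps in canonical source order, shape (k, N)."""
        return np.vstack([getattr(self, s).ravel() for s in self.labels])

    def map2d(self, name: str) -> np.ndarray:
        return self[name].reshape(self.shape)

    @classmethod
    def from_matrix(cls, S: np.ndarray, shape: tuple, **kw) -> "SourceSet":
        S = np.asarray(S, dtype=float)
        if S.shape[0] != 4:
            raise ValueError("expected a 4-row source matrix")
        return cls(oxy=S[0], deoxy=S[1], melanin=S[2], shading=S[3],
                   shape=tuple(shape), **kw)


@dataclass
class MixingMatrix:
    """4x4 mixing matrix; rows = bands (B, G, R, IR), columns = sources.

    Under the four-band model the oxy/deoxy absorption is negligible above
    ~620 nm, so the Red and IR rows have structural zeros in the first two
    columns.
    """

    m: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (4, 4):
            raise ValueError("mixing matrix must be 4x4")

    @property
    def structural_zeros_ok(self) -> bool:
        return bool(np.all(self.m[2:4, 0:2] == 0.0))

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.m, dtype=dtype)


def to_absorbance(image: MultispectralImage,
                  clip_epsilon: float | None = None) -> AbsorbanceMixtures:
    """Convert reflectance bands into zero-minimum log-absorbance mixtures.

    Parameters
    ----------
    image
        Valid four-band reflectance image.
    clip_epsilon
        Lower clip applied to each band before the log, as an absolute
        reflectance value.  Default: ``1e-6`` of the band maximum (the model
        never produces exact zeros, but quantized files may).

    Returns
    -------
    AbsorbanceMixtures
        Mixtures ``X`` of shape ``(4, H*W)`` with per-row minimum exactly 0,
        the subtracted offsets, and the image shape.

    Notes
    -----
    The transform is invariant to per-band multiplicative rescaling of the
    reflectance (a gain change only shifts the log, and the shift is removed
    with the minimum), so the normalization of the input files is immaterial.
    """
    bands = image.bands
    if not np.all(np.isfinite(bands)):
        i, r, c = np.argwhere(~np.isfinite(bands))[0]
        raise ValueError(
            f"non-finite reflectance in band {BAND_LABELS[i]!r} at pixel "
            f"({r}, {c})"
        )
    X = np.empty((4, bands.shape[1] * bands.shape[2]))
    offsets = np.empty(4)
    for i in range(4):
        band = bands[i]
        eps = clip_epsilon
        if eps is None:
            bmax = band.max()
            eps = 1e-6 * (bmax if bmax > 0 else 1.0)
        intensity = -np.log(np.maximum(band, eps))
        n_hat = intensity.min()
        offsets[i] = n_hat
        X[i] = (intensity - n_hat).ravel(order="C")
    return AbsorbanceMixtures(X=X, offsets=offsets, shape=image.shape)


def remove_specular(image: MultispectralImage,
                    brightness_quantile: float = 0.999) -> MultispectralImage:
    """Replace specular highlights by inverse-distance interpolation.

    Pixels brighter than ``brightness_quantile`` simultaneously in all three
    visible bands are treated as specular and replaced, in every band, by an
    inverse-squared-distance weighted mean of the non-flagged pixels in the
    smallest centered window that contains any.  This is simple artifact
    plumbing for acquisition highlights; it is a no-op when nothing is
    flagged, and it is off by default for simulated images (the forward
    model has no specular term).
    """
    visible = image.bands[:3]
    thresholds = np.quantile(visible.reshape(3, -1), brightness_quantile, axis=1)
    mask = np.all(visible > thresholds[:, None, None], axis=0)
    if not mask.any():
        return MultispectralImage(bands=image.bands.copy())
    if mask.all():
        raise ValueError("degenerate highlight mask: every pixel flagged")
    H, W = mask.shape
    out = image.bands.copy()
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        radius = 2
        while True:
            r0, r1 = max(0, r - radius), min(H, r + radius + 1)
            c0, c1 = max(0, c - radius), min(W, c + radius + 1)
            sub = ~mask[r0:r1, c0:c1]
            if sub.any():
                break
            radius *= 2
        rr, cc = np.nonzero(sub)
        d2 = (rr + r0 - r) ** 2 + (cc + c0 - c) ** 2
        w = 1.0 / d2
        for i in range(4):
            vals = image.bands[i, r0:r1, c0:c1][sub]
            out[i, r, c] = np.sum(w * vals) / np.sum(w)
    logger.info("remove_specular: interpolated %d highlight pixels", len(rows))
    return MultispectralImage(bands=out)
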