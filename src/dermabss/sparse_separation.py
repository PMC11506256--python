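"""Step 3: sparse-component separation of oxy- and deoxyhemoglobin.

The two hemoglobin maps cannot be separated by ICA (they are dependent —
both come from blood), but each is assumed to have at least one spatial zone
where it is the only active source in the deflated Blue/Green mixtures
(mono-source zones).  On such a zone the ratio of the Green to the Blue
deflated mixture is constant and equals a column ratio of the mixing matrix,
so mono-source zones are detected as raster segments where the ratio variance
is negligible (a ratio-of-mixtures detector), the two distinct column ratios
are read off the segment ratio means, and the sources are reconstructed by
cross-cancellation:

``Y_oxy  = r2 * X1' - X2'``  and  ``Y_deoxy = r1 * X1' - X2'``,

where ``r1 = m21/m11 < r2 = m22/m12`` — the orientation follows from the
hemoglobin absorption spectra in the blue vs. green bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MonoSourceZone:
    """A raster segment with the statistics of the mixture ratio on it."""

    start: int
    length: int
    variance: float
    ratio_mean: float
    n_valid: int


def zone_table(zones) -> pd.DataFrame:
    """Diagnostics table of detected zones (exportable as CSV)."""
    return pd.DataFrame(
        [(z.start, z.length, z.variance, z.ratio_mean, z.n_valid)
         for z in zones],
        columns=["start", "length", "variance", "ratio_mean", "n_valid"],
    )


def detect_monosource_zones(x1: np.ndarray, x2: np.ndarray,
                            L: int = 64,
                            var_threshold: float | None = None,
                            guard: float | None = None,
                            min_valid: int | None = None,
                            k_min: int = 10):
    """Detect low-ratio-variance raster segments of the deflated mixtures.

    The raster is split into ``floor(N/L)`` consecutive segments of length
    ``L``.  Per segment the ratio ``x2/x1`` is computed only on pixels with
    ``|x1| > guard``; segments with fewer than ``min_valid`` such pixels are
    discarded.  Segments whose ratio variance is at most ``var_threshold``
    are retained as mono-source zones and returned sorted by variance
    ascending.  If none qualifies, the ``k_min`` lowest-variance segments are
    retained as a fallback (logged).

    Parameters
    ----------
    x1, x2
        Deflated Blue and Green mixtures, equal length.
    L
        Segment length in pixels (>= 8).  User-defined in practice; the
        default of 64 matches the simulator's saturation-run guarantee.
    var_threshold
        Absolute variance threshold; default ``1e-4`` times the global ratio
        variance over all valid pixels.
    guard
        Division guard on ``|x1|``; default ``1e-8 * max|x1|``.
    min_valid
        Minimum valid pixels per segment; default ``L // 2``.

    Raises
    ------
    ValueError
        If fewer than 2 segments have enough valid pixels.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be equal-length vectors")
    if L < 8:
        raise ValueError("segment length L must be >= 8")
    if guard is None:
        guard = 1e-8 * max(np.abs(x1).max(), 1e-300)
    if min_valid is None:
        min_valid = L // 2

    valid = np.abs(x1) > guard
    if valid.sum() >= 2:
        global_var = float(np.var(x2[valid] / x1[valid]))
    else:
        global_var = 0.0
    if var_threshold is None:
        var_threshold = 1e-4 * global_var

    candidates = []
    n_seg = x1.size // L
    for k in range(n_seg):
        sl = slice(k * L, (k + 1) * L)
        m = valid[sl]
        n_val = int(m.sum())
        if n_val < min_valid:
            continue
        ratio = x2[sl][m] / x1[sl][m]
        candidates.append(MonoSourceZone(
            start=k * L, length=L,
            variance=float(np.var(ratio)),
            ratio_mean=float(np.mean(ratio)),
            n_valid=n_val,
        ))
    if len(candidates) < 2:
        raise ValueError("insufficient data for SCA: fewer than 2 segments "
                         "with enough valid pixels")
    candidates.sort(key=lambda z: z.variance)
    retained = [z for z in candidates if z.variance <= var_threshold]
    if not retained:
        retained = candidates[:k_min]
        logger.info(
            "detect_monosource_zones: no segment under the variance "
            "threshold %.3e; falling back to the %d lowest-variance segments",
            var_threshold, len(retained))
    logger.debug("detect_monosource_zones: %d/%d segments retained",
                 len(retained), n_seg)
    return retained


def select_ratios(zones, rule: str = "midpoint"):
    """Pick the two distinct column ratios from the ranked zones.

    ``R(1)`` is the ratio mean of the lowest-variance zone.  Scanning the
    remaining zones in variance-ascending order, the second ratio is the
    first ``R(k)`` on the opposite side of the midpoint
    ``e = (Rmin + Rmax) / 2`` of the retained ratio means (``rule=
    "midpoint"``), or the first with ``|R(k) - R(1)| >= e`` (``rule=
    "literal"``).  If no zone qualifies, the ``R(k)`` farthest from ``R(1)``
    is used.  Finally the larger ratio is assigned to ``r2`` (deoxy column)
    and the smaller to ``r1`` (oxy column), per the absorption spectra.

    Returns
    -------
    (float, float)
        ``(r1_hat, r2_hat)`` with ``r1_hat < r2_hat``.

    Raises
    ------
    ValueError
        If the two selected ratios coincide (sources not separable).
    """
    zones = sorted(zones, key=lambda z: z.variance)
    if len(zones) < 2:
        raise ValueError("at least 2 mono-source zones are required")
    R = np.array([z.ratio_mean for z in zones])
    R1 = R[0]
    e = 0.5 * (R.min() + R.max())
    second = None
    if rule == "midpoint":
        for rk in R[1:]:
            if (rk > e) if R1 <= e else (rk < e):
                second = rk
                break
    elif rule == "literal":
        for rk in R[1:]:
            if abs(rk - R1) >= e:
                second = rk
                break
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if second is None:
        second = R[1:][np.argmax(np.abs(R[1:] - R1))]
        logger.info("select_ratios: no zone beyond the threshold; using the "
                    "ratio farthest from R(1)")
    r1_hat, r2_hat = float(min(R1, second)), float(max(R1, second))
    if r1_hat == r2_hat:
        raise ValueError("ratios indistinguishable; sources not separable "
                         "on this image")
    logger.debug("select_ratios: r1=%.6g r2=%.6g (rule=%s)", r1_hat, r2_hat, rule)
    return r1_hat, r2_hat


def reconstruct_sources(x1: np.ndarray, x2: np.ndarray,
                        r1_hat: float, r2_hat: float):
    """Cross-cancel the mixtures to recover oxy and deoxy maps.

    ``Y_oxy = r2*x1 - x2`` cancels the deoxy column; ``Y_deoxy = r1*x1 - x2``
    cancels the oxy column.  Each map is sign-flipped so its mean is
    non-negative (the scale factors ``d_j`` have indeterminate sign).

    Returns
    -------
    (ndarray, ndarray)
        ``(y_oxy, y_deoxy)``.
    """
    if r1_hat == r2_hat:
        raise ValueError("ratios indistinguishable; sources not separable "
                         "on this image")
    y1 = r2_hat * np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    y2 = r1_hat * np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    if y1.mean() < 0:
        y1 = -y1
    if y2.mean() < 0:
        y2 = -y2
    return y1, y2
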