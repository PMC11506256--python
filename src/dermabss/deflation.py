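"""Step 2: remove the melanin and shading contributions from Blue and Green.

Assuming the hemoglobin maps are instantaneously uncorrelated with melanin
and shading, the coefficient of each estimated component in a visible-band
mixture equals ``E[x~ y~_j] / E[y~_j^2]`` (computed on centered signals), and
subtracting ``coef_j * Y_j`` with the *non-centered* estimates leaves a new
mixture containing only oxy- and deoxyhemoglobin (plus a constant).  The
source scale factors cancel in the ratio, so the deflation is invariant to
the scale of the Step-1 estimates.

Each regressor is removed with its own univariate coefficient (not a joint
bivariate least squares); when the Step-1 estimates are themselves slightly
correlated the two differ, and the residual correlation is logged as a
diagnostic.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def deflate(xi: np.ndarray, *regressors: np.ndarray):
    """Subtract second-moment projections of the regressors from ``xi``.

    Parameters
    ----------
    xi
        Mixture vector of length N (non-centered).
    *regressors
        One or more non-centered source estimates of length N (typically the
        melanin and shading maps from Step 1; only melanin in the RGB-only
        variant).

    Returns
    -------
    (ndarray, ndarray)
        The deflated mixture ``xi'`` and the array of projection
        coefficients (the estimates of ``m_ij / d_j``).

    Raises
    ------
    ValueError
        If a regressor has zero variance.
    """
    xi = np.asarray(xi, dtype=float)
    if not regressors:
        raise ValueError("at least one regressor is required")
    xc = xi - xi.mean()
    out = xi.copy()
    coefs = np.empty(len(regressors))
    for k, y in enumerate(regressors):
        y = np.asarray(y, dtype=float)
        if y.shape != xi.shape:
            raise ValueError("mixture and regressors must have equal length")
        yc = y - y.mean()
        power = np.mean(yc * yc)
        if power <= 0:
            raise ValueError(f"degenerate regressor {k}: zero variance")
        coefs[k] = np.mean(xc * yc) / power
        out -= coefs[k] * y
    if len(regressors) == 2:
        y3c = regressors[0] - np.mean(regressors[0])
        y4c = regressors[1] - np.mean(regressors[1])
        rho = np.mean(y3c * y4c) / np.sqrt(np.mean(y3c**2) * np.mean(y4c**2))
        logger.debug("deflate: coefficients=%s regressor correlation=%.3e",
                     coefs, rho)
    return out, coefs
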