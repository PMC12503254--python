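"""Integration/segregation metrics on a signed weighted connectivity map.

Operates on the per-component edge-wise beta matrix: weights are taken in
absolute value and scaled to [0, 1] by the maximum magnitude, each parcel is
assigned to one of the 7 coarse networks or the subcortex (8 modules), and
three per-parcel summaries are computed:

* module-degree z-score — within-module strength, z-scored inside the
  module (population standard deviation convention);
* participation coefficient — ``1 - sum_m (k_im / k_i)^2``, zero for a
  fully segregated node, approaching 1 for an even connector hub;
* integration/segregation ratio — min-max normalized within-strength over
  min-max normalized participation, epsilon-stabilized, summarizing the
  balance per parcel.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RATIO_EPS = 1e-6


def _check_square_symmetric(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.abs(np.diag(W)) > 1e-12):
        raise ValueError("weight matrix must have zero diagonal")
    return W


def normalize_weights(beta_matrix: np.ndarray, signed: bool = False) -> np.ndarray:
    """Weights scaled by the maximum magnitude.

    Default takes absolute values first (strengths are interpreted on
    magnitudes); ``signed=True`` keeps the signs and only rescales — an
    alternative convention exposed as a flag but not used by the tested
    pipeline path.
    """
    W = _check_square_symmetric(beta_matrix)
    mx = np.abs(W).max()
    if mx == 0:
        raise ValueError("all-zero weight matrix cannot be normalized")
    return (W if signed else np.abs(W)) / mx


def _module_codes(modules) -> np.ndarray:
    return pd.factorize(np.asarray(modules))[0]


def module_degree_z(W: np.ndarray, modules) -> np.ndarray:
    """Within-module strength of each parcel, z-scored inside its module.

    Modules of size 1, or modules whose members all have the same
    within-strength, get z = 0 with a warning.
    """
    W = _check_square_symmetric(W)
    codes = _module_codes(modules)
    if len(codes) != W.shape[0]:
        raise ValueError("module assignment does not cover every parcel")
    z = np.zeros(len(codes))
    for m in np.unique(codes):
        members = np.flatnonzero(codes == m)
        k = W[np.ix_(members, members)].sum(axis=1)
        sd = k.std()  # population (n) convention
        if len(members) < 2 or sd == 0:
            warnings.warn(
                f"module {m} has undefined within-module z (size "
                f"{len(members)}, sd {sd:.3g}); set to 0",
                UserWarning,
            )
            continue
        z[members] = (k - k.mean()) / sd
    return z


def participation_coefficient(W: np.ndarray, modules) -> np.ndarray:
    """``p_i = 1 - sum_m (k_im / k_i)^2`` over module-wise strengths.

    An isolated node (total strength 0) gets p = 0 by convention.
    """
    W = _check_square_symmetric(W)
    codes = _module_codes(modules)
    if len(codes) != W.shape[0]:
        raise ValueError("module assignment does not cover every parcel")
    n_mod = codes.max() + 1
    k_im = np.zeros((W.shape[0], n_mod))
    for m in range(n_mod):
        k_im[:, m] = W[:, codes == m].sum(axis=1)
    k_i = k_im.sum(axis=1)
    p = np.zeros(W.shape[0])
    nz = k_i > 0
    if (~nz).any():
        logger.info("%d isolated nodes assigned participation 0", (~nz).sum())
    p[nz] = 1.0 - ((k_im[nz] / k_i[nz, None]) ** 2).sum(axis=1)
    return p


def integration_segregation_ratio(
    within_z: np.ndarray, participation: np.ndarray, eps: float = RATIO_EPS
) -> np.ndarray:
    """Per-parcel balance of segregation (within) and integration (between).

    Both vectors are min-max normalized to [0, 1] across parcels, then
    ``ratio = (norm within_z + eps) / (norm participation + eps)``.  The
    epsilon keeps the ratio defined at the extremes; min-max normalization
    is required because the within-module z-scores are signed.
    """
    within_z = np.asarray(within_z, dtype=float)
    participation = np.asarray(participation, dtype=float)
    if within_z.shape != participation.shape:
        raise ValueError("metric vectors must have the same shape")

    def minmax(v, name):
        rng = v.max() - v.min()
        if rng == 0:
            raise ValueError(f"constant {name} vector; normalization undefined")
        return (v - v.min()) / rng

    nw = minmax(within_z, "within-z")
    np_ = minmax(participation, "participation")
    return (nw + eps) / (np_ + eps)


def module_metrics(
    beta_matrix: np.ndarray, modules, signed: bool = False
) -> pd.DataFrame:
    """All three per-parcel metrics on a signed beta matrix.

    Normalizes the weights, computes module-degree z, participation and the
    ratio, and returns a tidy per-parcel table.
    """
    W = normalize_weights(beta_matrix, signed=signed)
    z = module_degree_z(W, modules)
    p = participation_coefficient(W, modules)
    ratio = integration_segregation_ratio(z, p)
    return pd.DataFrame(
        {
            "parcel": np.arange(len(z)),
            "module": np.asarray(modules),
            "within_z": z,
            "participation": p,
            "ratio": ratio,
        }
    )


def module_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-module medians of the three metrics (violin-plot style summary)."""
    return (
        metrics.groupby("module")[["within_z", "participation", "ratio"]]
        .median()
        .reset_index()
    )
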