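"""Connectivity bookkeeping and brain-map GLMs.

Starts at per-run parcel-by-parcel correlation matrices: motion censoring
decides which frames (and runs) survive, correlations are Fisher
z-transformed and averaged across retained runs, parcels aggregate into
large-scale networks, and finally each edge (or network pair) is regressed
on the per-subject composite latent score after confound removal.

Censoring follows strict volume rules: a frame is an outlier when FD
exceeds 0.2 mm or DVARS exceeds 75; one frame before and two after every
outlier are censored too; any surviving segment shorter than five
contiguous frames is dropped; a run with more than half its frames censored
is excluded wholesale.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    BlockMatrix,
    CensorMask,
    ConfoundTable,
    ConnectomeSet,
    EdgeGLMMap,
    FrameTrace,
)
from .preprocess import residualize

logger = logging.getLogger(__name__)

FD_THRESHOLD_MM = 0.2
DVARS_THRESHOLD = 75.0


def censor_frames(
    trace: FrameTrace,
    fd_thresh: float = FD_THRESHOLD_MM,
    dvars_thresh: float = DVARS_THRESHOLD,
    pre_frames: int = 1,
    post_frames: int = 2,
    min_segment: int = 5,
    max_censored_frac: float = 0.5,
) -> CensorMask:
    """Apply the motion-censoring rules to one run's quality traces."""
    n = trace.n_frames
    if n < 1:
        raise ValueError("empty frame trace")
    keep = np.ones(n, dtype=bool)
    reasons: dict[int, str] = {}

    outliers = np.flatnonzero((trace.fd > fd_thresh) | (trace.dvars > dvars_thresh))
    for i in outliers:
        reasons[int(i)] = "fd" if trace.fd[i] > fd_thresh else "dvars"
    for i in outliers:
        lo = max(0, i - pre_frames)
        hi = min(n, i + post_frames + 1)
        for j in range(lo, hi):
            keep[j] = False
            reasons.setdefault(int(j), "window")

    # drop surviving segments shorter than min_segment contiguous frames
    j = 0
    while j < n:
        if keep[j]:
            end = j
            while end < n and keep[end]:
                end += 1
            if end - j < min_segment:
                for m in range(j, end):
                    keep[m] = False
                    reasons[m] = "short_segment"
            j = end
        else:
            j += 1

    censored_frac = 1.0 - keep.mean()
    return CensorMask(
        keep=keep,
        run_excluded=censored_frac > max_censored_frac,
        reasons=reasons,
    )


def fisher_z(r):
    """Fisher z-transform ``atanh(r)``; requires |r| < 1 elementwise."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z undefined for |r| >= 1")
    return np.arctanh(r)


def average_runs(
    run_matrices: list[np.ndarray], run_excluded: list[bool] | None = None
) -> np.ndarray:
    """Element-wise mean of retained runs' Fisher-z matrices."""
    if run_excluded is None:
        run_excluded = [False] * len(run_matrices)
    retained = [m for m, ex in zip(run_matrices, run_excluded) if not ex]
    if not retained:
        raise ValueError("all runs excluded; subject should be dropped")
    return np.mean(np.stack(retained), axis=0)


def _group_labels(atlas: pd.DataFrame, level: str = "network17") -> pd.Series:
    """Aggregation labels: cortical parcels keep their network label, all
    subcortical parcels collapse to one 'Subcortex' group."""
    labels = atlas[level].astype(str).copy()
    labels[atlas["compartment"] == "subcortex"] = "Subcortex"
    return labels


def network_average(
    matrix: np.ndarray, atlas: pd.DataFrame, level: str = "network17"
) -> tuple[np.ndarray, list[str]]:
    """Aggregate a parcel matrix into a network-by-network matrix.

    Off-diagonal entry (a, b) is the mean over all edges with one endpoint
    in group a and the other in group b; diagonal entry (a, a) is the mean
    of the within-group off-diagonal edges.  With the 17 cortical networks
    plus one subcortical group this yields an 18 x 18 matrix.  A singleton
    group has no within edges; its diagonal is NaN with a warning.
    """
    if matrix.shape[0] != len(atlas):
        raise ValueError("matrix size does not match atlas")
    labels = _group_labels(atlas, level)
    names = sorted(labels.unique())
    G = len(names)
    idx = {g: np.flatnonzero(labels.to_numpy() == g) for g in names}
    out = np.empty((G, G))
    for a in range(G):
        ia = idx[names[a]]
        if len(ia) == 1:
            warnings.warn(
                f"group '{names[a]}' has a single parcel; within value undefined",
                UserWarning,
            )
            out[a, a] = np.nan
        else:
            block = matrix[np.ix_(ia, ia)]
            iu = np.triu_indices(len(ia), k=1)
            out[a, a] = block[iu].mean()
        for b in range(a + 1, G):
            ib = idx[names[b]]
            out[a, b] = out[b, a] = matrix[np.ix_(ia, ib)].mean()
    return out, names


def _vector_glm(responses: np.ndarray, score: np.ndarray):
    """OLS of each response column on [intercept, score]; returns
    (beta, t, F, p) per column with F from the score-coefficient test."""
    n = len(score)
    sc = score - score.mean()
    ss = (sc**2).sum()
    rc = responses - responses.mean(axis=0)
    beta = (sc @ rc) / ss
    resid = rc - np.outer(sc, beta)
    dof = n - 2
    sigma2 = (resid**2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2 / ss)
    F = t**2
    p = stats.f.sf(F, 1, dof)
    return beta, t, F, p


def edge_glm(
    connectomes: ConnectomeSet,
    composite: np.ndarray,
    confounds: ConfoundTable | None = None,
    component: int = 0,
    q_level: float = 0.05,
    network_level: str = "network17",
) -> EdgeGLMMap:
    """GLMs of connectivity on the per-subject composite latent score.

    Confounds (age, sex, education) are first regressed out of the
    connectivity responses, then each unique upper-triangle edge is
    regressed on the standardized composite.  Edge-level betas are reported
    unthresholded; the network-level matrix (17 cortical networks + one
    subcortical group by default) is BH-FDR corrected across its unique
    pairs (171 for an 18-group matrix, diagonal included).
    """
    composite = np.asarray(composite, dtype=float)
    if composite.ndim == 2:
        composite = composite[:, component]
    if composite.std() == 0:
        raise ValueError("composite score has zero variance")
    score = (composite - composite.mean()) / composite.std()
    n, P = connectomes.n_subjects, connectomes.n_parcels
    if len(score) != n:
        raise ValueError("composite does not align with connectome subjects")

    iu = np.triu_indices(P, k=1)
    edges = connectomes.matrices[:, iu[0], iu[1]]
    if confounds is not None:
        edges = residualize(
            BlockMatrix(edges, [f"e{i}" for i in range(edges.shape[1])]), confounds
        ).values
    beta, t, F, p = _vector_glm(edges, score)

    def to_matrix(vec, fill=0.0):
        M = np.full((P, P), fill)
        M[iu] = vec
        M[(iu[1], iu[0])] = vec
        np.fill_diagonal(M, 0.0)
        return M

    # network-level: average each subject's (residualized) matrix, refit
    net_mats = []
    res_mats = np.zeros((n, P, P))
    res_mats[:, iu[0], iu[1]] = edges
    res_mats += res_mats.transpose(0, 2, 1)
    names: list[str] = []
    for s in range(n):
        nm, names = network_average(res_mats[s], connectomes.atlas, network_level)
        net_mats.append(nm)
    net = np.stack(net_mats)
    G = net.shape[1]
    gu = np.triu_indices(G, k=0)  # diagonal (within-network) included
    net_edges = net[:, gu[0], gu[1]]
    finite = np.all(np.isfinite(net_edges), axis=0)
    nb = np.full(len(gu[0]), np.nan)
    np_ = np.full(len(gu[0]), np.nan)
    nb[finite], _, _, np_[finite] = _vector_glm(net_edges[:, finite], score)
    from .inference import bh_fdr

    nq = np.full(len(gu[0]), np.nan)
    nq[finite], _ = bh_fdr(np_[finite], q_level)

    def net_matrix(vec):
        M = np.full((G, G), np.nan)
        M[gu] = vec
        M[(gu[1], gu[0])] = vec
        return M

    return EdgeGLMMap(
        component=component,
        edge_beta=to_matrix(beta),
        edge_t=to_matrix(t),
        edge_f=to_matrix(F),
        edge_p=to_matrix(p, fill=1.0),
        network_beta=net_matrix(nb),
        network_p=net_matrix(np_),
        network_q=net_matrix(nq),
        network_names=names,
    )
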