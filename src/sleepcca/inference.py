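"""Significance and stability machinery for the canonical components.

Twin cohorts violate exchangeability: siblings share latent traits, so a
naive permutation null is too narrow and anticonservative.  Here whole
families are the permutation units.  Families may swap positions only with
families of identical structure signature (relatedness class + size), and
members may additionally swap within their family; this preserves the
dependence structure under the null.  The same family units are the
resampling units for the bootstrap and are kept intact across
cross-validation folds.

The per-component permutation p compares the i-th observed canonical
correlation with the i-th correlation across permutations.  Note the null
distribution of sample canonical correlations is not centered at zero —
with many variables the largest null correlation is substantial, which is
exactly why permutation rather than a parametric reference is used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import svd

from . import cca as cca_mod
from . import preprocess
from .datatypes import (
    BlockMatrix,
    BootstrapResult,
    CCAModel,
    ConfoundTable,
    CrossValResult,
    PermutationResult,
)

logger = logging.getLogger(__name__)


@dataclass
class ExchangeabilityBlocks:
    """Family permutation units grouped by structure signature.

    ``families`` maps each family to its member row indices; ``groups``
    collects families with identical signature ``(relatedness class,
    size)`` — only those are mutually exchangeable.
    """

    families: list[np.ndarray]
    signatures: list[tuple[str, int]]
    n_subjects: int

    @property
    def groups(self) -> dict[tuple[str, int], list[int]]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, sig in enumerate(self.signatures):
            out.setdefault(sig, []).append(i)
        return out

    def n_valid_permutations(self) -> int:
        """Count of distinct block-valid permutations: for each signature
        group, (number of families)! times (family size)! per family."""
        from math import factorial

        total = 1
        for sig, fam_ids in self.groups.items():
            total *= factorial(len(fam_ids))
            for f in fam_ids:
                total *= factorial(len(self.families[f]))
        return total


def build_blocks(cohort: pd.DataFrame) -> ExchangeabilityBlocks:
    """Derive permutation units from the cohort's family columns.

    Subjects with a missing family id become their own singleton family
    (logged).  With all-singleton cohorts the blocks reduce to free
    permutation of all subjects.
    """
    fam = cohort["family_id"].astype(object).copy()
    missing = fam.isna()
    if missing.any():
        logger.info(
            "%d subjects without family_id treated as singletons", missing.sum()
        )
        fam[missing] = [f"__orphan_{i}" for i in np.flatnonzero(missing)]
    relatedness = cohort["relatedness"].astype(str).to_numpy()

    families, signatures = [], []
    for _, idx in pd.Series(range(len(fam)), index=fam.values).groupby(level=0):
        members = np.asarray(idx.to_numpy(), dtype=int)
        cls = relatedness[members[0]]
        families.append(np.sort(members))
        signatures.append((cls, len(members)))
    return ExchangeabilityBlocks(
        families=families, signatures=signatures, n_subjects=len(fam)
    )


def sample_permutation(
    blocks: ExchangeabilityBlocks, rng: np.random.Generator
) -> np.ndarray:
    """Draw a uniform block-valid permutation.

    Family order is shuffled within each signature group, then members are
    shuffled within each family.  Returns ``perm`` such that row ``i`` of
    the permuted data is row ``perm[i]`` of the original.
    """
    perm = np.empty(blocks.n_subjects, dtype=int)
    for fam_ids in blocks.groups.values():
        order = rng.permutation(len(fam_ids))
        for slot, src in zip(fam_ids, (fam_ids[o] for o in order)):
            members_dst = blocks.families[slot]
            members_src = rng.permutation(blocks.families[src])
            perm[members_dst] = members_src
    return perm


def is_valid_permutation(blocks: ExchangeabilityBlocks, perm: np.ndarray) -> bool:
    """Check that a permutation maps every family onto a family with the
    same structure signature (used as a test oracle and runtime assertion)."""
    fam_sets = {}
    for i, members in enumerate(blocks.families):
        fam_sets[frozenset(members.tolist())] = blocks.signatures[i]
    for i, members in enumerate(blocks.families):
        image = frozenset(int(perm[m]) for m in members)
        if fam_sets.get(image) != blocks.signatures[i]:
            return False
    return True


def bh_fdr(p: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and a significance mask.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the ascending order, capped
    at 1; ``mask = q <= q_level``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= q_level


def _null_canonical_corrs(
    Xc: np.ndarray,
    Yc: np.ndarray,
    blocks: ExchangeabilityBlocks | None,
    n_perm: int,
    k: int,
    rng: np.random.Generator,
    restrict: bool = True,
) -> np.ndarray:
    """Canonical correlations of (X, Y[perm]) for sampled permutations.

    Row-permuting an orthonormal column basis leaves it orthonormal and
    centering is permutation-invariant, so refitting the whole CCA reduces
    to an SVD of Q1' @ Q2[perm] — algebraically identical to a full refit.
    """
    Q1, _ = cca_mod._orthonormalize(Xc, "sleep")
    Q2, _ = cca_mod._orthonormalize(Yc, "biopsychosocial")
    n = Xc.shape[0]
    null = np.empty((n_perm, k))
    for b in range(n_perm):
        if restrict and blocks is not None:
            perm = sample_permutation(blocks, rng)
        else:
            perm = rng.permutation(n)
        s = svd(Q1.T @ Q2[perm], compute_uv=False)
        null[b] = s[:k]
    return null


def permutation_test(
    X: BlockMatrix,
    Y: BlockMatrix,
    blocks: ExchangeabilityBlocks | None,
    n_perm: int = 10_000,
    seed: int = 0,
    restrict: bool = True,
) -> PermutationResult:
    """Family-restricted permutation p-values for all canonical correlations.

    Only the rows of Y are permuted (equivalent in distribution to permuting
    either block).  ``p_i = (1 + #{null r_i >= observed r_i}) / (1 + n_perm)``
    so p is never exactly zero; q-values are BH-FDR across the k components.
    Set ``restrict=False`` to deliberately ignore family structure (for
    calibration comparisons only).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if 1.0 / (1.0 + n_perm) > 0.5:
        warnings.warn("n_perm too small for a meaningful p-value", UserWarning)
    model = cca_mod.fit_cca(X, Y)
    observed = model.canonical_corrs
    k = model.k
    rng = np.random.default_rng(seed)
    Xc = X.values - X.values.mean(axis=0)
    Yc = Y.values - Y.values.mean(axis=0)
    null = _null_canonical_corrs(Xc, Yc, blocks, n_perm, k, rng, restrict=restrict)
    p = (1.0 + (null >= observed).sum(axis=0)) / (1.0 + n_perm)
    q, _ = bh_fdr(p)
    return PermutationResult(
        observed_corrs=observed,
        null_corrs=null,
        p_values=p,
        q_values=q,
        n_perm=n_perm,
        seed=seed,
    )


def match_components(
    ref_sleep: np.ndarray,
    ref_bps: np.ndarray,
    boot_sleep: np.ndarray,
    boot_bps: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Match resampled components to the original ones.

    Greedy maximum on the absolute correlation between concatenated
    (sleep + biopsychosocial) weight vectors; deterministic lowest-index
    tie-break; injective by construction (each pair used once).  Returns
    ``(assignment, signs)`` where resampled component ``assignment[i]``
    corresponds to original component ``i`` with orientation ``signs[i]``.
    """
    ref = np.vstack([ref_sleep, ref_bps])
    boot = np.vstack([boot_sleep, boot_bps])
    k = ref.shape[1]
    refc = ref - ref.mean(axis=0)
    bootc = boot - boot.mean(axis=0)
    denom = np.outer(
        np.sqrt((refc**2).sum(axis=0)), np.sqrt((bootc**2).sum(axis=0))
    )
    corr = (refc.T @ bootc) / denom
    assignment = np.full(k, -1)
    signs = np.ones(k)
    absc = np.abs(corr).copy()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(absc), absc.shape)
        assignment[i] = j
        signs[i] = 1.0 if corr[i, j] >= 0 else -1.0
        absc[i, :] = -np.inf
        absc[:, j] = -np.inf
    assert len(set(assignment.tolist())) == k, "component matching not injective"
    return assignment, signs


def _resample_families(
    blocks: ExchangeabilityBlocks, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap row indices: whole families drawn with replacement."""
    n_fam = len(blocks.families)
    picks = rng.integers(0, n_fam, n_fam)
    return np.concatenate([blocks.families[f] for f in picks])


def bootstrap_loadings(
    X: BlockMatrix,
    Y: BlockMatrix,
    model: CCAModel,
    n_boot: int = 1000,
    seed: int = 0,
    blocks: ExchangeabilityBlocks | None = None,
    q_level: float = 0.05,
) -> BootstrapResult:
    """Bootstrap standard deviations and z-scores for all loadings.

    Resampling units are whole families (subjects, when no blocks are
    given), drawn with replacement.  Each replicate's CCA is refit, its
    components matched and sign-aligned to the original model, and its
    loadings recorded.  ``z = original loading / bootstrap sd``; two-sided
    normal p-values are BH-FDR corrected within each component across the
    stacked sleep + biopsychosocial variables.
    """
    if model.sleep_loadings is None:
        raise ValueError("model needs loadings (run compute_loadings first)")
    rng = np.random.default_rng(seed)
    p, q, k = X.n_variables, Y.n_variables, model.k
    reps = np.empty((n_boot, p + q, k))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        if blocks is not None:
            idx = _resample_families(blocks, rng)
        else:
            idx = rng.integers(0, X.n_subjects, X.n_subjects)
        Xb = X.with_values(X.values[idx])
        Yb = Y.with_values(Y.values[idx])
        if np.any(np.ptp(Xb.values, axis=0) == 0) or np.any(
            np.ptp(Yb.values, axis=0) == 0
        ):
            n_redrawn += 1
            logger.info("bootstrap replicate with zero-variance column redrawn")
            continue
        mb = cca_mod.fit_cca(Xb, Yb)
        mb = cca_mod.compute_loadings(mb, Xb, Yb)
        kk = min(k, mb.k)
        assign, signs = match_components(
            model.sleep_weights[:, :kk],
            model.bps_weights[:, :kk],
            mb.sleep_weights[:, :kk],
            mb.bps_weights[:, :kk],
        )
        stacked = np.vstack([mb.sleep_loadings, mb.bps_loadings])
        aligned = stacked[:, assign] * signs
        if kk < k:  # rank collapse in a replicate: pad with original loadings
            pad = np.hstack(
                [
                    aligned,
                    np.vstack([model.sleep_loadings, model.bps_loadings])[:, kk:],
                ]
            )
            aligned = pad
        reps[b] = aligned
        b += 1

    sd = reps.std(axis=0, ddof=1)
    original = np.vstack([model.sleep_loadings, model.bps_loadings])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, original / sd, np.inf * np.sign(original))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    qvals = np.empty_like(pvals)
    mask = np.empty(pvals.shape, dtype=bool)
    for i in range(k):
        qvals[:, i], mask[:, i] = bh_fdr(pvals[:, i], q_level)
    return BootstrapResult(
        loading_sd=sd,
        loading_z=z,
        loading_q=qvals,
        significant=mask,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def _assign_folds(
    blocks: ExchangeabilityBlocks, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Assign whole families to folds, balancing subject counts."""
    order = rng.permutation(len(blocks.families))
    fold_members: list[list[int]] = [[] for _ in range(n_folds)]
    fold_sizes = np.zeros(n_folds, dtype=int)
    for f in order:
        dst = int(np.argmin(fold_sizes))
        fold_members[dst].extend(blocks.families[f].tolist())
        fold_sizes[dst] += len(blocks.families[f])
    return [np.sort(np.asarray(m, dtype=int)) for m in fold_members]


def _restrict_blocks(
    blocks: ExchangeabilityBlocks, subset: np.ndarray
) -> ExchangeabilityBlocks:
    """Blocks re-indexed to a subset of subjects (for within-fold permutation)."""
    pos = {int(s): i for i, s in enumerate(subset)}
    families, signatures = [], []
    for fam, sig in zip(blocks.families, blocks.signatures):
        members = [pos[int(m)] for m in fam if int(m) in pos]
        if members:
            families.append(np.sort(np.asarray(members)))
            signatures.append((sig[0], len(members)))
    return ExchangeabilityBlocks(families, signatures, len(subset))


def crossval_cca(
    X: BlockMatrix,
    Y: BlockMatrix,
    confounds: ConfoundTable,
    blocks: ExchangeabilityBlocks,
    n_folds: int = 5,
    seed: int = 0,
    n_perm: int = 1000,
) -> CrossValResult:
    """Family-aware k-fold generalization test by coefficient projection.

    Folds are unions of whole families (no family is split).  Per fold the
    confound regression and the CCA are fit on the training subjects only;
    held-out blocks are residualized with the training coefficients and
    projected through the training weights, giving out-of-sample variate
    pairs whose Pearson correlation measures generalization.  Significance
    per component: block-valid permutation of the held-out rows against the
    across-fold mean correlation.

    ``n_folds=1`` is a degenerate train-equals-test mode kept for testing:
    it must reproduce the in-sample canonical correlations exactly.
    """
    rng = np.random.default_rng(seed)
    if n_folds == 1:
        folds = [np.arange(X.n_subjects)]
    elif n_folds >= 2:
        folds = _assign_folds(blocks, n_folds, rng)
    else:
        raise ValueError("n_folds must be >= 1")
    all_idx = np.arange(X.n_subjects)

    per_fold_UV = []
    k_ref: int | None = None
    for test_idx in folds:
        train_idx = (
            all_idx if n_folds == 1 else np.setdiff1d(all_idx, test_idx)
        )
        if len(test_idx) <= X.n_variables:
            raise ValueError(
                f"fold has {len(test_idx)} test subjects <= {X.n_variables} "
                "sleep variables; use fewer folds"
            )
        conf_tr = confounds.take(train_idx)
        conf_te = confounds.take(test_idx)
        res_x = preprocess.fit_residualizer(conf_tr, X.with_values(X.values[train_idx]))
        res_y = preprocess.fit_residualizer(conf_tr, Y.with_values(Y.values[train_idx]))
        Xtr = res_x(X.with_values(X.values[train_idx]), conf_tr)
        Ytr = res_y(Y.with_values(Y.values[train_idx]), conf_tr)
        Xte = res_x(X.with_values(X.values[test_idx]), conf_te)
        Yte = res_y(Y.with_values(Y.values[test_idx]), conf_te)
        model = cca_mod.fit_cca(Xtr, Ytr)
        if k_ref is None:
            k_ref = model.k
        Ustar, Vstar = cca_mod.project(model, Xte, Yte)
        per_fold_UV.append((Ustar[:, :k_ref], Vstar[:, :k_ref], test_idx))

    k = int(k_ref)  # type: ignore[arg-type]
    fold_corrs = np.empty((len(folds), k))
    for fi, (U, V, _) in enumerate(per_fold_UV):
        for i in range(k):
            fold_corrs[fi, i] = np.corrcoef(U[:, i], V[:, i])[0, 1]
    mean_corrs = fold_corrs.mean(axis=0)

    # permutation null for the across-fold mean correlation
    fold_blocks = [_restrict_blocks(blocks, idx) for (_, _, idx) in per_fold_UV]
    null_means = np.empty((n_perm, k))
    for b in range(n_perm):
        acc = np.zeros(k)
        for (U, V, _), fb in zip(per_fold_UV, fold_blocks):
            perm = sample_permutation(fb, rng)
            Vp = V[perm]
            for i in range(k):
                acc[i] += np.corrcoef(U[:, i], Vp[:, i])[0, 1]
        null_means[b] = acc / len(folds)
    p = (1.0 + (null_means >= mean_corrs).sum(axis=0)) / (1.0 + n_perm)

    assignments = {}
    for fi, (_, _, idx) in enumerate(per_fold_UV):
        for s in idx:
            assignments[int(s)] = fi
    fold_series = pd.Series(assignments).sort_index()
    return CrossValResult(
        fold_corrs=fold_corrs,
        mean_corrs=mean_corrs,
        p_values=p,
        fold_assignments=fold_series,
        n_perm=n_perm,
        seed=seed,
    )


def posthoc_associations(
    composite: np.ndarray,
    covariates: pd.DataFrame,
    continuous: list[str] | None = None,
    q_level: float = 0.05,
    min_category_n: int = 5,
) -> pd.DataFrame:
    """Association tests between composite scores and external covariates.

    Continuous covariates: Pearson correlation.  Categorical: pooled
    two-sample t-test for two levels, one-way ANOVA for more.  A covariate
    with any category below ``min_category_n`` subjects is skipped with a
    recorded reason.  BH-FDR is applied across all computed tests.
    """
    composite = np.atleast_2d(np.asarray(composite, dtype=float))
    if composite.shape[0] != len(covariates):
        composite = composite.T
    if composite.shape[0] != len(covariates):
        raise ValueError("composite rows do not align with covariates")
    if continuous is None:
        continuous = [
            c
            for c in covariates.columns
            if pd.api.types.is_float_dtype(covariates[c])
        ]

    rows = []
    for comp in range(composite.shape[1]):
        score = composite[:, comp]
        for cov in covariates.columns:
            col = covariates[cov]
            if cov in continuous:
                if not pd.api.types.is_numeric_dtype(col):
                    raise ValueError(f"continuous covariate '{cov}' is not numeric")
                r, p = stats.pearsonr(score, col.to_numpy(float))
                rows.append((comp, cov, "pearson", r, p, len(col), ""))
            else:
                counts = col.value_counts()
                if (counts < min_category_n).any():
                    small = counts[counts < min_category_n]
                    rows.append(
                        (
                            comp,
                            cov,
                            "skipped",
                            np.nan,
                            np.nan,
                            len(col),
                            f"category below {min_category_n} subjects: "
                            f"{list(small.index)}",
                        )
                    )
                    logger.info("posthoc test for '%s' skipped: small category", cov)
                    continue
                groups = [score[col.to_numpy() == lvl] for lvl in counts.index]
                if len(groups) < 2:
                    rows.append(
                        (comp, cov, "skipped", np.nan, np.nan, len(col),
                         "fewer than 2 categories")
                    )
                    continue
                if len(groups) == 2:
                    t, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
                    rows.append((comp, cov, "t-test", t, p, len(col), ""))
                else:
                    f, p = stats.f_oneway(*groups)
                    rows.append((comp, cov, "anova", f, p, len(col), ""))

    table = pd.DataFrame(
        rows,
        columns=["component", "covariate", "test", "stat", "p", "n", "note"],
    )
    computed = table["p"].notna()
    qvals = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    if computed.any():
        q, mask = bh_fdr(table.loc[computed, "p"].to_numpy(), q_level)
        qvals[computed.to_numpy()] = q
        sig[computed.to_numpy()] = mask
    table["q"] = qvals
    table["significant"] = sig
    return table
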