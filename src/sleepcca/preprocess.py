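"""Confound residualization and quantile normalization.

Both phenotype blocks are residualized on age, sex and education before the
canonical decomposition, mirroring the usual practice of removing nuisance
variance that would otherwise masquerade as sleep-biopsychosocial covariance.
Quantile normalization (rank-based inverse-normal transform) is the control
variant that removes scale-magnitude discrepancies between heterogeneous
measures.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BlockMatrix, ConfoundTable

logger = logging.getLogger(__name__)

# Relative tolerance on singular values when checking the confound design
# for collinearity.
_RANK_RTOL = 1e-10


def _clean_design(design: np.ndarray, names: list[str]):
    """Drop non-intercept columns that are constant (they add nothing beyond
    the intercept), then reject a still rank-deficient design by name."""
    keep = [0] + [
        j for j in range(1, design.shape[1]) if np.ptp(design[:, j]) > 0
    ]
    dropped = [names[j] for j in range(1, design.shape[1]) if j not in keep]
    if dropped:
        logger.info("constant confound columns ignored: %s", dropped)
    design = design[:, keep]
    names = [names[j] for j in keep]
    _check_design(design, names)
    return design


def _check_design(design: np.ndarray, names: list[str]) -> None:
    s = np.linalg.svd(design, compute_uv=False)
    if s[-1] <= _RANK_RTOL * s[0]:
        # name the offending columns: any column that is (nearly) in the
        # span of the others
        collinear = []
        for j in range(design.shape[1]):
            others = np.delete(design, j, axis=1)
            coef, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
            resid = design[:, j] - others @ coef
            scale = np.linalg.norm(design[:, j]) or 1.0
            if np.linalg.norm(resid) <= 1e-8 * scale:
                collinear.append(names[j])
        raise ValueError(
            f"confound design is rank deficient; collinear columns: {collinear}"
        )


def residualize(block: BlockMatrix, confounds: ConfoundTable) -> BlockMatrix:
    """Least-squares residuals of every block column on the confound design.

    The design is ``[intercept, age, sex, education]``; output columns are
    orthogonal to it (within numerical tolerance).  Residualization is affine
    invariant in the confound coding, so 0/1 versus effect-coded sex gives
    identical residuals.
    """
    if block.n_subjects != len(confounds):
        raise ValueError("block and confounds have different numbers of subjects")
    design = _clean_design(
        confounds.design(), ["intercept", "age", "sex", "education"]
    )
    coef, *_ = np.linalg.lstsq(design, block.values, rcond=None)
    return block.with_values(block.values - design @ coef)


def fit_residualizer(confounds: ConfoundTable, block: BlockMatrix):
    """Fit confound coefficients on one sample and return an apply-function.

    Used inside cross-validation: the regression is fit on the training
    subjects only, then applied to held-out subjects with the training
    coefficients, so no information leaks across folds.
    """
    design = confounds.design()
    keep = [0] + [j for j in range(1, design.shape[1]) if np.ptp(design[:, j]) > 0]
    _check_design(design[:, keep], ["intercept", "age", "sex", "education"])
    coef, *_ = np.linalg.lstsq(design[:, keep], block.values, rcond=None)

    def apply(new_block: BlockMatrix, new_confounds: ConfoundTable) -> BlockMatrix:
        return new_block.with_values(
            new_block.values - new_confounds.design()[:, keep] @ coef
        )

    return apply


def quantile_normalize(block: BlockMatrix) -> BlockMatrix:
    """Map every column to standard-normal quantiles by rank.

    Uses plotting positions ``(rank - 0.5) / n`` with average ranks for
    ties, so the output is invariant to any strictly monotone transform of
    the input column.
    """
    n = block.n_subjects
    if n < 3:
        raise ValueError("quantile normalization needs at least 3 subjects")
    out = np.empty_like(block.values)
    for j in range(block.n_variables):
        col = block.values[:, j]
        if np.ptp(col) == 0:
            raise ValueError(
                f"column '{block.variable_names[j]}' is constant; "
                "ranks are undefined for quantile normalization"
            )
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((ranks - 0.5) / n)
    return block.with_values(out)


def load_phenotypes(
    path,
    sleep_columns: list[str],
    bps_columns: list[str],
    confound_columns: dict[str, str] | None = None,
    family_columns: dict[str, str] | None = None,
    sep: str = "\t",
) -> tuple[pd.DataFrame, BlockMatrix, BlockMatrix, ConfoundTable]:
    """Read a phenotype table and split it into blocks and confounds.

    Rows with any missing value in the sleep block, biopsychosocial block or
    confounds are dropped (listwise deletion) with a logged count.  Returns
    the retained subject table (including family columns when mapped) plus
    the two blocks and the confound table, all row-aligned.
    """
    confound_columns = confound_columns or {
        "age": "age", "sex": "sex", "education": "education"
    }
    table = pd.read_csv(path, sep=sep)
    needed = list(sleep_columns) + list(bps_columns) + list(confound_columns.values())
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {missing_cols}")
    complete = table[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d subjects with missing data (listwise)", n_dropped)
    table = table.loc[complete].reset_index(drop=True)
    X = BlockMatrix.from_frame(table[sleep_columns])
    Y = BlockMatrix.from_frame(table[bps_columns])
    confounds = ConfoundTable(
        age=table[confound_columns["age"]].to_numpy(float),
        sex=table[confound_columns["sex"]].to_numpy(float),
        education=table[confound_columns["education"]].to_numpy(float),
    )
    if family_columns:
        rename = {v: k for k, v in family_columns.items()}
        table = table.rename(columns=rename)
    return table, X, Y, confounds
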