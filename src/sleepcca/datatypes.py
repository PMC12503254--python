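"""Shared containers for the sleep-biopsychosocial pipeline.

The pipeline links a small block of sleep questionnaire sub-scores (X) to a
wide block of biopsychosocial measures (Y) through canonical correlation
analysis, then maps the resulting latent-component scores onto parcellated
functional-connectivity matrices.  These dataclasses are the contract between
stages: a :class:`BlockMatrix` per phenotype block, a cohort table carrying
the family structure that drives all restricted resampling, a fitted
:class:`CCAModel`, and a :class:`ConnectomeSet` of per-subject Fisher-z
connectivity matrices with a parcel-to-network atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Relatedness classes a cohort subject may carry.  Twin and sibling pairs
#: are exchangeable only with pairs of the same class; singletons with
#: singletons.
RELATEDNESS_CLASSES = ("MZ", "DZ", "SIB", "SINGLETON")

#: Columns every cohort table must provide.
COHORT_COLUMNS = ("subject_id", "family_id", "relatedness", "age", "sex", "education")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check that a cohort table has the required columns and values.

    Returns the table unchanged so the call can be used inline.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad = set(cohort["relatedness"].unique()) - set(RELATEDNESS_CLASSES)
    if bad:
        raise ValueError(f"unknown relatedness classes: {sorted(bad)}")
    return cohort


@dataclass
class BlockMatrix:
    """A named subjects-by-variables numeric block.

    Parameters
    ----------
    values
        ``(n_subjects, n_variables)`` float array, no missing values.
    variable_names
        Column labels, one per variable.
    category
        Optional per-variable domain label (e.g. ``"cognition"``,
        ``"mental health"``); used only for reporting.
    worse_direction
        Optional per-variable flag: True where larger values mean a worse
        outcome (PSQI-style coding).
    """

    values: np.ndarray
    variable_names: list[str]
    category: list[str] | None = None
    worse_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BlockMatrix values must be 2-D")
        if self.values.shape[1] != len(self.variable_names):
            raise ValueError("variable_names length does not match values")
        if np.isnan(self.values).any():
            raise ValueError("BlockMatrix contains missing values; drop rows at load")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "BlockMatrix":
        """Copy of this block with new values and identical metadata."""
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names, index=index)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        category: Sequence[str] | None = None,
        worse_direction: Sequence[bool] | None = None,
    ) -> "BlockMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            variable_names=[str(c) for c in frame.columns],
            category=list(category) if category is not None else None,
            worse_direction=(
                np.asarray(worse_direction, dtype=bool)
                if worse_direction is not None
                else None
            ),
        )


@dataclass
class ConfoundTable:
    """Age, sex and education for each subject, aligned to the block rows."""

    age: np.ndarray
    sex: np.ndarray
    education: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.education = np.asarray(self.education, dtype=float)
        n = len(self.age)
        if len(self.sex) != n or len(self.education) != n:
            raise ValueError("confound columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.age)

    def design(self) -> np.ndarray:
        """Design matrix with intercept: ``[1, age, sex, education]``."""
        return np.column_stack(
            [np.ones(len(self)), self.age, self.sex, self.education]
        )

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "ConfoundTable":
        return cls(
            age=cohort["age"].to_numpy(float),
            sex=cohort["sex"].to_numpy(float),
            education=cohort["education"].to_numpy(float),
        )

    def take(self, idx: np.ndarray) -> "ConfoundTable":
        return ConfoundTable(self.age[idx], self.sex[idx], self.education[idx])


@dataclass
class CCAModel:
    """A fitted canonical correlation decomposition of two blocks.

    ``k`` latent components, each a pair of canonical variates: sleep-side
    scores ``U = X_c @ sleep_weights`` and biopsychosocial-side scores
    ``V = Y_c @ bps_weights`` (blocks column-centered with the stored means).
    ``canonical_corrs[i]`` is the Pearson correlation of ``U[:, i]`` with
    ``V[:, i]`` and equals ``singular_values[i]`` up to round-off.
    ``explained_cov`` holds the squared-singular-value fractions, i.e. the
    share of cross-block covariance each component carries.
    """

    sleep_weights: np.ndarray
    bps_weights: np.ndarray
    singular_values: np.ndarray
    canonical_corrs: np.ndarray
    sleep_scores: np.ndarray
    bps_scores: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    sleep_loadings: np.ndarray | None = None
    bps_loadings: np.ndarray | None = None
    explained_cov: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.sleep_weights.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.sleep_scores.shape[0]


@dataclass
class ConnectomeSet:
    """Per-subject symmetric Fisher-z connectivity matrices plus an atlas.

    ``matrices`` has shape ``(n_subjects, n_parcels, n_parcels)``; every
    slice is symmetric with zero diagonal.  ``atlas`` maps each parcel to a
    fine (17-network) and coarse (7-network) label and a cortical/subcortical
    compartment flag, with columns ``parcel_id``, ``network17``, ``network7``,
    ``compartment``.
    """

    matrices: np.ndarray
    atlas: pd.DataFrame
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3:
            raise ValueError("matrices must be (n_subjects, n_parcels, n_parcels)")
        need = {"parcel_id", "network17", "network7", "compartment"}
        if not need.issubset(self.atlas.columns):
            raise ValueError(f"atlas missing columns: {need - set(self.atlas.columns)}")
        if len(self.atlas) != self.matrices.shape[1]:
            raise ValueError("atlas does not cover every parcel exactly once")

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.matrices.shape[1]


@dataclass
class FrameTrace:
    """Per-frame head-motion (FD, mm) and signal-change (DVARS) traces."""

    fd: np.ndarray
    dvars: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.fd.shape != self.dvars.shape or self.fd.ndim != 1:
            raise ValueError("fd and dvars must be equal-length 1-D arrays")
        if (self.fd < 0).any() or (self.dvars < 0).any():
            raise ValueError("FD and DVARS must be nonnegative")

    @property
    def n_frames(self) -> int:
        return len(self.fd)


@dataclass
class CensorMask:
    """Result of motion-censoring a run.

    ``keep`` flags surviving frames; ``reasons`` holds a short code for each
    dropped frame ('fd', 'dvars', 'window', 'short_segment').  A run whose
    censored fraction exceeds the threshold is excluded wholesale and must be
    skipped by downstream run averaging.
    """

    keep: np.ndarray
    run_excluded: bool
    reasons: dict[int, str] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def censored_fraction(self) -> float:
        return 1.0 - self.keep.mean()


@dataclass
class EdgeGLMMap:
    """Per-edge and per-network-pair GLM statistics for one latent component.

    Edge-level matrices are reported unthresholded; the network-level
    (e.g. 18x18) matrices additionally carry BH-FDR q-values across the
    unique network pairs.
    """

    component: int
    edge_beta: np.ndarray
    edge_t: np.ndarray
    edge_f: np.ndarray
    edge_p: np.ndarray
    network_beta: np.ndarray | None = None
    network_p: np.ndarray | None = None
    network_q: np.ndarray | None = None
    network_names: list[str] | None = None


@dataclass
class PermutationResult:
    """Family-restricted permutation null for the canonical correlations."""

    observed_corrs: np.ndarray
    null_corrs: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_perm: int
    seed: int


@dataclass
class BootstrapResult:
    """Bootstrap spread of the loadings, with component re-alignment.

    Rows stack sleep then biopsychosocial variables; ``loading_z`` is the
    original loading divided by its bootstrap standard deviation, and
    ``significant`` flags loadings surviving BH-FDR within each component.
    """

    loading_sd: np.ndarray
    loading_z: np.ndarray
    loading_q: np.ndarray
    significant: np.ndarray
    n_boot: int
    seed: int
    n_redrawn: int = 0


@dataclass
class CrossValResult:
    """Family-aware k-fold out-of-sample canonical correlations."""

    fold_corrs: np.ndarray  # (n_folds, k)
    mean_corrs: np.ndarray  # (k,)
    p_values: np.ndarray  # (k,)
    fold_assignments: pd.Series  # family_id -> fold
    n_perm: int
    seed: int
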