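"""Configuration-driven end-to-end runner.

Stage order: preprocess (confound residualization) -> CCA -> inference
(family-restricted permutation, bootstrap loading stability,
cross-validation) -> connectome GLMs -> graph metrics.  Every stage writes
its tables under the output directory and the run manifest records seeds,
counts and every design flag in effect, so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cca as cca_mod
from . import connectome as conn_mod
from . import graph_metrics, inference, io, preprocess
from .datatypes import BootstrapResult, CCAModel, ConfoundTable, validate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("cca", "permute", "bootstrap", "crossval", "brainmap", "graphmetrics")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; mirrors the YAML config file."""

    phenotypes: str = ""
    connectomes: str = ""
    connectome_container: str = "tsv-dir"
    atlas: str = ""
    output_dir: str = "run_output"
    sleep_columns: list[str] = field(default_factory=list)
    bps_columns: list[str] = field(default_factory=list)
    confound_columns: dict[str, str] = field(
        default_factory=lambda: {"age": "age", "sex": "sex", "education": "education"}
    )
    family_columns: dict[str, str] = field(
        default_factory=lambda: {"family_id": "family_id", "relatedness": "relatedness"}
    )
    n_perm: int = 10_000
    n_boot: int = 1000
    n_folds: int = 5
    n_cv_perm: int = 1000
    q_level: float = 0.05
    quantile_normalize: bool = False
    use_separate_scores: bool = False
    signed_graph_weights: bool = False
    pca_reduce_bps: bool = False  # exposed but untested control variant
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages_run": []}

    stage = "load"
    try:
        table, X, Y, confounds = preprocess.load_phenotypes(
            cfg.phenotypes,
            cfg.sleep_columns,
            cfg.bps_columns,
            cfg.confound_columns,
            cfg.family_columns,
        )
        cohort = validate_cohort(
            table[
                ["subject_id", "family_id", "relatedness", "age", "sex", "education"]
            ]
            if "subject_id" in table.columns
            else table.assign(subject_id=[f"S{i:05d}" for i in range(len(table))])[
                ["subject_id", "family_id", "relatedness", "age", "sex", "education"]
            ]
        )
        blocks = inference.build_blocks(cohort)
        manifest["n_subjects"] = len(cohort)

        stage = "preprocess"
        if cfg.quantile_normalize:
            X = preprocess.quantile_normalize(X)
            Y = preprocess.quantile_normalize(Y)
        Xr = preprocess.residualize(X, confounds)
        Yr = preprocess.residualize(Y, confounds)

        stage = "cca"
        model = cca_mod.fit_cca(Xr, Yr)
        model = cca_mod.compute_loadings(model, Xr, Yr)
        model = cca_mod.orient_components(model)
        io.write_model(out / "model", model, X.variable_names, Y.variable_names)
        manifest["stages_run"].append("cca")
        manifest["k"] = model.k
        manifest["canonical_corrs"] = model.canonical_corrs.tolist()
        manifest["explained_cov"] = model.explained_cov.tolist()

        boot: BootstrapResult | None = None
        if "permute" in cfg.stages:
            stage = "permute"
            perm = inference.permutation_test(
                Xr, Yr, blocks, n_perm=cfg.n_perm, seed=cfg.seed + 1
            )
            pd.DataFrame(
                {
                    "component": [f"LC{i + 1}" for i in range(model.k)],
                    "observed_r": perm.observed_corrs,
                    "p": perm.p_values,
                    "q": perm.q_values,
                }
            ).to_csv(out / "permutation.tsv", sep="\t", index=False)
            manifest["stages_run"].append("permute")
            manifest["perm_p"] = perm.p_values.tolist()

        if "bootstrap" in cfg.stages:
            stage = "bootstrap"
            boot = inference.bootstrap_loadings(
                Xr,
                Yr,
                model,
                n_boot=cfg.n_boot,
                seed=cfg.seed + 2,
                blocks=blocks,
                q_level=cfg.q_level,
            )
            names = X.variable_names + Y.variable_names
            rows = []
            stacked = np.vstack([model.sleep_loadings, model.bps_loadings])
            for i in range(model.k):
                for v, name in enumerate(names):
                    rows.append(
                        (
                            f"LC{i + 1}",
                            name,
                            stacked[v, i],
                            boot.loading_sd[v, i],
                            boot.loading_z[v, i],
                            boot.loading_q[v, i],
                            bool(boot.significant[v, i]),
                        )
                    )
            pd.DataFrame(
                rows,
                columns=["component", "variable", "loading", "sd", "z", "q",
                         "significant"],
            ).to_csv(out / "bootstrap_loadings.tsv", sep="\t", index=False)
            manifest["stages_run"].append("bootstrap")

        if "crossval" in cfg.stages:
            stage = "crossval"
            cv = inference.crossval_cca(
                X,
                Y,
                confounds,
                blocks,
                n_folds=cfg.n_folds,
                seed=cfg.seed + 3,
                n_perm=cfg.n_cv_perm,
            )
            pd.DataFrame(
                {
                    "component": [f"LC{i + 1}" for i in range(len(cv.mean_corrs))],
                    "mean_cv_r": cv.mean_corrs,
                    "p": cv.p_values,
                }
            ).to_csv(out / "crossval.tsv", sep="\t", index=False)
            manifest["stages_run"].append("crossval")
            manifest["cv_mean_r"] = cv.mean_corrs.tolist()

        if "brainmap" in cfg.stages and cfg.connectomes:
            stage = "brainmap"
            conn = io.read_connectomes(cfg.connectomes, cfg.connectome_container)
            if conn.n_subjects != len(cohort):
                raise ValueError(
                    "connectome subject count does not match phenotype table"
                )
            if cfg.use_separate_scores:
                scores = [
                    ("sleep", model.sleep_scores),
                    ("bps", model.bps_scores),
                ]
            else:
                scores = [("composite", cca_mod.composite_scores(model))]
            glm_maps = []
            for label, sc in scores:
                for i in range(model.k):
                    gmap = conn_mod.edge_glm(
                        conn, sc[:, i], confounds, component=i, q_level=cfg.q_level
                    )
                    np.savetxt(
                        out / f"edge_beta_{label}_LC{i + 1}.tsv",
                        gmap.edge_beta,
                        delimiter="\t",
                    )
                    pd.DataFrame(
                        gmap.network_beta,
                        index=gmap.network_names,
                        columns=gmap.network_names,
                    ).to_csv(out / f"network_beta_{label}_LC{i + 1}.tsv", sep="\t")
                    pd.DataFrame(
                        gmap.network_q,
                        index=gmap.network_names,
                        columns=gmap.network_names,
                    ).to_csv(out / f"network_q_{label}_LC{i + 1}.tsv", sep="\t")
                    glm_maps.append(gmap)
            manifest["stages_run"].append("brainmap")

            if "graphmetrics" in cfg.stages:
                stage = "graphmetrics"
                modules = conn_mod._group_labels(conn.atlas, "network7").to_numpy()
                for gmap in glm_maps:
                    metrics = graph_metrics.module_metrics(
                        gmap.edge_beta, modules, signed=cfg.signed_graph_weights
                    )
                    metrics.to_csv(
                        out / f"graph_metrics_LC{gmap.component + 1}.tsv",
                        sep="\t",
                        index=False,
                    )
                    graph_metrics.module_summary(metrics).to_csv(
                        out / f"graph_summary_LC{gmap.component + 1}.tsv",
                        sep="\t",
                        index=False,
                    )
                manifest["stages_run"].append("graphmetrics")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def report_top_loadings(
    model: CCAModel,
    bootstrap: BootstrapResult,
    sleep_names: list[str],
    bps_names: list[str],
    categories: list[str] | None = None,
    top_n: int = 15,
) -> pd.DataFrame:
    """Per component: all sleep loadings plus the strongest biopsychosocial
    loadings by magnitude, annotated with bootstrap sd/z/q and significance.

    Ties in |loading| break lexicographically by variable name.
    """
    if model.sleep_loadings is None:
        raise ValueError("model needs loadings")
    p = len(sleep_names)
    stacked = np.vstack([model.sleep_loadings, model.bps_loadings])
    cats = categories or ["sleep"] * p + ["bps"] * len(bps_names)
    rows = []
    for i in range(model.k):
        bps = pd.DataFrame(
            {
                "variable": bps_names,
                "loading": model.bps_loadings[:, i],
                "abs_loading": np.abs(model.bps_loadings[:, i]),
            }
        ).sort_values(
            ["abs_loading", "variable"], ascending=[False, True], kind="stable"
        )
        chosen = list(range(p)) + [
            p + int(j) for j in bps.index[: min(top_n, len(bps_names))]
        ]
        for v in chosen:
            name = (sleep_names + bps_names)[v]
            rows.append(
                (
                    f"LC{i + 1}",
                    name,
                    cats[v],
                    stacked[v, i],
                    bootstrap.loading_sd[v, i],
                    bootstrap.loading_z[v, i],
                    bootstrap.loading_q[v, i],
                    bool(bootstrap.significant[v, i]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["component", "variable", "category", "loading", "sd", "z", "q",
                 "significant"],
    )
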