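"""Reading and writing the pipeline's on-disk artifacts.

Everything tabular is TSV with a one-line header; scalars and provenance go
into JSON manifests.  Connectomes are stored either as one TSV per subject
in a directory or as a single HDF5 container (config switch).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CCAModel, ConnectomeSet
from .synthetic import SyntheticTruth


def write_phenotypes(path, cohort: pd.DataFrame, X, Y) -> None:
    table = pd.concat(
        [cohort.reset_index(drop=True), X.to_frame(), Y.to_frame()], axis=1
    )
    table.to_csv(path, sep="\t", index=False)


def write_atlas(path, atlas: pd.DataFrame) -> None:
    atlas.to_csv(path, sep="\t", index=False)


def read_atlas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(path, truth: SyntheticTruth) -> None:
    payload = {
        "true_sleep_weights": truth.true_sleep_weights.tolist(),
        "true_bps_weights": truth.true_bps_weights.tolist(),
        "true_corrs": truth.true_corrs.tolist(),
        "true_subject_scores": truth.true_subject_scores.tolist(),
        "true_glm_betas": {f"{i},{j}": b for (i, j), b in truth.true_glm_betas.items()},
    }
    Path(path).write_text(json.dumps(payload))


def write_connectomes(
    path, conn: ConnectomeSet, container: str = "tsv-dir"
) -> None:
    """Store per-subject matrices.

    ``container='tsv-dir'`` writes one dense TSV per subject under a
    directory; ``container='hdf5'`` writes a single file with one dataset
    per subject plus the atlas as a table.
    """
    path = Path(path)
    ids = conn.subject_ids or [f"S{i:05d}" for i in range(conn.n_subjects)]
    if container == "tsv-dir":
        path.mkdir(parents=True, exist_ok=True)
        conn.atlas.to_csv(path / "atlas.tsv", sep="\t", index=False)
        for sid, mat in zip(ids, conn.matrices):
            np.savetxt(path / f"{sid}.tsv", mat, delimiter="\t")
    elif container == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            grp = f.create_group("connectomes")
            for sid, mat in zip(ids, conn.matrices):
                grp.create_dataset(str(sid), data=mat)
            f.attrs["subject_ids"] = [str(s) for s in ids]
            atlas_grp = f.create_group("atlas")
            for col in conn.atlas.columns:
                data = conn.atlas[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                atlas_grp.create_dataset(col, data=data)
    else:
        raise ValueError(f"unknown connectome container '{container}'")


def read_connectomes(path, container: str = "tsv-dir") -> ConnectomeSet:
    path = Path(path)
    if container == "tsv-dir":
        atlas = pd.read_csv(path / "atlas.tsv", sep="\t")
        files = sorted(p for p in path.glob("*.tsv") if p.name != "atlas.tsv")
        mats = np.stack([np.loadtxt(p, delimiter="\t") for p in files])
        ids = [p.stem for p in files]
    elif container == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            ids = [s for s in f.attrs["subject_ids"]]
            mats = np.stack([f["connectomes"][str(s)][...] for s in ids])
            cols = {}
            for col in f["atlas"]:
                data = f["atlas"][col][...]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            atlas = pd.DataFrame(cols)
    else:
        raise ValueError(f"unknown connectome container '{container}'")
    return ConnectomeSet(matrices=mats, atlas=atlas, subject_ids=ids)


def write_model(outdir, model: CCAModel, sleep_names, bps_names) -> None:
    """Serialize a fitted model: weights/loadings/scores as TSV, scalars in
    a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp_cols = [f"LC{i + 1}" for i in range(model.k)]
    pd.DataFrame(model.sleep_weights, index=sleep_names, columns=comp_cols).to_csv(
        outdir / "sleep_weights.tsv", sep="\t"
    )
    pd.DataFrame(model.bps_weights, index=bps_names, columns=comp_cols).to_csv(
        outdir / "bps_weights.tsv", sep="\t"
    )
    pd.DataFrame(model.sleep_scores, columns=comp_cols).to_csv(
        outdir / "sleep_scores.tsv", sep="\t", index=False
    )
    pd.DataFrame(model.bps_scores, columns=comp_cols).to_csv(
        outdir / "bps_scores.tsv", sep="\t", index=False
    )
    if model.sleep_loadings is not None:
        pd.DataFrame(
            model.sleep_loadings, index=sleep_names, columns=comp_cols
        ).to_csv(outdir / "sleep_loadings.tsv", sep="\t")
        pd.DataFrame(model.bps_loadings, index=bps_names, columns=comp_cols).to_csv(
            outdir / "bps_loadings.tsv", sep="\t"
        )
    manifest = {
        "k": model.k,
        "n_subjects": model.n_subjects,
        "canonical_corrs": model.canonical_corrs.tolist(),
        "singular_values": model.singular_values.tolist(),
        "explained_cov": (
            model.explained_cov.tolist() if model.explained_cov is not None else None
        ),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean.tolist(),
    }
    (outdir / "model.json").write_text(json.dumps(manifest, indent=2))
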