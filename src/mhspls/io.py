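"""Readers and writers: delimited text matrices, NIfTI views, run reports."""

from __future__ import annotations

import json
import logging

from pathlib import Path

import numpy as np
import pandas as pd

from .data import TwoViewDataset
from .framework import EffectRecord, FrameworkConfig
from .latent import LatentScores

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "load_two_view",
    "load_nifti_view",
    "load_region_labels",
    "save_weight_map",
    "save_results",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_matrix(path) -> pd.DataFrame:
    """Read a delimited matrix: header row of feature names, first column of
    sample identifiers; comma- or tab-separated by extension."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cells in the data matrix ({exc})") from exc
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: matrix contains NaN or infinite entries")
    return df


def write_matrix(path, X: np.ndarray, feature_names, sample_ids) -> Path:
    path = Path(path)
    pd.DataFrame(X, index=list(sample_ids), columns=list(feature_names)).to_csv(
        path, sep=_sep_for(path)
    )
    return path


def load_nifti_view(img_path, mask_path) -> tuple[np.ndarray, list[str], dict]:
    """Flatten a 4-D image stack through a 3-D mask into an n x p matrix.

    Returns the matrix, voxel names carrying the linear indices, and
    metadata (mask shape, affine, indices) sufficient to write weight maps
    back out as NIfTI volumes.
    """
    import nibabel as nib

    img = nib.load(str(img_path))
    vol = np.asarray(img.get_fdata())
    if vol.ndim != 4:
        raise ValueError(f"{img_path}: expected a 4-D image stack, got shape {vol.shape}")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.get_fdata()) > 0
    if mask.shape != vol.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image grid {vol.shape[:3]}"
        )
    X = vol[mask].T  # (n, p)
    indices = np.flatnonzero(mask.ravel())
    names = [f"vox_{i}" for i in indices]
    meta = {
        "mask_shape": mask.shape,
        "affine": np.asarray(img.affine),
        "indices": indices,
    }
    return X, names, meta


def load_region_labels(label_path, mask_path, names=None) -> list[str]:
    """Per-voxel region labels for the masked X view, from an integer-coded
    NIfTI label volume (e.g. an anatomical atlas resampled to the data grid).

    ``names`` optionally maps integer codes to region names (a dict, or a
    path to a two-column delimited file ``code,name``); unmapped or zero
    codes become the reserved "unlabeled" bucket. The returned list aligns
    with the columns produced by :func:`load_nifti_view` for the same mask.
    """
    import nibabel as nib

    labels_vol = np.asarray(nib.load(str(label_path)).get_fdata())
    mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    if labels_vol.shape != mask.shape:
        raise ValueError(
            f"label volume shape {labels_vol.shape} does not match mask {mask.shape}"
        )
    codes = np.rint(labels_vol[mask]).astype(int)
    lookup: dict[int, str] = {}
    if isinstance(names, (str, Path)):
        tab = pd.read_csv(names, header=None, names=["code", "name"])
        lookup = dict(zip(tab["code"].astype(int), tab["name"].astype(str)))
    elif names is not None:
        lookup = {int(k): str(v) for k, v in names.items()}
    out = []
    for code in codes:
        if code == 0:
            out.append("unlabeled")
        elif lookup:
            out.append(lookup.get(code, "unlabeled"))
        else:
            out.append(f"region_{code}")
    return out


def save_weight_map(u: np.ndarray, x_meta: dict, path) -> Path:
    """Write an X-view weight vector back into the masked 3-D grid as NIfTI."""
    import nibabel as nib

    vol = np.zeros(int(np.prod(x_meta["mask_shape"])))
    vol[x_meta["indices"]] = u
    img = nib.Nifti1Image(
        vol.reshape(x_meta["mask_shape"]).astype(np.float32), x_meta["affine"]
    )
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_two_view(path_x, path_y, format: str = "delim", mask=None) -> TwoViewDataset:
    """Load a paired dataset from delimited text, or NIfTI (X) + text (Y).

    Rows are aligned by order with an identifier cross-check: mismatched
    sample identifiers are an error, never silently reordered.
    """
    if format == "delim":
        dx = read_matrix(path_x)
        dy = read_matrix(path_y)
        if dx.shape[0] != dy.shape[0]:
            raise ValueError(
                f"row-count mismatch: {path_x} has {dx.shape[0]} samples, "
                f"{path_y} has {dy.shape[0]}"
            )
        if list(map(str, dx.index)) != list(map(str, dy.index)):
            raise ValueError("sample identifiers of the two views do not match")
        return TwoViewDataset(
            X=dx.to_numpy(dtype=float),
            Y=dy.to_numpy(dtype=float),
            x_names=list(dx.columns),
            y_names=list(dy.columns),
            sample_ids=list(map(str, dx.index)),
        )
    if format == "nifti":
        if mask is None:
            raise ValueError("format='nifti' requires a mask path")
        X, x_names, meta = load_nifti_view(path_x, mask)
        dy = read_matrix(path_y)
        if X.shape[0] != dy.shape[0]:
            raise ValueError(
                f"row-count mismatch: image stack has {X.shape[0]} volumes, "
                f"{path_y} has {dy.shape[0]} rows"
            )
        return TwoViewDataset(
            X=X,
            Y=dy.to_numpy(dtype=float),
            x_names=x_names,
            y_names=list(dy.columns),
            sample_ids=list(map(str, dy.index)),
            x_meta=meta,
        )
    raise ValueError(f"unknown format {format!r}")


def _effect_report(rec: EffectRecord) -> dict:
    per_split = []
    for s, sr in enumerate(rec.per_split):
        entry = {
            "split": s + 1,
            "p_value": sr.outcome.p_value,
            "holdout_correlation": sr.outcome.rho,
            "B": sr.outcome.B,
            "n_iter": sr.pair.n_iter,
            "converged": bool(sr.pair.converged),
        }
        if sr.grid_result is not None:
            entry["selected_c_u"] = sr.grid_result.selected.c_u
            entry["selected_c_v"] = sr.grid_result.selected.c_v
        per_split.append(entry)
    return {
        "effect": rec.effect_index,
        "omnibus_rejected": bool(rec.omnibus_rejected),
        "alpha": rec.alpha,
        "selected_split": None if rec.selected_split is None else rec.selected_split + 1,
        "per_split": per_split,
    }


def save_results(
    records: list[EffectRecord],
    data: TwoViewDataset,
    outdir,
    config: FrameworkConfig | None = None,
    scores: LatentScores | None = None,
    region_summaries: dict[int, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write weights, p-value tables, latent scores and a run report.

    The p-value table mirrors the usual presentation (one row per hold-out
    split, one column per effect, rounded to 4 decimal places); the JSON
    report keeps full precision. Weight vectors of selected pairs go to one
    delimited file per view and effect, plus NIfTI weight maps when the X
    view carries imaging metadata.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ptab = pd.DataFrame(
        {f"effect_{rec.effect_index}": np.round(rec.p_values, 4) for rec in records},
        index=[f"split_{s + 1}" for s in range(len(records[0].per_split))] if records else [],
    )
    paths["p_values"] = outdir / "p_values.csv"
    ptab.to_csv(paths["p_values"])
    rtab = pd.DataFrame(
        {f"effect_{rec.effect_index}": rec.holdout_correlations for rec in records},
        index=ptab.index,
    )
    paths["holdout_correlations"] = outdir / "holdout_correlations.csv"
    rtab.to_csv(paths["holdout_correlations"])

    for rec in records:
        if rec.selected_pair is None:
            continue
        h = rec.effect_index
        pu = outdir / f"effect_{h}_weights_u.csv"
        pv = outdir / f"effect_{h}_weights_v.csv"
        pd.Series(rec.selected_pair.u, index=data.x_names, name="weight").to_csv(
            pu, index_label="feature"
        )
        pd.Series(rec.selected_pair.v, index=data.y_names, name="weight").to_csv(
            pv, index_label="feature"
        )
        paths[f"effect_{h}_weights_u"] = pu
        paths[f"effect_{h}_weights_v"] = pv
        if data.x_meta is not None:
            pm = outdir / f"effect_{h}_weights_u.nii.gz"
            save_weight_map(rec.selected_pair.u, data.x_meta, pm)
            paths[f"effect_{h}_weight_map"] = pm

    if scores is not None:
        ids = scores.sample_ids or [f"s{i}" for i in range(scores.xi.shape[0])]
        sdf = pd.DataFrame(index=ids)
        for j, lab in enumerate(scores.effect_labels):
            sdf[f"xi_{lab}"] = scores.xi[:, j]
            sdf[f"omega_{lab}"] = scores.omega[:, j]
        paths["latent_scores"] = outdir / "latent_scores.csv"
        sdf.to_csv(paths["latent_scores"], index_label="sample")

    if region_summaries:
        for h, summary in region_summaries.items():
            ph = outdir / f"effect_{h}_regions.csv"
            summary.to_csv(ph, index=False)
            paths[f"effect_{h}_regions"] = ph

    report = {
        "config": None if config is None else config.to_dict(),
        "n_samples": data.n,
        "p": data.p,
        "q": data.q,
        "effects": [_effect_report(rec) for rec in records],
    }
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2))
    logger.info("results written to %s", outdir)
    return paths
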