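"""NIfTI ingestion, result export, and HDF5 checkpointing.

Images are flattened to the internal images x voxels matrix with a
voxel x D world-coordinate table taken from the NIfTI affine; the grid
shape and affine are carried along so reconstructions can be written back
to the original grid.  Synthetic bundles round-trip through the same path
(4-D image + binary mask + ground-truth TSVs), so every pipeline stage can
be exercised without external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .model import ImageDataset, reconstruct
from .networks import NetworkResult, threshold_network
from .variational import FitConfig, VariationalState

__all__ = [
    "load_dataset",
    "save_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "save_results",
    "sources_table",
]


def load_dataset(image_path, mask_path=None) -> ImageDataset:
    """Flatten a 4-D NIfTI series (plus optional 3-D mask) for analysis.

    Voxels with mask > 0 are retained; coordinates are world-space positions
    from the image affine; the time axis becomes the image (row) axis.
    """
    img = nib.load(str(image_path))
    vol = np.asarray(img.get_fdata(), dtype=float)
    if vol.ndim == 3:
        vol = vol[..., None]
    if vol.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {vol.shape}")
    grid_shape = vol.shape[:3]
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.get_fdata()) > 0
        if mask.shape != grid_shape:
            raise ValueError(
                f"mask grid {mask.shape} does not match image grid {grid_shape}"
            )
    else:
        mask = np.ones(grid_shape, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("mask contains no voxels")

    ijk = np.argwhere(mask)  # (V, 3) in C order
    affine = np.asarray(img.affine, dtype=float)
    coords = nib.affines.apply_affine(affine, ijk)
    activations = vol[mask].T  # (T, V): mask indexing yields (V, T)
    return ImageDataset(
        activations=activations,
        coords=coords,
        mask_shape=grid_shape,
        affine=affine,
        provenance={
            "image_path": str(image_path),
            "mask_path": None if mask_path is None else str(mask_path),
            "n_mask_voxels": n_vox,
        },
    )


def _grid_geometry(data: ImageDataset):
    """(shape, affine, ijk) for writing voxel data back onto a 3-D grid."""
    coords = data.coords
    d = coords.shape[1]
    if data.mask_shape is not None and data.affine is not None and d == 3:
        affine = np.asarray(data.affine, dtype=float)
        inv = np.linalg.inv(affine)
        ijk = np.rint(nib.affines.apply_affine(inv, coords)).astype(int)
        shape = tuple(int(s) for s in data.mask_shape)
        return shape, affine, ijk
    # infer an integer grid from the coordinates (synthetic datasets)
    mins = coords.min(axis=0)
    spacing = np.ones(d)
    for j in range(d):
        vals = np.unique(coords[:, j])
        if vals.size > 1:
            spacing[j] = np.diff(vals).min()
    ijk = np.rint((coords - mins) / spacing).astype(int)
    shape3 = np.ones(3, dtype=int)
    shape3[:d] = ijk.max(axis=0) + 1
    if d < 3:
        ijk = np.column_stack([ijk, np.zeros((len(ijk), 3 - d), dtype=int)])
    affine = np.eye(4)
    for j in range(d):
        affine[j, j] = spacing[j]
        affine[j, 3] = mins[j]
    return tuple(shape3), affine, ijk


def _volume_from_rows(rows: np.ndarray, shape, ijk) -> np.ndarray:
    vol = np.zeros(shape + (rows.shape[0],))
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :] = rows.T
    return vol


def save_dataset(data: ImageDataset, image_path, mask_path=None) -> None:
    """Write an ImageDataset as a 4-D NIfTI (and optional binary mask)."""
    shape, affine, ijk = _grid_geometry(data)
    vol = _volume_from_rows(data.activations, shape, ijk)
    nib.save(nib.Nifti1Image(vol, affine), str(image_path))
    if mask_path is not None:
        mask = np.zeros(shape, dtype=np.uint8)
        mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = 1
        nib.save(nib.Nifti1Image(mask, affine), str(mask_path))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

_STATE_FIELDS = (
    "weight_mean",
    "weight_log_precision",
    "center_mean",
    "center_log_precision",
    "width_mean",
    "width_log_precision",
)


def save_checkpoint(
    path,
    state: VariationalState,
    config: Optional[FitConfig] = None,
    elbo_trace=None,
) -> None:
    """Exact round-trip store of the variational state (HDF5)."""
    with h5py.File(str(path), "w") as f:
        grp = f.create_group("state")
        for name in _STATE_FIELDS:
            grp.create_dataset(name, data=getattr(state, name))
        acc = f.create_group("grad_sq")
        for name, arr in state.grad_sq.items():
            acc.create_dataset(name, data=arr)
        f.attrs["iteration"] = state.iteration
        f.attrs["tfa_version"] = __version__
        if config is not None:
            f.attrs["config_json"] = json.dumps(asdict(config))
        if elbo_trace is not None:
            f.create_dataset("elbo_trace", data=np.asarray(elbo_trace, dtype=float))


def load_checkpoint(path):
    """Load a checkpoint; returns (state, config_or_None, elbo_trace)."""
    with h5py.File(str(path), "r") as f:
        fields = {name: f["state"][name][()] for name in _STATE_FIELDS}
        grad_sq = {name: f["grad_sq"][name][()] for name in f["grad_sq"]}
        state = VariationalState(**fields, grad_sq=grad_sq, iteration=int(f.attrs["iteration"]))
        config = None
        if "config_json" in f.attrs:
            config = FitConfig(**json.loads(f.attrs["config_json"]))
        trace = f["elbo_trace"][()] if "elbo_trace" in f else np.empty(0)
    return state, config, trace


# ---------------------------------------------------------------------------
# Result export
# ---------------------------------------------------------------------------

def sources_table(state: VariationalState) -> pd.DataFrame:
    """Tidy per-source table: center coordinates, log width, expected width."""
    d = state.n_dims
    cols = {"source": np.arange(state.n_sources)}
    for j, axis in enumerate("xyz"[:d]):
        cols[axis] = state.center_mean[:, j]
    cols["log_width"] = state.width_mean
    cols["width"] = np.exp(state.width_mean)
    return pd.DataFrame(cols)


def save_results(
    out_dir,
    state: VariationalState,
    data: ImageDataset,
    config: Optional[FitConfig] = None,
    elbo_trace=None,
    network: Optional[NetworkResult] = None,
    seed=None,
) -> dict:
    """Write the standard result file set; returns {name: path}.

    Produces a source table TSV, the weight matrix TSV, a reconstruction
    NIfTI on the input grid, network TSVs (matrix, edge list, node table)
    when a network is given, an HDF5 checkpoint, and a JSON run manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    table = sources_table(state)
    files["sources"] = out / "sources.tsv"
    table.to_csv(files["sources"], sep="\t", index=False)

    files["weights"] = out / "weights.tsv"
    pd.DataFrame(
        state.weight_mean, columns=[f"source_{k}" for k in range(state.n_sources)]
    ).to_csv(files["weights"], sep="\t", index=False)

    recon = reconstruct(state.point_sources(), state.weight_mean, data.coords)
    files["reconstruction"] = out / "reconstruction.nii.gz"
    recon_data = ImageDataset(
        activations=recon, coords=data.coords,
        mask_shape=data.mask_shape, affine=data.affine,
    )
    save_dataset(recon_data, files["reconstruction"])

    if network is not None:
        files["network_matrix"] = out / "network_matrix.tsv"
        pd.DataFrame(network.interaction).to_csv(
            files["network_matrix"], sep="\t", index=False, header=False
        )
        files["network_edges"] = out / "network_edges.tsv"
        threshold_network(network, 0.0).to_csv(
            files["network_edges"], sep="\t", index=False
        )
        files["network_nodes"] = out / "network_nodes.tsv"
        table.to_csv(files["network_nodes"], sep="\t", index=False)

    files["checkpoint"] = out / "checkpoint.h5"
    save_checkpoint(files["checkpoint"], state, config=config, elbo_trace=elbo_trace)

    manifest = {
        "tfa_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": asdict(config) if config is not None else None,
        "n_images": data.n_images,
        "n_voxels": data.n_voxels,
        "elbo_trace": list(map(float, elbo_trace)) if elbo_trace is not None else None,
        "provenance": data.provenance,
    }
    files["manifest"] = out / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2))
    return files
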