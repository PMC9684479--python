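"""Serialization: CSV for signals/densities, HDF5 for offline bases and
basis banks, NIfTI (+ JSON sidecar) for multi-echo image stacks."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .algorithm import BasisBank, OfflineBasis
from .core import DistributionFunction, Signal, T2Grid, TimeGrid
from .dictionary import GaussianDictionary
from .solvers import LambdaLadder

__all__ = [
    "save_signal_csv",
    "load_signal_csv",
    "save_df_csv",
    "load_df_csv",
    "save_basis",
    "load_basis",
    "save_basis_bank",
    "load_basis_bank",
    "save_stack_nifti",
    "load_stack_nifti",
]


def save_signal_csv(path: str | Path, y: Signal) -> None:
    np.savetxt(
        path,
        np.column_stack([y.time_grid.times, y.values]),
        delimiter=",",
        header="time_ms,value",
        comments="",
    )


def load_signal_csv(path: str | Path) -> Signal:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return Signal(arr[:, 1], TimeGrid(arr[:, 0]))


def save_df_csv(path: str | Path, f: DistributionFunction) -> None:
    np.savetxt(
        path,
        np.column_stack([f.grid.values, f.weights]),
        delimiter=",",
        header="t2_ms,density",
        comments="",
    )


def load_df_csv(path: str | Path) -> DistributionFunction:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return DistributionFunction(arr[:, 1], T2Grid(arr[:, 0]))


def _write_basis_group(grp: h5py.Group, basis: OfflineBasis) -> None:
    grp.create_dataset("g_bar", data=basis.g_bar, compression="gzip")
    grp.create_dataset("beta_bar", data=basis.beta_bar)
    grp.create_dataset("ladder", data=basis.ladder.values)
    grp.create_dataset("t2grid", data=basis.dictionary.grid.values)
    grp.create_dataset("dict_matrix", data=basis.dictionary.matrix, compression="gzip")
    grp.create_dataset("dict_mus", data=basis.dictionary.mus)
    grp.create_dataset("dict_sds", data=basis.dictionary.sds)
    grp.attrs["sigma"] = basis.sigma
    grp.attrs["n_run"] = basis.n_run
    grp.attrs["seed"] = -1 if basis.seed is None else basis.seed


def _read_basis_group(grp: h5py.Group) -> OfflineBasis:
    grid = T2Grid(grp["t2grid"][()])
    dictionary = GaussianDictionary(
        matrix=grp["dict_matrix"][()],
        mus=grp["dict_mus"][()],
        sds=grp["dict_sds"][()],
        grid=grid,
    )
    seed = int(grp.attrs["seed"])
    return OfflineBasis(
        g_bar=grp["g_bar"][()],
        beta_bar=grp["beta_bar"][()],
        sigma=float(grp.attrs["sigma"]),
        n_run=int(grp.attrs["n_run"]),
        ladder=LambdaLadder(grp["ladder"][()]),
        dictionary=dictionary,
        seed=None if seed < 0 else seed,
    )


def save_basis(path: str | Path, basis: OfflineBasis) -> None:
    with h5py.File(path, "w") as h5:
        _write_basis_group(h5, basis)


def load_basis(path: str | Path) -> OfflineBasis:
    with h5py.File(path, "r") as h5:
        return _read_basis_group(h5)


def save_basis_bank(path: str | Path, bank: BasisBank) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("bin_centers", data=bank.bin_centers)
        for k, basis in enumerate(bank.bases):
            _write_basis_group(h5.create_group(f"bin{k:03d}"), basis)


def load_basis_bank(path: str | Path) -> BasisBank:
    with h5py.File(path, "r") as h5:
        centers = h5["bin_centers"][()]
        bases = tuple(
            _read_basis_group(h5[f"bin{k:03d}"]) for k in range(len(centers))
        )
    return BasisBank(centers, bases)


def save_stack_nifti(path: str | Path, data: np.ndarray, echo_times: np.ndarray,
                     sidecar: str | Path | None = None) -> None:
    """Write a rows x cols x echoes stack as 4D NIfTI (singleton z axis)
    with the TE vector in a JSON sidecar."""
    import nibabel as nib

    img = nib.Nifti1Image(data[:, :, None, :].astype(np.float32), np.eye(4))
    nib.save(img, str(path))
    if sidecar is None:
        sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
        sidecar = Path(str(sidecar) + ".json")
    Path(sidecar).write_text(json.dumps({"EchoTimesMs": list(map(float, echo_times))}))


def load_stack_nifti(path: str | Path, sidecar: str | Path):
    """Read a 4D NIfTI stack plus its TE sidecar; returns (data, echo_times)
    with the z axis flattened into extra rows when present."""
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim == 4:
        x, y, z, e = arr.shape
        arr = arr.transpose(0, 2, 1, 3).reshape(x * z, y, e)
    tes = np.asarray(json.loads(Path(sidecar).read_text())["EchoTimesMs"], dtype=float)
    return arr, tes
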