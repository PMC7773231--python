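"""File formats: TIFF stacks with JSON sidecars, CSV transients, map export.

The interchange dialect is deliberately open and simple: a FLIM stack is a
multi-page TIFF with time as the page axis (uint16 when counts allow, float32
otherwise) plus a JSON sidecar carrying the time axis (``n_bins``,
``bin_width_ns``, ``origin_ns``); a single transient (or IRF) is a two-column
CSV ``time_ns,counts`` with the times at bin centers; parameter maps are one
float32 single-page TIFF per parameter plus a JSON manifest.  Vendor TCSPC
formats (.sdt, PicoQuant, .ics) are not parsed — convert upstream.

All writes are atomic: data goes to a temporary file in the destination
directory which is then renamed into place.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .core import DataError, DecayCurve, FLIMImage, IRF, TimeGrid

_SIDE_SUFFIX = ".json"


def _sidecar_path(path_tiff) -> Path:
    return Path(str(path_tiff) + _SIDE_SUFFIX)


def _atomic_bytes(path: Path, writer) -> None:
    """Write via temp file + rename so readers never see a partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_tiff(path: Path, array: np.ndarray) -> None:
    """Atomic TIFF write (tifffile needs a named path, not a raw handle)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(
        dir=path.parent, prefix=f".{path.name}.", suffix=".tif"
    )
    os.close(fd)
    try:
        # explicit photometric so 3-page stacks are never stored as RGB
        tifffile.imwrite(tmp, array, photometric="minisblack")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_flim_stack(
    image: FLIMImage, path_tiff, path_sidecar=None
) -> tuple[Path, Path]:
    """Write a count stack as a multi-page TIFF plus a JSON sidecar."""
    path_tiff = Path(path_tiff)
    if path_sidecar is None:
        path_sidecar = _sidecar_path(path_tiff)
    counts = image.counts
    if np.all(counts == np.round(counts)) and counts.max(initial=0) < 2**16:
        data = counts.astype(np.uint16)
    else:
        data = counts.astype(np.float32)
    _atomic_tiff(path_tiff, data)
    side = {
        "n_bins": image.grid.n_bins,
        "bin_width_ns": image.grid.bin_width_ns,
        "origin_ns": image.grid.origin_ns,
    }
    _atomic_bytes(
        Path(path_sidecar),
        lambda fh: fh.write(json.dumps(side, indent=1).encode()),
    )
    return path_tiff, Path(path_sidecar)


def read_flim_stack(path_tiff, path_sidecar=None) -> FLIMImage:
    """Read a multi-page TIFF + sidecar back into a :class:`FLIMImage`."""
    path_tiff = Path(path_tiff)
    if path_sidecar is None:
        path_sidecar = _sidecar_path(path_tiff)
    with open(path_sidecar) as fh:
        side = json.load(fh)
    stack = tifffile.imread(path_tiff)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise DataError(f"expected a 3-D stack in {path_tiff}, got shape {stack.shape}")
    n_pages = stack.shape[0]
    if side["n_bins"] != n_pages:
        raise DataError(
            f"sidecar n_bins={side['n_bins']} but TIFF has {n_pages} pages"
        )
    grid = TimeGrid(
        n_bins=int(side["n_bins"]),
        bin_width_ns=float(side["bin_width_ns"]),
        origin_ns=float(side.get("origin_ns", 0.0)),
    )
    return FLIMImage(grid, stack.astype(float))


def _read_two_columns(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataError(f"{path}: need two columns (time_ns, counts)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 3:
        raise DataError(f"{path}: need at least 3 rows")
    return t, y


def _grid_from_times(t: np.ndarray, where: str) -> TimeGrid:
    """Infer a uniform bin-center time axis; reject drifting spacing."""
    dt = np.diff(t)
    step = float(np.mean(dt))
    if step <= 0 or np.any(np.abs(dt - step) > 1e-6 * abs(step)):
        raise DataError(f"{where}: time spacing is not uniform (tolerance 1e-6)")
    return TimeGrid(n_bins=t.size, bin_width_ns=step, origin_ns=float(t[0]) - step / 2)


def read_transient_csv(path) -> DecayCurve:
    """Two-column CSV (time_ns at bin centers, counts) -> DecayCurve."""
    t, y = _read_two_columns(path)
    return DecayCurve(_grid_from_times(t, str(path)), y)


def read_irf_csv(path) -> IRF:
    t, y = _read_two_columns(path)
    return IRF(_grid_from_times(t, str(path)), y)


def write_transient_csv(curve: DecayCurve, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"time_ns": curve.grid.bin_centers(), "counts": curve.counts}
    )
    _atomic_bytes(path, lambda fh: fh.write(df.to_csv(index=False).encode()))
    return path


def write_param_maps(maps, directory, extra_meta: Optional[dict] = None) -> Path:
    """Write each parameter map as a float32 TIFF plus a JSON manifest.

    ``maps`` is an :class:`~flimkit.imagefit.ParamMaps`; the manifest lists
    the parameter names, files, method and fit configuration.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    extra_maps = (("intensity", maps.intensity), ("valid_mask", maps.mask))
    for name, arr in list(maps.maps.items()) + list(extra_maps):
        fname = f"{name}.tif"
        _atomic_tiff(directory / fname, np.asarray(arr, dtype=np.float32))
        files[name] = fname
    manifest = {
        "parameters": list(maps.maps),
        "method": maps.method,
        "shape": list(maps.shape),
        "files": files,
        "config": maps.meta,
    }
    if extra_meta:
        manifest["extra"] = extra_meta
    mpath = directory / "manifest.json"
    _atomic_bytes(mpath, lambda fh: fh.write(json.dumps(manifest, indent=1).encode()))
    return mpath
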