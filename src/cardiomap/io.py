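"""Reading deposited movie containers and settings files; writing maps.

Movies are distributed as MAT containers, one experiment per folder, with
plain-text "suggested settings" files alongside.  MAT v5/v7 files are read
through :func:`scipy.io.loadmat`; v7.3 containers are HDF5 and are read
with h5py.  Acquisition metadata (frame rate, pixel size) is never guessed
from the file — it comes from the dataset profile or explicit config.

Maps are written as headerless CSV ('.' decimal, ',' separator, ``NaN``
for undefined pixels) so that re-reading reproduces in-mask values
bit-exactly, plus a rendered PNG with a colour bar for quick inspection.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import scipy.io

from .config import KEY_REGISTRY
from .containers import (
    FluorescenceMovie,
    ScalarMap,
    SettingsOverrides,
    VectorMap,
)

DIM_ORDERS = ("row_col_frame", "frame_row_col")


class MovieFormatError(ValueError):
    """Raised when a container holds no usable 3-D numeric variable."""


def _candidate_arrays_matv5(path: Path) -> dict[str, np.ndarray]:
    raw = scipy.io.loadmat(str(path), squeeze_me=False)
    return {
        k: np.asarray(v)
        for k, v in raw.items()
        if not k.startswith("__") and isinstance(v, np.ndarray)
        and v.ndim == 3 and np.issubdtype(v.dtype, np.number)
    }


def _candidate_arrays_hdf5(path: Path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset) and obj.ndim == 3 and \
                    np.issubdtype(obj.dtype, np.number):
                # MATLAB writes arrays to HDF5 in reversed (C-order) layout;
                # transpose back to the MATLAB on-disk index order.
                out[name] = np.asarray(obj).transpose(2, 1, 0)
        f.visititems(visit)
    return out


def load_mat_movie(
    path,
    frame_rate: float = 1000.0,
    pixel_size: float = 1.0,
    polarity: str = "inverted_voltage",
    dim_order: str = "row_col_frame",
    variable: Optional[str] = None,
    label: str = "",
) -> FluorescenceMovie:
    """Load a fluorescence movie from a MAT v5/v7 or v7.3 (HDF5) container.

    The first 3-D numeric variable is used, ties broken by largest element
    count; ``variable`` overrides the choice explicitly.  ``dim_order``
    states how the stack is laid out on disk and defaults to the image-stack
    convention ``(row, col, frame)``.
    """
    path = Path(path)
    if dim_order not in DIM_ORDERS:
        raise ValueError(f"dim_order must be one of {DIM_ORDERS}")
    try:
        if h5py.is_hdf5(path):
            arrays = _candidate_arrays_hdf5(path)
        else:
            arrays = _candidate_arrays_matv5(path)
    except OSError as exc:
        raise OSError(f"cannot read MAT container {path}: {exc}") from exc

    if variable is not None:
        if variable not in arrays:
            raise MovieFormatError(
                f"{path}: variable {variable!r} not found among 3-D numeric "
                f"variables {sorted(arrays)}"
            )
        data = arrays[variable]
    else:
        if not arrays:
            names = _all_variable_names(path)
            raise MovieFormatError(
                f"{path}: no 3-D numeric variable found; variables present: "
                f"{names}"
            )
        # insertion order is file order; max() keeps the first on ties
        data = max(arrays.values(), key=lambda a: a.size)

    if dim_order == "row_col_frame":
        data = np.moveaxis(data, 2, 0)
    return FluorescenceMovie(
        data=np.ascontiguousarray(data, dtype=float),
        frame_rate=frame_rate,
        pixel_size=pixel_size,
        polarity=polarity,
        label=label or path.stem,
    )


def _all_variable_names(path: Path) -> list[str]:
    try:
        if h5py.is_hdf5(path):
            names: list[str] = []
            with h5py.File(path, "r") as f:
                f.visit(names.append)
            return names
        return [k for k in scipy.io.loadmat(str(path)) if not k.startswith("__")]
    except Exception:
        return []


def save_mat_movie(movie: FluorescenceMovie, path, variable: str = "movie",
                   dim_order: str = "row_col_frame") -> None:
    """Write a movie to a MAT v5 container so it round-trips via
    :func:`load_mat_movie` with the same ``dim_order``."""
    if dim_order not in DIM_ORDERS:
        raise ValueError(f"dim_order must be one of {DIM_ORDERS}")
    data = movie.data
    if dim_order == "row_col_frame":
        data = np.moveaxis(data, 0, 2)
    scipy.io.savemat(str(path), {variable: data})


def load_settings(path) -> SettingsOverrides:
    """Parse a plain-text settings file of ``key = value`` / ``key: value``
    lines ('#' starts a comment) against the pipeline key registry.

    Recognised keys are returned typed; unknown keys are listed in
    ``unknown`` and reported with a warning, never silently dropped.
    """
    path = Path(path)
    values: dict = {}
    unknown: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, val = line.partition(sep)
                break
        else:
            raise ValueError(f"{path}:{lineno}: cannot parse line {raw!r}")
        key, val = key.strip(), val.strip()
        if not key or not val:
            raise ValueError(f"{path}:{lineno}: cannot parse line {raw!r}")
        if key in KEY_REGISTRY:
            field, parser = KEY_REGISTRY[key]
            try:
                values[field] = parser(val)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad value for {key!r}: {exc}"
                ) from exc
        else:
            unknown.append(key)
    if unknown:
        warnings.warn(
            f"{path}: unrecognised settings keys ignored: {', '.join(unknown)}",
            stacklevel=2,
        )
    return SettingsOverrides(values=values, unknown=unknown)


def write_scalar_map(smap: ScalarMap, path, header: bool = False,
                     image: bool = True) -> None:
    """Write a scalar map as headerless CSV (NaN for undefined pixels) and,
    optionally, a rendered PNG alongside with a colour bar."""
    path = Path(path)
    rows = []
    for row in smap.values:
        rows.append(",".join("NaN" if not np.isfinite(v) else repr(float(v))
                             for v in row))
    text = ""
    if header:
        text += f"# kind={smap.kind} units={smap.units}\n"
    text += "\n".join(rows) + "\n"
    path.write_text(text)
    if image:
        _render_map(smap.values, path.with_suffix(".png"),
                    f"{smap.kind} [{smap.units}]" if smap.units else smap.kind)


def read_scalar_map(path, kind: str = "apd_ms", units: str = "") -> ScalarMap:
    """Read a CSV written by :func:`write_scalar_map` back into a ScalarMap."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln and not ln.startswith("#")]
    values = np.array([[float(v) for v in ln.split(",")] for ln in lines])
    return ScalarMap(values=values, mask=np.isfinite(values), kind=kind,
                     units=units)


def write_vector_map(vmap: VectorMap, out_prefix, image: bool = True) -> None:
    """Write a velocity field as three CSVs (vx, vy, speed) and a quiver
    overlay image ``<prefix>_quiver.png``."""
    out_prefix = Path(out_prefix)
    for name, comp in (("vx", vmap.vx), ("vy", vmap.vy), ("speed", vmap.speed)):
        arr = np.where(vmap.defined, comp, np.nan)
        lines = [",".join("NaN" if not np.isfinite(v) else repr(float(v))
                          for v in row) for row in arr]
        Path(f"{out_prefix}_{name}.csv").write_text("\n".join(lines) + "\n")
    if image:
        _render_quiver(vmap, Path(f"{out_prefix}_quiver.png"))


def _render_map(values: np.ndarray, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(values, interpolation="nearest")
    fig.colorbar(im, ax=ax)
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _render_quiver(vmap: VectorMap, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.6))
    im = ax.imshow(np.where(vmap.defined, vmap.speed, np.nan),
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label="speed [cm/s]")
    step = max(1, vmap.speed.shape[0] // 16)
    yy, xx = np.mgrid[0:vmap.speed.shape[0]:step, 0:vmap.speed.shape[1]:step]
    u = vmap.vx[::step, ::step]
    v = vmap.vy[::step, ::step]
    ax.quiver(xx, yy, u, v, color="white", scale_units="xy", width=0.004)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
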