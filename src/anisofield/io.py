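"""File formats, configuration loading, seeding and run manifests.

Conventions: CSV/TSV are for inspection (UTF-8, '.' decimal, mandatory
header, a ``time`` column plus one ``node_x_y`` column per grid node); NPZ
is the lossless interchange format. Movies travel as multi-page TIFF (with
the frame interval supplied separately) or as NPZ/HDF5 with documented
keys. Posteriors, comparisons and manifests are JSON. Every CLI run writes
exactly one manifest alongside its outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from anisofield import __version__
from anisofield.exceptions import FormatError
from anisofield.mapping import BetaMap, Movie

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_movie",
    "write_movie",
    "read_beta_map",
    "write_beta_map",
    "load_config",
    "config_hash",
    "RunManifest",
]


def _parse_node_columns(columns, path):
    coords = []
    for c in columns:
        parts = c.split("_")
        if len(parts) != 3 or parts[0] != "node":
            raise FormatError(f"{path}: malformed node column {c!r} (want node_x_y)")
        try:
            coords.append((int(parts[1]), int(parts[2])))
        except ValueError as err:
            raise FormatError(f"{path}: non-integer node coordinates in {c!r}") from err
    return coords


def read_timeseries(path):
    """Read a wide timeseries (CSV/TSV/NPZ).

    Returns ``(frame, coords)``: a DataFrame with ``time`` plus node
    columns, and the parsed ``(x, y)`` coordinate per node column.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            for key in ("times", "values", "coords"):
                if key not in z:
                    raise FormatError(f"{path}: NPZ missing key {key!r}")
            times, values, coords = z["times"], z["values"], z["coords"]
        coords = [tuple(map(int, c)) for c in coords]
        df = pd.DataFrame(values, columns=[f"node_{x}_{y}" for x, y in coords])
        df.insert(0, "time", times)
    else:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.ParserError as err:
            raise FormatError(f"{path}: ragged or unparseable rows ({err})") from err
        if "time" not in df.columns:
            raise FormatError(f"{path}: missing 'time' column")
        coords = _parse_node_columns(
            [c for c in df.columns if c != "time"], path
        )
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows (missing values)")
    t = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    return df, coords


def write_timeseries(path, frame: pd.DataFrame) -> None:
    """Write a wide timeseries; format chosen by suffix (.csv/.tsv/.npz)."""
    path = Path(path)
    if "time" not in frame.columns:
        raise ValueError("timeseries frame needs a 'time' column")
    node_cols = [c for c in frame.columns if c != "time"]
    if path.suffix == ".npz":
        coords = np.array(_parse_node_columns(node_cols, path))
        np.savez(
            path,
            times=frame["time"].to_numpy(dtype=float),
            values=frame[node_cols].to_numpy(dtype=float),
            coords=coords,
        )
    else:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
        frame.to_csv(path, sep=sep, index=False)


def write_movie(path, movie: Movie) -> None:
    """Write a movie; format chosen by suffix (.tif/.tiff, .npz, .h5/.hdf5).

    TIFF holds only the frames; mask, dt and labels go to a JSON sidecar
    ``<path>.meta.json``. NPZ/HDF5 carry everything in one file.
    """
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.data.astype(np.float32),
                         photometric="minisblack")
        meta = {"dt": movie.dt, "labels": movie.labels,
                "mask": movie.mask.astype(int).tolist()}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))
    elif path.suffix == ".npz":
        np.savez(
            path,
            data=movie.data,
            mask=movie.mask,
            dt=np.array(movie.dt),
            labels=np.frombuffer(
                json.dumps(movie.labels).encode(), dtype=np.uint8
            ),
        )
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=movie.data)
            f.create_dataset("mask", data=movie.mask)
            f.attrs["dt"] = movie.dt
            f.attrs["labels"] = json.dumps(movie.labels)
    else:
        raise ValueError(f"unsupported movie format: {path.suffix!r}")


def read_movie(path, mask_path=None, dt: float | None = None) -> Movie:
    """Read a movie from multi-page TIFF, NPZ or HDF5.

    For TIFF, ``dt`` must come from the ``.meta.json`` sidecar or the
    ``dt`` argument -- never a silent default. ``mask_path`` (TIFF/NPY)
    overrides any stored mask.
    """
    path = Path(path)
    labels: dict = {}
    mask = None
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        sidecar = Path(str(path) + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            dt = dt if dt is not None else meta.get("dt")
            labels = meta.get("labels", {})
            if meta.get("mask") is not None:
                mask = np.asarray(meta["mask"], dtype=bool)
        if dt is None:
            raise FormatError(
                f"{path}: no frame interval; supply dt explicitly or provide "
                "a .meta.json sidecar"
            )
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            if "data" not in z:
                raise FormatError(f"{path}: NPZ missing key 'data'")
            data = z["data"]
            mask = z["mask"] if "mask" in z else None
            if dt is None:
                if "dt" not in z:
                    raise FormatError(f"{path}: no frame interval stored; supply dt")
                dt = float(z["dt"])
            if "labels" in z:
                labels = json.loads(bytes(z["labels"]).decode())
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            mask = f["mask"][()] if "mask" in f else None
            if dt is None:
                if "dt" not in f.attrs:
                    raise FormatError(f"{path}: no frame interval stored; supply dt")
                dt = float(f.attrs["dt"])
            labels = json.loads(f.attrs.get("labels", "{}"))
    else:
        raise ValueError(f"unsupported movie format: {path.suffix!r}")
    if mask_path is not None:
        mask_path = Path(mask_path)
        if mask_path.suffix in (".tif", ".tiff"):
            mask = np.asarray(tifffile.imread(mask_path)) > 0
        else:
            mask = np.load(mask_path).astype(bool)
    if mask is not None and mask.shape != data.shape[1:]:
        raise FormatError(
            f"mask shape {mask.shape} does not match frames {data.shape[1:]}"
        )
    return Movie(data=data, mask=mask, dt=float(dt), labels=labels)


def write_beta_map(path, beta_map: BetaMap) -> None:
    """Write a map as NPZ (mean, var, evaluated); .tif exports a scaled
    16-bit image with the scaling recorded in a JSON sidecar; .csv a table."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, mean=beta_map.mean, var=beta_map.var,
                 evaluated=beta_map.evaluated)
    elif path.suffix in (".tif", ".tiff"):
        finite = beta_map.mean[np.isfinite(beta_map.mean)]
        lo = float(finite.min()) if finite.size else 0.0
        hi = float(finite.max()) if finite.size else 1.0
        span = (hi - lo) or 1.0
        scaled = np.zeros(beta_map.shape, dtype=np.uint16)
        good = np.isfinite(beta_map.mean)
        scaled[good] = np.round(
            (beta_map.mean[good] - lo) / span * 65534
        ).astype(np.uint16) + 1  # 0 marks missing
        tifffile.imwrite(path, scaled)
        Path(str(path) + ".meta.json").write_text(
            json.dumps({"lo": lo, "hi": hi, "missing_value": 0})
        )
    elif path.suffix == ".csv":
        ii, jj = np.nonzero(beta_map.evaluated)
        pd.DataFrame(
            {"x": ii, "y": jj, "mean": beta_map.mean[ii, jj],
             "var": beta_map.var[ii, jj]}
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported map format: {path.suffix!r}")


def read_beta_map(path) -> BetaMap:
    path = Path(path)
    if path.suffix != ".npz":
        raise ValueError("maps are read back from NPZ only")
    with np.load(path) as z:
        return BetaMap(z["mean"], z["var"], z["evaluated"])


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise FormatError(f"{path}: expected a mapping at the top level")
    return out


def config_hash(obj) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration object."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    seed: int | None
    parameters: dict
    inputs: list
    outputs: list
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )

    @property
    def hash(self) -> str:
        return config_hash(
            {"command": self.command, "seed": self.seed, "parameters": self.parameters,
             "inputs": self.inputs}
        )

    def write(self, out_path) -> Path:
        """Write the manifest as ``<out_path>.manifest.json``."""
        target = Path(str(out_path) + ".manifest.json")
        payload = asdict(self)
        payload["config_hash"] = self.hash
        target.write_text(json.dumps(payload, indent=2, default=str))
        return target
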