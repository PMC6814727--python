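"""Gridded environmental covariate stacks.

An :class:`EnvStack` holds a regular lon/lat grid of environmental covariate
layers (bioclimatic variables, elevation, cultivated-land fraction, ...)
together with a categorical region label per cell and a nodata mask.  The
coordinate convention is cell-center referencing: row 0 is the northernmost
row (latitude decreases with row index) and longitude increases with column
index.

Stacks are stored on disk as a portable compressed NumPy archive (``.npz``)
with a JSON metadata entry, so round-trips are lossless and need no
geospatial libraries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, SchemaError

__all__ = ["EnvStack", "read_env_stack"]


@dataclass
class EnvStack:
    """A rows x cols x n_vars stack of gridded covariates with region labels.

    Parameters
    ----------
    values
        Array of shape ``(rows, cols, n_vars)`` with covariate values in the
        units of each variable.
    var_names
        One name per layer, e.g. ``"annual_mean_temp"``.
    region_label
        Integer grid of shape ``(rows, cols)`` indexing into ``region_names``.
    region_names
        Names of the regions; a region called ``"desert"`` (if present) is
        treated as the out-of-range area by the synthetic generator.
    nodata_mask
        Boolean grid, ``True`` where the cell carries no data.
    origin
        ``(lon, lat)`` of the center of cell ``(0, 0)``.
    cell_size
        Edge length of a cell in degrees (lon and lat share the step).
    """

    values: np.ndarray
    var_names: list[str]
    region_label: np.ndarray
    region_names: list[str]
    nodata_mask: np.ndarray
    origin: tuple[float, float] = (38.0, 12.0)
    cell_size: float = 0.05
    _name_to_idx: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.region_label = np.asarray(self.region_label, dtype=np.int64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        self.var_names = list(self.var_names)
        self.region_names = list(self.region_names)
        self._name_to_idx = {n: i for i, n in enumerate(self.var_names)}
        self.validate()

    # -- shape helpers -----------------------------------------------------
    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_vars(self) -> int:
        return self.values.shape[2]

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise InvalidArgumentError("values must be rows x cols x n_vars")
        if self.values.shape[2] != len(self.var_names):
            raise InvalidArgumentError("var_names must match the number of layers")
        if len(set(self.var_names)) != len(self.var_names):
            raise InvalidArgumentError("var_names must be unique")
        if self.values.shape[2] < 1:
            raise InvalidArgumentError("a stack needs at least one layer")
        grid = self.values.shape[:2]
        if self.region_label.shape != grid or self.nodata_mask.shape != grid:
            raise InvalidArgumentError("region_label and nodata_mask must match the grid shape")
        lab = self.region_label[~self.nodata_mask]
        if lab.size and (lab.min() < 0 or lab.max() >= len(self.region_names)):
            raise InvalidArgumentError("region_label must index region_names on every non-nodata cell")
        if self.cell_size <= 0:
            raise InvalidArgumentError("cell_size must be positive")

    # -- layer & coordinate access -----------------------------------------
    def layer(self, name: str) -> np.ndarray:
        """Return one covariate layer as a (rows, cols) array."""
        try:
            return self.values[:, :, self._name_to_idx[name]]
        except KeyError:
            raise SchemaError(f"stack has no layer named {name!r}") from None

    def lonlat(self, row, col):
        """Cell-center coordinates of (row, col); row 0 is northernmost."""
        lon0, lat0 = self.origin
        return lon0 + np.asarray(col) * self.cell_size, lat0 - np.asarray(row) * self.cell_size

    def cell_at(self, lon: float, lat: float) -> tuple[int, int]:
        """Nearest cell center to (lon, lat); halfway ties go to the lower index."""
        lon0, lat0 = self.origin
        col = int(np.ceil((lon - lon0) / self.cell_size - 0.5))
        row = int(np.ceil((lat0 - lat) / self.cell_size - 0.5))
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise InvalidArgumentError(f"({lon}, {lat}) falls outside the grid")
        return row, col

    def covariate_row(self, row: int, col: int, var_names=None) -> np.ndarray:
        """Covariate vector at one cell, in ``var_names`` order (default: all)."""
        if var_names is None:
            return self.values[row, col, :]
        idx = [self._name_to_idx[v] for v in var_names]
        return self.values[row, col, idx]

    def region_name_grid(self) -> np.ndarray:
        """Region name per cell as an object array (nodata cells included)."""
        names = np.asarray(self.region_names, dtype=object)
        return names[self.region_label]

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Write the stack as a compressed ``.npz`` archive."""
        meta = {
            "var_names": self.var_names,
            "region_names": self.region_names,
            "origin": list(self.origin),
            "cell_size": self.cell_size,
        }
        np.savez_compressed(
            path,
            values=self.values,
            region_label=self.region_label,
            nodata_mask=self.nodata_mask,
            meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "EnvStack":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            return cls(
                values=z["values"],
                var_names=meta["var_names"],
                region_label=z["region_label"],
                region_names=meta["region_names"],
                nodata_mask=z["nodata_mask"],
                origin=tuple(meta["origin"]),
                cell_size=float(meta["cell_size"]),
            )


def read_env_stack(path, expected_vars=None) -> EnvStack:
    """Load a stack and optionally check that all expected layers are present.

    Raises
    ------
    SchemaError
        If any name in ``expected_vars`` has no matching layer.
    """
    stack = EnvStack.load(path)
    if expected_vars is not None:
        missing = [v for v in expected_vars if v not in stack.var_names]
        if missing:
            raise SchemaError(f"stack is missing expected layers: {missing}")
    return stack
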