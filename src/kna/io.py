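"""Reading, writing and windowing of localisation tables.

Single-molecule localisation microscopy (SMLM) software exports one row per
detected fluorophore position ("localisation") as delimited text.  Column
headers differ between exporters (ThunderSTORM writes ``x [nm]``, others
plain ``x``), so loading goes through an explicit column map.  Coordinates
are continuous real values in a single length unit per analysis (nm for
experimental data, arbitrary units for simulations); no pixel snapping is
ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LocalisationTable",
    "Window",
    "ReadReport",
    "read_localisations",
    "write_localisations",
    "crop_to_window",
]


class ConfigurationError(ValueError):
    """A column map or parameter does not match the input file."""


class EmptyInputError(ValueError):
    """No valid localisations remain after filtering."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular region of interest.

    Boundaries are closed on all four sides; a point exactly on an edge is
    inside.  Units follow the localisation table the window is applied to.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate window: x [{self.xmin}, {self.xmax}], "
                f"y [{self.ymin}, {self.ymax}]"
            )

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @classmethod
    def square(cls, side: float, origin: tuple[float, float] = (0.0, 0.0)) -> "Window":
        ox, oy = origin
        return cls(ox, ox + side, oy, oy + side)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (closed) window."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        )

    def boundary_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest window edge."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.minimum.reduce(
            [x - self.xmin, self.xmax - x, y - self.ymin, self.ymax - y]
        )


@dataclass(frozen=True)
class LocalisationTable:
    """A set of 2D localisations from one image.

    Parameters
    ----------
    x, y
        Coordinates, one length unit per analysis (nm for experimental
        data).  Must be finite.
    channel
        Optional categorical label per localisation (e.g. two-colour data).
    image_id
        Identifier of the source image; carried through all downstream
        tables.
    """

    x: np.ndarray
    y: np.ndarray
    channel: np.ndarray | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.channel is not None:
            ch = np.asarray(self.channel)
            if ch.shape != x.shape:
                raise ValueError("channel must match coordinate length")
            object.__setattr__(self, "channel", ch)

    def __len__(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        """(N, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def select(self, mask: np.ndarray) -> "LocalisationTable":
        """Row subset by boolean mask or index array, order preserved."""
        ch = self.channel[mask] if self.channel is not None else None
        return LocalisationTable(self.x[mask], self.y[mask], ch, self.image_id)

    def subset_channel(self, label) -> "LocalisationTable":
        if self.channel is None:
            raise ValueError("table has no channel column")
        return self.select(self.channel == label)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"x": self.x, "y": self.y}
        if self.channel is not None:
            data["channel"] = self.channel
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, image_id: str = ""
    ) -> "LocalisationTable":
        channel = frame["channel"].to_numpy() if "channel" in frame else None
        return cls(
            frame["x"].to_numpy(dtype=float),
            frame["y"].to_numpy(dtype=float),
            channel,
            image_id,
        )


@dataclass(frozen=True)
class ReadReport:
    """Bookkeeping from :func:`read_localisations`."""

    n_read: int
    n_kept: int
    n_dropped_nonfinite: int


DEFAULT_COLUMN_MAP = {"x": "x", "y": "y"}


def read_localisations(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str = ",",
    image_id: str | None = None,
) -> tuple[LocalisationTable, ReadReport]:
    """Load a localisation table from delimited text.

    ``column_map`` maps the canonical field names ``x``, ``y`` and
    optionally ``channel`` onto the file's header names, e.g.
    ``{"x": "x [nm]", "y": "y [nm]"}``.  Rows with non-finite coordinates
    are dropped and counted in the returned report; remaining row order is
    preserved.
    """
    path = Path(path)
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    frame = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    for key in ("x", "y"):
        name = column_map.get(key)
        if name is None or name not in frame.columns:
            raise ConfigurationError(
                f"column map entry {key!r} -> {name!r} not found in "
                f"{sorted(frame.columns)}"
            )
    x = pd.to_numeric(frame[column_map["x"]], errors="coerce").to_numpy(float)
    y = pd.to_numeric(frame[column_map["y"]], errors="coerce").to_numpy(float)
    keep = np.isfinite(x) & np.isfinite(y)
    channel = None
    if "channel" in column_map:
        name = column_map["channel"]
        if name not in frame.columns:
            raise ConfigurationError(f"channel column {name!r} not found")
        channel = frame[name].to_numpy()[keep]
    n_read = len(frame)
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise EmptyInputError(f"no valid localisations in {path}")
    table = LocalisationTable(
        x[keep], y[keep], channel, image_id if image_id is not None else path.stem
    )
    return table, ReadReport(n_read, n_kept, n_read - n_kept)


def write_localisations(
    table: LocalisationTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write the canonical CSV dialect (UTF-8, header ``x,y[,channel]``).

    Coordinates round-trip bit-exactly through :func:`read_localisations`
    (written with ``repr`` precision).
    """
    frame = table.to_dataframe()
    frame.to_csv(path, sep=delimiter, index=False, float_format=lambda v: repr(float(v)))


def crop_to_window(table: LocalisationTable, window: Window) -> LocalisationTable:
    """Retain points inside the closed window; idempotent."""
    return table.select(window.contains(table.x, table.y))
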