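"""Image containers and table I/O.

The canonical in-memory object is :class:`ImageStack`: a numpy voxel grid
with explicit physical voxel spacing (micrometres) and named leading axes.
Axis order follows the ImageJ hyperstack convention restricted to the axes
actually present, i.e. a subset of ``TCZYX`` with ``YX`` always last.

Particle and track tables are plain :class:`pandas.DataFrame` objects with
documented column names; helpers here read/write them as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

#: canonical column order for particle tables
PARTICLE_COLUMNS = [
    "frame", "channel", "x_um", "y_um", "z_um",
    "intensity", "background", "sigma_xy", "sigma_z", "quality",
]


@dataclass
class ImageStack:
    """Voxel grid with physical spacing.

    Parameters
    ----------
    data
        Array whose trailing axes are always ``(y, x)``; leading axes are
        named by ``axes`` (a subset of ``"TCZYX"`` matching ``data.ndim``).
    voxel_size
        Physical size of one voxel in micrometres as ``(z, y, x)``.
        For 2D data the z entry is ignored but kept for uniformity.
    meta
        Free-form metadata (seed, generator config, ...), serialised to the
        TIFF description on save.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)
    axes: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not self.axes:
            self.axes = "TCZYX"[5 - self.data.ndim:]
        if len(self.axes) != self.data.ndim:
            raise ValueError(
                f"axes {self.axes!r} does not match ndim {self.data.ndim}")
        if self.axes[-2:] != "YX":
            raise ValueError("trailing axes must be YX")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[self.axes.index("T")] if "T" in self.axes else 1

    @property
    def n_channels(self) -> int:
        return self.data.shape[self.axes.index("C")] if "C" in self.axes else 1

    def channel(self, c: int) -> "ImageStack":
        """Single-channel view (drops the C axis)."""
        if "C" not in self.axes:
            if c != 0:
                raise IndexError("stack has no channel axis")
            return self
        i = self.axes.index("C")
        return replace(self, data=self.data.take(c, axis=i),
                       axes=self.axes[:i] + self.axes[i + 1:])

    def frame(self, t: int) -> "ImageStack":
        """Single-timepoint view (drops the T axis)."""
        if "T" not in self.axes:
            if t != 0:
                raise IndexError("stack has no time axis")
            return self
        i = self.axes.index("T")
        return replace(self, data=self.data.take(t, axis=i),
                       axes=self.axes[:i] + self.axes[i + 1:])

    def save(self, path) -> None:
        import json
        tifffile.imwrite(
            path, self.data,
            photometric="minisblack",
            metadata={"axes": self.axes},
            description=json.dumps(
                {"voxel_size_um": list(self.voxel_size), **_jsonable(self.meta)}),
        )

    @classmethod
    def load(cls, path, voxel_size=None, axes="") -> "ImageStack":
        import json
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ax = axes or (tf.series[0].axes if tf.series else "")
            desc = tf.pages[0].description or ""
        meta = {}
        if voxel_size is None:
            voxel_size = (0.2, 0.1, 0.1)
            try:
                meta = json.loads(desc)
                voxel_size = tuple(meta.pop("voxel_size_um"))
            except (ValueError, KeyError):
                pass
        ax = "".join(a for a in ax if a in "TCZYX")[-data.ndim:]
        if len(ax) != data.ndim or not ax.endswith("YX"):
            ax = "TCZYX"[5 - data.ndim:]
        return cls(data, tuple(voxel_size), ax, meta)


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, dict):
            v = _jsonable(v)
        out[k] = v
    return out


def write_particles(df: pd.DataFrame, path) -> None:
    cols = [c for c in PARTICLE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)


def read_particles(path) -> pd.DataFrame:
    return pd.read_csv(path)
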