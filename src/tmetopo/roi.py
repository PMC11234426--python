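"""Shared containers for multiplexed imaging data.

An acquisition ("ROI", region of interest) is a stack of single-channel
intensity images, one channel per antibody/metal in the panel. The panel
assigns each channel a role: exactly one ``nucleus`` channel (DNA
intercalator), plus ``membrane``, ``lineage`` and ``structure`` channels.
Spillover between channels is described by a square matrix whose entry
(i, j) is the fraction of channel-i signal detected in channel j.

ROIs round-trip through multi-page TIFF plus a JSON sidecar holding the
panel, site label, pixel size and (optionally) the spillover matrix used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

ROLES = ("nucleus", "membrane", "lineage", "structure")


@dataclass(frozen=True)
class Channel:
    """One panel channel: marker name plus its role in the panel."""

    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {ROLES}")


@dataclass(frozen=True)
class Panel:
    """Ordered antibody panel; exactly one nucleus channel, unique names."""

    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("panel channel names must be unique")
        n_nuc = sum(c.role == "nucleus" for c in self.channels)
        if n_nuc != 1:
            raise ValueError(f"panel must have exactly one nucleus channel, found {n_nuc}")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def nucleus_index(self) -> int:
        return next(i for i, c in enumerate(self.channels) if c.role == "nucleus")

    @property
    def nucleus_name(self) -> str:
        return self.channels[self.nucleus_index].name

    def index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(name)

    def roles(self) -> list[str]:
        return [c.role for c in self.channels]

    def to_dict(self) -> dict:
        return {"channels": [[c.name, c.role] for c in self.channels]}

    @classmethod
    def from_dict(cls, d: dict) -> "Panel":
        return cls(tuple(Channel(n, r) for n, r in d["channels"]))


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square channel crosstalk matrix, row-indexed by source channel.

    Diagonal entries are exactly 1; off-diagonal entries lie in [0, 1).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("spillover matrix must be square")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("spillover matrix diagonal must be all 1")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < 0 or off.max() >= 1):
            raise ValueError("off-diagonal spillover entries must lie in [0, 1)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def identity(cls, n: int) -> "SpilloverMatrix":
        return cls(np.eye(n))

    @classmethod
    def random(cls, n: int, rng: np.random.Generator, max_spill: float = 0.08,
               density: float = 0.3) -> "SpilloverMatrix":
        """Draw a realistic sparse spillover matrix (small off-diagonals)."""
        v = np.eye(n)
        mask = rng.random((n, n)) < density
        np.fill_diagonal(mask, False)
        v[mask] = rng.uniform(0.0, max_spill, size=mask.sum())
        return cls(v)


@dataclass
class ROIImage:
    """Multi-channel ROI: C x H x W intensities plus panel metadata.

    Coordinates are pixel units, origin top-left, x = column, y = row;
    geometry is half-open [0, W) x [0, H). ``pixel_size`` is in um/pixel.
    """

    data: np.ndarray
    panel: Panel
    roi_id: str = "roi"
    site: str = ""
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ROI data must be C x H x W")
        if self.data.shape[0] != len(self.panel):
            raise ValueError(
                f"ROI has {self.data.shape[0]} channels but panel lists {len(self.panel)}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("ROI intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.panel.index(name)]

    def with_data(self, data: np.ndarray) -> "ROIImage":
        return ROIImage(data, self.panel, self.roi_id, self.site, self.pixel_size,
                        dict(self.meta))

    # ------------------------------------------------------------------ IO
    def to_tiff(self, path: str | Path) -> None:
        """Write one page per channel plus a JSON sidecar (same stem)."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32), photometric="minisblack")
        sidecar = {
            "roi_id": self.roi_id,
            "site": self.site,
            "pixel_size": self.pixel_size,
            "panel": self.panel.to_dict(),
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ROIImage":
        path = Path(path)
        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        side = json.loads(path.with_suffix(".json").read_text())
        return cls(data, Panel.from_dict(side["panel"]), side["roi_id"], side["site"],
                   side["pixel_size"], side.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
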