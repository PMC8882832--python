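"""Systematic-biopsy core templates and lesion-distance core ranking.

The prostate is represented as a unit box in normalized coordinates:
x runs left (-1) to right (+1), y posterior (-1) to anterior (+1), and
z base (-1) to apex (+1).  Two named templates ship as JSON assets:

``changhai_12``
    the 12-core template, {left, right} x {base, mid, apex} x
    {medial, lateral}, all cores posterior (y = -0.5), with base at
    z = -0.7, mid at z = 0, apex at z = +0.7, medial |x| = 0.25 and
    lateral |x| = 0.75;
``fujian_13``
    the same 12 cores plus one midline core at the origin of the
    transverse plane (x = 0, y = -0.5, z = 0).

A lesion is located either by coarse sector labels (side x level x
zone, the granularity a clinician reads off mpMRI) or by explicit
normalized coordinates.  Reduced k-core schemes are the k cores closest
to the lesion point, so the schemes are nested by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .errors import ValidationError

__all__ = [
    "CorePosition",
    "CoreLayout",
    "LesionLocation",
    "get_layout",
    "sector_centroid",
    "rank_cores",
    "mirror_location",
]

SIDES = ("left", "right")
LEVELS = ("base", "mid", "apex")
ZONES = ("peripheral", "transition")
LATERALITIES = ("medial", "lateral", "midline")

_LEVEL_ORDER = {"base": 0, "mid": 1, "apex": 2}
_SIDE_ORDER = {"right": 0, "left": 1, "midline": 2}


@dataclass(frozen=True)
class CorePosition:
    """A single template core: labels plus normalized coordinates."""

    core_id: int
    side: str        # left / right, or midline for the 13th core
    level: str       # base / mid / apex
    laterality: str  # medial / lateral / midline
    x: float
    y: float
    z: float

    def __post_init__(self):
        if self.side not in SIDES + ("midline",):
            raise ValidationError(f"unknown side {self.side!r}")
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}")
        if self.laterality not in LATERALITIES:
            raise ValidationError(f"unknown laterality {self.laterality!r}")
        expected_sign = {"right": 1, "left": -1, "midline": 0}[self.side]
        if np.sign(self.x) != expected_sign:
            raise ValidationError(f"core {self.core_id}: x={self.x} inconsistent with side {self.side!r}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class CoreLayout:
    """A named biopsy template (ordered, contiguous core ids from 1)."""

    name: str
    cores: tuple

    def __post_init__(self):
        ids = [c.core_id for c in self.cores]
        if ids != list(range(1, len(ids) + 1)):
            raise ValidationError(f"layout {self.name!r}: core ids must be contiguous from 1, got {ids}")

    @property
    def n(self) -> int:
        return len(self.cores)

    def core(self, core_id: int) -> CorePosition:
        return self.cores[core_id - 1]

    @property
    def standard_core_ids(self) -> tuple:
        """Core ids excluding any midline core (the 12-core reference set)."""
        return tuple(c.core_id for c in self.cores if c.laterality != "midline")

    def positions(self) -> np.ndarray:
        return np.vstack([c.position for c in self.cores])

    @classmethod
    def from_dict(cls, payload: dict) -> "CoreLayout":
        cores = tuple(
            CorePosition(
                core_id=int(c["core_id"]), side=c["side"], level=c["level"],
                laterality=c["laterality"], x=float(c["x"]), y=float(c["y"]), z=float(c["z"]),
            )
            for c in payload["cores"]
        )
        return cls(name=payload["name"], cores=cores)


def _load_asset(name: str) -> dict:
    ref = resources.files(__package__).joinpath("data", f"{name}.json")
    with ref.open(encoding="utf-8") as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def get_layout(name: str) -> CoreLayout:
    """Load a shipped template by name (``changhai_12`` or ``fujian_13``)."""
    if name not in ("changhai_12", "fujian_13"):
        raise ValidationError(f"unknown layout {name!r}; valid layouts: changhai_12, fujian_13")
    return CoreLayout.from_dict(_load_asset(name))


@lru_cache(maxsize=1)
def _sector_table() -> dict:
    table = {}
    for row in _load_asset("sector_centroids")["sectors"]:
        table[(row["side"], row["level"], row["zone"])] = np.array([row["x"], row["y"], row["z"]])
    return table


@dataclass(frozen=True)
class LesionLocation:
    """The most suspicious lesion, by sector labels or explicit coordinates.

    Exactly one description is required: either all three sector labels
    (``side``, ``level``, ``zone``) or a normalized coordinate triple.
    Explicit coordinates take precedence when both are given.
    """

    side: str = None
    level: str = None
    zone: str = None
    coords: tuple = None

    def __post_init__(self):
        if self.coords is not None:
            coords = tuple(float(v) for v in self.coords)
            object.__setattr__(self, "coords", coords)
            if len(coords) != 3 or any(not np.isfinite(v) or abs(v) > 1 for v in coords):
                raise ValidationError(f"coords must be 3 finite values in [-1, 1], got {self.coords!r}")
            return
        if self.side not in SIDES:
            raise ValidationError(f"unknown lesion side {self.side!r}; valid sides: {SIDES}")
        if self.level not in LEVELS:
            raise ValidationError(f"unknown lesion level {self.level!r}; valid levels: {LEVELS}")
        if self.zone not in ZONES:
            raise ValidationError(f"unknown lesion zone {self.zone!r}; valid zones: {ZONES}")


def sector_centroid(loc: LesionLocation, layout: CoreLayout = None) -> np.ndarray:
    """Canonical lesion point: explicit coordinates pass through; sector
    labels resolve to the shipped centroid table."""
    if loc.coords is not None:
        return np.array(loc.coords, dtype=float)
    return _sector_table()[(loc.side, loc.level, loc.zone)].copy()


def rank_cores(loc: LesionLocation, layout: CoreLayout) -> list:
    """All core ids of ``layout`` sorted by ascending Euclidean distance
    from the lesion point.

    The k-core scheme is the length-k prefix, so schemes are nested.
    Distance ties are broken deterministically: level order
    base < mid < apex, then side right < left, then lower core id.
    """
    point = sector_centroid(loc, layout)
    dist = np.linalg.norm(layout.positions() - point[None, :], axis=1)
    keyed = sorted(
        (round(float(dist[i]), 12), _LEVEL_ORDER[c.level], _SIDE_ORDER[c.side], c.core_id)
        for i, c in enumerate(layout.cores)
    )
    return [k[-1] for k in keyed]


def mirror_location(loc: LesionLocation) -> LesionLocation:
    """Left-right mirror image of a lesion location (testing aid)."""
    if loc.coords is not None:
        x, y, z = loc.coords
        return LesionLocation(coords=(-x, y, z))
    flip = {"left": "right", "right": "left"}
    return LesionLocation(side=flip[loc.side], level=loc.level, zone=loc.zone)
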