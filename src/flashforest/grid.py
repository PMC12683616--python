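"""Spatial domain, species and tree records, and lattice queries.

The simulated world is a rectangular block of 1 m^3 voxels.  Each ground
voxel (x, y) can hold at most one living tree; the vertical dimension only
matters for the canopy light field.  Trees are stored structure-of-arrays
inside :class:`ForestGrid` so that the monthly update is fully vectorised;
:class:`Tree` is a lightweight record view used by the single-tree API and
the tests.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTraits",
    "SpeciesTable",
    "Tree",
    "Forcing",
    "ForestGrid",
    "build_grid",
    "voxels_within",
    "disk_offsets",
]


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species trait record.

    Parameters
    ----------
    lma : leaf mass per area, g m^-2.
    wsg : wood specific gravity, dimensionless (0, 1.2].
    leaf_n : leaf nitrogen, % of dry mass.
    leaf_p : leaf phosphorus, % of dry mass; ``nan`` when unmeasured.
    allom_a, allom_b, allom_k : generalised Michaelis-Menten height
        allometry H(D) = a D^b / (k + D^b) with D in cm and H in m.
    maturity_dbh : reproductive DBH threshold, cm.
    delta_i : lightning log10-odds shift; negative = tolerant, 0 = the
        community mean (also the default for unmeasured species).
    """

    species_id: str
    lma: float
    wsg: float
    leaf_n: float
    allom_a: float
    allom_b: float
    allom_k: float
    maturity_dbh: float
    leaf_p: float = float("nan")
    delta_i: float = 0.0

    def __post_init__(self) -> None:
        if not self.lma > 0:
            raise ValueError(f"lma must be > 0, got {self.lma}")
        if not 0 < self.wsg <= 1.2:
            raise ValueError(f"wsg must be in (0, 1.2], got {self.wsg}")
        if not self.allom_a > 0:
            raise ValueError(f"allom_a must be > 0, got {self.allom_a}")
        if not self.maturity_dbh > 0:
            raise ValueError(f"maturity_dbh must be > 0, got {self.maturity_dbh}")
        d = self.delta_i
        if d is None or (isinstance(d, float) and np.isnan(d)):
            object.__setattr__(self, "delta_i", 0.0)
        elif not np.isfinite(d):
            raise ValueError(f"delta_i must be finite (or unknown -> 0), got {d}")


class SpeciesTable:
    """Vectorised view over a list of :class:`SpeciesTraits`.

    Exposes each trait as a numpy array indexed by integer species index,
    which is what the simulation engine uses throughout.
    """

    _FIELDS = (
        "lma",
        "wsg",
        "leaf_n",
        "leaf_p",
        "allom_a",
        "allom_b",
        "allom_k",
        "maturity_dbh",
        "delta_i",
    )

    def __init__(self, species: list[SpeciesTraits]):
        if not species:
            raise ValueError("species table must contain at least one species")
        self.species = list(species)
        self.ids = [s.species_id for s in species]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate species_id in table")
        for name in self._FIELDS:
            arr = np.array([getattr(s, name) for s in species], dtype=float)
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.species)

    def __getitem__(self, i: int) -> SpeciesTraits:
        return self.species[i]

    def index_of(self, species_id: str) -> int:
        return self.ids.index(species_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpeciesTable":
        """Build from a trait table (one row per species).

        Missing/blank ``delta_i`` and ``leaf_p`` are tolerated: delta_i
        defaults to 0 (community-mean lightning risk), leaf_p to nan
        (the N-only physiological route is used).
        """
        df = df.copy()
        if "delta_i" not in df.columns:
            df["delta_i"] = 0.0
        if "leaf_p" not in df.columns:
            df["leaf_p"] = np.nan
        df["delta_i"] = pd.to_numeric(df["delta_i"], errors="coerce").fillna(0.0)
        records = []
        for _, row in df.iterrows():
            records.append(
                SpeciesTraits(
                    species_id=str(row["species_id"]),
                    lma=float(row["lma"]),
                    wsg=float(row["wsg"]),
                    leaf_n=float(row["leaf_n"]),
                    leaf_p=float(row["leaf_p"]),
                    allom_a=float(row["allom_a"]),
                    allom_b=float(row["allom_b"]),
                    allom_k=float(row["allom_k"]),
                    maturity_dbh=float(row["maturity_dbh"]),
                    delta_i=float(row["delta_i"]),
                )
            )
        return cls(records)

    @classmethod
    def from_csv(cls, path) -> "SpeciesTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        cols = {"species_id": self.ids}
        for name in self._FIELDS:
            cols[name] = getattr(self, name)
        return pd.DataFrame(cols)


@dataclass
class Tree:
    """Single-tree record view (the engine stores trees as arrays)."""

    tree_id: int
    species: SpeciesTraits
    x: int
    y: int
    dbh: float  # cm
    height: float  # m
    crown_radius: float  # m
    crown_depth: float  # m
    leaf_area: float  # m^2
    npp_negative_months: int = 0
    alive: bool = True


@dataclass
class Forcing:
    """Half-hourly climatology over one repeating year.

    Arrays are shaped (12 months, 48 half-hour slots).
    """

    ppfd: np.ndarray  # umol photon m^-2 s^-1
    temperature: np.ndarray  # degC
    vpd: np.ndarray  # kPa

    def __post_init__(self) -> None:
        for name in ("ppfd", "temperature", "vpd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, 48):
                raise ValueError(f"{name} must have shape (12, 48), got {arr.shape}")
            setattr(self, name, arr)
        if (self.ppfd < 0).any():
            raise ValueError("ppfd must be nonnegative")
        if (self.vpd < 0).any():
            raise ValueError("vpd must be nonnegative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Forcing":
        """Read from a long table with columns month (1-12), slot (1-48),
        ppfd, temperature, vpd."""
        arrs = {}
        for name in ("ppfd", "temperature", "vpd"):
            arr = np.full((12, 48), np.nan)
            arr[df["month"].to_numpy() - 1, df["slot"].to_numpy() - 1] = df[
                name
            ].to_numpy()
            if np.isnan(arr).any():
                raise ValueError(f"forcing table is missing (month, slot) cells for {name}")
            arrs[name] = arr
        return cls(**arrs)

    @classmethod
    def from_csv(cls, path) -> "Forcing":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        month, slot = np.meshgrid(np.arange(1, 13), np.arange(1, 49), indexing="ij")
        return pd.DataFrame(
            {
                "month": month.ravel(),
                "slot": slot.ravel(),
                "ppfd": self.ppfd.ravel(),
                "temperature": self.temperature.ravel(),
                "vpd": self.vpd.ravel(),
            }
        )


class ForestGrid:
    """Voxel domain with at-most-one-tree-per-ground-voxel occupancy.

    Tree state lives in flat numpy arrays of capacity ``width * length``
    (the hard cap on tree number).  ``occ[x, y]`` holds the slot index of
    the living tree rooted at (x, y), or -1.
    """

    def __init__(self, width: int, length: int, height: int, *, toroidal: bool = True):
        for name, v in (("width", width), ("length", length), ("height", height)):
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        self.width = int(width)
        self.length = int(length)
        self.height = int(height)
        self.toroidal = bool(toroidal)

        cap = self.width * self.length
        self.capacity = cap
        self.occ = np.full((self.width, self.length), -1, dtype=np.int32)
        self.alive = np.zeros(cap, dtype=bool)
        self.species_idx = np.zeros(cap, dtype=np.int32)
        self.x = np.zeros(cap, dtype=np.int32)
        self.y = np.zeros(cap, dtype=np.int32)
        self.dbh = np.zeros(cap, dtype=float)
        self.height_m = np.zeros(cap, dtype=float)
        self.crown_radius = np.zeros(cap, dtype=float)
        self.crown_depth = np.zeros(cap, dtype=float)
        self.leaf_area = np.zeros(cap, dtype=float)
        self.wood_mass = np.zeros(cap, dtype=float)  # kg dry matter, aboveground
        self.canopy_mass = np.zeros(cap, dtype=float)  # kg dry matter
        self.neg_months = np.zeros(cap, dtype=np.int16)
        self._free: list[int] = list(range(cap - 1, -1, -1))
        self._next_tree_id = 0
        self.tree_id = np.full(cap, -1, dtype=np.int64)
        # per-voxel seedbank: species index sets are implicit (external seed
        # rain reaches every voxel); recruitment weighting is handled by the
        # demography module.
        self.n_recruited = 0
        self.n_died = 0
        self.n_initial = 0

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_ground_voxels(self) -> int:
        return self.width * self.length

    @property
    def n_trees(self) -> int:
        return int(self.alive.sum())

    def living_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def add_tree(
        self,
        species_idx: int,
        x: int,
        y: int,
        *,
        dbh: float = 1.0,
        height: float = 1.5,
        crown_radius: float = 0.5,
        crown_depth: float = 1.0,
        leaf_area: float = 0.5,
        wood_mass: float = 0.05,
        canopy_mass: float = 0.01,
    ) -> int:
        """Place a living tree on an empty ground voxel; returns its slot."""
        if dbh < 1.0:
            raise ValueError(f"dbh must be >= 1 cm, got {dbh}")
        if self.occ[x, y] != -1:
            raise ValueError(f"voxel ({x}, {y}) is already occupied")
        slot = self._free.pop()
        self.alive[slot] = True
        self.species_idx[slot] = species_idx
        self.x[slot] = x
        self.y[slot] = y
        self.dbh[slot] = dbh
        self.height_m[slot] = min(height, self.height)
        self.crown_radius[slot] = crown_radius
        self.crown_depth[slot] = crown_depth
        self.leaf_area[slot] = leaf_area
        self.wood_mass[slot] = wood_mass
        self.canopy_mass[slot] = canopy_mass
        self.neg_months[slot] = 0
        self.tree_id[slot] = self._next_tree_id
        self._next_tree_id += 1
        self.occ[x, y] = slot
        return slot

    def remove_tree(self, slot: int) -> None:
        if not self.alive[slot]:
            raise ValueError(f"slot {slot} holds no living tree")
        self.alive[slot] = False
        self.occ[self.x[slot], self.y[slot]] = -1
        self._free.append(slot)
        self.n_died += 1

    def remove_trees(self, slots: np.ndarray) -> None:
        for s in np.atleast_1d(slots):
            self.remove_tree(int(s))

    def tree_view(self, slot: int, table: SpeciesTable) -> Tree:
        return Tree(
            tree_id=int(self.tree_id[slot]),
            species=table[int(self.species_idx[slot])],
            x=int(self.x[slot]),
            y=int(self.y[slot]),
            dbh=float(self.dbh[slot]),
            height=float(self.height_m[slot]),
            crown_radius=float(self.crown_radius[slot]),
            crown_depth=float(self.crown_depth[slot]),
            leaf_area=float(self.leaf_area[slot]),
            npp_negative_months=int(self.neg_months[slot]),
            alive=bool(self.alive[slot]),
        )

    def iter_trees(self, table: SpeciesTable) -> Iterator[Tree]:
        for slot in self.living_indices():
            yield self.tree_view(int(slot), table)

    # -- geometry ------------------------------------------------------

    def displacement(self, x0, y0, x1, y1) -> tuple[np.ndarray, np.ndarray]:
        """Signed (dx, dy) from (x0, y0) to (x1, y1) under the boundary rule."""
        dx = np.asarray(x1) - np.asarray(x0)
        dy = np.asarray(y1) - np.asarray(y0)
        if self.toroidal:
            w, l = self.width, self.length
            dx = (dx + w // 2) % w - w // 2
            dy = (dy + l // 2) % l - l // 2
        return dx, dy

    def distance(self, x0, y0, x1, y1) -> np.ndarray:
        dx, dy = self.displacement(x0, y0, x1, y1)
        return np.hypot(dx, dy)

    def check_invariants(self) -> None:
        """Occupancy/census consistency; raises AssertionError on violation."""
        live = self.living_indices()
        occ_slots = self.occ[self.occ >= 0]
        assert len(occ_slots) == len(live), "occupancy count != living tree count"
        assert set(occ_slots.tolist()) == set(live.tolist())
        for slot in live:
            assert self.occ[self.x[slot], self.y[slot]] == slot
        assert self.n_trees == self.n_initial + self.n_recruited - self.n_died


def build_grid(width: int, length: int, height: int, *, toroidal: bool = True) -> ForestGrid:
    """Create an empty simulation domain of ``width x length`` ground voxels.

    The default study domain is 200 x 200 m with a 50 m vertical extent,
    giving 40,000 ground voxels and hence at most 40,000 trees.
    """
    return ForestGrid(width, length, height, toroidal=toroidal)


@functools.lru_cache(maxsize=128)
def disk_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets (dx, dy) with dx^2 + dy^2 <= radius^2.

    Cached; used for crown footprints and lightning neighbourhoods.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    r_int = int(np.floor(radius))
    ax = np.arange(-r_int, r_int + 1)
    dx, dy = np.meshgrid(ax, ax, indexing="ij")
    mask = dx * dx + dy * dy <= radius * radius
    return np.stack([dx[mask], dy[mask]], axis=1)


def voxels_within(grid: ForestGrid, center: tuple[int, int], radius: float) -> list[tuple[int, int]]:
    """Ground voxels whose center-to-center distance from ``center`` is
    <= ``radius``, under the grid's boundary rule.

    With toroidal wrap the offsets are folded back into the domain; with a
    hard edge, offsets falling outside are dropped.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    cx, cy = center
    offs = disk_offsets(radius)
    xs = cx + offs[:, 0]
    ys = cy + offs[:, 1]
    if grid.toroidal:
        xs = xs % grid.width
        ys = ys % grid.length
    else:
        keep = (xs >= 0) & (xs < grid.width) & (ys >= 0) & (ys < grid.length)
        xs, ys = xs[keep], ys[keep]
    out = sorted(set(zip(xs.tolist(), ys.tolist())))
    return out
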