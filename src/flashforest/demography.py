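"""Recruitment and the first two mortality stages.

Stage 1 combines a wood-density-dependent background rate with carbon
starvation: a tree whose run of consecutive negative-NPP months exceeds
its leaf lifespan dies with certainty.  Stage 2 is treefall, with a
height-increasing primary probability and a crushing rule for trees in the
fall corridor.  Lightning, when enabled, acts as a third stage after these
(see :mod:`flashforest.lightning`); recruitment runs last each month so
voxels vacated by any death become available immediately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ForestGrid, SpeciesTable, Tree

__all__ = [
    "MortalityParams",
    "leaf_lifespan_months",
    "background_probability",
    "stage1_probability",
    "treefall_probability",
    "stage2_treefall",
    "recruit",
]


@dataclass(frozen=True)
class MortalityParams:
    """Demographic mortality parameters.

    m0 : maximal baseline mortality rate, yr^-1 (uncertainty range 0-0.03);
        realised by the softest wood (wsg = wsg_ref) and declining linearly
        to zero at wsg_max.
    treefall_height_scale : midpoint (m) of the logistic height response.
    treefall_width : logistic width (m).
    treefall_max_prob : monthly ceiling on the primary treefall draw.
    wsg_ref : wood specific gravity of the softest configured wood.
    """

    m0: float = 0.015
    treefall_height_scale: float = 38.0
    treefall_width: float = 8.0
    treefall_max_prob: float = 0.0025
    wsg_ref: float = 0.0
    wsg_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m0 <= 0.03:
            raise ValueError(f"m0 must be in [0, 0.03] yr^-1, got {self.m0}")
        if not 0.0 <= self.treefall_max_prob <= 1.0:
            raise ValueError("treefall_max_prob must be a probability")
        if not 0.0 <= self.wsg_ref < self.wsg_max:
            raise ValueError("need 0 <= wsg_ref < wsg_max")


def leaf_lifespan_months(lma) -> np.ndarray:
    """Leaf lifespan (months) from LMA by a power law, normalised so
    LMA = 100 g m^-2 gives 12 months."""
    return 12.0 * (np.asarray(lma, dtype=float) / 100.0) ** 0.7


def background_probability(wsg, mort: MortalityParams):
    """Monthly background mortality: (m0/12) at the softest wood,
    declining linearly to zero at wsg_max."""
    wsg = np.asarray(wsg, dtype=float)
    slope = (1.0 - wsg / mort.wsg_max) / (1.0 - mort.wsg_ref / mort.wsg_max)
    return mort.m0 / 12.0 * np.clip(slope, 0.0, 1.0)


def stage1_probability(tree: Tree, mort: MortalityParams) -> float:
    """Monthly stage-1 mortality probability for one tree.

    p = min(1, p_background(wsg) + p_starvation), where p_starvation is 1
    once the consecutive negative-NPP months exceed the leaf lifespan and 0
    otherwise.
    """
    p_b = float(background_probability(tree.species.wsg, mort))
    lifespan = float(leaf_lifespan_months(tree.species.lma))
    p_starv = 1.0 if tree.npp_negative_months > lifespan else 0.0
    return min(1.0, p_b + p_starv)


def stage1_probability_arrays(
    wsg: np.ndarray, lma: np.ndarray, neg_months: np.ndarray, mort: MortalityParams
) -> np.ndarray:
    p = background_probability(wsg, mort)
    p = p + (neg_months > leaf_lifespan_months(lma))
    return np.minimum(1.0, p)


def treefall_probability(height_m, mort: MortalityParams):
    """Monthly primary-treefall probability: logistic in height with
    midpoint ``treefall_height_scale``, saturating at
    ``treefall_max_prob``; vanishes as height -> 0."""
    h = np.asarray(height_m, dtype=float)
    logistic = 1.0 / (1.0 + np.exp(-(h - mort.treefall_height_scale) / mort.treefall_width))
    base = 1.0 / (1.0 + np.exp(mort.treefall_height_scale / mort.treefall_width))
    # rescale so p(0) = 0 exactly while keeping the saturating ceiling
    return mort.treefall_max_prob * np.clip((logistic - base) / (1.0 - base), 0.0, 1.0)


def stage2_treefall(
    grid: ForestGrid,
    slot: int,
    mort: MortalityParams,
    rng: np.random.Generator,
) -> list[int]:
    """Resolve treefall for one tree that has already drawn a fall.

    A uniform random azimuth is drawn; trees whose voxel lies within the
    fall corridor (length = faller height, half-width = faller crown
    radius) are crushed and die if shorter than half the faller's height.
    Returns the slots killed (faller first).  The caller removes them.
    """
    killed = [slot]
    h = float(grid.height_m[slot])
    cr = max(1.0, float(grid.crown_radius[slot]))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    ux, uy = np.cos(theta), np.sin(theta)
    x0, y0 = int(grid.x[slot]), int(grid.y[slot])

    live = grid.living_indices()
    live = live[live != slot]
    if len(live) == 0 or h < 1.0:
        return killed
    dx, dy = grid.displacement(x0, y0, grid.x[live], grid.y[live])
    along = dx * ux + dy * uy
    across = np.abs(-dx * uy + dy * ux)
    in_corridor = (along > 0) & (along <= h) & (across <= cr)
    crushed = live[in_corridor & (grid.height_m[live] < 0.5 * h)]
    killed.extend(int(s) for s in crushed)
    return killed


def recruit(
    grid: ForestGrid,
    ground_light: np.ndarray,
    table: SpeciesTable,
    rng: np.random.Generator,
    *,
    compensation: float = 20.0,
    mature_weight: float = 4.0,
    init_geometry: dict | None = None,
) -> list[int]:
    """Monthly recruitment from the seedling banks.

    ``ground_light`` is the mean-day PPFD (umol m^-2 s^-1) reaching each
    ground voxel.  Every unoccupied voxel whose light exceeds the
    compensation threshold recruits one individual at DBH = 1 cm.  The
    seedling bank mixes uniform external seed rain over all species with a
    contribution from reproductively mature trees (dbh >= maturity_dbh) in
    the domain, weighted ``mature_weight * sqrt(stems)`` — the square root
    damps the dominant's seed shadow so rare species stay in the bank.

    Returns the new slots.
    """
    empty = grid.occ < 0
    lit = ground_light >= compensation
    sites = np.argwhere(empty & lit)
    if len(sites) == 0:
        return []

    weights = np.ones(len(table), dtype=float)
    live = grid.living_indices()
    if len(live):
        mature = live[grid.dbh[live] >= table.maturity_dbh[grid.species_idx[live]]]
        if len(mature):
            counts = np.bincount(grid.species_idx[mature], minlength=len(table))
            weights = weights + mature_weight * np.sqrt(counts)
    weights = weights / weights.sum()

    geom = init_geometry or {}
    choices = rng.choice(len(table), size=len(sites), p=weights)
    new_slots = []
    for (x, y), sp in zip(sites, choices):
        new_slots.append(grid.add_tree(int(sp), int(x), int(y), dbh=1.0, **geom))
    grid.n_recruited += len(new_slots)
    return new_slots
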