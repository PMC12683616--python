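"""Tree carbon balance: allometry, canopy light, photosynthesis, allocation.

The monthly carbon balance follows the usual gap-model chain: Beer-Lambert
attenuation of photosynthetic photon flux density (PPFD) down voxel
columns, gross photosynthesis as the minimum of a Rubisco-limited and an
RuBP-regeneration(light)-limited rate, maintenance respiration for leaves,
stems and roots, growth respiration proportional to the surplus, and fixed
fractional allocation of the resulting net primary production (NPP) to
wood, canopy and belowground pools.  Leaf-level capacities (Vcmax and dark
respiration) are derived from leaf nitrogen, phosphorus and LMA by
log-linear trait relationships; when leaf %P is unmeasured the same
relationship is used with the %P term dropped and its mean contribution
folded into the intercept.

Coefficient values are package defaults recorded in
:class:`PhysiologyParams`; the structural forms are the contract, the
constants are tunables exposed through the run configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import ForestGrid, Forcing, SpeciesTable, SpeciesTraits, Tree

__all__ = [
    "PhysiologyParams",
    "allometric_height",
    "crown_radius_from_dbh",
    "crown_depth_from_height",
    "light_field",
    "monthly_npp",
    "allocate_and_grow",
]

SECONDS_PER_SLOT = 1800.0  # one half-hour
DAYS_PER_MONTH = 30.0
KGC_PER_UMOL = 12.0e-9  # umol C -> kg C
CARBON_FRACTION = 0.5  # kg C per kg dry matter


@dataclass(frozen=True)
class PhysiologyParams:
    """Carbon-balance parameters.

    phi : apparent quantum yield, mol C (mol photon)^-1; the uncertainty
        range explored is (0.04, 0.09).
    f_below, f_wood, f_canopy : NPP allocation fractions, summing to 1.
    medlyn_g1 : stomatal slope (kPa^0.5) of the Medlyn conductance model;
        enters as a multiplicative VPD limitation on gross photosynthesis.
    k_ext : canopy extinction coefficient for Beer-Lambert attenuation.
    resp_leaf_frac : leaf dark respiration as a fraction of Vcmax.
    resp_stem_coef : stem maintenance respiration per sapwood volume,
        kg C m^-3 month^-1 at 25 degC.
    resp_below_scale : belowground maintenance scaled to aboveground.
    resp_growth_frac : growth respiration fraction of the surplus.
    size_threshold_frac : fraction of the species' asymptotic stature above
        which wood allocation is reduced by ``wood_reduction_factor``.
    vcmax_n_slope : Vcmax25 per unit leaf N per area (umol CO2 g N^-1 s^-1).
    q10 : temperature sensitivity of metabolic rates.
    form_factor : stem volume = form_factor * (pi/4) * (D/100)^2 * H.
    lai_max : cap on within-crown leaf area index.
    """

    phi: float = 0.06
    f_below: float = 0.25
    f_wood: float = 0.45
    f_canopy: float = 0.30
    medlyn_g1: float = 3.77
    k_ext: float = 0.5
    resp_leaf_frac: float = 0.015
    resp_stem_coef: float = 0.8
    resp_below_scale: float = 0.5
    resp_growth_frac: float = 0.25
    size_threshold_frac: float = 0.66
    wood_reduction_factor: float = 0.5
    vcmax_n_slope: float = 3.5
    vcmax_intercept: float = 2.0
    vcmax_p_ref: float = 0.15
    vcmax_p_strength: float = 0.3
    q10: float = 2.0
    form_factor: float = 0.6
    lai_max: float = 6.0

    def __post_init__(self) -> None:
        s = self.f_below + self.f_wood + self.f_canopy
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"allocation fractions must sum to 1, got {s}")
        for name in ("f_below", "f_wood", "f_canopy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.phi <= 0.1:
            raise ValueError(f"phi must be in (0, 0.1], got {self.phi}")

    def with_allocation(self, f_below: float, f_wood: float, f_canopy: float) -> "PhysiologyParams":
        return replace(self, f_below=f_below, f_wood=f_wood, f_canopy=f_canopy)


# -- allometry ---------------------------------------------------------


def allometric_height(dbh, traits: SpeciesTraits):
    """Tree height (m) from DBH (cm): H = a D^b / (k + D^b).

    Generalised Michaelis-Menten form; monotone in D, asymptote ``allom_a``.
    """
    dbh = np.asarray(dbh, dtype=float)
    if (dbh <= 0).any():
        raise ValueError("dbh must be positive")
    db = dbh**traits.allom_b
    return traits.allom_a * db / (traits.allom_k + db)


def _height_arrays(dbh: np.ndarray, a: np.ndarray, b: np.ndarray, k: np.ndarray) -> np.ndarray:
    db = dbh**b
    return a * db / (k + db)


def crown_radius_from_dbh(dbh, coef: float = 0.5, exponent: float = 0.6):
    """Crown radius (m) from DBH (cm), power-law CR = coef * D^exponent."""
    return coef * np.asarray(dbh, dtype=float) ** exponent


def crown_depth_from_height(height, frac: float = 0.2, minimum: float = 1.0):
    """Crown depth (m): a fixed fraction of height, at least one voxel."""
    return np.maximum(minimum, frac * np.asarray(height, dtype=float))


def species_max_dbh(traits: SpeciesTraits, height_frac: float = 0.9) -> float:
    """DBH at which the species reaches ``height_frac`` of its asymptotic
    height; used as the reference stature for the wood-allocation taper."""
    ratio = height_frac / (1.0 - height_frac)
    return float((ratio * traits.allom_k) ** (1.0 / traits.allom_b))


def _vcmax25(lma, leaf_n, leaf_p, p: PhysiologyParams):
    """Leaf-level Vcmax at 25 degC (umol CO2 m^-2 leaf s^-1) from traits.

    Narea = leaf %N/100 * LMA.  The %P modifier is centred at
    ``vcmax_p_ref``; for species without %P the modifier is identically 1
    (its mean effect is already in the intercept).
    """
    lma = np.asarray(lma, dtype=float)
    leaf_n = np.asarray(leaf_n, dtype=float)
    leaf_p = np.asarray(leaf_p, dtype=float)
    narea = leaf_n / 100.0 * lma  # g N m^-2
    vc = p.vcmax_intercept + p.vcmax_n_slope * narea
    with np.errstate(invalid="ignore"):
        p_mod = 1.0 + p.vcmax_p_strength * np.log(leaf_p / p.vcmax_p_ref)
    p_mod = np.where(np.isnan(leaf_p), 1.0, np.clip(p_mod, 0.5, 1.5))
    return vc * p_mod


def saturating_leaf_area(leaf_area, crown_radius, k_ext: float):
    """Sunlit-equivalent leaf area bounding the Rubisco-limited rate.

    Leaves deep in the crown are too shaded to run at Vcmax, so the
    light-saturated rate scales with min(LA, A_crown * (1 - e^-k*LAI)/k)
    rather than with total leaf area.
    """
    leaf_area = np.asarray(leaf_area, dtype=float)
    area = np.pi * np.maximum(np.asarray(crown_radius, dtype=float), 0.5) ** 2
    lai = leaf_area / area
    return np.minimum(leaf_area, area * (1.0 - np.exp(-k_ext * lai)) / k_ext)


def _temp_factor(temp_c, q10: float):
    return q10 ** ((np.asarray(temp_c, dtype=float) - 25.0) / 10.0)


def _vpd_factor(vpd_kpa, g1: float):
    """Medlyn-style stomatal limitation: g ~ 1 + g1/sqrt(D) implies the
    assimilation discount 1/(1 + sqrt(D)/g1)."""
    return 1.0 / (1.0 + np.sqrt(np.maximum(np.asarray(vpd_kpa, dtype=float), 1e-3)) / g1)


# -- canopy light ------------------------------------------------------


def _crown_cells(grid: ForestGrid):
    """Flat (z, column) indices, leaf area weights and owning-tree rows for
    every crown voxel of every living tree.

    Crowns are "umbrella" disks: one-voxel-thick layers spanning the crown
    depth below the tree top, uniform leaf area density, toroidal footprint
    wrap when the grid is toroidal.
    """
    from .grid import disk_offsets

    nz = grid.height
    w, l = grid.width, grid.length
    live = grid.living_indices()
    if len(live) == 0:
        return live, (np.empty(0, np.int64), np.empty(0), np.empty(0, np.int64))

    r_int = np.maximum(0, np.floor(grid.crown_radius[live])).astype(np.int64)
    z_top = np.clip(np.round(grid.height_m[live]).astype(np.int64), 1, nz)
    n_layers = np.clip(np.round(grid.crown_depth[live]).astype(np.int64), 1, z_top)
    cells_by_radius = np.array([len(disk_offsets(float(r))) for r in range(int(r_int.max()) + 1)])
    n_cells = cells_by_radius[r_int]
    la_per_cell = grid.leaf_area[live] / (n_cells * n_layers)

    idx_parts, w_parts, row_parts = [], [], []
    rows = np.arange(len(live))
    for r in np.unique(r_int):
        sel = r_int == r
        offs = disk_offsets(float(r))
        m = len(offs)
        xs = grid.x[live][sel][:, None] + offs[:, 0]
        ys = grid.y[live][sel][:, None] + offs[:, 1]
        if grid.toroidal:
            xs, ys = xs % w, ys % l
        else:
            xs, ys = np.clip(xs, 0, w - 1), np.clip(ys, 0, l - 1)
        cols = (xs * l + ys).astype(np.int64)
        zt, nl, vals, rr = z_top[sel], n_layers[sel], la_per_cell[sel], rows[sel]
        for j in range(int(nl.max())):
            has = nl > j
            z = zt[has] - 1 - j
            flat = (z[:, None] * (w * l) + cols[has]).ravel()
            idx_parts.append(flat)
            w_parts.append(np.repeat(vals[has], m))
            row_parts.append(np.repeat(rr[has], m))
    return live, (
        np.concatenate(idx_parts),
        np.concatenate(w_parts),
        np.concatenate(row_parts),
    )


def light_field(grid: ForestGrid, k_ext: float = 0.5) -> np.ndarray:
    """Cumulative leaf area index at-and-above each voxel level.

    Returns ``lai_above`` of shape (height + 1, width, length) where
    ``lai_above[z]`` is the total LAI in layers z and higher, so the PPFD
    transmitted to the *top* of layer z is ``exp(-k_ext * lai_above[z+1])``
    and the flux reaching the ground is ``exp(-k_ext * lai_above[0])``.
    """
    nz = grid.height
    w, l = grid.width, grid.length
    live, (idx, wts, _) = _crown_cells(grid)
    out = np.zeros((nz + 1, w, l))
    if len(live) == 0:
        return out
    lai = np.bincount(idx, weights=wts, minlength=nz * w * l).reshape(nz, w, l)
    out[:nz] = np.cumsum(lai[::-1], axis=0)[::-1]
    return out


def canopy_light(grid: ForestGrid, k_ext: float):
    """Per-tree absorbed-light coefficients with column conservation.

    Returns ``(coef, ground_trans)`` where ``coef[i]`` (m^2 of fully
    absorbing equivalent area, ordered as ``grid.living_indices()``) gives
    the crown's absorbed flux ``coef * I0`` for incident top-of-canopy
    PPFD I0, and ``ground_trans`` is the (width, length) transmission
    factor reaching the ground.

    Within each 1 m column the incident flux is attenuated by
    Beer-Lambert over the stacked crown layers and the flux absorbed in a
    voxel is attributed to the trees owning leaf area there in proportion
    to their LAI share, so the summed absorption in any column never
    exceeds the incident flux.
    """
    nz = grid.height
    w, l = grid.width, grid.length
    live, (idx, wts, rows) = _crown_cells(grid)
    if len(live) == 0:
        return np.empty(0), np.ones((w, l))
    # restrict the vertical work to the occupied layers
    nz_used = int(idx.max() // (w * l)) + 1 if len(idx) else 1
    lai_flat = np.bincount(idx, weights=wts, minlength=nz_used * w * l)
    lai = lai_flat.reshape(nz_used, w * l)
    above = np.zeros((nz_used + 1, w * l))
    above[:nz_used] = np.cumsum(lai[::-1], axis=0)[::-1]
    trans = np.exp(-k_ext * above)
    # flux entering layer z from above is exp(-k*above[z+1]); leaving is
    # exp(-k*above[z]); the difference is absorbed within layer z
    absorbed = trans[1:] - trans[:nz_used]  # (nz_used, w*l), nonnegative
    with np.errstate(invalid="ignore", divide="ignore"):
        per_lai = np.where(lai_flat > 0, absorbed.ravel() / lai_flat, 0.0)
    coef = np.bincount(rows, weights=wts * per_lai[idx], minlength=len(live))
    ground_trans = trans[0].reshape(w, l)
    return coef, ground_trans


def absorbed_fraction(grid: ForestGrid, lai_above: np.ndarray | None, k_ext: float) -> np.ndarray:
    """Per-living-tree absorbed-light coefficient (see :func:`canopy_light`)."""
    return canopy_light(grid, k_ext)[0]


# -- monthly carbon balance -------------------------------------------


def gpp_umol_slots(
    absorbed_coef: np.ndarray,
    vcmax_tree: np.ndarray,
    month: int,
    forcing: Forcing,
    p: PhysiologyParams,
) -> np.ndarray:
    """Gross photosynthesis (umol C s^-1) per tree per half-hour slot.

    A_j = phi * absorbed PPFD (light/RuBP-regeneration limited);
    A_c = Vcmax-limited rate scaled by Q10 temperature response; the
    realised rate is min(A_j, A_c) discounted by the Medlyn VPD factor.
    Shapes: absorbed_coef (n,), returns (n, 48).
    """
    i0 = forcing.ppfd[month]  # (48,)
    ft = _temp_factor(forcing.temperature[month], p.q10)
    fv = _vpd_factor(forcing.vpd[month], p.medlyn_g1)
    a_j = p.phi * absorbed_coef[:, None] * i0[None, :]
    a_c = vcmax_tree[:, None] * ft[None, :]
    return np.minimum(a_j, a_c) * fv[None, :]


def monthly_carbon_balance(
    absorbed_coef: np.ndarray,
    vcmax_tree: np.ndarray,
    leaf_area: np.ndarray,
    stem_volume: np.ndarray,
    month: int,
    forcing: Forcing,
    p: PhysiologyParams,
) -> tuple[np.ndarray, np.ndarray]:
    """(gpp, npp) in kg C per tree for one month (vectorised).

    NPP = GPP - R_leaf - R_stem - R_below - R_growth; may be negative.
    """
    gpp_slots = gpp_umol_slots(absorbed_coef, vcmax_tree, month, forcing, p)
    gpp = gpp_slots.sum(axis=1) * SECONDS_PER_SLOT * DAYS_PER_MONTH * KGC_PER_UMOL

    ft_mean = _temp_factor(forcing.temperature[month], p.q10).mean()
    # leaf dark respiration: fraction of Vcmax, per leaf area, all month
    r_leaf = (
        p.resp_leaf_frac
        * _vcmax25_per_area(vcmax_tree, leaf_area)
        * leaf_area
        * ft_mean
        * 86400.0
        * DAYS_PER_MONTH
        * KGC_PER_UMOL
    )
    r_stem = p.resp_stem_coef * stem_volume * ft_mean
    r_below = p.resp_below_scale * (r_leaf + r_stem)
    r_maint = r_leaf + r_stem + r_below
    r_growth = p.resp_growth_frac * np.maximum(0.0, gpp - r_maint)
    npp = gpp - r_maint - r_growth
    return gpp, npp


def _vcmax25_per_area(vcmax_tree: np.ndarray, leaf_area: np.ndarray) -> np.ndarray:
    return vcmax_tree / np.maximum(leaf_area, 1e-9)


def monthly_npp(
    tree: Tree,
    absorbed_ppfd: np.ndarray,
    forcing: Forcing,
    p: PhysiologyParams,
    month: int = 0,
) -> float:
    """Single-tree monthly NPP (kg C) given the absorbed PPFD per slot.

    ``absorbed_ppfd`` is the crown-absorbed photon flux (umol s^-1) in each
    of the month's 48 half-hour slots.  This is the scalar contract used by
    tests and examples; the engine runs the vectorised equivalent.
    """
    absorbed_ppfd = np.asarray(absorbed_ppfd, dtype=float)
    if absorbed_ppfd.shape != (48,):
        raise ValueError("absorbed_ppfd must provide 48 half-hourly slots")
    tr = tree.species
    vcmax_area = _vcmax25(tr.lma, tr.leaf_n, tr.leaf_p, p)
    vcmax_tree = float(vcmax_area) * max(
        float(saturating_leaf_area(tree.leaf_area, tree.crown_radius, p.k_ext)), 1e-9
    )

    ft = _temp_factor(forcing.temperature[month], p.q10)
    fv = _vpd_factor(forcing.vpd[month], p.medlyn_g1)
    a_j = p.phi * absorbed_ppfd
    a_c = vcmax_tree * ft
    gpp_slots = np.minimum(a_j, a_c) * fv
    gpp = gpp_slots.sum() * SECONDS_PER_SLOT * DAYS_PER_MONTH * KGC_PER_UMOL

    stem_vol = p.form_factor * np.pi / 4.0 * (tree.dbh / 100.0) ** 2 * tree.height
    ft_mean = ft.mean()
    r_leaf = (
        p.resp_leaf_frac
        * vcmax_area
        * tree.leaf_area
        * ft_mean
        * 86400.0
        * DAYS_PER_MONTH
        * KGC_PER_UMOL
    )
    r_stem = p.resp_stem_coef * stem_vol * ft_mean
    r_below = p.resp_below_scale * (r_leaf + r_stem)
    r_maint = r_leaf + r_stem + r_below
    r_growth = p.resp_growth_frac * max(0.0, gpp - r_maint)
    return float(gpp - r_maint - r_growth)


# -- allocation and geometry update -----------------------------------


def stem_volume(dbh_cm, height_m, form_factor: float):
    return form_factor * np.pi / 4.0 * (np.asarray(dbh_cm) / 100.0) ** 2 * np.asarray(height_m)


def dbh_from_wood_mass(wood_kg, height_m, wsg, form_factor: float):
    """Invert the stem-volume relation for DBH (cm) at a given height."""
    vol = np.asarray(wood_kg) / (np.asarray(wsg) * 1000.0)
    d_m = np.sqrt(4.0 * vol / (np.pi * form_factor * np.maximum(np.asarray(height_m), 0.1)))
    return d_m * 100.0


def allocate_and_grow(tree: Tree, npp: float, p: PhysiologyParams) -> Tree:
    """Apply one month's NPP to a single tree (contract-level scalar path).

    Non-positive NPP increments the starvation counter and leaves geometry
    untouched.  Positive NPP is split f_wood / f_canopy / f_below, the wood
    share halved (``wood_reduction_factor``) above the species size
    threshold; wood mass then drives DBH, height, crown radius and crown
    depth through the allometries.  DBH never decreases.
    """
    tr = tree.species
    if npp <= 0.0:
        tree.npp_negative_months += 1
        return tree
    tree.npp_negative_months = 0
    f_wood = p.f_wood
    d_thresh = p.size_threshold_frac * species_max_dbh(tr)
    if tree.dbh > d_thresh:
        f_wood = f_wood * p.wood_reduction_factor
    wood_c = f_wood * npp
    canopy_c = p.f_canopy * npp

    wsg = tr.wsg
    old_wood = stem_volume(tree.dbh, tree.height, p.form_factor) * wsg * 1000.0
    new_wood = old_wood + wood_c / CARBON_FRACTION
    # joint (D, H) consistent with the new mass: fixed-point iteration on
    # D -> H(D) -> D(new_wood, H) converges in a handful of steps
    new_dbh, new_h = tree.dbh, tree.height
    for _ in range(8):
        new_h = max(tree.height, float(allometric_height(max(new_dbh, 1.0), tr)))
        new_dbh = float(dbh_from_wood_mass(new_wood, new_h, wsg, p.form_factor))
    tree.dbh = max(tree.dbh, new_dbh)
    tree.height = max(tree.height, float(allometric_height(tree.dbh, tr)))
    tree.crown_radius = float(crown_radius_from_dbh(tree.dbh))
    tree.crown_depth = float(crown_depth_from_height(tree.height))
    tree.leaf_area += canopy_c / CARBON_FRACTION / (tr.lma / 1000.0)
    crown_area = np.pi * max(tree.crown_radius, 0.5) ** 2
    tree.leaf_area = float(min(tree.leaf_area, p.lai_max * crown_area))
    return tree


def compensation_ppfd(p: PhysiologyParams, traits_lma: float = 100.0) -> float:
    """Mean-day PPFD (umol m^-2 s^-1) below which a 1 cm recruit cannot
    sustain positive NPP; simple closed form from the quantum yield and a
    nominal seedling respiration load."""
    # seedling: leaf_area ~ 0.5 m^2, maintenance ~ 2e-4 kg C month^-1
    maint = 2.0e-4
    seconds = 12 * 3600 * DAYS_PER_MONTH  # lit seconds per month
    return maint / (p.phi * 0.5 * seconds * KGC_PER_UMOL)
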