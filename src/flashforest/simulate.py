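"""The monthly simulation loop and its run-level outputs.

Order of operations each month: carbon balance and growth, stage-1
mortality (background + starvation), stage-2 treefall (with secondary
crushing), lightning (third stage, when enabled), then recruitment — so
voxels vacated by any death become available the same month.

The engine is array-based: all per-tree quantities live in the
:class:`~flashforest.grid.ForestGrid` arrays and every stage is a
vectorised draw, so fixed seeds give bit-reproducible runs (voxel
iteration is row-major wherever order matters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demography, physiology
from .demography import MortalityParams
from .grid import Forcing, ForestGrid, SpeciesTable, build_grid
from .lightning import LightningParams, apply_strike, sample_strikes
from .physiology import PhysiologyParams

__all__ = ["RunOutputs", "Simulator", "run_simulation"]

DBH_CLASS_EDGES = np.array([1.0, 10.0, 30.0, 60.0, np.inf])


@dataclass
class RunOutputs:
    """Equilibrium outputs of one run, averaged over the final window.

    agb : aboveground biomass, Mg ha^-1.
    gpp : gross primary production, Mg C ha^-1 yr^-1.
    n10, n30, n60 : stems with DBH > 10 / 30 / 60 cm in the domain.
    strikes, lightning_kills : totals over the full run.
    kills_per_strike : lightning kills per strike over the window.
    species_agb : per-species AGB (Mg ha^-1), window average.
    annual : per-year table of the state trajectory.
    """

    agb: float
    gpp: float
    n10: float
    n30: float
    n60: float
    strikes: int
    lightning_kills: int
    kills_per_strike: float
    species_agb: pd.Series
    annual: pd.DataFrame
    deaths_by_cause: dict[str, int] = field(default_factory=dict)
    kills_by_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("agb", "gpp", "n10", "n30", "n60"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.n60 <= self.n30 <= self.n10:
            raise ValueError("size-class counts must nest: n60 <= n30 <= n10")

    def metrics(self) -> dict[str, float]:
        return {
            "agb": self.agb,
            "gpp": self.gpp,
            "n10": self.n10,
            "n30": self.n30,
            "n60": self.n60,
        }


class Simulator:
    """One forest stand, stepped monthly.

    Parameters
    ----------
    table : species-trait table.
    forcing : half-hourly climatology (12 x 48).
    phys, mort, lightning : process parameters; lightning.mode selects
        none / CLLR / SSLR.
    width, length, height : domain size, m.
    seed : RNG seed; two runs with identical config and seed are
        bit-identical.
    lam_schedule : optional callable month-index -> lambda, overriding the
        constant ``lightning.lam`` (used for transient frequency ramps).
    """

    def __init__(
        self,
        table: SpeciesTable,
        forcing: Forcing,
        *,
        phys: PhysiologyParams = PhysiologyParams(),
        mort: MortalityParams = MortalityParams(),
        lightning: LightningParams = LightningParams(mode="none"),
        width: int = 200,
        length: int = 200,
        height: int = 50,
        seed: int = 0,
        toroidal: bool = True,
        lam_schedule=None,
        light_update_months: int = 1,
    ):
        self.table = table
        self.forcing = forcing
        self.phys = phys
        self.mort = mort
        self.lightning = lightning
        self.lam_schedule = lam_schedule
        self.light_update_months = int(light_update_months)
        # independent streams for demography and lightning: runs that
        # differ only in the lightning configuration stay demographically
        # synchronised until lightning itself changes the stand, which
        # makes paired frequency comparisons far less noisy
        _demo_ss, _light_ss = np.random.SeedSequence(seed).spawn(2)
        self.rng = np.random.default_rng(_demo_ss)
        self.rng_lightning = np.random.default_rng(_light_ss)
        self.seed = seed
        self.grid = build_grid(width, length, height, toroidal=toroidal)
        self.month_index = 0

        self._vcmax_area = physiology._vcmax25(
            table.lma, table.leaf_n, table.leaf_p, phys
        )  # per species, umol m^-2 s^-1
        self._lai_above = None
        self._absorbed_coef = None
        self._ground_light_mean = None

        self.strikes_total = 0
        self.kills_total = 0
        self.deaths = {"background": 0, "starvation": 0, "treefall_primary": 0,
                       "treefall_secondary": 0, "lightning": 0}
        self.kills_by_class = np.zeros(len(DBH_CLASS_EDGES) - 1, dtype=np.int64)
        self.kills_by_species = np.zeros(len(table), dtype=np.int64)
        self.event_log: list[dict] = []
        self._annual_rows: list[dict] = []
        self._gpp_accum_kg = 0.0
        self._monthly_strikes = 0
        self._monthly_kills = 0

    # -- initialisation ------------------------------------------------

    def initialise_bare(self) -> None:
        """Bare-ground start: every voxel recruits a random species sapling."""
        g = self.grid
        n = g.n_ground_voxels
        sp = self.rng.integers(0, len(self.table), size=n)
        k = 0
        for x in range(g.width):
            for y in range(g.length):
                self._add_sapling(int(sp[k]), x, y)
                k += 1
        g.n_initial = g.n_trees

    def _add_sapling(self, sp: int, x: int, y: int) -> int:
        tr = self.table[sp]
        h = float(physiology.allometric_height(1.0, tr))
        return self.grid.add_tree(
            sp,
            x,
            y,
            dbh=1.0,
            height=max(1.0, h),
            crown_radius=float(physiology.crown_radius_from_dbh(1.0)),
            crown_depth=1.0,
            leaf_area=0.5,
            wood_mass=physiology.stem_volume(1.0, max(1.0, h), self.phys.form_factor)
            * tr.wsg
            * 1000.0,
            canopy_mass=0.05,
        )

    # -- monthly step --------------------------------------------------

    def step_month(self) -> None:
        month = self.month_index % 12
        self._monthly_strikes = 0
        self._monthly_kills = 0
        self._update_light(month)
        self._growth(month)
        self._stage1()
        self._stage2()
        self._stage3_lightning()
        self._recruitment()
        self.month_index += 1
        if self.month_index % 12 == 0:
            self._record_year()

    def _update_light(self, month: int) -> None:
        if self._absorbed_coef is None or (self.month_index % self.light_update_months == 0):
            coef, ground_trans = physiology.canopy_light(self.grid, self.phys.k_ext)
            self._absorbed_coef = coef
            self._coef_live = self.grid.living_indices()
            self._ground_trans = ground_trans
        day = self.forcing.ppfd[month] > 0
        mean_day_ppfd = self.forcing.ppfd[month][day].mean() if day.any() else 0.0
        self._ground_light_mean = self._ground_trans * mean_day_ppfd

    def _growth(self, month: int) -> None:
        g = self.grid
        live = self._coef_live
        live = live[g.alive[live]]  # drop trees that died since the light pass
        if len(live) == 0:
            return
        coef = self._absorbed_coef[g.alive[self._coef_live]]
        la_sat = physiology.saturating_leaf_area(
            g.leaf_area[live], g.crown_radius[live], self.phys.k_ext
        )
        vcmax_tree = self._vcmax_area[g.species_idx[live]] * np.maximum(la_sat, 1e-9)
        stem_vol = physiology.stem_volume(g.dbh[live], g.height_m[live], self.phys.form_factor)
        gpp, npp = physiology.monthly_carbon_balance(
            coef, vcmax_tree, g.leaf_area[live], stem_vol, month, self.forcing, self.phys
        )
        self._gpp_accum_kg += gpp.sum()

        neg = npp <= 0.0
        g.neg_months[live[neg]] += 1
        g.neg_months[live[~neg]] = 0

        grow = live[~neg]
        if len(grow) == 0:
            self._leaf_turnover(live)
            return
        npp_pos = npp[~neg]
        sp = g.species_idx[grow]
        tr = self.table
        # wood share, tapered above the species stature threshold
        ratio = 0.9 / 0.1
        d_max = (ratio * tr.allom_k[sp]) ** (1.0 / tr.allom_b[sp])
        f_wood = np.where(
            g.dbh[grow] > self.phys.size_threshold_frac * d_max,
            self.phys.f_wood * self.phys.wood_reduction_factor,
            self.phys.f_wood,
        )
        wood_c = f_wood * npp_pos
        canopy_c = self.phys.f_canopy * npp_pos

        g.wood_mass[grow] += wood_c / physiology.CARBON_FRACTION
        new_dbh = physiology.dbh_from_wood_mass(
            g.wood_mass[grow], g.height_m[grow], tr.wsg[sp], self.phys.form_factor
        )
        g.dbh[grow] = np.maximum(g.dbh[grow], new_dbh)
        h = physiology._height_arrays(
            g.dbh[grow], tr.allom_a[sp], tr.allom_b[sp], tr.allom_k[sp]
        )
        g.height_m[grow] = np.minimum(np.maximum(g.height_m[grow], h), self.grid.height)
        g.crown_radius[grow] = physiology.crown_radius_from_dbh(g.dbh[grow])
        g.crown_depth[grow] = physiology.crown_depth_from_height(g.height_m[grow])

        g.canopy_mass[grow] += canopy_c / physiology.CARBON_FRACTION
        g.leaf_area[grow] += canopy_c / physiology.CARBON_FRACTION / (tr.lma[sp] / 1000.0)
        self._leaf_turnover(live)
        crown_area = np.pi * np.maximum(g.crown_radius[live], 0.5) ** 2
        g.leaf_area[live] = np.minimum(g.leaf_area[live], self.phys.lai_max * crown_area)

    def _leaf_turnover(self, live: np.ndarray) -> None:
        g = self.grid
        lifespan = demography.leaf_lifespan_months(self.table.lma[g.species_idx[live]])
        g.leaf_area[live] *= 1.0 - 1.0 / np.maximum(lifespan, 1.0)
        g.canopy_mass[live] *= 1.0 - 1.0 / np.maximum(lifespan, 1.0)

    def _stage1(self) -> None:
        g = self.grid
        live = g.living_indices()
        if len(live) == 0:
            return
        sp = g.species_idx[live]
        p = demography.stage1_probability_arrays(
            self.table.wsg[sp], self.table.lma[sp], g.neg_months[live], self.mort
        )
        u = self.rng.random(len(live))
        dead = live[u < p]
        starving = g.neg_months[dead] > demography.leaf_lifespan_months(
            self.table.lma[g.species_idx[dead]]
        )
        self.deaths["starvation"] += int(starving.sum())
        self.deaths["background"] += int(len(dead) - starving.sum())
        g.remove_trees(dead)

    def _stage2(self) -> None:
        g = self.grid
        live = g.living_indices()
        if len(live) == 0:
            return
        p = demography.treefall_probability(g.height_m[live], self.mort)
        u = self.rng.random(len(live))
        fallers = live[u < p]
        for slot in fallers:
            if not g.alive[slot]:
                continue  # already crushed by an earlier faller this month
            killed = demography.stage2_treefall(g, int(slot), self.mort, self.rng)
            self.deaths["treefall_primary"] += 1
            self.deaths["treefall_secondary"] += len(killed) - 1
            g.remove_trees(np.array(killed))

    def _stage3_lightning(self) -> None:
        lp = self.lightning
        if lp.mode == "none":
            return
        if self.lam_schedule is not None:
            lp = lp.with_lam(float(self.lam_schedule(self.month_index)))
        if lp.lam == 0.0:
            return
        struck = sample_strikes(self.grid, lp, self.rng_lightning)
        for voxel in struck:
            self.strikes_total += 1
            self._monthly_strikes += 1
            ev = apply_strike(
                self.grid, voxel, lp, self.rng_lightning, species_delta=self.table.delta_i
            )
            if ev.target_slot is None:
                continue
            nk = len(ev.killed_slots)
            self.kills_total += nk
            self._monthly_kills += nk
            self.deaths["lightning"] += nk
            # note: killed slots were just freed; their records are still
            # readable until the slots are reused, so tally classes now
            for s in ev.killed_slots:
                cls = int(np.searchsorted(DBH_CLASS_EDGES, self.grid.dbh[s], side="right") - 1)
                self.kills_by_class[min(cls, len(self.kills_by_class) - 1)] += 1
                self.kills_by_species[self.grid.species_idx[s]] += 1
            self.event_log.append(
                {
                    "year": self.month_index // 12,
                    "month": self.month_index % 12 + 1,
                    "x": voxel[0],
                    "y": voxel[1],
                    "target_species": self.table.ids[
                        int(self.grid.species_idx[ev.target_slot])
                    ],
                    "n_killed": nk,
                }
            )

    def _recruitment(self) -> None:
        g = self.grid
        before = g.n_trees
        sites = np.argwhere((g.occ < 0) & (self._ground_light_mean >= 20.0))
        if len(sites) == 0:
            return
        # seed rain: uniform external input plus a locally produced term
        # damped as sqrt(mature stems) — the damping keeps rare species in
        # the bank (negative density dependence) instead of letting the
        # dominant's seed shadow fix the community
        weights = np.ones(len(self.table), dtype=float)
        live = g.living_indices()
        if len(live):
            mature = live[g.dbh[live] >= self.table.maturity_dbh[g.species_idx[live]]]
            if len(mature):
                counts = np.bincount(g.species_idx[mature], minlength=len(self.table))
                weights = weights + 4.0 * np.sqrt(counts)
        weights /= weights.sum()
        choices = self.rng.choice(len(self.table), size=len(sites), p=weights)
        for (x, y), sp in zip(sites, choices):
            self._add_sapling(int(sp), int(x), int(y))
        g.n_recruited += g.n_trees - before

    # -- bookkeeping ---------------------------------------------------

    def _area_ha(self) -> float:
        return self.grid.width * self.grid.length / 10000.0

    def current_agb_mg_ha(self) -> float:
        g = self.grid
        live = g.living_indices()
        kg = (g.wood_mass[live] + g.canopy_mass[live]).sum()
        return kg / 1000.0 / self._area_ha()

    def species_agb_mg_ha(self) -> np.ndarray:
        g = self.grid
        live = g.living_indices()
        kg = np.bincount(
            g.species_idx[live],
            weights=g.wood_mass[live] + g.canopy_mass[live],
            minlength=len(self.table),
        )
        return kg / 1000.0 / self._area_ha()

    def _record_year(self) -> None:
        g = self.grid
        live = g.living_indices()
        dbh = g.dbh[live]
        row = {
            "year": self.month_index // 12,
            "agb": self.current_agb_mg_ha(),
            "gpp": self._gpp_accum_kg / 1000.0 / self._area_ha(),  # Mg C ha-1 yr-1
            "n10": int((dbh > 10.0).sum()),
            "n30": int((dbh > 30.0).sum()),
            "n60": int((dbh > 60.0).sum()),
            "n_trees": int(len(live)),
            "strikes": self.strikes_total,
            "lightning_kills": self.kills_total,
        }
        self._annual_rows.append(row)
        self._gpp_accum_kg = 0.0
        self._species_agb_snapshot = self.species_agb_mg_ha()
        if not hasattr(self, "_species_agb_rows"):
            self._species_agb_rows = []
        self._species_agb_rows.append(self._species_agb_snapshot)

    # -- run driver ----------------------------------------------------

    def run(self, years: int, *, averaging_years: int = 50, check_every: int = 12) -> RunOutputs:
        """Step ``years`` simulated years and summarise the final window."""
        if averaging_years > years:
            raise ValueError("averaging window longer than the run")
        for _ in range(years * 12):
            self.step_month()
            if check_every and self.month_index % check_every == 0:
                self.grid.check_invariants()
        return self.summarise(averaging_years)

    def summarise(self, averaging_years: int) -> RunOutputs:
        annual = pd.DataFrame(self._annual_rows)
        window = annual.tail(averaging_years)
        first = max(0, len(annual) - averaging_years - 1)
        strikes_win = int(annual["strikes"].iloc[-1] - annual["strikes"].iloc[first])
        kills_win = int(
            annual["lightning_kills"].iloc[-1] - annual["lightning_kills"].iloc[first]
        )
        sp_rows = np.array(self._species_agb_rows[-averaging_years:])
        species_agb = pd.Series(sp_rows.mean(axis=0), index=self.table.ids)
        return RunOutputs(
            agb=float(window["agb"].mean()),
            gpp=float(window["gpp"].mean()),
            n10=float(window["n10"].mean()),
            n30=float(window["n30"].mean()),
            n60=float(window["n60"].mean()),
            strikes=self.strikes_total,
            lightning_kills=self.kills_total,
            kills_per_strike=kills_win / strikes_win if strikes_win else 0.0,
            species_agb=species_agb,
            annual=annual,
            deaths_by_cause=dict(self.deaths),
            kills_by_class=self.kills_by_class.copy(),
        )


def run_simulation(
    table: SpeciesTable,
    forcing: Forcing,
    *,
    years: int = 600,
    averaging_years: int = 50,
    seed: int = 0,
    **kwargs,
) -> RunOutputs:
    """Convenience wrapper: bare-ground start, run, summarise."""
    sim = Simulator(table, forcing, seed=seed, **kwargs)
    sim.initialise_bare()
    return sim.run(years, averaging_years=averaging_years)
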