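"""Synthetic stand-ins for the model's external inputs.

The real parameterisation draws on site trait censuses, a trait database,
a half-hourly meteorological climatology, and field observations of
lightning damage.  None of those are distributable here, so this module
generates statistically plausible substitutes: a species-trait table
spanning lightning-tolerant to -intolerant strategies, a smooth diurnal
forcing climatology, and binned lightning-mortality counts drawn from
known CLLR parameters (so calibration can be validated by parameter
recovery).  All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import BinnedMortality
from .grid import Forcing
from .lightning import LightningParams, cllr_probability

__all__ = [
    "FixtureSpec",
    "gen_species",
    "gen_forcing",
    "gen_binned_mortality",
    "default_binned_mortality",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic species community.

    The default shape mirrors a tropical community in which roughly a
    quarter of species have measured lightning tolerances and about forty
    percent of those differ from the community mean: most species are
    neutral (delta_i = 0), a tolerant minority has delta_i < 0, and an
    intolerant minority delta_i > 0.  At least one tolerant species is
    tall-statured so compositional acclimation has somewhere to go.
    """

    n_species: int = 27
    fraction_tolerant: float = 0.2
    fraction_intolerant: float = 0.2
    delta_scale: float = 2.0
    seed: int = 0
    lma_range: tuple[float, float] = (40.0, 220.0)
    wsg_range: tuple[float, float] = (0.3, 0.9)
    leaf_n_range: tuple[float, float] = (1.2, 3.5)
    leaf_p_range: tuple[float, float] = (0.06, 0.25)
    allom_a_range: tuple[float, float] = (20.0, 46.0)
    allom_b_range: tuple[float, float] = (0.9, 1.2)
    allom_k_range: tuple[float, float] = (15.0, 60.0)
    maturity_range: tuple[float, float] = (5.0, 18.0)
    leaf_p_missing: float = 0.2

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.fraction_tolerant + self.fraction_intolerant > 1.0 + 1e-12:
            raise ValueError("tolerance fractions must sum to <= 1")


def gen_species(spec: FixtureSpec = FixtureSpec()) -> pd.DataFrame:
    """Synthetic species-trait table (one row per species).

    Columns match the trait-table dialect: species_id, lma, wsg, leaf_n,
    leaf_p, allom_a, allom_b, allom_k, maturity_dbh, delta_i.  Trait
    covariance is injected weakly: taller-statured species get denser wood
    (hence lower background mortality), so equilibrium stands contain
    large trees.  The tallest tolerant species is forced to be strongly
    tolerant (delta <= -delta_scale).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species

    stature = rng.uniform(0.0, 1.0, n)  # latent size axis
    lo, hi = spec.allom_a_range
    allom_a = lo + (hi - lo) * stature
    lo, hi = spec.wsg_range
    wsg = np.clip(lo + (hi - lo) * (0.35 + 0.5 * stature + 0.25 * rng.normal(size=n)), 0.25, 1.1)
    lma = rng.uniform(*spec.lma_range, n)
    leaf_n = rng.uniform(*spec.leaf_n_range, n)
    leaf_p = rng.uniform(*spec.leaf_p_range, n)
    leaf_p[rng.random(n) < spec.leaf_p_missing] = np.nan
    allom_b = rng.uniform(*spec.allom_b_range, n)
    allom_k = rng.uniform(*spec.allom_k_range, n)
    maturity = rng.uniform(*spec.maturity_range, n)

    n_tol = int(round(spec.fraction_tolerant * n))
    n_int = int(round(spec.fraction_intolerant * n))
    delta = np.zeros(n)
    # Stature-aware assignment: the very tallest species stay neutral or
    # intolerant (so dominance without lightning is not confounded with
    # tolerance), while one tall-but-not-top species is strongly tolerant —
    # the candidate that compositional acclimation can promote.
    donor = strong = None
    if n_tol and n > 1:
        # Build a controlled near-isogenic pair that isolates the
        # tolerance axis: two copies of a tall, productive, dense-wooded
        # "emergent" archetype that differ only in their lightning
        # tolerance (one neutral, one strongly tolerant).  Dense wood
        # keeps their background mortality low, so lightning is the
        # process that distinguishes their canopy survival.  The tolerant
        # twin gets the full archetype stature — emulating a forest whose
        # leading emergent is lightning-tolerant — so the species-specific
        # risk model has a resistant canopy from the start, while the
        # community-level model treats the same canopy as fully killable.
        archetype = {
            "lma": 120.0,
            "wsg": 0.85,
            "leaf_n": 3.2,
            "leaf_p": 0.18,
            "allom_a": spec.allom_a_range[1] - 1.0,
            "allom_b": 1.1,
            "allom_k": 30.0,
            "maturity": 12.0,
        }
        by_n = np.argsort(leaf_n)
        donor, strong = int(by_n[0]), int(by_n[1])
        for arrs, key in (
            (lma, "lma"), (wsg, "wsg"), (leaf_n, "leaf_n"), (leaf_p, "leaf_p"),
            (allom_a, "allom_a"), (allom_b, "allom_b"), (allom_k, "allom_k"),
            (maturity, "maturity"),
        ):
            arrs[donor] = archetype[key]
            arrs[strong] = archetype[key]
        allom_a[donor] = 0.97 * archetype["allom_a"]  # neutral twin slightly shorter
        delta[strong] = -max(spec.delta_scale, 2.0)
        delta[donor] = 0.0
        rest_pool = [i for i in range(n) if i not in (donor, strong)]
        rest_tol = rng.choice(rest_pool, size=min(n_tol - 1, len(rest_pool)), replace=False)
        delta[rest_tol.astype(int)] = -rng.uniform(0.5, spec.delta_scale, len(rest_tol))
    by_stature = np.argsort(-allom_a)  # descending
    top = by_stature[: min(3, n)]
    if n_int:
        # bias intolerance toward the tall end so high strike frequencies
        # have something to remove; the pair above stays as constructed
        candidates = [
            i for i in range(n) if delta[i] == 0.0 and i not in (donor, strong)
        ]
        candidates.sort(key=lambda i: -allom_a[i])
        chosen = candidates[:n_int]
        delta[chosen] = rng.uniform(0.5, spec.delta_scale, len(chosen))

    return pd.DataFrame(
        {
            "species_id": [f"sp{i:03d}" for i in range(n)],
            "lma": lma,
            "wsg": wsg,
            "leaf_n": leaf_n,
            "leaf_p": leaf_p,
            "allom_a": allom_a,
            "allom_b": allom_b,
            "allom_k": allom_k,
            "maturity_dbh": maturity,
            "delta_i": delta,
        }
    )


def gen_forcing(seed: int = 0) -> Forcing:
    """Smooth tropical diurnal climatology, 12 months x 48 half-hours.

    PPFD follows a sinusoidal daylight arc (06:00-18:00, zero at night)
    with a mild wet/dry seasonal modulation; temperature and VPD follow
    diurnal cycles peaking in early afternoon.  Deterministic in the seed.
    """
    rng = np.random.default_rng(seed)
    slots = np.arange(48)
    hours = (slots + 0.5) * 0.5  # slot centre, hours
    months = np.arange(12)

    seasonal = 1.0 + 0.15 * np.cos(2.0 * np.pi * (months - 2) / 12.0)
    seasonal *= 1.0 + 0.02 * rng.normal(size=12)

    day = (hours >= 6.0) & (hours < 18.0)
    arc = np.where(day, np.sin(np.pi * (hours - 6.0) / 12.0), 0.0)

    peak_ppfd = 1800.0
    ppfd = peak_ppfd * seasonal[:, None] * arc[None, :]

    t_mean, t_amp = 26.0, 4.0
    temp = t_mean + t_amp * np.sin(np.pi * (hours - 8.0) / 12.0) * (hours > 6) - 1.5 * (
        hours <= 6
    )
    temperature = np.tile(temp, (12, 1)) + 0.5 * (seasonal[:, None] - 1.0) * 10.0

    vpd = np.clip(0.25 + 1.3 * arc[None, :] * seasonal[:, None], 0.05, None)
    return Forcing(ppfd=np.maximum(ppfd, 0.0), temperature=temperature, vpd=vpd)


DEFAULT_DISTANCE_EDGES = np.array([0.0, 1.0, 5.0, 10.0, 20.0, 30.0])
DEFAULT_DBH_EDGES = np.array([10.0, 30.0, 60.0, 100.0])


def gen_binned_mortality(
    a: float,
    p_direct: float,
    d_true: float,
    n_per_cell: int | np.ndarray = 400,
    seed: int = 0,
    *,
    exact: bool = False,
) -> BinnedMortality:
    """Binned lightning-mortality counts drawn from known CLLR parameters.

    Each tree in cell (r, D) is lightning-affected with probability
    P_aff = P / (c + d_true (1 - c)) where P = P_com(r, D) and
    c = max(0.6, P) is the immediate-death share among affected trees;
    affected trees then die immediately with probability c or remain
    damaged.  This split makes the effective observation unbiased:
    E[killed + d_true * damaged] = n_trees * P for every cell, so a round
    trip through the grid search recovers (a, P_direct).

    With ``exact=True`` the expected (non-integer) counts are returned
    instead of binomial draws — the noise-free identification case.
    """
    rng = np.random.default_rng(seed)
    lp = LightningParams(a=a, p_direct=p_direct, mode="CLLR")
    edges_r, edges_d = DEFAULT_DISTANCE_EDGES, DEFAULT_DBH_EDGES
    rep_r = np.where(edges_r[:-1] == 0, 0.0, np.sqrt(edges_r[:-1] * edges_r[1:]))
    rep_d = 0.5 * (edges_d[:-1] + edges_d[1:])
    p = cllr_probability(
        np.broadcast_to(rep_r[:, None], (5, 3)), np.broadcast_to(rep_d[None, :], (5, 3)), lp
    )
    n_trees = np.broadcast_to(np.asarray(n_per_cell, dtype=float), (5, 3)).copy()

    c = np.maximum(0.6, p)
    denom = c + d_true * (1.0 - c)
    p_aff = np.where(denom > 0, p / np.maximum(denom, 1e-12), 0.0)
    p_kill = p_aff * c
    p_dam = p_aff * (1.0 - c)
    if exact:
        killed = n_trees * p_kill
        damaged = n_trees * p_dam
    else:
        killed = np.zeros((5, 3))
        damaged = np.zeros((5, 3))
        for i in range(5):
            for j in range(3):
                counts = rng.multinomial(
                    int(n_trees[i, j]),
                    [p_kill[i, j], p_dam[i, j], 1.0 - p_kill[i, j] - p_dam[i, j]],
                )
                killed[i, j], damaged[i, j] = counts[0], counts[1]
    return BinnedMortality(
        distance_edges=edges_r,
        dbh_edges=edges_d,
        n_trees=n_trees,
        n_killed=killed,
        n_damaged=damaged,
    )


def default_binned_mortality() -> BinnedMortality:
    """The package's bundled calibration fixture: a fixed, reproducible
    synthetic dataset generated from a = -3.04, P_direct = 0.85,
    d = 0.6 with 400 trees per cell.  Stands in for the field counts that
    the CLLR fit would normally consume."""
    return gen_binned_mortality(a=-3.04, p_direct=0.85, d_true=0.6, n_per_cell=400, seed=42)
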