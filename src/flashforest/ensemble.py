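"""Parameter-uncertainty propagation and the lightning-frequency sweep.

Six parameters are propagated: the apparent quantum yield phi, the
maximal baseline mortality rate m0, the belowground allocation fraction
f_below, the allocation angle theta (the wood/canopy split in cylindrical
coordinates, f_canopy/f_wood = tan(theta)), the strike frequency lambda,
and the damaged-tree death fraction d.  Draws come from the first n points
of an (unscrambled) Sobol' sequence scaled to the ranges; one simulation
is run per draw and its outputs are averaged over the final 50 years.

For runs with lightning, each draw's d re-calibrates (a, P_direct) by the
exhaustive grid search against the binned-mortality dataset, so the CLLR
model a run uses is always the one its own d implies.

The frequency sweep crosses a list of lambda values with a fixed list of
parameter sets (the same sets at every frequency), supporting the
compositional-acclimation summaries: per-tolerance-bin AGB differences
between a high and a low frequency, their empirical CDF across parameter
sets, and kills-per-strike trends.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .calibration import BinnedMortality, grid_search
from .demography import MortalityParams
from .grid import Forcing, SpeciesTable
from .lightning import LightningParams, scaling_factor
from .physiology import PhysiologyParams
from .simulate import RunOutputs, Simulator

__all__ = [
    "ParamRanges",
    "ParamSet",
    "sobol_sample",
    "allocation_from_cylindrical",
    "run_one",
    "filter_consistent",
    "lambda_sweep_manifest",
    "tolerance_binning",
    "agb_delta_summary",
    "transient_lambda",
    "SWEEP_FREQUENCIES",
]

SWEEP_FREQUENCIES = list(range(9, 24))  # 9..23 CG fl km^-2 yr^-1


@dataclass(frozen=True)
class ParamRanges:
    """Uncertainty ranges (lower, upper) for the six propagated parameters."""

    phi: tuple[float, float] = (0.04, 0.09)
    m0: tuple[float, float] = (0.0, 0.03)
    f_below: tuple[float, float] = (0.1, 0.5)
    theta: tuple[float, float] = (np.pi / 12.0, 5.0 * np.pi / 12.0)
    lam: tuple[float, float] = (10.9, 14.5)
    d: tuple[float, float] = (0.0, 1.0)

    _ORDER = ("phi", "m0", "f_below", "theta", "lam", "d")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([getattr(self, k)[0] for k in self._ORDER])
        hi = np.array([getattr(self, k)[1] for k in self._ORDER])
        return lo, hi


@dataclass(frozen=True)
class ParamSet:
    """One uncertainty draw, with the derived allocation fractions."""

    phi: float
    m0: float
    f_below: float
    theta: float
    lam: float
    d: float
    index: int = 0

    @property
    def f_wood(self) -> float:
        return allocation_from_cylindrical(self.f_below, self.theta)[0]

    @property
    def f_canopy(self) -> float:
        return allocation_from_cylindrical(self.f_below, self.theta)[1]

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "phi": self.phi,
            "m0": self.m0,
            "f_below": self.f_below,
            "theta": self.theta,
            "lam": self.lam,
            "d": self.d,
            "f_wood": self.f_wood,
            "f_canopy": self.f_canopy,
        }


def sobol_sample(n: int, ranges: ParamRanges = ParamRanges()) -> list[ParamSet]:
    """First ``n`` points of the 6-d Sobol' sequence, affinely scaled.

    Unscrambled, so the sequence is deterministic and any shorter sample
    is a prefix of a longer one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.Sobol(d=6, scramble=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-two draws
        u = sampler.random(n)
    lo, hi = ranges.bounds()
    vals = lo + u * (hi - lo)
    return [
        ParamSet(
            phi=float(v[0]),
            m0=float(v[1]),
            f_below=float(v[2]),
            theta=float(v[3]),
            lam=float(v[4]),
            d=float(v[5]),
            index=i,
        )
        for i, v in enumerate(vals)
    ]


def allocation_from_cylindrical(f_below: float, theta: float) -> tuple[float, float]:
    """(f_wood, f_canopy) from the cylindrical parameterisation.

    theta is the angle between the wood and canopy axes
    (f_canopy / f_wood = tan(theta)); the pair is scaled so that
    f_wood + f_canopy = 1 - f_below exactly.
    """
    if not 0.0 <= f_below < 1.0:
        raise ValueError(f"f_below must be in [0, 1), got {f_below}")
    if not 0.0 < theta < np.pi / 2.0:
        raise ValueError(f"theta must be strictly inside (0, pi/2), got {theta}")
    c, s = np.cos(theta), np.sin(theta)
    rest = 1.0 - f_below
    f_wood = rest * c / (c + s)
    f_canopy = rest - f_wood  # exact complement keeps the sum constraint
    return float(f_wood), float(f_canopy)


def run_seed(run_id: str, lam: float, param_index: int, base_seed: int = 0) -> int:
    """Deterministic per-run seed below 2^31, independent across runs."""
    key = f"{run_id}|{lam:.6f}|{param_index}|{base_seed}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def run_one(
    params: ParamSet,
    table: SpeciesTable,
    forcing: Forcing,
    binned: BinnedMortality,
    *,
    mode: str = "CLLR",
    lam: float | None = None,
    width: int = 100,
    length: int = 100,
    height: int = 50,
    years: int = 600,
    averaging_years: int = 50,
    seed: int | None = None,
    lam_schedule=None,
    light_update_months: int = 1,
) -> RunOutputs:
    """One full simulation for one parameter draw.

    The draw's d fixes the CLLR calibration via the grid search on
    ``binned``; phi / m0 / f_below / theta parameterise physiology and
    mortality; lambda comes from the draw unless overridden (the sweep
    overrides it).  Deterministic given ``seed``.
    """
    f_wood, f_canopy = allocation_from_cylindrical(params.f_below, params.theta)
    phys = PhysiologyParams(
        phi=params.phi, f_below=params.f_below, f_wood=f_wood, f_canopy=f_canopy
    )
    mort = MortalityParams(m0=params.m0)
    use_lam = params.lam if lam is None else float(lam)
    if mode != "none":
        cal = grid_search(binned, params.d)
        lp = LightningParams(
            lam=use_lam, a=cal.a_star, p_direct=cal.p_direct_star, d=params.d, mode=mode
        )
    else:
        lp = LightningParams(lam=0.0, mode="none")
    if seed is None:
        seed = run_seed("run", use_lam, params.index)
    sim = Simulator(
        table,
        forcing,
        phys=phys,
        mort=mort,
        lightning=lp,
        width=width,
        length=length,
        height=height,
        seed=seed,
        lam_schedule=lam_schedule,
        light_update_months=light_update_months,
    )
    sim.initialise_bare()
    return sim.run(years, averaging_years=averaging_years, check_every=0)


def filter_consistent(
    outputs: list[RunOutputs], ci: dict[str, tuple[float, float]]
) -> list[int]:
    """Indices of runs whose AGB, GPP, N10 and N60 all fall inside the
    supplied observational confidence intervals."""
    required = ("agb", "gpp", "n10", "n60")
    for k in required:
        if k not in ci:
            raise ValueError(f"missing interval for {k}")
        lo, hi = ci[k]
        if hi < lo:
            raise ValueError(f"empty interval for {k}: ({lo}, {hi})")
    keep = []
    for i, out in enumerate(outputs):
        vals = out.metrics()
        if all(ci[k][0] <= vals[k] <= ci[k][1] for k in required):
            keep.append(i)
    return keep


def lambda_sweep_manifest(
    freqs: list[float], paramsets: list[ParamSet], *, base_seed: int = 0
) -> pd.DataFrame:
    """Cross-product manifest of frequencies x parameter sets.

    The same parameter combinations are used at every strike frequency;
    each row carries a deterministic seed derived from (run id, lambda,
    parameter index).  Pure function: no RNG is consumed.
    """
    rows = []
    for lam in freqs:
        for ps in paramsets:
            run_id = f"lam{lam}_p{ps.index}"
            rows.append(
                {
                    "run_id": run_id,
                    "lam": float(lam),  # the sweep frequency, not the draw's lam
                    "param_index": ps.index,
                    **{
                        k: v
                        for k, v in ps.to_dict().items()
                        if k not in ("index", "lam")
                    },
                    "seed": run_seed(run_id, float(lam), ps.index, base_seed),
                }
            )
    return pd.DataFrame(rows)


def tolerance_binning(
    species_values: pd.Series, deltas: pd.Series | dict
) -> pd.Series:
    """Aggregate a per-species quantity into tolerant / neutral /
    intolerant bins by the scaling factor s_i.

    s_i < 0.5 (delta < 0) is tolerant, s_i = 0.5 neutral, s_i > 0.5
    intolerant; the three bins partition the species set, so the bin sums
    conserve the total.
    """
    deltas = pd.Series(deltas)
    s = deltas.reindex(species_values.index).fillna(0.0).map(scaling_factor)
    bins = pd.Series(
        np.where(s < 0.5, "tolerant", np.where(s > 0.5, "intolerant", "neutral")),
        index=species_values.index,
    )
    out = species_values.groupby(bins).sum()
    return out.reindex(["tolerant", "neutral", "intolerant"], fill_value=0.0)


def agb_delta_summary(
    sweep: pd.DataFrame,
    deltas: pd.Series | dict,
    lam_low: float,
    lam_high: float,
) -> dict:
    """Per-tolerance-bin AGB response to a frequency change.

    ``sweep`` must carry one row per run with columns ``lam``,
    ``param_index`` and per-species AGB columns prefixed ``agb:``.
    For each parameter set, computes AGB(lam_high) - AGB(lam_low) per
    tolerance bin; returns the per-set differences, their empirical CDF
    (sorted values and cumulative probabilities), and the fraction of sets
    declining in each bin.
    """
    lo = sweep[sweep["lam"] == lam_low].set_index("param_index")
    hi = sweep[sweep["lam"] == lam_high].set_index("param_index")
    if sorted(lo.index) != sorted(hi.index):
        raise ValueError("parameter sets differ between the two frequencies")
    agb_cols = [c for c in sweep.columns if c.startswith("agb:")]
    species = [c.split(":", 1)[1] for c in agb_cols]
    diffs = {b: [] for b in ("tolerant", "neutral", "intolerant", "total")}
    for idx in sorted(lo.index):
        per_sp = pd.Series(
            hi.loc[idx, agb_cols].to_numpy(dtype=float)
            - lo.loc[idx, agb_cols].to_numpy(dtype=float),
            index=species,
        )
        binned = tolerance_binning(per_sp, deltas)
        for b in ("tolerant", "neutral", "intolerant"):
            diffs[b].append(float(binned[b]))
        diffs["total"].append(float(per_sp.sum()))
    out = {"diffs": {}, "cdf": {}, "fraction_declining": {}}
    for b, vals in diffs.items():
        vals = np.asarray(vals)
        srt = np.sort(vals)
        out["diffs"][b] = vals.tolist()
        out["cdf"][b] = {
            "x": srt.tolist(),
            "p": ((np.arange(len(srt)) + 1) / len(srt)).tolist(),
        }
        out["fraction_declining"][b] = float((vals < 0).mean())
    return out


def transient_lambda(
    lam_start: float, lam_end: float, t_start: float, t_end: float
):
    """Monthly lambda(t) schedule: constant at ``lam_start`` before
    ``t_start`` (years), linear in between, constant at ``lam_end`` after.

    Returns a callable month-index -> lambda suitable for the simulator's
    ``lam_schedule`` hook.
    """
    if not t_start < t_end:
        raise ValueError("need t_start < t_end")
    if lam_start < 0 or lam_end < 0:
        raise ValueError("lambda must be nonnegative")

    def schedule(month_index: int) -> float:
        t = month_index / 12.0
        if t <= t_start:
            return lam_start
        if t >= t_end:
            return lam_end
        frac = (t - t_start) / (t_end - t_start)
        return lam_start + frac * (lam_end - lam_start)

    return schedule
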