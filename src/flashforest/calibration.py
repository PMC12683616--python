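"""Calibration of the community-level lightning risk model.

Binned field observations of lightning mortality (trees at risk, killed,
and damaged-but-alive per distance x DBH class) are matched to the CLLR
model by an exhaustive grid search.  Because the eventual fate of damaged
trees is unobserved, a free parameter d in [0, 1] converts them into an
effective observed mortality count O = killed + d * damaged; predictions
are M = n_trees * P_com(r, D) at class-representative (r, D), and the fit
minimises the scaled residual

    R(a, P_direct; d) = sum_cells (M - O)^2 / O

over the lattice a in [-7, -1] at step 0.06 and P_direct in [0, 1] at
step 0.01 (101 x 101 points, endpoints included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lightning import LightningParams, cllr_probability

__all__ = [
    "BinnedMortality",
    "CalibrationResult",
    "A_LATTICE",
    "P_LATTICE",
    "effective_observed",
    "predicted_mortalities",
    "scaled_residual",
    "goodness_of_fit",
    "grid_search",
]

log = logging.getLogger(__name__)

A_LATTICE = np.round(np.linspace(-7.0, -1.0, 101), 10)  # step 0.06
P_LATTICE = np.round(np.linspace(0.0, 1.0, 101), 10)  # step 0.01


@dataclass(frozen=True)
class BinnedMortality:
    """5 distance classes x 3 DBH classes of lightning outcomes.

    distance_edges : 6 ascending edges (m); the first class is the
        direct-hit class when its lower edge is 0.
    dbh_edges : 4 ascending edges (cm).
    n_trees, n_killed, n_damaged : (5, 3) arrays of counts, rows =
        distance classes, columns = DBH classes.
    """

    distance_edges: np.ndarray
    dbh_edges: np.ndarray
    n_trees: np.ndarray
    n_killed: np.ndarray
    n_damaged: np.ndarray

    def __post_init__(self) -> None:
        de = np.asarray(self.distance_edges, dtype=float)
        be = np.asarray(self.dbh_edges, dtype=float)
        if de.shape != (6,) or be.shape != (4,):
            raise ValueError("need 6 distance edges and 4 DBH edges (5 x 3 classes)")
        if (np.diff(de) <= 0).any() or (np.diff(be) <= 0).any():
            raise ValueError("class edges must be strictly increasing")
        for name in ("n_trees", "n_killed", "n_damaged"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (5, 3):
                raise ValueError(f"{name} must be (5, 3), got {arr.shape}")
            if (arr < 0).any():
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "distance_edges", de)
        object.__setattr__(self, "dbh_edges", be)
        if ((self.n_killed + self.n_damaged) > self.n_trees + 1e-9).any():
            raise ValueError("killed + damaged exceeds trees at risk in some cell")

    @property
    def rep_distances(self) -> np.ndarray:
        """Class-representative distances: 0 for a direct-hit class whose
        lower edge is 0, geometric midpoint sqrt(lo*hi) otherwise."""
        lo, hi = self.distance_edges[:-1], self.distance_edges[1:]
        with np.errstate(invalid="ignore"):
            mid = np.sqrt(lo * hi)
        return np.where(lo == 0.0, 0.0, mid)

    @property
    def rep_dbhs(self) -> np.ndarray:
        """Arithmetic midpoints of the DBH classes."""
        return 0.5 * (self.dbh_edges[:-1] + self.dbh_edges[1:])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinnedMortality":
        """Read the 15-row long format: distance_lo, distance_hi, dbh_lo,
        dbh_hi, n_trees, n_killed, n_damaged."""
        df = df.sort_values(["distance_lo", "dbh_lo"]).reset_index(drop=True)
        if len(df) != 15:
            raise ValueError(f"expected 15 cells (5 x 3), got {len(df)}")
        dlo = np.sort(df["distance_lo"].unique())
        dhi = np.sort(df["distance_hi"].unique())
        blo = np.sort(df["dbh_lo"].unique())
        bhi = np.sort(df["dbh_hi"].unique())
        if len(dlo) != 5 or len(blo) != 3:
            raise ValueError("need exactly 5 distance and 3 DBH classes")
        shape_arrays = {}
        for col in ("n_trees", "n_killed", "n_damaged"):
            arr = np.zeros((5, 3))
            for _, row in df.iterrows():
                i = int(np.searchsorted(dlo, row["distance_lo"]))
                j = int(np.searchsorted(blo, row["dbh_lo"]))
                arr[i, j] = row[col]
            shape_arrays[col] = arr
        return cls(
            distance_edges=np.append(dlo, dhi[-1]),
            dbh_edges=np.append(blo, bhi[-1]),
            **shape_arrays,
        )

    @classmethod
    def from_csv(cls, path) -> "BinnedMortality":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(5):
            for j in range(3):
                rows.append(
                    {
                        "distance_lo": self.distance_edges[i],
                        "distance_hi": self.distance_edges[i + 1],
                        "dbh_lo": self.dbh_edges[j],
                        "dbh_hi": self.dbh_edges[j + 1],
                        "n_trees": self.n_trees[i, j],
                        "n_killed": self.n_killed[i, j],
                        "n_damaged": self.n_damaged[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the exhaustive CLLR fit for a fixed d."""

    a_star: float
    p_direct_star: float
    r_min: float
    bias: float
    rmse: float
    d: float

    def to_dict(self) -> dict:
        return {
            "a_star": self.a_star,
            "p_direct_star": self.p_direct_star,
            "r_min": self.r_min,
            "bias": self.bias,
            "rmse": self.rmse,
            "d": self.d,
        }


def effective_observed(binned: BinnedMortality, d: float) -> np.ndarray:
    """Effective observed mortalities O = n_killed + d * n_damaged.

    The same d applies to every DBH and distance class; O may be
    non-integer and is used as-is.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"d must be in [0, 1], got {d}")
    return binned.n_killed + d * binned.n_damaged


def predicted_mortalities(binned: BinnedMortality, a: float, p_direct: float) -> np.ndarray:
    """Predicted mortalities M = n_trees * P_com at class-representative
    (distance, DBH) values."""
    lp = LightningParams(a=a, p_direct=p_direct, mode="CLLR")
    r = binned.rep_distances[:, None]
    dbh = binned.rep_dbhs[None, :]
    return binned.n_trees * cllr_probability(np.broadcast_to(r, (5, 3)), np.broadcast_to(dbh, (5, 3)), lp)


def scaled_residual(m: np.ndarray, o: np.ndarray) -> float:
    """Scaled residual R = sum (M - O)^2 / O over the cells.

    Cells with O = 0 cannot be scaled and are skipped with a warning.
    """
    m = np.asarray(m, dtype=float)
    o = np.asarray(o, dtype=float)
    mask = o > 0
    if not mask.all():
        log.warning("scaled_residual: skipping %d cell(s) with O = 0", (~mask).sum())
    return float((((m - o) ** 2)[mask] / o[mask]).sum())


def goodness_of_fit(m: np.ndarray, o: np.ndarray) -> tuple[float, float]:
    """(bias, rmse) of the fitted predictions: mean(M - O) and
    sqrt(mean((M - O)^2)) over the cells."""
    diff = np.asarray(m, dtype=float) - np.asarray(o, dtype=float)
    return float(diff.mean()), float(np.sqrt((diff**2).mean()))


def residual_lattice(binned: BinnedMortality, d: float) -> np.ndarray:
    """R evaluated on the full (a, p_direct) lattice; shape (101, 101)."""
    o = effective_observed(binned, d)
    mask = o > 0
    if not mask.all():
        log.warning("residual_lattice: %d cell(s) with O = 0 skipped", (~mask).sum())
    r = binned.rep_distances[:, None]
    dbh = binned.rep_dbhs[None, :]
    expo = (70.0 / dbh) * (r / 45.0)  # (5, 3)
    decay = 10.0 ** (A_LATTICE[:, None, None] * expo[None, :, :])  # (101, 5, 3)
    # M over the lattice: (101 a, 101 p, 5, 3)
    m = P_LATTICE[None, :, None, None] * decay[:, None, :, :] * binned.n_trees[None, None, :, :]
    resid = (m - o[None, None, :, :]) ** 2 / np.where(mask, o, 1.0)[None, None, :, :]
    resid = np.where(mask[None, None, :, :], resid, 0.0)
    return resid.sum(axis=(2, 3))


def grid_search(binned: BinnedMortality, d: float) -> CalibrationResult:
    """Exhaustive search for (a, P_direct) minimising the scaled residual.

    101 x 101 lattice (a step 0.06 on [-7, -1]; P_direct step 0.01 on
    [0, 1], endpoints included).  Ties break toward smaller |a|, then
    smaller P_direct.
    """
    o = effective_observed(binned, d)
    if (o == 0).all():
        raise ValueError("all observed mortalities are zero; nothing to fit")
    lattice = residual_lattice(binned, d)
    r_min = lattice.min()
    # tie-break: smaller |a| (A_LATTICE ascends from -7 to -1, so larger
    # index = smaller |a|), then smaller p_direct (smaller index)
    cand = np.argwhere(np.isclose(lattice, r_min, rtol=0.0, atol=1e-12))
    order = np.lexsort((cand[:, 1], -cand[:, 0]))
    ia, ip = cand[order[0]]
    a_star = float(A_LATTICE[ia])
    p_star = float(P_LATTICE[ip])
    m = predicted_mortalities(binned, a_star, p_star)
    bias, rmse = goodness_of_fit(m, o)
    return CalibrationResult(
        a_star=a_star,
        p_direct_star=p_star,
        r_min=float(lattice[ia, ip]),
        bias=bias,
        rmse=rmse,
        d=d,
    )
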