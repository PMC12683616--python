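"""A miniature lightning-frequency sweep with tolerance binning.

Runs two Sobol' parameter draws at a low and a high strike frequency
under the species-specific risk model, then reports the per-tolerance-bin
AGB response.  (The full experiment crosses 15 frequencies with 1000
parameter sets; this is the same machinery at demonstration scale.)
"""

import logging

import pandas as pd

import flashforest as ff
from flashforest.ensemble import run_one, run_seed

logging.getLogger("flashforest.calibration").setLevel(logging.ERROR)

species_frame = ff.gen_species()
species = ff.SpeciesTable.from_frame(species_frame)
deltas = pd.Series(species_frame["delta_i"].to_numpy(), index=species_frame["species_id"])
forcing = ff.gen_forcing(0)
binned = ff.default_binned_mortality()
paramsets = ff.sobol_sample(2)

rows = []
for lam in (9.0, 23.0):
    for ps in paramsets:
        out = run_one(
            ps, species, forcing, binned, mode="SSLR", lam=lam,
            width=40, length=40, years=150, averaging_years=30,
            seed=run_seed("example", lam, ps.index), light_update_months=2,
        )
        rec = {"lam": lam, "param_index": ps.index, "agb": out.agb,
               "kills_per_strike": out.kills_per_strike}
        rec.update({f"agb:{s}": v for s, v in out.species_agb.items()})
        rows.append(rec)
        print(f"lam={lam:5.1f} set={ps.index}: AGB={out.agb:6.1f} Mg/ha, "
              f"kills/strike={out.kills_per_strike:.2f}")

sweep = pd.DataFrame(rows)
summary = ff.agb_delta_summary(sweep, deltas, 9.0, 23.0)
print()
print("AGB change from lambda 9 -> 23 by tolerance bin (per parameter set):")
for bin_name in ("tolerant", "neutral", "intolerant", "total"):
    vals = ", ".join(f"{v:+.1f}" for v in summary["diffs"][bin_name])
    print(f"  {bin_name:>10}: {vals}  Mg ha^-1")
print()
print("at this demonstration scale single runs are dominated by stand-")
print("level stochasticity; the ensemble machinery aggregates many sets")
print("(and the test suite's mini-sweep shows the median tolerant gain).")
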