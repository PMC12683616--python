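# flashforest

An individual-based, spatially explicit forest dynamics model with an
explicit lightning disturbance process — for ecologists studying how
tropical forest structure and composition respond to changing
cloud-to-ground lightning frequency, and for modellers who need a
calibratable, ensemble-ready representation of lightning mortality.

Lightning is a major but under-modelled agent of large-tree death in
tropical forests.  `flashforest` simulates a voxel-discretised stand
(1 m³ voxels, at most one tree per ground voxel, 200 × 200 × 50 m by
default) with monthly growth, recruitment, and a three-stage mortality
process: background + carbon starvation, treefall, and lightning.

## The lightning risk models

Strikes occur voxel-wise with monthly probability λ·10⁻⁶/12 (λ in
CG flashes km⁻² yr⁻¹) and target the tallest tree within 15 m.  The
**community-level lightning risk (CLLR)** model gives the mortality
probability of a tree of diameter D (cm) at distance r (m) from the
struck tree as

    P_com(r, D) = P_direct · 10^( a · (70/D) · (r/45) ),    a < 0

so a direct hit kills with probability P_direct and risk decays with
distance, faster for thin stems.  The **species-specific (SSLR)** model
shifts the log₁₀-odds by a species tolerance parameter Δi:

    log10( P_i / (1−P_i) ) = log10( P_com / (1−P_com) ) + Δi

summarised by the scaling factor s_i = 1/(1+e^(−Δi)) (< 0.5 tolerant,
0.5 neutral, > 0.5 intolerant).  CLLR is calibrated to binned field
counts of killed and damaged trees by exhaustively minimising the scaled
residual R = Σ (M−O)²/O over a 101 × 101 lattice (a ∈ [−7, −1] step
0.06; P_direct ∈ [0, 1] step 0.01), where O = killed + d·damaged and
d ∈ [0, 1] is the assumed death fraction of damaged trees.

Parameter uncertainty (φ, m0, f_below, θ, λ, d) is propagated with
Sobol'-sequence ensembles, and a frequency sweep (λ = 9…23) with
tolerance-binned summaries quantifies compositional acclimation — the
shift toward lightning-tolerant species that damps the stand-level AGB
response to rising strike frequency.

## Worked example

```python
import flashforest as ff

# calibrate the CLLR model to binned mortality counts at d = 0.6
binned = ff.gen_binned_mortality(-3.04, 0.85, 0.6, n_per_cell=400, seed=42)
res = ff.grid_search(binned, d=0.6)
print(res.a_star, res.p_direct_star)   # -> -3.1 0.87

# run a 40 x 40 m stand for 150 years under CLLR at the site rate
species = ff.SpeciesTable.from_frame(ff.gen_species())
lp = ff.LightningParams(lam=12.7, a=res.a_star, p_direct=res.p_direct_star, mode="CLLR")
sim = ff.Simulator(species, ff.gen_forcing(0), lightning=lp, width=40, length=40, seed=1)
sim.initialise_bare()
out = sim.run(150, averaging_years=30)
print(round(out.agb, 1), round(out.n60, 1), out.strikes, out.lightning_kills)
# -> 773.8 14.2 4 13
```

The calibration recovers the generating parameters to within one or two
lattice steps (−3.1, 0.87 vs the true −3.04, 0.85).  The simulation
reaches a closed-canopy equilibrium near 774 Mg ha⁻¹ AGB with ~14 stems
above 60 cm DBH on the 0.16 ha domain; over 150 years it received 4
strikes that killed 13 trees, concentrated among the tallest stems.
The scripts in `examples/` walk through the risk-model algebra,
calibration, a single simulation, and a miniature frequency sweep, each
printing and explaining its numbers; `docs/methods.md` documents the
model, its parameters and its limitations.

## Command line

A thin CLI wraps the library: `flashforest simulate --config cfg.yml`,
`flashforest calibrate --data binned.csv --d 0.6`,
`flashforest synth species|forcing|mortality`, and
`flashforest ensemble design|run|summarize` / `flashforest sweep` for
manifest-driven ensembles.  Configs are flat YAML; all tables are CSV
(schemas in the module docstrings).  Exit codes: 0 success, 2 validation
error, 3 runtime invariant violation.

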