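"""Calibrate the community-level risk model against binned mortality data.

Generates synthetic binned counts (5 distance x 3 DBH classes) from known
parameters, then recovers them with the exhaustive scaled-residual grid
search at the matching damaged-death fraction d.  The printed bias and
RMSE are in trees per cell.
"""

import flashforest as ff

a_true, p_true, d_true = -3.04, 0.85, 0.6
binned = ff.gen_binned_mortality(a_true, p_true, d_true, n_per_cell=400, seed=42)

print("observed cells (killed / damaged out of trees at risk):")
frame = binned.to_frame()
print(frame.to_string(index=False))

res = ff.grid_search(binned, d=d_true)
print()
print(f"true parameters:   a = {a_true:.2f}, P_direct = {p_true:.2f}")
print(
    f"fitted parameters: a = {res.a_star:.2f}, P_direct = {res.p_direct_star:.2f} "
    f"(R = {res.r_min:.2f}, bias = {res.bias:.3f}, rmse = {res.rmse:.3f})"
)
print("the lattice resolution is 0.06 in a and 0.01 in P_direct; with a")
print("few hundred trees per cell the fit lands within a step or two of")
print("the generating parameters.")
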