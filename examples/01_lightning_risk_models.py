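"""Evaluate the two lightning mortality risk models.

Builds the community-level risk (CLLR) curve for a few tree sizes, shifts
it for a tolerant and an intolerant species (SSLR), and prints the
logistic scaling factor s_i that summarises each species' tolerance.
"""

import numpy as np

import flashforest as ff

lp = ff.LightningParams(a=-3.0, p_direct=0.85, mode="CLLR")

print("CLLR mortality probability P(r, D), a = -3, P_direct = 0.85")
print(f"{'r (m)':>6} " + " ".join(f"D={d:>3.0f}cm" for d in (10, 30, 70)))
for r in (0.0, 5.0, 10.0, 20.0):
    row = [ff.cllr_probability(r, d, lp) for d in (10.0, 30.0, 70.0)]
    print(f"{r:6.0f} " + " ".join(f"{p:7.4f}" for p in row))

print()
print("SSLR shifts the log10-odds of the community risk by delta_i:")
p_com = ff.cllr_probability(5.0, 70.0, lp)
for delta in (-2.0, 0.0, 2.0):
    p_i = ff.sslr_probability(p_com, delta)
    s_i = ff.scaling_factor(delta)
    label = "tolerant" if delta < 0 else ("neutral" if delta == 0 else "intolerant")
    print(
        f"  delta={delta:+.1f} ({label:>10}): P_i = {p_i:.4f} "
        f"(community {p_com:.4f}), s_i = {s_i:.3f}"
    )

print()
print("s_i < 0.5 marks tolerance, 0.5 neutrality, > 0.5 intolerance;")
print("a direct hit (r = 0) always has community risk P_direct.")
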