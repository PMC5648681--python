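"""Q_ST from the nested half-sib breeding design.

Simulates one trait on the 8-population x 4-sire x 4-dam design with
known variance components (V_b, V_male, V_res) = (1, 0.25, 0.75), fits
the nested random-effects model by REML and applies
Q_ST = V_b / (2 V_w + V_b) with V_w = V_male + V_res.  The generative
truth is 1/(2*1 + 1) = 1/3.
"""

from qstfst import fit_nested_ranef, pairwise_qst, qst, simulate_nested_trait

df = simulate_nested_trait(n_populations=8, sires_per_pop=4, dams_per_sire=4,
                           v_pop=1.0, v_male=0.25, v_res=0.75, seed=3)
vc = fit_nested_ranef(df)
print("REML variance components:")
print(f"  V_b (between populations)    = {vc.v_between:.3f}  (truth 1.00)")
print(f"  V_male (sires within pops)   = {vc.v_male:.3f}  (truth 0.25)")
print(f"  V_res (residual = dams+error)= {vc.v_res:.3f}  (truth 0.75)")
print(f"  Q_ST = V_b/(2 V_w + V_b)     = {qst(vc):.3f}  (truth 0.333)")

dm, log = pairwise_qst(df)
print("\npairwise Q_ST (subset refits, one estimate per population pair):")
print(dm.to_frame().round(3))
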