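# Reference half-sarcomere configuration (bullfrog sartorius, SL 2.3 um).
# Flat keys carry their unit in the name; nested geometry:/elastic:/rates:
# sections are also accepted.  Any key can be overridden on the CLI.
sarcomere_length_um: 2.3
thin_length_um: 1.0
n_monomers: 364
monomer_spacing_s0_nm: 2.73
strand_half_period_nm: 35.5
thick_length_um: 1.58
n_crowns: 50
crown_spacing_nm: 14.3
heads_per_crown: 3
d10_sim_nm: 36.5
d10_slack_nm: 37.0
myofibril_occupancy: 0.8
n_thick: 20            # 500 at production scale

Ka_pN: 65000.0         # actin filament modulus (65 pN/nm per um)
Km_pN: 132000.0        # myosin filament modulus
kappa_xb_pN_per_nm: 1.3
titin_stiffness_pN_per_nm: 0.0

dG_bind_kBT: -3.0      # binding equilibrium constant ~20
dG_stroke_kBT: -15.0
k_bind_per_s: 134.0    # titrated against tension per experiment
k_adp0_per_s: 70.0
stroke_d_nm: 10.5
delta2_nm: 1.0
cap_k23_per_s: 1000.0
cap_k32_per_s: 100.0
cap_k31_per_s: 10000.0
kBT_pN_nm: 3.96        # 287 K
dt_s: 1.0e-6

binding_reach_nm: 8.0
solve_tol_pN: 1.0e-6
record_every_s: 1.0e-3
snapshot_every_s: 0.02
snapshot_after_s: 0.2
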