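"""Translate a drift profile into forces via the overdamped Langevin picture.

gamma = k_B T / D_eff (Einstein relation) converts the drift velocity into
the mean force biasing the locus; the point of the exercise is the order
of magnitude, which lands far below the ~1 pN of cytoskeletal motors.
"""
import locusdrift as ld

ens = ld.orient(ld.synchronize(
    ld.simulate_split_cycle(ld.SimulationConfig(n_cells=200, seed=5))
))
prof = ld.compute_drift_profile(ens, "Rapid-Translocation", selection="mirror")
d_eff = ld.summarize_steps(
    ld.compute_steps(ens, "Rapid-Translocation", selection="mirror")
).d_eff

ctx = ld.PhysicalContext(temperature_K=303.0, cell_length_um=2.5)
fp = ld.force_profile(prof, d_eff, ctx)
print(f"D_eff = {d_eff:.2e} rel^2/min -> {fp.d_eff_m2_s:.2e} m^2/s")
print(f"drag gamma = {fp.gamma_kg_s:.2e} kg/s")
print(f"peak |F| = {fp.peak_force_N:.2e} N")
print(fp.annotation)
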