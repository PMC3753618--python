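"""Drift-velocity profile, equilibria and spring relaxation time.

The central object of the analysis: binned mean velocity versus relative
position, per cell-cycle interval.  Before the split the profile restores
toward mid-cell; immediately after, stable equilibria appear at the
quarter-cell positions.
"""
import locusdrift as ld

ens = ld.orient(ld.synchronize(
    ld.simulate_split_cycle(ld.SimulationConfig(n_cells=300, seed=4))
))

pre = ld.compute_drift_profile(ens, "Pre-Replication", selection="both")
for e in ld.find_equilibria(pre).stable:
    print(f"pre-split stable equilibrium at x = {e.position:+.3f}, "
          f"tau = {e.tau:.1f} min")

for selection in ("left", "right"):
    prof = ld.compute_drift_profile(ens, "Post-Segregation", selection=selection)
    for e in ld.find_equilibria(prof).stable:
        print(f"post-split {selection:5s} focus: stable equilibrium at "
              f"x = {e.position:+.3f}")

fit = ld.fit_relaxation_time(pre, x_eq=0.0)
print(f"relaxation time from v(x) slope: {fit.tau:.1f} +/- {fit.tau_se:.1f} min "
      f"(generator truth 10 min)")
# The equilibrium jumps from ~0 to ~+/-0.25 across the split while the
# spring stiffness (1/tau) stays similar: segregation is a relocation of
# the restoring potential, not a change of transport mechanism.
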