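"""Step-size statistics per cell-cycle interval on a simulated ensemble.

The mean step is the drift velocity, the step variance the effective
diffusion constant; the excess-tail statistic asks whether segregation is
driven by rare large jumps (it is not: the step distribution stays
Gaussian, the whole distribution shifts instead).
"""
import locusdrift as ld

cfg = ld.SimulationConfig(n_cells=150, seed=3)
ens = ld.orient(ld.synchronize(ld.simulate_split_cycle(cfg)))

print(f"{'interval':22s} {'v (rel/min)':>12s} {'D_eff':>10s} {'excess':>8s} {'rho1':>7s} {'n':>6s}")
for name in ld.DEFAULT_SCHEME.names:
    s = ld.summarize_steps(ld.compute_steps(ens, name, selection="right"))
    print(
        f"{name:22s} {s.v:12.4f} {s.d_eff:10.2e} {s.excess_tail:8.4f} "
        f"{s.lag1_autocorr:7.3f} {s.n:6d}"
    )
# Only the right-destined focus is kept after the split, so the
# Rapid-Translocation drift is positive (toward +1/4) while the stationary
# intervals have v ~ 0.  The excess tail stays below 0.005: the white-noise
# spring produces no surplus of large steps over the Gaussian null, and the
# small negative lag-1 step autocorrelation is the spring's signature.
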