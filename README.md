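# wormstates

Hidden-Markov-model discovery and quantification of locomotive
behavioral states — roaming, dwelling, quiescence and intermediates —
from single-animal centroid tracks.

Long recordings of a crawling animal reduce to a time series of
center-of-mass positions at ~1 Hz. `wormstates` turns such a track into
an interpretable sequence of behavioral states and quantitative
comparisons between recordings:

1. **Motion reduction.** Each triple of consecutive positions becomes a
   translation/rotation-invariant frame: a reversal bit *r* (heading
   change > 90°), a speed *s*, and tangential/radial acceleration
   (*a_t*, *a_r*) in the animal's own frame — continuous in the
   positions, and exactly invertible up to rigid motion. Speed and
   acceleration magnitudes are deskewed with asinh(*x*/*x₀*).
2. **Fat-tailed HMM.** A state is seven numbers
   (*P*_rev, μ_s, μ_a, σ²_s, σ²_a, σ²_ar, c_sa); emissions combine a
   Bernoulli reversal term with a 3-D Student's-t style density
   ∝ (1 + d²/ν)^(−(ν+1)/2), ν = 5, whose bounded likelihood ratios stop
   single outlier frames from forcing state switches. Transitions are
   governed by one lifetime τ: stay probability e^(−Δt/τ), the rest
   split evenly — with τ = 1 day a switch must overcome an 86,400-fold
   penalty per second.
3. **Unbiased state discovery.** Closed-loop fitting (forward–backward
   decode + weighted moment re-estimation, variances pooled across
   states) seeded only from the track itself by successive state
   splitting; 1-, 2- and 3-state fits compete on *excess entropy*
   S = H(p̄) − ⟨H(p_t)⟩ (bits/point), the amount of time-resolved
   structure a fit extracts.
4. **Geometry and similarity.** Discovered states form a
   probability-weighted 7-D cloud: weighted PCA, a triangularity
   statistic (convex-hull area over minimal-enclosing-triangle area)
   with a permutation test for Pareto-style archetype geometry, and
   cross-likelihood dissimilarities between recordings with
   metrification and multidimensional scaling.

A simulator generates synthetic tracks and characteristic series from
any generative state set, so the entire pipeline is testable without
recorded data. See `docs/methods.md` for the model details and design
choices.

## Worked example

Simulate one hour of three-state behavior, rediscover the states from
the series alone, and run the scramble control:

```python
import wormstates as ws

states, lifetimes = ws.three_state_example()
cfg = ws.SimConfig(states=states, lifetimes=lifetimes, duration=3600, seed=11)
seq = ws.simulate_state_sequence(cfg)
series = ws.simulate_characteristics(states, seq, seed=12)

u = ws.unbiased_fit(series, 86400.0, 1.0)
print(f"selected {u.best_m} states, excess entropy "
      f"{u.best.excess_entropy_bits:.3f} bits/point")
for st in sorted(u.best_states, key=lambda s: -s.mu_s):
    print(f"  p_rev={st.p_rev:.3f}  mu_s={st.mu_s:.2f}  "
          f"mu_a={st.mu_a:.2f}  pi={st.pi:.2f}")

null = ws.entropy_null(series, lambda s: ws.unbiased_fit(s, 86400.0, 1.0),
                       n_scrambles=5, seed=0)
print(f"scrambled null: mean {null.mean():.3f} bits/point")
```

prints

```
selected 3 states, excess entropy 1.505 bits/point
  p_rev=0.018  mu_s=3.70  mu_a=1.51  pi=0.49
  p_rev=0.329  mu_s=2.61  mu_a=1.22  pi=0.22
  p_rev=0.060  mu_s=0.25  mu_a=0.27  pi=0.29
scrambled null: mean 0.000 bits/point
```

The three discovered states recover the generating roaming
(fast, few reversals), dwelling (moderate speed, frequent reversals) and
quiescence (near-immobile) descriptions, with their occupancies `pi`;
1.5 bits/point approaches the 3-state maximum log₂ 3 ≈ 1.58, while
scrambling the frames destroys the temporal structure and the discovered
entropy collapses to zero.

## Command line

The `wormstates` command wraps the pipeline for shell use; tracks are
CSV files with columns `time_s, x_um, y_um` (gaps as missing rows or
NaN):

```bash
wormstates simulate track.csv --duration 1800 --seed 1   # synthetic track
wormstates reduce track.csv motion.csv                   # motion characteristics
wormstates fit-unbiased track.csv fit                    # fit.csv + fit.json
wormstates geometry states.csv geom.json --n-perm 10000  # triangularity
wormstates dissim track1.csv track2.csv track3.csv out/  # matrix + MDS
```

Subcommands `fit-standard`, `build-standard-states`, `rate-graph`,
`entropy-null`, `typical-segment` and `recovery-trend` cover the rest of
the pipeline; `--config` takes a YAML file of the defaults in
`wormstates.config.RunConfig`, and every output embeds the config digest
and seed.

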