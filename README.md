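# blazedtrail

Simulation and analysis toolkit for *locally-blazed* pheromone trails — the
navigation strategy of *Paratrechina longicornis* ants cooperatively carrying
a food item too large for any individual. Instead of a stable nest-to-food
trail, accompanying ants continuously lay short scent-mark bouts at the moving
load, and the carrying team follows each local cue only stochastically. The
package provides:

- **Probabilistic-Following (PF) routing** on line and grid graphs with
  unreliable per-node advice: at each node the agent obeys the local pointer
  with probability *q* and steps to a uniformly random neighbor otherwise,
  while each pointer is correct (lies on a shortest path to the target) with
  probability *p*.
- **First-passage and stretch analysis**: exact expected hitting times via the
  absorbing Markov chain of the PF kernel, Monte-Carlo batches (numba-compiled),
  stretch = hops / shortest-path hops, and *effective stretch* — the mean over
  the best 90% of runs in a scenario.
- **Experiment drivers** reproducing the model's headline behaviors: linear
  passage times under mostly-correct advice vs. exponential ones under flipped
  advice; the (p, q) effective-stretch heatmap; robustness of a fixed q = 0.8
  policy; and exponential escape times from uniformly misleading advice
  (the enclosed-obstacle geometry).
- **Scent-mark information content**: 36-bin angular histograms, plug-in
  Shannon entropy, absolute information I = log2(36) − H and load-gained
  information I = H_before − H_after, bootstrap SDs, and the bits → degrees
  precision conversion 360/2^bits.
- **Marking-event detection** from single-ant speed profiles (local minimum
  < 3.5 cm/s flanked by |a| > 30 cm/s² within 0.25 s), bout segmentation,
  binomial order-statistic confidence intervals for the median bout length,
  and extreme-bout tail probabilities.
- **Synthetic data generators** for load tracks (~10 cm persistence length),
  nest-biased marks (~1.4 marks/s), marking-dip speed profiles, and
  right-skewed bout lengths — so every pipeline stage is testable without
  field recordings.

## Worked example

```python
from blazedtrail import (SynthSpec, bin_angles, generate_load_track,
                         generate_marks, info_absolute, mark_angles,
                         precision_from_bits)

spec = SynthSpec(duration_s=300, seed=7)
track = generate_load_track(spec)
marks, _ = generate_marks(spec, track)
angles = mark_angles(track, (1e6, 0.0), marks, frame="nest")
est = info_absolute(bin_angles(angles), n_boot=10_000, seed=0)
print(f"marks: {len(marks)}  information: {est.bits:.2f} +/- {est.sd:.2f} bits/mark")
print(f"20 marks x 0.35 bits -> {precision_from_bits(20 * 0.35):.1f} degrees")
```

prints

```
marks: 409  information: 1.46 +/- 0.03 bits/mark
20 marks x 0.35 bits -> 2.8 degrees
```

409 synthetic marks laid over 300 s carry 1.46 bits each about the nest
direction (entropy reduction relative to a uniform circle, ± bootstrap SD).
If each mark transfers 0.35 bits to the carrying team, twenty marks narrow the
360° uncertainty to 360/2⁷ ≈ 2.8° — better than 5° precision within seconds of
collective marking.

More narrative scripts live in `examples/` (routing robustness, escape
times, mark detection, bout statistics); a thin CLI exposes the same
operations (`blazedtrail simulate-line|simulate-grid|escape|info|detect|bouts|synth`),
each writing CSV tables plus a JSON run log.

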