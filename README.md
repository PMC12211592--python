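# gaitspace

Gait-space analysis of multi-legged locomotion from dorsal-view landmark
tracking: per-leg oscillation phases, a hypertorus embedding of leg
coordination with a common-phase quotient metric, unsupervised gait
clustering, and the standard kinematic and static-stability measures that
accompany them.  A seeded simulator generates complete synthetic trials, so
every stage of the pipeline runs and is tested without any recordings.

The package targets researchers studying how hexapods, octopods and other
multi-legged runners coordinate their legs — in particular how coordination
reorganizes after limb loss (autotomy) and regeneration — and anyone who
wants to classify leg-coordination patterns in large tracking datasets
without committing to predefined gait labels.

## The model

For an animal with `N` legs, each tracked tarsus tip is treated as a noisy
oscillator along the fore–aft body axis. With the fore–aft position `ŷᵢ` and
velocity `v̂ᵢ` of leg `i` standardized to zero mean and unit variance, the
effective oscillation phase is

```
φᵢ(t) = atan2(−v̂ᵢ, ŷᵢ) / 2π   (mod 1)            [cycles]
```

Leg coordination is summarized by the `N − 1` adjacent-leg phase differences
`Δφᵢ = φᵢ₊₁ − φᵢ (mod 1)`, taken counterclockwise in dorsal view from the
foremost left leg. Because each `Δφᵢ` is periodic, a gait is a point on an
`(N−1)`-dimensional hypertorus. Distances between gaits quotient out the
common phase (when the cycle starts is not part of the gait): starting from
the flat unit-weight metric on the `N` leg phases, the induced metric on the
difference coordinates is

```
gᵢⱼ = min(N−i, N−j) − (N−i)(N−j)/N,     dAB = √(Σᵢⱼ gᵢⱼ xᵢ xⱼ)
```

with `xᵢ` the signed minimal circular separation per coordinate, and the
normalized distance `ΔAB = dAB / dmax`, `dmax = √(0.25 Σᵢⱼ gᵢⱼ)` (attained
when every leg pair is in antiphase). Model gaits are built in: the
eight-leg alternating tetrapod ALT = (0.5, …, 0.5), and for six legs after
loss of a diagonal leg pair, the modified tripod MT = (0.5, 0.5, 0.5, 0.5,
0.5) and the ablated tetrapod ABT = (0.5, 0.5, 0, 0.5, 0.5); ABT and MT sit
`Δ = 0.29` apart.

Empirical gait points are grouped by Ward hierarchical clustering on the
pairwise normalized gait distances, the dendrogram is cut below its highest
merges, and clusters are named after the nearest model gait via their
per-coordinate circular-mean centroids (with percentile-bootstrap confidence
intervals on cluster-to-model distances). Note that Ward linkage formally
assumes Euclidean distances; applying it to the precomputed non-Euclidean
gait distances follows common practice and is validated here on simulated
mixtures, not justified theoretically.

Alongside the gait space, the package computes the standard measures: speed
and relative speed (BL s⁻¹), path tortuosity (straightness index
`τ = d/D ≤ 1`), yaw, stride period/frequency/length from tarsus-velocity
peaks, stance/swing segmentation from caudal motion relative to the COM,
duty factors, support polygons, static stability margins (SSM/ISSM),
adjacent-leg spacing, tarsal range of motion and leg extension.

## Worked example

Simulate a six-leg trial running a modified tripod with per-stride phase
jitter, recover its gait points, and measure where it sits in gait space:

```python
import numpy as np
import gaitspace as gs

cfg = gs.SyntheticTrialConfig(gait="MT", phase_kappa=8.0, seed=42)
trial = gs.synth_trial(cfg)

points, valid, tp = gs.gait_points(trial)
metric = gs.metric_tensor(6)
abt, mt = gs.model_gaits(6)

for m in (mt, abt):
    mean, ci = gs.dataset_to_model(points[valid], m, metric, seed=42)
    print(f"mean distance to {m.name:3s}: {mean:.3f}  (95% CI {ci[0]:.3f}-{ci[1]:.3f})")

ps = gs.path_summary(trial)
print(f"speed {ps.mean_speed:.1f} mm/s ({ps.relative_speed:.1f} BL/s), "
      f"tortuosity {ps.tortuosity:.3f}")

stance = gs.stance_swing(tp.body_frame)
trace = gs.stability_trace(trial, stance.masks)
core = slice(20, -20)
print(f"modal N_support: {np.bincount(trace.n_support[core]).argmax()}, "
      f"median SSM {np.nanmedian(trace.ssm[core]):.1f} mm")
print(f"fitted phase-noise kappa: {gs.fit_kappa(points[valid]):.1f}")
```

prints

```
mean distance to MT : 0.068  (95% CI 0.066-0.069)
mean distance to ABT: 0.296  (95% CI 0.294-0.299)
speed 128.0 mm/s (8.0 BL/s), tortuosity 0.989
modal N_support: 3, median SSM 4.2 mm
fitted phase-noise kappa: 3.9
```

The trial's gait points sit close to the modified tripod and roughly the
full ABT–MT model separation away from the ablated tetrapod; the path is
nearly straight; three feet are on the ground in the typical frame, as a
tripod gait demands, with a positive stability margin; and the fitted von
Mises concentration recovers the scale of the injected phase jitter (the
per-stride jitter at κ = 8 accumulates through adjacent-leg differencing
into a wider per-frame spread, hence κ̂ ≈ 4).

The same steps are available from the shell:

```sh
gaitspace simulate trial --gait MT --seed 42 --out mt.csv
gaitspace phases mt.csv --out gaitpoints.csv
gaitspace cluster gaitpoints.csv --legs 6 --k 3 --seed 7 --out clusters.csv
gaitspace distance --a ABT --b MT --legs 6
```

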