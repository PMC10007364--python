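# lidarhar

Indoor human-activity detection with a 2D Lidar mounted on a mobile robot —
simulated end to end at desk scale.

A 2D Lidar near the floor can watch over an elderly person living alone:
a lying body at ankle height is unmistakable in a range scan, and a fall
that happened minutes ago is still detectable.  A *fixed* sensor, however,
loses its subject behind every piece of furniture.  Mounting the Lidar on a
cleaning robot fixes the coverage problem and creates a new one: the sensor
frame now moves and rotates, so scans can no longer be compared directly
against each other or against a stored background.

This package implements and evaluates that whole system in simulation:

- **`world`** — rooms as binary occupancy grids (PGM + YAML), a
  boustrophedon robot sweep, scripted human activity sequences with a
  transition-legality graph, and per-tick ground truth;
- **`footprints`** — parametric 2D body cross-sections per (activity,
  phase, sensor height): leg discs when upright, a 1.7 × 0.4 m ellipse when
  lying, nothing at all when the scan plane is above a lying torso;
- **`lidar`** — beam casting against grid + body geometry (DDA, occlusion
  for free), a four-parameter noise model (range error ±2 %, 4 % lost
  beams, 2 % spurious points, 0.04° angle jitter), and interpolation of
  every rotation to exactly N = 720 beams at 0.5°;
- **`localization`** — per scan: polar→Cartesian with the sensor pose
  composed in, `x_j = x_l + r_j cos(θ_j + ψ)`; background subtraction
  against the room map (keep points farther than δd = 0.2 m from occupied
  cells); DBSCAN (ε = 0.3 m, min 3 points); and track gating (nearest
  cluster within Δr = 0.8 m, coasting through occlusions);
- **`representation`** — subject points per tick rasterized into a 60 × 60
  Boolean grid anchored to the room frame (10 cm/pixel), or rendered as
  circles/ellipses at 1200²; sliding 2 s windows with majority labels;
- **`classifier`** — time-distributed ConvLSTM architectures implemented
  on NumPy/numba: v1 = conv(32 @ 3×3) + pool → LSTM(40) → dense(100, N_C);
  v2 = 3 conv blocks (64, 64, 32, 32, 32, 32) → same tail; softmax +
  cross-entropy + Adam (lr 0.001, batch 16), bit-deterministic per seed;
- **`evaluation`** — confusion matrices, per-class accuracy / precision /
  recall / F1, micro-averaged overall metrics, parameter-count reports,
  and a fixed-vs-mobile sensor comparison harness.

## Worked example

Reproduce a published per-class results table from its raw confusion
matrix with the metrics engine:

```python
>>> from lidarhar.evaluation import REFERENCE_CONFUSION, per_class_metrics
>>> print(per_class_metrics(REFERENCE_CONFUSION).table())
Activity             Acc    Prec     Rec      F1
crawling           99.6%   91.2%   88.3%   89.7%
falling down       99.4%   88.5%   81.2%   84.7%
getting up         98.6%   90.0%   93.4%   91.7%
lying down         99.7%   99.3%   99.0%   99.2%
running            96.9%   77.5%   73.0%   75.2%
sitting            99.0%   95.1%   93.9%   94.5%
standing           98.6%   95.3%   97.4%   96.3%
walking            95.1%   87.0%   83.4%   85.2%
unsteady walk      95.8%   85.1%   89.1%   87.0%
Overall            91.3%   91.3%   91.3%   91.3%
```

Lying-down recall is 99.0 % and falling-down recall 81.2 % at 88.5 %
precision — the numbers that matter for fall monitoring: even when the
fall event itself is missed (it lasts ~2 s and may be occluded), the
lying body is found afterwards.  (Application papers often label the
recall column "Accuracy"; the `Acc` column here is (TP+TN)/total.)

Simulate a scenario and localize the subject from the moving robot:

```python
>>> import numpy as np
>>> from lidarhar.scenarios import BenchmarkConfig, simulate_scenario
>>> from lidarhar.localization import localize_stream
>>> cfg = BenchmarkConfig()
>>> run = simulate_scenario(seed=[1, 0], cfg=cfg)       # 56 s at 10 Hz
>>> obs = localize_stream(run.scans["mobile"], run.room, cfg.loc)
>>> det = [o for o in obs if o.status == "detected"]
>>> err = [np.linalg.norm(o.location - [p.x, p.y])
...        for o, p in zip(obs, run.truth.poses) if o.status == "detected"]
>>> print(f"{len(det)}/{len(obs)} ticks detected, "
...       f"median centroid error {np.median(err):.2f} m")
558/560 ticks detected, median centroid error 0.15 m
```

The few undetected ticks are occlusion by the room's obstacles — exactly
the situations the roaming robot recovers from and a fixed corner sensor
does not.  The same pipeline is scriptable from the shell:

```sh
lidarhar simulate --out out/ --seed 1
lidarhar localize --scans out/scans_mobile.ndjson --map out/room.yaml --out out/
lidarhar train --data windows.npz --arch v1 --profile desk --out model
lidarhar evaluate --pred pred.npz --truth truth.npz --out report/
```

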