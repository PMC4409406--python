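# aquatrack

Movement-path analysis for small benthic macroinvertebrates (e.g. the
crawling isopod *Asellus aquaticus* or the swimming amphipod *Gammarus
pulex*) video-tracked in a square laboratory arena. The package covers the
whole desk side of such an experiment: detecting a fluorescent marker blob
in 1-Hz frame sequences, filtering the resulting coordinate series into
analysis-ready path segments, computing step-length / turning-angle /
resting metrics, estimating path tortuosity with the divider-method
fractal dimension, and comparing treatments with a fixed statistical
scheme. A synthetic-data module generates trajectories and rendered
frames with known ground truth, so every stage can be calibrated without
recorded video.

## The quantities at the core

For a track sampled at 1 Hz, position \((x_t, y_t)\) in cm:

* **step length** \(D_i = \lVert (x_{i+1},y_{i+1}) - (x_i,y_i) \rVert\);
  steps below the calibrated noise threshold of 1 mm are *resting*
  intervals, steps at or above it *relocations*;
* **turning angle** \(\theta\): the signed deviation from straight-line
  locomotion between successive relocation steps, in \((-180°, 180°]\),
  counterclockwise positive, analysed with circular statistics
  (circular mean, mean resultant length \(\bar R\), von Mises
  concentration \(\kappa\), Watson–Wheeler rank test);
* **fractal dimension** \(D \in [1, 2]\) by the divider method: re-trace
  the path with rulers of length \(\delta\) and regress
  \(\log L(\delta)\) on \(\log\delta\) under the power law

  \[ L(\delta) = k\,\delta^{1-D}, \]

  so \(D = 1 - \text{slope}\). \(D = 1\) is a straight line, \(D = 2\)
  plane-filling Brownian motion. The estimator averages forward and
  backward traversals per ruler and averages \(D\) over an individual's
  paths.

Paths within 10 cm of an arena wall are excluded (wall-following bias),
detection gaps split paths rather than being interpolated, and every
metric is restricted to segments with at least 5 locations.

## Worked example

Simulate a two-treatment cohort whose walkers differ only in resting-bout
occupancy (30 % vs 60 % of time resting), then run the full pipeline:

```python
from aquatrack import PipelineConfig, run_pipeline
from aquatrack.synthetic import generate_density_experiment, rest_occupancy_params
from aquatrack.io import write_trajectories

scenario = {
    "low_density":  rest_occupancy_params(0.3, n_steps=900),
    "high_density": rest_occupancy_params(0.6, n_steps=900),
}
write_trajectories(generate_density_experiment(scenario, 5, seed=0), "cohort.csv")
run_pipeline(PipelineConfig(trajectories_csv="cohort.csv", out_dir="out"))
```

`out/summary_table.csv` then contains (this exact run):

```
   treatment  n_individuals  resting_pct_mean  resting_pct_sd  step_cm_mean  fractal_D_mean
 low_density              5            39.101           4.821         0.796           1.104
high_density              5            66.060           2.977         0.813           1.106
```

and `out/comparisons.csv` the treatment contrasts:

```
           metric              test  statistic     df  p_value transform
     resting_time           welch_t   -10.6382 6.6631   0.0000
      step_length wilcoxon_rank_sum    11.0000          0.8413
fractal_dimension           welch_t    -0.3456 4.9600   0.7438  log(D-1)
    turning_angle    watson_wheeler     2.3424 2.0000   0.3100
```

Reading: the resting-time contrast (Welch's t on per-individual resting
fractions) detects the simulated effect decisively, while step length,
tortuosity and turning behaviour — which the scenario leaves unchanged —
stay null. The measured resting percentages (≈39 % and ≈66 %) sit above
the generative bout occupancies (30 %/60 %) because a moving animal's
occasional sub-millimetre step is, by construction of the noise
threshold, indistinguishable from rest; `docs/methods.md` discusses this.

The same stages are available from the shell:

```
aquatrack simulate --rest-occupancy 0.3 --rest-occupancy 0.6 --out cohort.csv
aquatrack track    --frames frames/ --out detections.csv
aquatrack paths    --detections detections.csv --out segments.csv
aquatrack fractal  --segments segments.csv --out fractal.csv
aquatrack run      --config pipeline.yaml
```

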