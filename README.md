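# fishrra

Dekadal CPUE gridding and high/low relative-resource-abundance (RRA)
classification for high-seas trawl fisheries, built around the Argentine
shortfin squid (*Illex argentinus*) fishery in the southwest Atlantic.

Commercial logbooks record where each trawl haul was set and what it caught,
but the positions are hand-entered and a non-trivial share disagrees with
the vessel's AIS/VMS track. This package implements the full analysis chain
a fisheries lab needs to turn such records into short-term abundance
forecasts:

1. **Logbook QC** — match every haul to the vessel fix nearest its set time
   and replace the logged position when the latitude or longitude
   discrepancy exceeds 0.3° (≈15 n.mi., beyond what a trawler covers in one
   2–5 h haul at 3–6 kn).
2. **CPUE gridding** — aggregate hauls on a 0.1° × 0.1° lattice per dekad
   (each month split into days 1–10 / 11–20 / 21–end):
   `CPUE_{i,j,t} = Σ_k C_{i,j,t,k} / Σ_k E_{i,j,t,k}` with per-haul effort
   (`E = 1`, so CPUE is t/net), plus catch-weighted centroids
   `X = Σ C_i X_i / Σ C_i`, `Y = Σ C_i Y_i / Σ C_i`.
3. **RRA labeling** — cells with CPUE above the global median are "high"
   RRA, the rest "low".
4. **Predictor ranking** — nine candidates (SST, SSS, SSH, Chl-a, 50 m and
   100 m temperature, mixed layer depth, Lon, Lat) are ranked by the
   impurity-decrease importances of a random forest whose
   (max_depth, n_estimators) are selected by particle swarm optimisation
   over the 2–7 × 40–50 box, benchmarked against AdaBoost under the same
   exhaustive grid and shared stratified five-fold cross-validation.
5. **Attention CNN** — a small two-path convolutional network over the five
   selected factors: a 16-channel stem, a squeeze-and-excitation attention
   gate (global average pooling → 16→8→16 dense bottleneck → sigmoid), a
   two-convolution local path, element-wise fusion, and a softmax head.
   Implemented directly in NumPy with analytic gradients and Adam, so
   seeded training is bit-reproducible.
6. **Evaluation** — accuracy/precision/recall/F1 (positive class = high
   RRA) and per-dekad rates whose denominators are the predicted-class
   counts; undefined rates (e.g. no high cells predicted early in the
   season) are reported as missing, never zero.

Because real fleet data are proprietary, a first-class synthetic generator
(`fishrra.synthetic`) emulates the study conditions: suitability-seeking
vessel tracks with configurable fix intervals, haul records with an 8.4%
injected position-error rate (offsets ≥ 0.31°), smooth seasonal
environmental fields, and gamma-distributed catch whose mean is
`catch_scale × suitability`, where suitability is a product of smooth
window responses over the informative factors (SST 10.1–14.6 °C,
SSS 33.8–34.1 ‰, SSH −16.4…−3.6 cm, 50 m temperature 5.9–8.9 °C, and three
MLD bands). Ground truth (true positions, error flags, suitability, the
informative-factor set) is returned alongside, so every downstream stage is
tested as a recovery problem.

## Worked example

```python
import datetime as dt
from fishrra import *

cfg = SimConfig(rng_seed=1)                      # Dec 2023 - Jun 2024 season
env = simulate_environment(cfg)                  # 7 dekadal covariate rasters
hauls, fixes, truth = simulate_fleet(cfg, env)   # logbook + AIS/VMS tracks

corrected, report = correct_logbook(hauls, fixes, threshold_deg=0.3)
print(f"hauls: {report.n_hauls}, replaced: {report.n_corrected} "
      f"({100 * report.corrected_fraction:.1f}%)")

cells = compute_cpue(corrected, cfg.grid)        # t/net per 0.1 deg cell-dekad
labeled, thr = label_rra(cells, "median")
print(f"cell-dekads: {len(labeled)}, median threshold: {thr:.3f} t/net, "
      f"high share: {100 * (labeled.rra_label == 'high').mean():.1f}%")

feats = build_features(labeled, env, optional_factors=("t100",)).dropna()
X = feats[list(PREDICTORS)].to_numpy()
y = feats["rra_label"].to_numpy(dtype=str)
res, ranking = fit_pso_rf(X, y, PREDICTORS, seed=0)
print(f"PSO-RF: depth {res.best_params['max_depth']}, "
      f"{res.best_params['n_estimators']} trees, CV accuracy {res.best_accuracy:.3f}")
print("top-5 factors:", ranking.top(5))

clf, curves = RRAClassifier.fit(feats, ranking.top(5),
                                tcfg=TrainConfig(steps=4000, seed=0))
print(f"CNN validation accuracy: {curves.frame.iloc[-1]['val_acc']:.3f}")
```

Output:

```
hauls: 12581, replaced: 1035 (8.2%)
cell-dekads: 5279, median threshold: 0.498 t/net, high share: 50.0%
PSO-RF: depth 7, 42 trees, CV accuracy 0.893
top-5 factors: ['mld', 'sst', 't50', 'sss', 'ssh']
CNN validation accuracy: 0.887
```

The replaced share recovers the injected 8.4% error rate (binomial
sampling), the median split puts half the cell-dekads in each class by
construction, the top-5 ranked factors are exactly the five that drive the
generator's suitability, and the CNN learns the window rule well above
chance.

The same stages are available from a shell via the `fishrra` command
(`simulate`, `correct`, `cpue`, `features`, `importance`, `train`,
`predict`, `evaluate`); run `fishrra --help` for the options.

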