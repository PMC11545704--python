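# Methods

## Problem setting

The package estimates and forecasts the relative resource abundance (RRA)
of a short-lived pelagic stock from trawl-fishery catch records. Catch per
unit effort (CPUE, tonnes per haul) on a 0.1° × 0.1° grid per dekad
(ten-day period: days 1–10, 11–20, 21–month-end of each month) serves as
the abundance index; the binary high/low RRA label — CPUE above/below the
median — is the prediction target. The fishing season runs December through
June (austral summer–autumn).

## Logbook position correction

Logged haul positions are audited against the vessel's AIS/VMS track. The
matching fix is the one nearest in time to the haul's *set* time (the
earlier fix wins exact ties; no match beyond a 4 h gap, the coarsest VMS
reporting interval in the emulated fleet). The discrepancy metric is the
per-axis maximum |Δlat|, |Δlon| (a component-wise reading of a "latitude
and longitude difference" rule; Euclidean distance is available as an
option). At 0.3° the position is replaced by the fix; the retrieve position
is shifted by the same offset so the haul's geometry is preserved. Catches
and times are never modified, so correction conserves the catch multiset
and is idempotent. Unmatched hauls pass through flagged. The threshold is
deliberately larger than the area a trawler sweeps during one haul
(3–6 kn × 2–5 h ≈ 0.1–0.5° along-track), so legitimate set/retrieve offsets
are not flagged.

## CPUE, centroids, labels

CPUE_{i,j,t} = Σ_k C_{i,j,t,k} / Σ_k E_{i,j,t,k} over the hauls k of cell
(i, j) and dekad t. The default effort model is per-haul (E = 1), making
CPUE mean catch per haul in t/net; haul-duration effort (hours) is an
option. Cells are half-open [edge, edge + step): a point on an interior
edge belongs to the cell whose lower edge it is. Hauls are gridded at the
corrected set position (midpoint optional). The catch-weighted centroid is
X = Σ C_i X_i / Σ C_i (latitude) and Y = Σ C_i Y_i / Σ C_i (longitude).

The RRA threshold is the *global* median of all cell-dekad CPUE values in
the training period (a rolling or per-dekad median would make labels depend
on evaluation-time context; the global median is deterministic and
reproducible). Strict ">" sends exact-median cells to "low", so the class
split is 45–55% up to ties.

## Environmental features

Seven covariates — SST (°C), SSS (‰), SSH (cm), Chl-a (mg/m³), 50 m and
100 m water temperature (°C), mixed-layer depth (m) — live on the analysis
lattice as dekadal cubes. Sources on a different lattice (e.g. 0.083°) are
regridded by area-weighted averaging; a target cell is missing when less
than half its area carries valid data. Each labelled cell-dekad receives
the seven covariates plus its cell-centre Lon/Lat (nine candidate
predictors). Rows missing a mandatory predictor are dropped and counted;
100 m temperature may be declared optional because bathymetry makes it
patchy. Predictors are min-max scaled to [0, 1] with statistics fitted on
training rows only — the mixed units (°C, ‰, cm, m, degrees) would
otherwise dominate gradient-based training.

## Ensemble ranking and hyperparameter search

AdaBoost (depth-limited trees, learning rate 1.0, SAMME) and a random
forest are compared over the same hyperparameter box: max_depth ∈ {2…7},
n_estimators ∈ {40, 42, …, 50}. Fit quality is mean accuracy over a shared
stratified five-fold partition (regenerated if a fold ever misses a class);
the best model's precision/recall/F1 come from pooled out-of-fold
predictions with "high" as the positive class. The forest's box is searched
two ways: exhaustively (emitting the full accuracy surface) and by a
canonical particle swarm (inertia 0.72, cognitive = social = 1.49, clipped
to bounds) over the continuous relaxation, with fitness the CV accuracy at
the rounded integer point, memoised so PSO can never evaluate a point the
grid could not. What the swarm optimises had to be chosen — the
hyperparameter box is the only parameter space defined for the model, so
that is what it searches. The final forest is refit on all rows at the best
integers; its mean impurity-decrease importances, normalised to sum to 1,
rank the nine predictors and the top five (ties to the lexicographically
earlier id) feed the neural classifier.

## Attention-CNN classifier

Input: the five selected factors of one cell-dekad, as a length-5 sequence.
A kernel-3, same-padded stem convolution lifts it to a 5 × 16 feature map,
which splits into two paths: (a) an attention path — global average pooling
over the factor axis, a 16→8→16 fully connected bottleneck with rectifier
then sigmoid, giving one gate in (0, 1) per channel; (b) a local path of two
kernel-3 convolutions. The fused map is the element-wise product of the
local map with the broadcast gate (an all-ones gate reduces fusion to the
local path exactly; a zeroed gate silences the network's input dependence —
both are tested). One more convolution, flattening, and a dense layer yield
two softmax logits trained with cross-entropy.

Unstated engineering choices, fixed as defaults: rectifier activations,
Adam at 1e-3, batch 64, 80/20 stratified train/validation split,
He-initialised weights. The study-scale budget is 50,000 mini-batch steps;
the step budget is configuration, and on synthetic data the loss curves
plateau well before 4,000 steps, so tests and the acceptance run use that
reduced budget. The network is small enough to run in plain NumPy (im2col
convolutions, analytic gradients verified against numerical differentiation
to ~1e-8), which keeps seeded training bit-reproducible on a single thread.

## Evaluation

Per dekad, three rates are reported: correct-low / predicted-low,
correct-high / predicted-high (per-class precisions — the denominators are
*predicted* class counts), and overall accuracy. A rate whose denominator
is zero (typically no predicted-high cells in the early season) is flagged
undefined rather than zeroed. Season summaries pool the confusion counts
(so pooled accuracy is the cell-weighted mean of per-dekad accuracies) and
report monthly predicted-high cell counts and their ratios to January.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:

- **Environment** — per factor, a seasonal cycle peaking in February plus a
  latitudinal gradient plus band-limited (Gaussian-filtered) noise,
  calibrated so each factor's marginal spans its suitability window.
  Factors outside the informative set are sampled from noise alone, with no
  shared seasonal/latitudinal structure, making them independent of catch
  given the informative factors — the property the importance-recovery
  tests rely on. A static random "bathymetry" mask removes a configurable
  fraction (default 15%) of 100 m-temperature cells.
- **Suitability** — the product of smooth window responses (logistic
  shoulders, width 10% of window width, peak normalised to 1) over the
  informative factors; multi-band factors (MLD) take the maximum over
  bands. Only the windows are specified by the fishery's habitat analysis;
  the product form is the simplest function with "optimal range" semantics.
- **Fleet** — vessels walk within the box at 3–6 kn, reflecting at the
  walls, choosing among candidate headings by the suitability at the
  destination; hauls are anchored at fix times (so a haul's true position
  coincides with a reported fix) and placed preferentially at the most
  suitable positions visited that day. This emulates a fleet that targets
  grounds; a pure random walk is available (`fleet_targeting=False`).
- **Catch** — gamma-distributed with mean catch_scale × suitability
  (catch_scale 2 t, dispersion shape 2), giving the right-skewed t/net
  distribution observed in trawl fisheries. Because simulated effort still
  samples sub-optimal habitat in transit, the global median CPUE lands near
  0.5 t/net rather than the ~2 t/net a fleet with full knowledge of the
  grounds would produce; the median *split* and everything downstream are
  invariant to this scale.
- **Errors** — a Bernoulli(0.084) subset of hauls has its logged positions
  displaced by ≥ 0.31° on both axes (sign random, magnitude
  0.31 + Exp(0.1)), so every injected error is detectable at the 0.3°
  threshold and recovery can be scored exactly.

Not emulated: hydrodynamics and currents, vessel economics, position noise
*below* the threshold (real logbooks have small transcription errors too),
seasonal fleet entry/exit, and any spatial correlation between effort and
error rate. Passing tests therefore demonstrate that the pipeline recovers
what it is designed to recover under its own assumptions — not that those
assumptions hold for any particular real fleet.

## Numerical and degenerate-input choices

- Timestamps are UTC at second resolution throughout.
- Cell assignment uses floor((x − origin)/step); grids smaller than 2 × 2
  cells are rejected by the environment generator.
- An all-identical CPUE table labels every cell low (with a warning);
  fewer than two cells is an error.
- Zero total catch makes the centroid undefined (error), as does an empty
  confusion matrix for metrics.
- Non-finite PSO fitness values are treated as worst-possible; positions
  are clipped to bounds every step, and the best-fitness trace is
  non-decreasing by construction.
- NetCDF stacks are written via the NETCDF3 (scipy) engine with dekad
  labels in a global attribute, keeping files dependency-light and
  text-tool-inspectable.

## Problem sizes

The default simulated season (20 vessels, 2 h fixes, ~3 hauls/vessel/day,
5° × 4° box, December–June) yields ≈ 12,500 hauls, ≈ 51,000 fixes and
≈ 5,300 labelled cell-dekads — large enough for the binomial recovery bands
(±3 SD at n ≥ 5,000) while the full test suite and the acceptance run each
finish in a few minutes on one CPU. Model-fit tests use a 2° × 2°
December–March subset (~800 labelled cell-dekads).
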