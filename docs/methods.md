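# Methods

## The analysis

The package classifies leaf spectra into four nitrogen-treatment classes
(D0 = day before an excess-nitrogen application, D1–D3 = the three days
after). The pipeline is staged exactly as a practitioner would run it:
data → preprocessing → effective-wavelength selection → classifier
training → repeated evaluation → report. A single master seed fans out to
per-stage seeds by stable hashing (BLAKE2 of `"<seed>:<stage>"`), so a run
is reproducible end to end.

### Preprocessing

Reflectance is converted to absorbance *A* = log₁₀(1/*R*) (base 10, the
chemometrics convention), corrected for multiplicative scatter, and
median-smoothed, in that order. MSC regresses each spectrum on a
*reference* spectrum — the column mean of the training set — by ordinary
least squares, *x* ≈ *a* + *b*·ref, and replaces it with (*x* − *a*)/*b*.
The reference is learned once and frozen before being applied to new
spectra, so no test-set information reaches the correction. The median
filter uses replicate (edge-value) padding and a default width of 5 bands
(10 nm): the smallest odd width greater than 3 that removes isolated
spikes. MSC is applied to absorbance, following the narrated stage order;
it is exactly idempotent on scatter-free data and raises on a spectrum
whose fitted gain |b| < 1e−12.

### Metaheuristics

BBO, ICA and harmony search all minimise a generic objective (costs,
lower better — the "habitat suitability index" is stored as a cost since
the quantity actually optimised is an MSE) and share conventions: seeded
determinism, best-so-far histories of length budget + 1, and a returned
solution whose cost equals a fresh evaluation.

* **BBO** — rank-based migration: rank *k* of *n* gets immigration rate
  λ = I·k/(n−1) and emigration rate μ = E·(1−k/(n−1)); an immigrating
  variable is copied from a donor drawn ∝ μ; elites survive unchanged.
  Defaults (population 30, 50 generations, I = E = 1, mutation 0.05,
  2 elites) follow the algorithm's original description, since none are
  given for this application.
* **ICA** — colonies are allocated to imperialists ∝ normalised power,
  assimilated by per-dimension steps U(0, β·d) toward their imperialist
  (β = 2), re-randomised with revolution probability 0.3, and swap roles
  with an imperialist they surpass; the weakest empire (total cost =
  imperialist cost + ζ·mean colony cost, ζ = 0.05) loses its weakest
  colony to a power-weighted lottery and collapses when empty.
* **HS** — each improvisation draws every variable from memory with
  probability 0.9, pitch-adjusts within ±bandwidth with probability 0.3
  (default bandwidth 5% of the range), else samples uniformly; the new
  harmony replaces the worst memory entry when better.

Index-subset encoding (for wavelength selection) uses fixed-length vectors
of distinct band indices. Duplicates arising from migration or rounding
are repaired deterministically to the nearest unused index — a random
re-sample would make a solution's cost non-deterministic. BBO's mutation
for this encoding is half global (uniform random index) and half local
(±1–3 grid steps): the local moves let the search settle onto a sharp
optimum, the global ones keep all regions reachable. ICA and HS treat
subset problems through a continuous relaxation rounded at evaluation.

### Neural models

The feed-forward network is fixed at two hidden layers of 18 and 16
rectifier units with a softmax output (one unit per class). Gradient
training minimises cross-entropy plus an L2 penalty (default 1e−4) by
L-BFGS with a line search, so the loss over accepted iterates never
increases; "Bayesian-regularisation" backprop is approximated by this
fixed L2 penalty. The ANN-ICA and ANN-HS classifiers let the
metaheuristic search the flattened weight vector (bounds ±2, cost =
training MSE of the softmax outputs against one-hot targets) and then
polish the best vector with the same gradient trainer (default 200
iterations). The polish is deliberate: the architecture specification
pairs the metaheuristics with a backprop training function, and direct
metaheuristic search of a 400+-dimensional weight space stalls far above
the accuracy this analysis reports — the metaheuristic's role is global
initialisation, backprop's is local convergence. `refine_epochs=0`
recovers the pure-metaheuristic variant.

The RBF network uses Gaussian units ω\_i(x) = exp(−‖x−C\_i‖²/2∂\_i²) and a
linear readout fitted by least squares onto one-hot targets. Centres come
from k-means; all widths share the heuristic ∂ = d\_max/√(2·n\_centres)
(d\_max = largest inter-centre distance, floored at 1e−6). The classifier
default is **4 centres** — one per class. This is intentionally small: the
shared-width, low-capacity RBF mirrors the weak RBF member of the
replicated ensemble (it trails the other four classifiers by several CCR
points while staying far above chance), which is what gives majority
voting something to be robust against.

### Wavelength selection

`select_wavelengths` runs BBO over band subsets of size k (default 3).
The fitness of a subset is the validation MSE of the standard network
trained on those bands only, under a single seeded 60/10 train/validation
split (the remaining 30% mirrors the evaluation protocol's test share and
is untouched). Samples are put into a content-canonical order before the
seeded shuffle (the order is cached on the dataset instance), so the
split — and hence the selection — is invariant to permutations of the
input rows. The fitness trainer uses a strong L2 penalty (1e−2) and 18
L-BFGS iterations: heavier regularisation makes the subset ranking stable
(an overfitted network's validation MSE fluctuates more between
neighbouring subsets than the band signal itself), and the short budget
keeps a full selection run to a few seconds. Subset MSEs are cached per
run. The search budget for selection (population 24, 70 generations,
mutation 0.22) is deliberately mutation-heavy: finding a 3-grid-step
window around each planted centre in a 351-band grid is an exploration
problem, and the local half of each mutation then pins the band onto the
optimum.

### Classifiers and voting

All five classifiers expose `predict` (labels) and `predict_scores`
(rows summing to 1) so that ensemble confidences are comparable:

* KNN: Euclidean distances; label = modal class of the k nearest, ties
  broken by smallest summed distance, then class order; scores =
  neighbour fractions; k chosen on the validation split from
  {1, 3, 5, 7, 9}.
* Stepwise LDA: Wilks'-lambda partial-F entry/removal (F ≥ 3.84 to enter,
  F < 2.71 to remove — the conventional 5%/10% thresholds), capped at 30
  selected variables as a numerical guard for full-grid runs; linear
  discriminant scores with pooled covariance (diagonal ridge 1e−8),
  empirical priors, softmax posteriors. If nothing passes entry the model
  warns and falls back to all variables.
* RBF: as above, scores = softmax of the linear outputs.
* ANN-ICA / ANN-HS: as above.

Majority voting takes the plurality label; ties go to the class with the
highest summed score, then class order. The MV ROC score of a class is
the mean of the members' normalised scores.

### Evaluation protocol and metric conventions

`repeated_evaluation` runs seeded 60/30/10 splits (default 200 iterations;
desk-scale runs use 20), refits every classifier per iteration, and pools
test-set confusion matrices by summation; per-iteration CCR and
one-vs-rest AUC series are kept alongside. A split that misses a class in
its training share is reseeded once, then raises.

Two metric conventions are exposed. `convention="study"` reproduces the
replicated report's orientation — recall = diagonal/column-total and
precision = diagonal/row-total of a rows-are-actual matrix (the transpose
of the textbook assignment), and "misclassified %" = row off-diagonal sum
over the *diagonal* cell, which can exceed 100% for a weak classifier.
`convention="standard"` gives the textbook definitions. The study
orientation is the default so that published tables can be reproduced
bit-for-bit; both are computed from the same counts. AUC uses the
trapezoidal rule over the full threshold sweep, equal to the midrank
Mann–Whitney statistic under ties.

The paired t-test (two-sided, df = n−1) handles the degenerate
zero-variance case as an exact-difference report: t = 0, p = 1 when all
differences vanish; ±∞, p = 0 for a constant non-zero difference.

The Kjeldahl utility converts titration volumes to percent total
nitrogen: N% = 100 · ((Vs − Vb)/m_d) · N_H₂SO₄ · 0.014. A blank exceeding
the sample yields a negative value with a warning rather than an error.

## The synthetic-data generator

The generator is the package's stand-in for the undeposited measurements;
its defaults define the study conditions used by the tests and the
acceptance script.

Each spectrum is `mean_class(λ)·gain + offset + noise`, clipped to (0, 1]:

* **Base curve** — a fixed sum of logistic and Gaussian terms: low visible
  reflectance with a green bump at 550 nm, a red-edge rise centred near
  715 nm, a NIR plateau ≈ 0.8, and a water dip at 970 nm.
* **Informative bands** — Gaussian absorption features (default centres
  723, 781, 901 nm, width 4 nm) with per-class depths. The default depth
  pattern gives every band a class contrast the other two cannot replace:
  723 nm is the only band separating D0 from D1, 781 nm the only band
  separating D2 from D3, and 901 nm the only band separating D3 from D1.
* **D3 structure** — D3's mean is the convex blend
  0.927·mean(D1) + 0.073·mean(D0) (newly grown leaves revert toward the
  pre-treatment spectrum) *minus* a small D3-specific feature at 901 nm.
  The blend alone would confine all class differences to a
  two-dimensional space, in which a third band is never essential and
  band selection cannot be pinned to three centres; the extra feature
  restores full rank while keeping D1/D3 the most confusable pair.
* **Scatter and noise** — per-spectrum gain (sd 0.01) and offset
  (sd 0.002), consistent with an enclosed, artificially lit imaging rig,
  and Gaussian noise of per-band sd 0.0025 smoothed to a 4 nm correlation
  length (detector/illumination noise is spectrally smooth; correlation
  also means adjacent duplicate bands cannot stand in for a distinct
  centre).

Depth magnitudes were calibrated once so that, *after* preprocessing, the
weakest contrasts sit in a deliberate window: D1/D3 ≈ 4 pooled standard
deviations (split between 723 and 901 nm), D2/D3 ≈ 6 (781 nm only),
D0/D1 ≈ 12 (723 nm only). Contrasts in this window make every centre's
removal or ±8 nm displacement produce a large, split-independent jump in
validation MSE, while saturated contrasts (z ≫ 6) would leave off-centre
bands costless and make selection arbitrary. The resulting desk-scale
ensemble behaviour mirrors the replicated experiment qualitatively:
pooled CCRs in the mid-90s, D1↔D3 the dominant confusion, the RBF network
clearly weakest.

What the generator does **not** emulate: radiative-transfer leaf optics,
spatial (image) structure, instrument wavelength drift, day-to-day
illumination shifts, or biological covariance between leaves of one
plant. Tests passing on this generator show the pipeline's machinery is
correct and its selection/ensemble guarantees hold under the stated
statistical structure — not that the same accuracies would be reached on
real leaves.

## Problem sizes

Default desk-scale conditions: 100 samples per class (400 spectra),
351 bands (400–1100 nm at 2 nm), 20 evaluation iterations, BBO selection
with population 24 × 70 generations. The acceptance script uses these
sizes; the published experiment's 200-iteration protocol is available by
setting `SplitScheme(iterations=200)`.

## Known limitations

* The metaheuristic ANN training is only as good as its budget; with the
  default budgets the backprop polish dominates the final weights.
* Stepwise LDA recomputes Wilks' lambda by determinant ratios; for very
  high-dimensional inputs the 30-variable cap, not the F thresholds,
  usually ends selection.
* The evaluation's preprocessing is fitted once on the full dataset
  before the repeated splits (matching the staged pipeline), so the MSC
  reference sees future test rows; with scatter this mild the effect is
  negligible, but a fully nested variant would refit MSC per iteration.
* `d1_d3_overlap` near 1 makes D1/D3 nearly indistinguishable by design;
  classifier CCRs then drop and selection may legitimately return only
  two distinct informative regions.
* On this generator the entire-wavelength run scores *below* the
  effective-wavelength run: the 348 signal-free bands are (nearly)
  independent noise that drowns the distance-based members (KNN, RBF).
  Real leaf spectra carry redundant class information across the grid, so
  a real entire-grid run can match or beat the selected bands; the
  effective-vs-entire t-test the acceptance script reports should be read
  with that difference in mind.
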