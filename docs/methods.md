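# Methods

This note records the models, conventions and numerical choices behind
`restgraph`, and what the synthetic-data tests do and do not demonstrate.

## Motion model and scrubbing

Rigid-body realignment parameters are consumed as a T × 6 matrix (3
translations in mm, 3 rotations in radians, SPM column order). Framewise
displacement is the backward difference
FD(t) = Σᵢ|Δxᵢ(t)| + 50·Σᵢ|Δθᵢ(t)|; the factor 50 converts radians to mm
of arc on a 50 mm sphere approximating the head. FD of the first volume is
defined as 0 (no predecessor). Three censoring rules apply per volume:
absolute excursion of any translation axis > 1 mm *relative to the first
(reference) volume*, absolute excursion of any rotation axis > 1°
(converted to radians for comparison), or FD > 1 mm. "Excursion over the
run" is interpreted as deviation from the reference volume, the standard
realignment-parameter convention; every rule a volume violates is recorded
as a reason code.

A subject is retained only if some contiguous window of at least 300 s
contains at most 10 % censored volumes. The implementation scans every
window of every admissible length (O(T²), negligible at T ≈ 250) and
reports the window with the smallest censored fraction, ties broken toward
longer and then earlier windows.

## Nuisance regression and filtering

Detrending is folded into a single OLS design — intercept, standardized
linear trend, WM, CSF, global signal, and the 6 motion parameters —
mathematically equivalent to detrending first and simpler to reason about.
The fit uses uncensored volumes only; residuals at censored positions are
reconstructed from the fitted model so that interpolation in the filtering
step bridges plausible values, and they remain flagged throughout. The
global-signal regressor is always included. A rank-deficient design is
rejected with the names of the collinear columns.

Band-pass filtering is a forward-backward (zero-phase) 4th-order
Butterworth with pass band 0.009–0.1 Hz, applied after linear
interpolation across censored frames (edge frames held constant); censored
frames are re-flagged afterwards and excluded from every downstream
covariance. The filter realization is a package choice recorded in the
provenance log; only the band itself is part of the analysis definition.

## Connectivity

Partial correlations condition on all remaining nodes:
ρᵢⱼ = −Pᵢⱼ/√(PᵢᵢPⱼⱼ) with P the inverse sample covariance of the
uncensored volumes (listwise deletion). Plain inversion is used when the
covariance is well-posed; when its condition number exceeds 1e8 or fewer
than 2N uncensored volumes remain, a Ledoit–Wolf shrinkage covariance is
inverted instead, and the estimator choice is logged per subject. Edge
weights are |ρᵢⱼ|: positive and negative couplings of equal magnitude are
deliberately identified. No thresholding or binarization is applied; the
graphs are complete and weighted.

## Graph measures

All path-based quantities use the Brain-Connectivity-Toolbox distance
convention l = 1/w (∞ for absent edges). Nodal path length Lᵢ is the mean
finite distance to the other nodes (infinite pairs excluded and counted;
isolated nodes reported NaN with a warning); L is the mean of the defined
Lᵢ. Global efficiency is the mean of 1/d over ordered pairs, with 0 for
disconnected pairs. Betweenness uses Brandes counting (via networkx) over
*ordered* source–target pairs; the "global" betweenness is defined as the
mean of the nodal values (the aggregation is a package choice; max is
selectable). Two weighted clustering families are provided and tested:

- `onnela` (default): cᵢ = Σⱼₖ(ŵᵢⱼŵⱼₖŵₖᵢ)^⅓ / (kᵢ(kᵢ−1)), ŵ = w/max(w),
  kᵢ = number of nonzero-weight neighbours;
- `zhang`: cᵢ = Σⱼₖ ŵᵢⱼŵⱼₖŵₖᵢ / ((Σⱼŵᵢⱼ)² − Σⱼŵᵢⱼ²), which never
  references the binary degree.

Both reduce to the classical binary coefficient on 0/1 weights. Local
efficiency is the global efficiency of the subgraph induced on a node's
neighbours, with the original weights. Every measure is verified against
exhaustive enumeration oracles (Floyd–Warshall, triple enumeration,
path-count DP) to 1e-10 on hundreds of small random graphs.

## Null normalization

Each subject's global measures are divided by their mean over an ensemble
(default 1000) of random equivalent graphs: the upper-triangle weights —
zeros included, since they are part of the weight distribution — are
permuted uniformly, preserving the exact multiset, symmetry and zero
diagonal. The mean is the default aggregate (median selectable); the null
mean and SD per measure are stored. When a measure and its entire null
ensemble are all 0 (betweenness of a uniform-weight graph), the normalized
value is defined as 1, the ratio of identical ensembles; a zero null
aggregate with a nonzero numerator is reported NaN. Each subject gets an
independent child stream of the master seed, so normalization is
reproducible per subject and in aggregate. Nodal measures are left raw;
only global measures are normalized, matching how such results are
reported.

## Hubs

The hub score counts four criteria: top-20 % strength, bottom-20 % nodal
path length, bottom-20 % nodal clustering, top-20 % betweenness; a node
with score ≥ 2 is a hub. Because partial-correlation graphs are complete,
binary degree is constant; the "highest degree" criterion is therefore
evaluated on node strength, the weighted-graph analogue (flagged here
because the classical scheme says "degree"). Criteria use *strict*
inequality against the 80th/20th percentile so that fully tied graphs
produce no hubs; with 45 tie-free values exactly 9 nodes hit each
criterion. Group-level hubs are nodes whose within-group hub frequency
exceeds the mean + 2 SD of the frequencies obtained from one
subject-matched random equivalent graph per subject — one defensible
reading of hub identification "versus equivalent random networks", and
labelled as interpretive in the outputs.

## Modularity

Newman spectral community detection maximizes
Q = (1/2m)Σᵢⱼ(wᵢⱼ − sᵢsⱼ/2m)δ(cᵢ,cⱼ): recursive bisection by the leading
eigenvector of the (generalized) modularity matrix, Kernighan–Lin
fine-tuning of every split, and a final refinement combining greedy
single-node moves (including split-offs), pairwise module merges, and a
multi-way KL pass that moves every node once and keeps the best
intermediate state. The procedure is deterministic (eigenvector sign ties
broken toward the positive group) and attains the exhaustive-search
optimum on all tested graphs of ≤ 8 nodes. Group-level module tables come
from the partition of the group-mean weight matrix (a consensus of subject
partitions is a reasonable alternative; the group-mean choice is recorded).

## Statistics

Descriptives use Kruskal–Wallis with the χ² approximation (exact rank
enumeration backs the small-n tests) and Pearson χ² for sex. Group
comparisons of normalized measures use Welch t-tests (Satterthwaite df)
throughout — never pooled variance. Hub and co-module probabilities use
two-sided Fisher exact tests. Symptom associations use tie-corrected
Spearman correlations in patients only. The ANCOVA fits
measure ~ group + z + group×z with the covariate standardized and the
group sum-coded, reporting type-III F tests via explicit model comparison
(verified against statsmodels' type-III ANOVA) plus per-group Pearson
correlations and slopes. Box-Cox transformation ((xᵏ−1)/k, ln x at k = 0;
λ chosen by profile likelihood on a 601-point grid over [−3, 3], automatic
positivity shift) is applied to the dependent variable or covariate when a
normality gate fires: |skewness| > 1 or Shapiro–Wilk p < 0.05. FDR control
is Benjamini–Hochberg, applied per reporting family (45 hub tests, the
node-pair co-module tests, the symptom-correlation table); the procedure
and family definitions are configuration, recorded in outputs.

## Synthetic cohorts

The generator emulates the study design, not the physics of BOLD imaging.
Per subject it draws T × N Gaussian series from a planted block covariance
(unit diagonal, `within_r` inside modules, `between_r` across; positive
definite whenever 0 ≤ between < within < 1), mixes in three AR(1)
(φ = 0.9) nuisance signals, and builds a motion trace from slow sinusoidal
drift (0.2 mm / 0.002 rad amplitude) plus Bernoulli spikes (rate 0.02,
1.5 mm). Questionnaire scores are Gaussians truncated to the instrument
ranges (IBS-SSS 0–500, VSI 0–75, HADS 0–42 total, STAI-T/SDS 20–80);
the per-group locations/scales of the two cohort presets place the group
medians near published descriptives for a milder and a more severe cohort
(e.g. IBS-SSS medians ≈ 41 vs 179.5 in the milder preset). Sample sizes,
TRs and volume counts mirror the two-cohort design (29/30 at TR 1.8 s,
250 volumes; 29/62 at TR 2.0 s, 300 volumes analyzed to 250). Network
defaults are three 15-node modules with within_r = 0.4 and
between_r = 0.1 — typical within- versus between-network resting-state
correlation magnitudes. A patient-group effect, when wanted, is injected
as an *increase* of the between-module correlation (loss of segregation);
the default `group_effect = 0` reproduces the null regime, which is what
the emulated study design reports. All randomness flows from one seed via
spawned child streams; cohorts are bit-reproducible.

What the generator does **not** model: hemodynamic autocorrelation of the
signal of interest (ROI series are temporally white before nuisance
mixing), physiological (cardiac/respiratory) noise, spatial structure
within nodes, scanner drift beyond a linear trend, or realistic
questionnaire discreteness. Passing tests therefore demonstrate that the
pipeline is *correct and calibrated* under its stated assumptions and that
planted structure is recovered — not that any particular empirical effect
exists in real cohorts.

## Calibration and power checks

Statistical operating characteristics are measured on cohorts simulated at
the measure level (covariate ~ N(0,1), measure = per-group slope ×
covariate + noise): type-I error of the Welch and ANCOVA-interaction tests
stays within [0.035, 0.065] at α = 0.05 over 1000 scaled-down (15/15)
cohorts, and the planted control-positive/patient-null slope structure
(r = 0.48 vs −0.006 with unit residual SD, i.e. slopes 0.547 vs −0.006)
is detected in over half of 2000 simulated 30/30 cohorts. Simulation sizes
were chosen to make the Monte-Carlo error small relative to the bounds
being checked.

## Numerical conventions and degenerate inputs

- Identical-ensemble normalization 0/0 → 1 (see above); isolated nodes
  NaN-reported and excluded from L with a warning.
- Welch with two zero-variance groups: t = 0, p = 1 for equal means.
- Constant descriptive variables: p = 1 with a warning.
- Fisher tables with a zero margin: p = 1.
- Spearman with a constant input: reported undefined (NaN).
- Noiseless ANCOVA: a term explaining nothing of an exactly-fit model has
  F = 0, p = 1; a term carrying all remaining variance has F = ∞, p = 0.
- Q of a single-module partition is exactly the formula value (≈ 0 up to
  float round-off for any graph).
- Matrix TSVs round-trip bit-identically (shortest-repr writing,
  round-trip float parsing on read).

## Known limitations

- The pipeline operates on ROI time series; voxel-level spatial
  preprocessing (realignment, normalization, segmentation) is out of scope
  and assumed done (the optional NIfTI extraction averages GM voxels > 0.3
  per node as a convenience).
- The random-equivalent-graph null permutes weights only; degree-preserving
  rewiring (Maslov–Sneppen) nulls are not implemented.
- Hub identification "versus random networks" at the group level is one
  reading among several; the threshold (null mean + 2 SD) is logged.
- Fisher tests on co-module counts reconstruct counts from frequencies;
  with very small groups this is exact, with fractional frequencies it
  rounds to the nearest count.
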