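# Methods

`gsrpipe` re-implements, as a tested pipeline, a resting-state fMRI
analysis of how global-signal regression (GSR) changes temporal
variability, functional connectivity (FC) and weighted graph-theoretic
network properties of BOLD recordings across consciousness states
(awake baseline vs. anesthetic-induced unconsciousness, two drug arms).
Because such patient data are restricted, the pipeline ships with a
synthetic cohort generator whose statistical structure matches every
assumption the downstream stages make, together with a closed-form FC
oracle for parameter-recovery testing.

## Synthetic cohort model

Each of the two groups (7 and 6 subjects by default) is recorded in two
states for 540 s at TR = 2 s (270 volumes). ROI signals on a 114-ROI /
17-network cortical parcellation are linear mixtures of independent
latent processes:

    x_i(t) = g_s G(t) + b_s B(t) + w_s N_k(t) + s_w S(t)
             + lam c(t) + sigma eps_i(t)

* `G` — global component; its amplitude `g_s` is the per-state
  `gs_amplitude` (default 0.6 baseline, 0.35 unconscious).
* `B` — shared between-network component; `N_k` — the latent of ROI
  *i*'s network. Their weights are solved from per-state *correlation
  targets*: `coupling_within` (0.50 / 0.40) and `coupling_between`
  (0.25 / 0.10). With latent-part variance `T0 = sigma^2/(1-r_w)`,
  `w^2 = (r_w - r_b) T0` and `b^2 = r_b T0 - g^2`; a negative `b^2`
  means the requested global amplitude is incompatible with the
  between-network target (non-PSD implied covariance) and is rejected
  at construction.
* `S` — a subject-specific process with weight `subject_effect`
  (0.15), drawn once per subject and reused in both states: the paired
  random effect linking a subject's two recordings.
* `c` — a motion-composite that leaks into the signal with weight
  `confound_leak` (0.2); `eps_i` — white unit-variance noise scaled by
  `noise_sd` (1.0).

`G`, `B`, `N_k`, `S`, `c` are Gaussian processes band-limited to
0.01–0.1 Hz (complex-Gaussian Fourier coefficients on the in-band bins,
inverted and z-scored) and are QR-orthonormalized *in sample*, so the
covariance implied by the mixing weights is exact for the structural
part; only white-noise terms contribute O(1/sqrt(T)) sampling error.
`expected_fc` returns the implied population ROI correlation matrix in
closed form; a 50 000-volume simulation reproduces it entrywise within
0.02. Orthonormalization slightly perturbs the shared subject process
(it is re-orthogonalized against each recording's fresh latents); the
perturbation is O(1/sqrt(T)) and irrelevant at the tested scales.

Voxel expansion replicates each ROI signal `n_voxels_per_roi` times
(default 5) plus white voxel noise (`voxel_noise_sd`, 0.5), enabling
voxel-wise SD/ALFF without volumetric images.

The confound table carries 6 motion-like series, their temporal
derivatives, and WM/CSF series. Motion series mix the leak composite
`c` (weight 0.5) with independent very-low-frequency processes, so the
motion block spans `c` exactly and nuisance regression can remove the
leak. Deliberate design choice: band-limited processes instead of
literal random walks — random-walk confounds are non-stationary, which
would break the closed-form FC oracle, while the band-limited version
preserves the feature that matters (slow drift-like regressors).
WM/CSF correlate 0.5 with `G`, so confound-only regression removes part
of the global component and the two GS branches genuinely differ.

### Why the state effect is "between-dominant"

The unconscious state mainly attenuates the shared components
(`gs_amplitude` 0.6→0.35, `coupling_between` 0.25→0.10) and only mildly
the within-network coupling (0.50→0.40). The network-level FC between
two network-averaged series is `shared / (shared + w^2 + sigma^2/n_k)`:
the within-network latent acts as *noise* at this level, so a state
effect that reduced `w` strongly would paradoxically *raise*
between-network FC after averaging. The between-dominant parameterization
reproduces the study's phenomenology — baseline-minus-unconscious FC
contrasts positive, path length up, clustering/efficiency down, GM-mean
SD down — and is fixed as the generator default.

### What the generator does not emulate

No hemodynamic response or neurovascular forward model, no volumetric
images or spatial smoothing, no motion spikes, no non-Gaussian or
non-stationary artifacts, no drug-specific pharmacology (both arms share
one parameter set and differ only in sample size and random draws).
Passing direction-recovery tests therefore shows the pipeline correctly
propagates this class of covariance structure — not that it would
reproduce every property of real BOLD data.

## Preprocessing

Per recording and GS condition: (1) zero-phase Butterworth band-pass
(order 5 forward–backward, odd-extension padding), 0.01–0.1 Hz;
(2) discard the first 5 volumes; (3) least-squares nuisance regression —
14 confounds (+ intercept), with the GM-average series (the global
signal) added as a 16th regressor in the *withoutGS* branch (GSR) and
left in the data in the *withGS* branch; (4) per-unit z-scoring
(ddof = 1). Confounds are band-passed with the identical filter before
regression (`filter_confounds`, default on) so no out-of-band variance
re-enters. The GS is computed from the band-passed, trimmed data
(equal unit weights); computing it before vs. after filtering is not
independently meaningful here since filtering and averaging commute up
to edge effects. Each step is recorded in a provenance list.

Rank-deficient designs raise with the offending columns named.
Residuals are orthogonal to every regressor to solver precision
(checked at 1e-10). In the no-global-signal limit the two branches
converge; the gap floor is ~ `1/sqrt(n_units) + 1/sqrt(T_eff)` (with
`T_eff` the effective number of in-band samples), because the GS
regressor is estimated from the data rather than known. The convergence
test probes the limit with 1 140 units and 5 400 volumes, where the
floor sits near 0.03.

## Fluctuation indices

* SD of the GM-average series (sample SD, ddof = 1) on the z-scored data.
* Unit-wise SD on the *pre-z-score* residuals (after z-scoring it is 1
  by construction); both entry points are exposed.
* ALFF: one-sided FFT amplitude (`2|X_k|/n`, so a unit-amplitude
  sinusoid scores 1), averaged — not summed — over the 0.01–0.1 Hz bins,
  making the index invariant to zero padding; then min–max normalized
  across units to [0, 1] within subject. Raw ALFF is homogeneous of
  degree 1 in amplitude; normalized ALFF is scale-free. A Parseval check
  (1e-6 relative) guards the FFT conventions.

## Connectivity

ROI/network series are unweighted means of member units. FC is the
Pearson matrix with the diagonal set to 0, plus its Fisher-Z transform.
Group-average FC is computed on Z values and back-transformed; edge
contrasts report `delta_r` = mean baseline r − mean unconscious r on the
correlation scale, while the paired tests run on Z values. The 136
17-network edges are tested without multiplicity correction (a BH-FDR
utility exists, default off); ROI-level (114) FC feeds the graph stage
only.

## Graph metrics

Cost thresholding keeps the `m = round(cost * n(n-1)/2)` largest
*positive* correlations as weighted edges (weights = r), ties broken by
lexicographic (i, j) order. Negative correlations never become edges:
the length transform `1/w` requires positivity (relevant because GSR
produces negative FC).

* Shortest paths: Dijkstra on lengths `1/w`; unreachable pairs are
  infinite.
* Characteristic path length `L`: per-node mean of finite distances
  (unreachable pairs excluded, their fraction recorded; isolated nodes
  get NaN and are excluded from the average).
* Clustering `C`: geometric-mean triangle intensity
  `C_i = 2 t_i / (k_i(k_i-1))`, `t_i = 1/2 sum (w_ij w_ih w_jh)^(1/3)`
  on max-normalized weights; `C_i = 0` for degree < 2.
* Local efficiency: `E_loc(i) = sum_{ordered j!=h in N(i)}
  (w_ij w_ih / d_jh(N_i))^(1/3) / (k_i(k_i-1))` with `d_jh(N_i)` the
  shortest path inside the neighborhood subgraph on lengths `1/w`.
  This normalization makes a binary clique score exactly 1.
* Global efficiency: mean inverse distance, unreachable pairs = 0.
* Null model: degree-preserving double-edge swaps, weights traveling
  with edges, 10 accepted swaps per edge per realization (configurable),
  100 realizations by default; `L_rand`, `C_rand` are ensemble means
  using the same exclusion rules. Cliques (no swappable pairs) fall back
  to the graph's own metrics with a flag. `lambda = L/L_rand`,
  `gamma = C/C_rand`, `SW = gamma/lambda`.

The admissible cost range scans a 0.005-step grid for the maximal
contiguous run satisfying: ≤10 % of nodes off the giant component in
≥95 % of subjects; mean degree > ln(n); subject-mean SW > 1. Metrics can
be averaged across the admissible grid (AUC convention) or evaluated at
fixed costs; per cost the identity SW = gamma/lambda is exact, and the
across-cost average is the mean of per-cost values. Network-level nodal
summaries average member-ROI values per the 8 coarse groups (7 groups
are the usual reporting panels; the temporoparietal group is reported
alongside).

## Bayesian inference

Paired two-sided JZS t test: Cauchy(0, 0.707) prior on the standardized
effect under H1, point null under H0.
`BF10 = ∫ T_nu(t; sqrt(n) delta) Cauchy(delta) d delta / T_nu(t; 0)`,
evaluated by adaptive quadrature (relative tolerance 1e-6) after the
substitution `delta = r tan(u)`; the computation runs on the log scale
relative to the null density, with the quadrature pointed at the
posterior peak, so extreme t values neither underflow nor get missed.
Posterior median, 95 % central interval and probability of direction
come from a normalized 4 001-point grid spanning ±10 prior scales
(deterministic; a sampler would add Monte-Carlo noise for no benefit in
1-D). `BF10 > 3` is the significance rule. Calibration: under H0
(n = 10) the false-positive rate of that rule is ~1–2 %; under a
delta = 1.2 effect its power exceeds 50 %. BH-FDR (step-up) is provided
for ROI/voxel maps via statsmodels.

The original analysis additionally fit Bayesian linear mixed models for
three-way interactions; the pipeline deliberately reports per-condition
BFs only. Reported credible intervals are for the standardized paired
effect; bracketed intervals in other software may be on the raw-difference
scale, so small numerical differences are expected.

## Problem sizes and numerical choices

Full-size defaults: 540-s scans, 5 voxels/ROI, 100-null ensembles, AUC
over the admissible cost range. The test suite and the acceptance
script run the same code at desk scale — ROI-level units, 240–360 s
scans, fixed cost 0.15, 4–20 nulls — sizes chosen so the complete
validation (50-graph brute-force equivalence, 10-seed null calibration,
2 000-replicate BF calibration, 20-replicate direction recovery,
byte-level determinism of two full runs) executes on one CPU in a few
minutes. Tolerances: graph oracles 1e-12; BF vs. independent quadrature
1e-4 relative; long-run FC consistency 0.02; ER null ratios within 0.1
of 1.

## Known limitations

* The generator's two drug arms are statistically exchangeable; drug-
  specific contrasts are sample-size effects only.
* `expected_fc` describes the raw generator output; preprocessing
  (band-pass, confound regression) changes correlations in predictable
  but not closed-form ways, so parameter-recovery tests on preprocessed
  data are directional, not numeric.
* Proportional thresholding with few positive correlations (strong GSR,
  high cost) can be infeasible; this is signalled, and the feasibility
  scan treats it as an inadmissible cost rather than an error.
* The rewiring null preserves the degree sequence and the weight
  multiset but not the weight-degree correlation.
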