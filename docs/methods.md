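# Methods

## Diffusion signal model and tensor fit

Signals follow the monoexponential tensor law S(g) = S₀·exp(−b·gᵀDg) with a
single shell (default b = 1000 s/mm², 32 directions plus one b = 0 volume,
voxels 1×1×2 mm). The fit is ordinary least squares on ln S with the seven
unknowns (ln S₀ and the six unique tensor elements); weighted or nonlinear
variants are deliberately not used, so the fit is exact to machine precision
on noiseless data and the phantom generator's stored tensors serve as an
exact oracle. Eigenvalues are sorted descending; negative eigenvalues from
noisy fits are clamped to 10⁻¹² mm²/s (per-voxel `clamped` flag) so FA stays
in [0, 1]. Scalar maps: AD = λ₁, RD = (λ₂+λ₃)/2, MD = mean(λ),
FA = √(3/2)·‖λ−λ̄‖/‖λ‖.

Noise, when requested, is Rician: each channel's magnitude is
√((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, σ). σ = 0 is allowed and used by the
exactness tests.

**Head-motion QC.** The exclusion rule "1.5 mm/degree" is applied as a
displacement equivalence: the three rotation parameters (radians) are
converted to arc displacement θ·r at r = 50 mm and compared — like the three
translations — against 1.5 mm, with exclusion only on strict exceedance.
Conflating angle units with displacement is the one genuinely ambiguous rule
in the protocol; the displacement reading is the only one in which the 50 mm
radius plays a role. Motion/eddy image correction itself is out of scope —
synthetic data are generated aligned — so QC consumes externally supplied
parameter traces.

## Tractography

Tracking runs in millimetre space. The direction field is obtained by
trilinear interpolation of the six tensor components followed by
eigendecomposition at the interpolated point; the principal eigenvector is
sign-aligned with the previous step. From the centre of every white-matter
voxel with FA ≥ 0.2 (the `fa_floor`), both antipodal directions are
integrated with 0.5 mm Euler steps and the two branches concatenated —
bidirectional seeding is standard practice and recorded here as an
assumption, since seeding direction is otherwise unspecified. Termination:
entering a voxel with FA below the floor, turning more than 60° between
successive steps, leaving the tracking mask, or a 2000-step safety cap.
Nearest-voxel lookup uses floor(x/voxel + 0.5), which keeps tie-breaking
independent of integer parity.

Probabilistic fibre-direction posteriors are approximated, not implemented:
an optional von Mises–Fisher perturbation of the principal direction
(concentration `jitter_kappa`, with `samples_per_seed` repetitions) preserves
the probabilistic-count character of the streamline matrices at desk scale.
The full Bayesian posterior is a non-goal.

**Connectome.** A streamline connects ROI pair (i, j) when its point set
intersects both label regions at nearest-voxel resolution; a streamline
touching ≥ 3 ROIs increments every touched pair. Counts accumulate
symmetrically into a 24×24 integer matrix with zero diagonal. Mean-AD edge
weights average AD over all voxels visited by all connecting streamlines of
that pair; a constant-AD bundle therefore yields the exact field value.

## Graph analysis

Weighted matrices are proportionally thresholded: exactly
k = round(level·N(N−1)/2) strongest off-diagonal weights are retained (round
half to even; ties broken by lexicographic edge order so runs are
reproducible), then binarized. The study grid is level .15–.40 in steps of
.01 (26 levels); by construction every subject's network has identical
density at each level. If fewer than k weights are nonzero, all nonzero edges
are kept with a warning.

Metric conventions (all on the binary, undirected network):

- **Betweenness** is unnormalized, with each unordered source–target pair
  counted once. This matches grand-mean magnitudes of tens on 24 nodes.
- **Nodal path length** averages geodesic distance over reachable nodes only;
  unreachable pairs contribute nothing, and a `reachable_fraction` helper
  reports coverage. Efficiency uses 1/∞ = 0 (Brain Connectivity Toolbox
  convention).
- **Local efficiency** of a node is the global efficiency of its
  neighbour-induced subgraph, 0 for fewer than two neighbours.
- **Assortativity** is the Pearson correlation of degrees over edge
  endpoints; it is NaN with a warning when degenerate (e.g. regular graphs).
- **Small-worldness**: γ = C/⟨C_null⟩, λ = L/⟨L_null⟩, σ = γ/λ, against 500
  degree-preserving nulls per (subject, threshold). Nulls are produced by
  Maslov–Sneppen double-edge swaps (10·E attempted swaps per null, rejecting
  self-loops and duplicate edges), which preserve node count, edge count and
  the exact degree sequence; graphs with no valid swap (star, complete) fall
  back to source copies with a warning. The swap/metric loop is a compiled
  numba kernel fed with pre-drawn random numbers, so ensembles are
  reproducible bit-for-bit; networkx's rewiring is used as an independent
  cross-check in tests, and all other metrics are cross-checked against
  exhaustive path-enumeration oracles on small graphs.
- **Hubs**: z ≥ 2 on both degree and betweenness, z-scored across the 24
  nodes of the group-mean nodal values averaged over the threshold grid. The
  protocol reports one hub set per group without naming the threshold at
  which it is computed; threshold-averaging is this package's documented
  choice.

## Inference

**Group comparison.** Each metric cell is tested with a GLM (group + age +
IQ + TIV). The permutation scheme is Freedman–Lane: the metric is
residualized against the covariate-only model, residuals are permuted and
added back to the reduced fit, and the full-model group-term t is recomputed;
p = (1 + #{|t*| ≥ |t|})/(1 + 1000), never zero. The group-term t (not a raw
mean difference) is the test statistic, matching common GLM permutation
tools. One permutation schedule is shared across cells of a family, as in
standard neuroimaging permutation software. FDR is applied per metric across
its (node × threshold) family; a lenient p < .001 uncorrected flag is also
emitted, since screening before correction is part of the analysis protocol.

**Clinical association scan.** Patients only (clinical scores are not
recorded for controls, so the generator emits them for patients only). At
every (threshold, node, metric) cell the score is regressed on the metric
with age, IQ and TIV as covariates; the metric-term β, t and parametric p are
recorded, plus a Freedman–Lane permutation p when requested — whether the
original analysis used parametric or permutation p-values is unstated, so
both are available. Global metrics are replicated across the 24 nodes so one
scan is exactly 26 × 24 × 9 = 5,616 cells, corrected as a single BH-FDR
family at q = .05 (Benjamini–Yekutieli available by flag). Cells with a
constant or non-finite regressor (density is constant across subjects by the
thresholding contract) are reported as degenerate with p = 1.

## Synthetic cohort generator

The generator defines the study conditions: 28 patients vs 30 controls,
24-node connectomes.

- **Backbone.** All subjects share one fixed "anatomical backbone" of
  lognormal edge weights (log-mean 3.2, log-sd 0.6 — streamline counts of
  order tens, as is typical for ROI pairs at this scale), with iid lognormal
  subject-level variation (log-sd 0.3) per edge. The backbone is deliberately
  independent of the cohort seed: real cohorts share one anatomy, and
  realisations differ in subjects, not in the population structure.
- **Hubs.** Right putamen and left SMA incident weights are doubled in both
  groups, which reliably reproduces a two-node hub set at z ≥ 2.
- **Group effect.** A requested Cohen's d in one nodal metric (default:
  betweenness of the left putamen, d = 1.2) is planted by scaling the target
  node's incident edge weights in patients. Because the mapping from edge
  scale to metric effect size is not analytic, the scale is calibrated by
  Monte-Carlo bisection (150 subjects per group per evaluation, common random
  numbers with the no-perturbation baseline subtracted) against the metric at
  the reference threshold 0.25; realised cohort-level d averages within ~0.05
  of target. Calibration uses its own fixed RNG stream, so the same study
  conditions give one scale factor regardless of cohort seed, and replicate
  simulations can reuse it.
- **Clinical associations.** Scores are drawn as linear functions of the
  realized z-scored nodal metric(s) plus a standardized age term (0.3) and
  Gaussian residual, then mapped to instrument scales — YGTSS ≈ 33 ± 15 on
  0–100, PUTS ≈ 20 ± 6 on 9–36, matching the reported patient sample — and
  clipped/rounded. Defaults plant local-efficiency/PUTS slopes at the left
  caudate (−.55), right posterior insula (+.55) and left anterior insula
  (+.60), and betweenness/YGTSS slopes at left thalamus and right M1 (+.60).
- **Motion traces** are Gaussian with `amplitude` interpreted in mm for
  translations and as 50 mm-radius arc displacement for rotations, so QC
  behaviour is predictable from the amplitude alone; amplitude 0 is exactly
  zero motion.

What the generator does *not* emulate: realistic anatomy or geometry of the
connectome backbone (the weight template is unstructured apart from hubs, so
generated cohort networks have σ ≈ 1 rather than the small-world organisation
of real connectomes — small-worldness machinery is validated on a
ring-lattice-plus-shortcuts construction instead), crossing fibres, scanner
artefacts beyond Rician noise, and group differences in density (excluded by
the proportional-thresholding contract). Passing tests therefore demonstrate
correctness of the machinery and calibration of the inference under known
truth, not recovery of any real cohort's effect sizes. Cohort matrices are
generated directly at the connectome level rather than by tracking a phantom
per subject, keeping cohort-scale simulations fast; the full
signal→fit→track→connectome path is validated separately on phantoms.

## Problem sizes and numerical choices

The default run (58 subjects × 26 thresholds, 500 nulls per cell, 1000
permutations, two 5,616-cell scans) completes in ~2 minutes on one CPU.
Statistical calibration checks use 200 null cohorts (type-I error inside the
binomial 95% band at α = .05) and 100 planted-effect replicates (power ≥
80%), with the tested quantity — betweenness of the planted node — evaluated
at the 0.25 reference threshold, the same threshold at which effects are
calibrated. Monte-Carlo sizes were chosen so each check's sampling error is
small relative to its acceptance band.

Per-stage RNG seeds are derived from the master seed by fixed offsets, so any
stage can be re-run independently; every run writes a manifest with the
configuration hash and all stage seeds, and identical configuration + seed
yields byte-identical outputs.

## Known limitations

- Deterministic tracking with optional jitter is a stand-in for full Bayesian
  fibre-direction posteriors; uncertainty in the tensor fit itself is not
  propagated.
- Binary metrics only; weighted-graph variants, directed networks and
  community structure are out of scope.
- The association scan treats global metrics as node-replicated cells to
  preserve the 5,616-cell family; their 24 copies per threshold are perfectly
  dependent, which BH-FDR tolerates but does not exploit.
- Registration, brain extraction, eddy correction and voxelwise
  skeleton-based statistics are out of scope; synthetic data are generated in
  a common native space.
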