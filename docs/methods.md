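# Methods

## The voxel model

A white-matter voxel's diffusion-weighted signal is modelled as a small
number of axially symmetric anisotropic tensors (axonal fiber bundles) plus
a continuous spectrum of isotropic diffusivities:

    S_k = sum_i f_i exp(-b_k λ⊥i) exp(-b_k (λ∥i - λ⊥i) cos² ψ_ik)
          + ∫_a^b f(D) exp(-b_k D) dD

with b-values in s/mm², diffusivities in µm²/ms (every exponent is scaled by
10⁻³), and ψ_ik the angle between gradient k and fiber i. Signals are
normalized by the mean b = 0 intensity, so the total signal fraction
(Σ f_i + ∫ f(D) dD) is 1. The isotropic spectrum is split at 0.3 and
3.0 µm²/ms into restricted (cellularity), hindered (edema / extracellular
water) and free (CSF-like) fractions; a node exactly on an edge belongs to
the lower band. Eight scalar metrics summarize a voxel: fiber fraction,
fiber FA (= (λ∥−λ⊥)/√(λ∥²+2λ⊥²)), fiber AD, fiber RD, the three isotropic
band fractions, and the CSF-normalized b0 intensity.

Assumptions: Gaussian diffusion within each compartment, no exchange, an
axially symmetric tensor per fiber population, at most two fiber populations
per voxel (white-matter regime), and magnitude (Rician) noise.

## Acquisition scheme

The default scheme emulates a 99-direction, maximum b = 1500 s/mm²
multi-b-value protocol: one b = 0 measurement plus 99 directions spread by
electrostatic repulsion (antipodally symmetric energy) and assigned
round-robin to 5 evenly spaced shells (300…1500 s/mm²). The shell count is
a design choice — the protocol's exact shell layout is not public — and is
configurable; multi-b coverage is required for the spectrum deconvolution.
Gradient directions live in the image frame (fitting is voxel-wise and
orientation-relative); the NIfTI affine is passed through untouched.

## Fitting

**Stage 1 — orientations.** Non-negative least squares over a dense basis:
one anisotropic column per candidate direction (subdivided-icosahedron
hemisphere, 321 directions) at provisional diffusivities
(λ∥ = 1.5, λ⊥ = 0.3 µm²/ms) plus the isotropic columns. Surviving candidate
weights are clustered by angular proximity (20°, antipodally symmetric);
clusters whose summed weight exceeds 5% of the total become fiber
candidates, capped at two. Each cluster direction is then polished by a
deterministic shrinking 5×5 tangent-grid search (half-width 0.06 rad, 3
iterations): the candidate grid resolves orientations only to ~4°, and the
leftover angular misfit would otherwise be absorbed by the spectrum solve as
spurious band mass.

**Stage 2 — diffusivities and fractions.** A bounded Nelder–Mead search over
the per-fiber (λ∥, λ⊥) (bounds [0.5, 3.0] and [0, 1.5] µm²/ms, λ⊥ ≤ λ∥
enforced, two deterministic starts) with an inner non-negative least squares
jointly solving the fiber fractions and the isotropic spectrum
(Tikhonov-regularized on the spectrum coefficients). Metrics come from the
normalized parameters; multi-fiber voxels report fraction-weighted means of
the per-tensor AD/RD/FA.

**Regularization.** Both ridge weights are expressed as multiples of the
design matrix's largest singular value and both default small: 2·10⁻³ for
orientation selection, 2·10⁻⁴ for the spectrum solve. On this highly
coherent exponential basis a stronger ridge (the more conventional ~2·10⁻²)
visibly redistributes mass across correlated columns: a free-water spike at
D = 3.2 loses about a tenth of its mass across the 3.0 band edge, and
isotropic voxels acquire diffuse anisotropic weight. The chosen defaults
keep the inversions well-posed without flattening noiseless spikes;
increasing the weight smooths the recovered spectrum monotonically (fewer
isolated peaks), which is property-tested.

**Degenerate voxels.** Non-positive b0 or all-zero signals are flagged
(`quality = "degenerate"`), never fit, and excluded from downstream tables;
optimizer non-convergence is flagged (`"max_iter"`) rather than silently
returning NaN.

## Spectral resolution — what recovery can and cannot promise

The default spectrum grid is uniform on [0, 4] µm²/ms with 41 nodes and
trapezoidal weights. The information content, however, is set by the number
of distinct b-values: with 5 shells + b0 the isotropic basis has numerical
rank ≈ 6, so the inverse-Laplace problem admits alternative non-negative
representations that reproduce a noiseless signal to ~10⁻⁸ while moving band
sums by a few hundredths. Consequences, quantified in the test suite:

* Two-component voxels (one fiber + free water) are fully identified:
  noiseless recovery of all fractions to ±0.02 and diffusivities to ±5%.
* Three-component spectra (restricted + hindered + free alongside a fiber)
  are identified to roughly ±0.05–0.08 even at infinite SNR, worse where a
  low-FA fiber's λ⊥ overlaps the hindered band. This is an information
  limit of the acquisition, not an optimizer failure — the fitted model
  reproduces the data essentially exactly.
* At b0 SNR 30 the mean bias of each fraction over repeated noise draws on
  a white-matter-like voxel stays below 0.05.

## DTI comparison fit

Weighted log-linear least squares for the 6 tensor elements + ln S0: an
ordinary pass on log-signals, then one reweighting with weights equal to the
squared predicted signals (adequate at phantom SNR; no iterative WLS or
outlier rejection). Negative eigenvalues are clamped to zero with a quality
flag; rank-deficient designs are rejected with the condition number named.
ADC/FA/AD/RD follow from the eigenvalues. On mixed fiber + free-water
voxels the single-tensor FA falls below the spectrum model's fiber FA — the
directional property that motivates the model comparison.

## Structural contrasts and lesion typing

MTR = (S_off − S_on)/S_off × 100, elementwise, with non-positive S_off
masked. CSF baselines are the mean (median via config) of a ≥ 100-voxel CSF
region; constructing the anatomical mask is the caller's responsibility. b0,
T1 and T2 intensities are divided by the baseline.

The intensity-ratio labeler implements the printed closed bands —
[1.00, 1.70] black hole, [1.71, 2.60] gray hole, > 2.60 NBH (if
T2-hyperintense) or NAWM — with three documented decisions: IR is rounded to
2 decimals so the bands tile the line (the printed ranges leave a gap at
(1.70, 1.71)); IR below 1.00 (darker than CSF) maps into the black-hole band
with a warning; holes with neither the enhancing nor the persistence flag
return an explicit `"unclassified"` code. Enhancement and persistence are
input flags — they derive from longitudinal and contrast imaging, which are
out of scope. IR is computed per lesion from the lesion-mean T1 intensity
(per-voxel available via config).

## The synthetic cohort

Because the study data are not deposited, the package ships a generator
whose defaults emulate the study's composition: 92 PBH / 89 PGH / 16 AGH /
189 NBH / 113 NAWM lesions (499 total), with lesion sizes drawn from
rounded log-normals whose means (108.3 / 66.5 / 141.1 / 60.6 / 120.9
voxels) match the published mean lesion volumes read on a 1 mm³ grid — the
reading that reproduces the published ~43,000-voxel total. `size_scale`
shrinks lesions proportionally for desk-scale runs.

Each lesion draws lesion-level parameter means from its class profile
(truncated normals), each voxel adds independent jitter (one-level
hierarchy — the simplest structure that makes lesion-grouped splitting
matter). DWI signals are synthesized from the forward model (one fiber +
three isotropic spikes at lesion-specific diffusivities: restricted
0.10–0.25, hindered 0.7–1.4, free 3.05–3.4 µm²/ms), scaled by the
normalized-b0 draw times a nominal CSF intensity, and corrupted by Rician
noise at b0 SNR 30 (typical 3 T DWI). T1/T2 ratios, MTR and the flags are
drawn directly from the profile.

Class-conditional values are **invented** — only histogram shapes of the
source distributions are public — and were fixed by three constraints:
(1) the documented orderings (NAWM highest fiber fraction and MTR; PBH
lowest fiber fraction and most free water; PGH between PBH and NBH; AGH
elevated restricted fraction); (2) T1-IR truncation bounds strictly inside
each class's IR band, so the lesion-level label is always consistent with
the IR labeler while the much larger per-voxel T1 jitter makes voxel-level
distributions overlap (PBH/PGH Bayes error on T1 alone > 10%); (3) a
one-shot separability calibration against the published difficulty
hierarchy: PGH and AGH share fiber fraction, tensor diffusivities and mean
isotropic ADC, differing only in how the isotropic mass splits between the
restricted and free bands — a contrast only the spectrum model sees. Under
these defaults a linear probe reaches ≈ 0.95 / 0.89 / 0.81 / 0.75 test
accuracy on the spectrum / DTI / MTR / conventional feature sets, and the
trained networks land near the published ~93 / 80 / 78 / 74% hierarchy.

What the phantom does **not** emulate: spatial lesion shapes and partial
voluming at borders, scanner drift and artifacts, within-lesion spatial
correlation beyond the lesion-mean shift, registration error between
contrasts, and the real biological coupling between MTR and the diffusion
compartments (MTR is drawn, not derived). Passing results therefore show
the pipeline is correct and well-behaved under the stated generative
assumptions; they do not certify accuracy levels on patient data.

## Classifier

Architecture: input → [dense(nodes) → ELU → batch normalization] × L →
dense(5) → softmax; defaults 10 hidden layers × 100 nodes. Training:
categorical cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999), minibatch 200.
Decisions the source leaves open: features are z-scored with statistics
fit on the training split only (batch normalization alone is sensitive to
input scale at initialization); learning rate 1e-3 (the Adam default);
He-uniform-equivalent initialization; epoch budget 150; no dropout; no
class reweighting (the composition already matches NAWM volumes to lesion
volumes, and precision-recall analysis addresses the residual imbalance);
optional early stopping, off by default. The implementation is plain numpy
in float32, bit-reproducible given a seed.

Splitting is 8:1:1 by voxels but grouped by lesion: within each class,
lesions are shuffled and greedily assigned to the partition with the
largest remaining voxel deficit; no lesion contributes voxels to more than
one partition, and each class reaches every partition. On the full-size
cohort the realized test share lands within one percentage point of 10%.

The architecture-sweep protocol retrains each (depth, width) grid point
under repeated random states (fresh split + fresh initialization) and
records mean/sd validation accuracy and the median number of epochs to
reach 90% validation accuracy (infinite when never reached).

## Evaluation

Confusion matrices use rows = reference, columns = predicted. Discrimination
is one-vs-rest: ROC with trapezoidal AUC; precision-recall with
step-interpolated AUC (average precision — trapezoidal PR interpolation is
optimistic). "Optimal cutoff" is Youden's J with ties broken toward higher
sensitivity (the source does not define its optimum). F1 is 2PR/(P+R) with
0 when both vanish. Confidence intervals: percentile bootstrap, default
1000 iterations, resampling test voxels (lesion-level resampling available);
degenerate resamples (a class absent) are redrawn and counted. The overall
error rate carries an exact Clopper–Pearson binomial interval. No
multiple-testing correction is applied anywhere, and reports say so.

## Known limitations

* Band fractions of multi-component spectra are resolution-limited by the
  shell count (see above); more shells, not more grid nodes, would tighten
  them.
* The two-fiber ceiling and the 20° cluster angle make crossings below
  ~30° unresolvable by design.
* The DNN is CPU-bound numpy; it is sized for 10-feature tabular inputs,
  not images.
* The narrow-network failure mode reported for the source data (10-node
  networks never reaching 90% validation accuracy) does not reproduce on a
  10-feature phantom whose achievable accuracy is ≈ 95%: width-10 networks
  retain enough capacity and merely need ~10× more epochs. Reproducing that
  failure would require making the phantom hard enough that the 90%
  landmark itself becomes unreachable.
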