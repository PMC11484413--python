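# Methods

## Problem setting

Physics plan review of VMAT (volumetric modulated arc therapy) treatment
plans checks, among other things, that the recorded multi-leaf-collimator
(MLC) trajectories and per-control-point metersets are plausible before a
plan is delivered.  `vmatqa` automates this as unsupervised anomaly
detection: an autoencoder is trained on the feature maps of regular
(clinically acceptable) plans only; a new plan is flagged when its
reconstruction error exceeds a calibrated threshold.

## Feature maps

Each control point (CP) is digitized on a uniform raster.  Rows index the
leaf axis (each pair of opposing leaves owns `round(width / resolution)`
contiguous rows, i.e. leaf widths are resampled by row replication), and
columns index the leaf-travel axis.  The aperture map is the binary
indicator of the open region between the banks, evaluated at pixel
centres with open intervals, so a closed pair contributes no pixels.  The
intensity (fluence) map is the per-CP meterset times the aperture,

    A_k(i, j) = 1 if (i, j) inside the open region, else 0
    I_k(i, j) = D_k * A_k(i, j),

a joint geometric/dosimetric descriptor of the beam at that gantry angle.
A full-field raster at sub-leaf resolution (e.g. 0.1 mm -> 3000 x 4000 px
for a 300 x 400 mm field) is far too large for a network input, so maps
are reduced to a configurable target shape (default 64 x 64) by exact
separable area-overlap downsampling: the aperture by area-fraction
coverage binarized at >= 0.5, the intensity by area mean.  The overlap
matrices are row-stochastic and mass-preserving, so the map mean is
conserved for any resize factor, integer or not.  The default logical
raster is 1 mm; `featurize_plan` exploits the per-pair row structure to
avoid materializing the fine raster, and is bit-identical to
rasterize-then-downsample (cross-checked in the tests).

## Models

All four models share one encoder topology: four down-convolution blocks
(a 3x3 stride-2 convolution then a 3x3 stride-1 convolution, each followed
by batch normalization and ReLU), which halve the spatial size four times
(64 -> 4), then a linear block (linear + ReLU) to the latent vector `h`
(default 32 units).  Inputs are intensity maps divided by the training-set
maximum dose; the factor is stored with the model.

**Multi-task AE** (the principal model) has two decoders: an aperture
decoder (linear block, then four up-conv blocks of a 2x2 stride-2
up-convolution plus a 3x3 stride-1 convolution with batch norm + ReLU,
then a 1-channel convolution with a sigmoid head) producing per-pixel
aperture probabilities `A'`, and a dose decoder (three linear blocks and a
linear scalar head) producing the normalized dose `D'`.  The objective is

    L_R = lambda * L_A + L_D,

with `L_A` the mean binary cross-entropy between `A` and `A'` and `L_D`
the mean squared error between normalized doses, `lambda = 1` by default.
The cross-entropy is implemented fused with the sigmoid (logits form) for
numerical stability.

**Baselines** reuse the encoder with a single intensity decoder (sigmoid
output on the normalized scale) under an MSE loss: a Vanilla AE; a
Contractive AE, which adds `gamma * ||dh/dx||_F^2`; and a Variational AE,
whose latent head is a plain linear layer emitting `(mu, log sigma^2)`
(a ReLU there would clamp the log-variance), with reparameterized sampling
in training, the closed-form KL term against N(0, I), and the latent mean
used at inference.

The exact contractive penalty is available through `contractive_penalty`
(one reverse pass per latent unit, batch-norm in inference mode).
Training instead uses an unbiased stochastic estimator,
`||h(x + d*eps) - h(x)||^2 / d^2` with `eps ~ N(0, I)` and `d = 1e-3`,
whose expectation is the squared Frobenius norm; differentiating the exact
norm with respect to the weights would need second-order derivatives that
the layer library does not provide.  The probe size keeps the difference
inside one linear region of the ReLU network while staying well above
float32 resolution; estimator and exact value agree to a few percent on
test models.

### Numerical substrate

No deep-learning framework is used: `vmatqa.nn` implements the layers in
numpy (float32, channels-last) with hand-derived backward passes.  3x3
convolutions run as a single GEMM over a contiguous patch matrix; input
gradients are computed as the matching transposed convolution (stride-2
gradients dilate with zeros first), avoiding slow scatter-adds.  Adam
(lr 1e-3, betas 0.9/0.999) is the only optimizer.  All randomness
(initialization, shuffling, probes, sampling) flows from a single seeded
generator per model, making training bit-reproducible on one CPU.

### Training protocol

The training unit is the individual control point.  Only regular plans
may enter training (enforced).  `cp_stride` subsamples every n-th CP
(adjacent CPs are near-duplicates of one another by the leaf-speed
constraint); the benchmark uses stride 3.  Small minibatches (16) are
preferred because at the fixed learning rate the number of optimizer
steps, not the number of sample visits, limits reconstruction quality on
a single-CPU budget.  Before the first step, the biases of all pre-ReLU
fully connected layers are calibrated on a probe batch (the q = 0.25
pre-activation quantile of each unit is shifted to +0.1): the inputs to
these layers are non-negative, strongly correlated feature vectors, so at
a random initialization a unit's pre-activation can have constant sign
across the whole dataset, and a unit that starts negative everywhere
never recovers.  Batch norm uses batch statistics (and updates
running averages) in training and the running averages at evaluation.
Training aborts with a diagnostic on any non-finite loss.

## Scoring and thresholding

A plan's score is a reconstruction distance averaged over its CPs:

* `d_I` - per-pixel mean squared intensity error, `1/(K M N) sum (I - I')^2`,
  on the physical dose scale.  The per-pixel normalization (rather than a
  per-CP matrix norm) makes scores comparable across raster resolutions.
  For the multi-task model `I' = D' * A'` with `A'` kept as continuous
  probabilities.
* `d_A` - binary cross-entropy between `A` and `A'` (multi-task only).
* `d_D` - mean squared dose error (multi-task only).

A plan is anomalous iff its active distance strictly exceeds the
threshold `alpha` (ties are regular).  Two calibration policies exist:
`oracle_fnr0` chooses the largest observed score that keeps the false
negative rate exactly zero on labeled calibration data — the clinically
motivated operating point where no anomalous plan is ever missed — and is
used for evaluation parity; the label-free `quantile` policy (default
q = 0.99 of regular scores) is the deployable variant, since a training
archive of regular plans carries no anomaly labels to verify FNR = 0 on.

## Synthetic data

No clinical archive is distributable, so `synth_data` generates the study
population: two full 360-degree arcs of 90 CPs each (4-degree spacing, 180
CPs per plan) on an Elekta-Synergy-like machine (40 leaf pairs of 10 mm,
400 mm travel, 5 mm/deg leaf-speed limit, 5 mm minimum gap).  Apertures
follow an elliptical target silhouette whose per-pair gap centre and width
evolve as Gaussian random walks, smoothed along the CP axis (delivery is
continuous; correlation length 15 CPs) and along the leaf-index axis
(apertures conform to smooth organ outlines, so adjacent pairs are
strongly correlated; window = n_pairs/5), then projected CP-by-CP onto
the feasible set (travel range, minimum gap, speed limit) — every regular
plan passes `validate_plan` by construction.  Per-CP metersets are
truncated-normal, mean 5 MU, CV 0.25.

Faults are injected into otherwise-regular plans with kind-specific
defaults chosen once to be gross, human-reviewable errors that corrupt a
substantial fraction of the delivery:

| kind              | default extent                | mechanism                                   |
|-------------------|-------------------------------|---------------------------------------------|
| leaf_jump         | 4 pairs, 60 CPs, 60 mm        | leaf group displaced and snapped back        |
| crossed_leaves    | 6 pairs, 60 CPs, 20 mm        | right bank driven past the left              |
| bank_swap         | 90 CPs (one arc)              | left/right bank columns exchanged            |
| aperture_collapse | 60 CPs                        | gap collapses to the machine minimum         |
| dose_spike        | 5 CPs, x10                    | meterset multiplied                          |
| dose_dropout      | 45 CPs, -> 0                  | meterset zeroed                              |

The first four violate machine constraints and are caught by the
rule-based `validate_plan`; the dose faults leave geometry intact and are
only detectable from the dose record.  What the generator does **not**
emulate: treatment-plan optimizer structure, patient anatomy, dose-rate /
delivery-time dynamics, tongue-and-groove or transmission physics, and —
critically — the unknown phenotype of real clinical anomalies.  Passing
results on this population therefore demonstrate that the pipeline works
end-to-end and can recover known gross faults, not that it attains any
particular clinical sensitivity.

## Evaluation protocol

Anomalous plans are scarce, so they are never split: regular plans are
partitioned into five seeded folds (sizes differing by at most one); each
fold's model trains on the other four fifths (regular only) and is tested
on the held-out regular fifth plus *all* anomalous plans.  Reported
metrics (accuracy, precision, recall, FPR, FNR, F1; anomalous = positive)
are means across folds; ratios with zero denominators are reported as
missing, never as zero.  AUC uses the tie-aware Mann-Whitney (mid-rank)
formulation, which the trapezoidal area under the threshold-sweep ROC
matches to 1e-12 (asserted in tests).  The default benchmark (the
`benchmark` module) uses a single 80/20 split of 200 regular plans plus
20 anomalies, with 2 training epochs over every third CP — about 19k
sample-updates (1,200 optimizer steps) per model, identical for all four
model kinds so the comparison is fair.

## Findings on the synthetic benchmark, and limitations

With the uniform fault mix, the three distances behave very differently.
Signal-*adding* faults (dose spikes, jumped or crossed leaf groups)
inflate `d_I` far beyond the regular range and are detected essentially
perfectly.  Signal-*removing* faults (bank swap, dose dropout, full
aperture collapse — 8 of 20 anomalies) produce near-empty intensity
records; an all-zero map is trivially reconstructable (the dose head
extrapolates `D' ~ 0` on empty inputs, so `I' = D' A' ~ 0`), and the
intensity MSE typically *deflates* their plan scores below the regular
range.  At the default budget the measured AUCs across three seeds are
`d_A` 0.83-0.98, `d_D` 0.80-0.86, `d_I` 0.53-0.69: the aperture
cross-entropy is the most reliable (log loss punishes the decoder's
hallucinated aperture probability mass on off-manifold inputs), the dose
distance second, and the intensity distance the weakest.  The multi-task
decomposition — separate aperture and dose reconstructions — is what
rescues detection where the single intensity distance is structurally
insensitive; a single-output baseline AE scored by intensity MSE shares
that blindness.  The intensity distance *can* dominate when a training
trajectory converges very sharply (one configuration reached `d_I` AUC
0.98 on one seed: a sharp model hallucinates confidently on empty inputs,
inflating even the removal faults' intensity error), but this is not
reliable across seeds at the CPU-scale budget.  Whether clinical
anomalies behave like the adding or the removing kinds is unknowable from
the public record, so these numbers characterize this synthetic
population only.

Other limitations: the numpy substrate trains orders of magnitude more
slowly than a GPU framework, so default budgets stop at an aperture BCE
around 0.1 (reconstructions are sharp to roughly one pixel at 64 x 64);
per-CP fault localization is out of scope; thresholds calibrated under
`oracle_fnr0` use the evaluation labels and are an upper bound on
deployable performance.

## Reproducibility

Every stochastic stage (simulation, splits, initialization, shuffling,
probes) derives from explicit integer seeds; repeated runs are
bit-identical on one CPU.  `run_experiment` writes plan JSONs, the
feature HDF5, model checkpoints, score and metric CSVs, figures, and a
run summary with the config hash, so an artifact directory re-derives
every reported number.
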