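# Methods

This note documents the models implemented in `stesi`, the choices made
where the design was genuinely open, and what the synthetic benchmarks
do and do not demonstrate.

## Forward model

**Geometry.** The head is three concentric homogeneous spheres
(brain < skull < scalp; default radii 79/82/87 mm, conductivities
0.3/0.006/0.3 S/m). Electrodes lie quasi-uniformly on the scalp sphere
and sources quasi-uniformly on a sphere of radius 0.85 × the brain
radius, oriented radially (the spherical analogue of "perpendicular to
the cortical surface"). Quasi-uniformity comes from a Fibonacci lattice
followed by a seeded random rotation, so every head is deterministic
given its seed yet free of axis artifacts.

**Potentials.** For concentric spheres the quasi-static forward problem
has an exact Legendre-series solution. Per degree *n* the radial part in
each layer is `A r^n + B r^-(n+1)`; the dipole contributes a known
singular term in the innermost layer, and the interface conditions
(continuity of potential and of radial current, zero current through the
scalp) give a small linear system per degree whose outer-surface value is
the transfer coefficient t_n. The series is truncated when the newest
term falls below 1e-10 of the accumulated potential (cap 200 terms); with
sources at 0.85 R_brain the terms decay like (0.85·79/87)^n ≈ 0.77^n, so
~100 terms suffice at double precision. The per-degree systems are
column/row equilibrated before solving because r^n and r^-(n+1) spread
over many orders of magnitude at large n.

**Validation.** Setting the three conductivities equal must reproduce a
homogeneous sphere. For that case the series collapses via generating
functions to a closed form (implemented independently in
`homogeneous_sphere_potential`):

    4π σ R² V = m_r [2(c−x)/d³ + (1/d − 1)/x]
              + m_t [2/d³ + (d+1)/(d(1 − xc + d))]

with x = b/R the relative dipole depth, c = cos γ the angle to the
electrode, d = √(1 − 2xc + x²), m_r the radial moment component and
m_t = m·(r̂ − c p̂). The acceptance suite checks 100 random dipoles to
1e-6 relative.

**Region-level source space.** Sources are grouped by farthest-point
seeding plus nearest-seed assignment (regions are spherical Voronoi
cells: non-empty and connected by construction). The regional leadfield
column of region j is the *sum* of its member columns — the "equal
activity within a region" convention — with no size normalization.
Region adjacency links regions containing triangulation-adjacent
sources. All leadfields and all simulated EEG are average-referenced.

Region-size statistics of this synthetic parcellation are configurable
but not calibrated against any anatomical atlas; at 400 sources /
50 regions the mean region holds 8 sources and centroid spacing is
~19 mm, which sets the granularity of the localization-error metric.

## Event-related simulator

Each sample activates `n_regions_active` (default 2) patches: a seed
region drawn uniformly, grown to a graph ball of random order (default
1–3), all members sharing one Gaussian waveform
`f(t) = a exp(−½(6(t−c)/w)²)` with amplitude decayed by
`exp(−d²/2σ_d²)` in the centroid distance d from the seed. Defaults:
amplitude 0.5–1.5 nA·m divided by the head's mean region size, center
49–51 ms, width 125–375 ms, 1 s at 500 Hz, white sensor noise at exactly
5 dB (Frobenius-power ratio, `10·log10(‖Ỹ‖²/‖ε‖²)` — stated explicitly
because several SNR conventions coexist in the literature). Overlapping
patches sum (linearity of the source model). The decay scale σ_d
defaults to the mean centroid spacing of adjacent regions, giving the
first neighbors e^{−1/2} ≈ 0.61 of the seed amplitude.

Two deliberate quirks are worth knowing:

* The default center range (49–51 ms) puts the waveform early in the
  epoch, with much of the Gaussian truncated at t = 0 for wide widths; a
  late-centered variant (e.g. 490–510 ms) is one config field away.
* On coarse toy parcellations the default extension orders can grow two
  patches that jointly cover *every* region, leaving no negatives for
  the extent-AUC. Toy-head experiments therefore use order 1–2
  (maximum observed union 39/50 regions); the 1–3 default is intended
  for parcellations with hundreds of regions.

## Neural-mass simulator

Each region is an *uncoupled* Jansen–Rit column: six states, two
second-order synaptic kinetics (excitatory a = 100 s⁻¹, gain A mV;
inhibitory b = 50 s⁻¹, gain B = 22 mV), connectivity constants
C·(1, 0.8, 0.25, 0.25) with C = 135, and the sigmoid rate function
(e₀ = 2.5 s⁻¹, v₀ = 6 mV, r = 0.56 mV⁻¹). Integration is
Euler–Maruyama at 2000 Hz with ≥ 2 s burn-in discarded; the output is
the net pyramidal potential y₁ − y₂.

**Drive units.** The afferent drive is `p(t) ~ N(μ, σ²)` per step, in
pulses/s. At the canonical operating point (μ = 220 s⁻¹, σ = 22 s⁻¹,
A = 3.25) the column shows the textbook alpha-band oscillation
(spectral peak ≈ 10–11 Hz). The spike dataset uses a *lower* drive,
μ = 87 s⁻¹ (0.087 per ms), where the A = 3.25 column rests quietly while
raising A to 3.6 pushes it across the fold into recurrent
interictal-spike transients. The drive noise there is σ = 100 s⁻¹ — the
package's own calibration, chosen once so that the two regimes separate
cleanly (spikes in ≥ 90 % of 10-s windows at A = 3.6, almost none at
A = 3.25); the literature states the noise scale without units, and no
value in (50, 150) s⁻¹ changes the qualitative picture.

**Spike bank.** Because the columns are uncoupled they are statistically
independent, so instead of simulating Nr separate "region r active"
portions the builder runs, per portion, one vectorized simulation of all
regions at A = 3.6 and one at A = 3.25. A 1-s window (decimated 4:1 with
an order-8 Chebyshev anti-alias filter) centered on a detected spike of
region r is kept iff no background column has an event in that window —
the same acceptance rule as the per-region loop, at 1/Nr the cost.
Spike detection: local maxima above median + 6·MAD with a 250 ms
refractory period (an invented but configurable criterion; the source
recipe does not state one). Windows are median-baseline-corrected.
Event-free background windows are pooled per region for EEG synthesis.

**Sample assembly.** Two patches of order 3 (order 1 on toy heads, same
rationale as above) receive a randomly drawn seed-region spike with the
same Gaussian distance decay as the event-related generator; spike rows
are rescaled so their Frobenius power sits 15 dB above the resting rows;
the EEG projects spikes *plus* background, then white sensor noise at an
SNR drawn per sample from {5, 10, 15, 20} dB (a fixed-SNR mode exists).
The stored ground truth contains only the active rows — background
drives the measurements but never the training target, so the networks
learn to suppress it.

## Inverse solvers

`mne_solve` uses the dual form `X̂ = Lᵀ(LLᵀ + λ̃ I)⁻¹ Y` with
λ̃ = λ·tr(LLᵀ)/Ne, making λ unitless and transferable across head
models. The default "auto" rule is the standard heuristic
λ = 1/SNR_linear with the assumed sensor SNR in dB taken from the
generator (logged with every solution). `sloreta_solve` divides each MNE
row by √S_j, S = diag(K L) the resolution diagonal; S_j > 0 for λ > 0
unless a leadfield column is null, in which case the source is excluded
and flagged. Noise is assumed white (the simulators' truth); a
covariance hook whitens both L and Y for real data. No depth weighting
is applied. The dual and primal forms agree to 1e-8 (tested via the
Woodbury identity), and the noiseless single-source localization of
sLORETA is exact on every region of the test head — the property that
anchors the whole solver/metric chain.

## Learned inverse operators

Three architectures map Ne×T to Ns×T for any T:

* **1D-CNN** — one convolution bank whose kernel spans all electrodes ×
  5 time steps (same-padded), ReLU, dense map to Ns per time step.
  Default 2048 filters; reduced desk-scale 128.
* **LSTM** — two bidirectional layers (hidden 85/direction, dropout 0.2
  between layers), ReLU, dense 170 → Ns per time step.
* **deepSIF-style** — spatial module per time step (residual dense block
  at Ne, residual block lifting Ne → 500 with a dense skip, dense
  500 → 500, ELU activations), then three stacked LSTMs with hidden
  size Ns whose final hidden sequence is the estimate.

Published parameter counts for these architectures cannot be reconciled
with their prose descriptions at the stated sizes; the package logs its
own counts (`Model.n_parameters`) and makes no attempt to match
external tables.

**Loss and scaling.** Training minimizes the per-instant cosine loss
(scale-free; columns with zero norm contribute 0 and are counted), on
pairs normalized by α = max|Y| — a normalization that preserves
Y = L X + ε exactly. Amplitudes are restored at inference by GFP
rescaling: each column of the estimate is scaled so its re-projection
through L matches the spatial standard deviation of the measured column
(zero-variance columns keep scale 1 and are flagged). GFP rescaling is
exact on noiseless self-consistent pairs and idempotent.

**Training.** Adam (lr 1e-3, defaults), batch 8, early stopping on
validation loss (patience 20, best weights restored), global-norm
gradient clipping for the recurrent models, per-pair normalization, all
seeded. The networks run on a ~400-line reverse-mode autodiff engine
over numpy arrays written for this package (broadcast arithmetic,
batched/flattened GEMMs, an unfold op so the CNN trains as one large
matrix product per batch, LSTM graphs unrolled over time with an
iterative topological sort so 500-step sequences do not hit recursion
limits). Gradients of all three architectures are verified against
finite differences in the unit tests. float32 weights are used for the
larger benchmark runs; float64 is the default elsewhere.

## Metrics

LE, extent-AUC and nMSE are evaluated at t₀ = argmax_t |X[seed, t]|
(first index on ties); PSNR over the whole window (normalizing each
matrix by its own max-abs; 10·log10(peak²/MSE), capped at 300 dB when
MSE = 0); time error from argmax_t Σᵢ|X_{i,t}|. The extent-AUC uses the
rank-based ROC area (equivalent to the Mann–Whitney statistic, verified
against it), with TPR = TP/(TP+FN). nMSE uses a 1/Ns factor at the
single evaluated instant.

Multi-patch conventions: AUC labels the union of active members and
per-seed AUC/nMSE values (one t₀ per seed) are averaged. LE defaults to
the strict single-number rule — distance between the global argmax of
truth and estimate at the first seed's t₀. A greedy alternative (each
seed matched to its nearest unclaimed estimated local maximum, averaged)
is provided but not default: it systematically favours noisy estimates,
which always offer a nearby local maximum, over smooth ones, and can
invert method orderings for reasons unrelated to localization quality.

Degenerate estimates never crash an evaluation: an all-zero solution
reports AUC 50 % (tie convention), flagged LE/TE fallbacks, and the
flags travel with the report.

Method comparison: one-way ANOVA per metric across methods (samples as
replicates) plus Tukey HSD pairwise adjusted p-values; identical
distributions with zero pooled variance report p = 1 rather than NaN.

## Benchmark scale and what the tests show

The tested configuration is deliberately desk-scale: 32 electrodes,
400 sources, 50 regions, 2 000 event-related samples (1 600 train /
400 validation), a 128-filter CNN trained for 60 epochs — sized so the
full suite runs on one CPU core in well under half an hour. At this
scale the trained CNN reproduces the qualitative ordering against the
linear baselines: lower mean held-out LE than MNE and a far higher
extent-AUC (the AUC difference is Tukey-significant at p ≪ 1e-6). The
LE *difference*, by contrast, is not statistically resolvable here: the
50-region parcellation quantizes LE to ~19 mm centroid hops (per-sample
std ~17 mm), so an unpaired three-method Tukey test would need roughly
760 validation samples per method to flag a ~2 mm mean gap, and the
2 000-sample 80/20 protocol provides 400. The corresponding
significance assertion in the acceptance suite is kept at face value
and documents this as its expected failure mode at desk scale. The
*magnitudes* of full-scale results do not transfer either: the toy
patches cover a far larger cortical fraction than realistic extended
sources, and 60 epochs on 1 600 samples is far short of convergence at
full scale. Full-scale settings (90 electrodes, ~10³ regions, 10⁴ samples,
2048 filters, 500-epoch budget) are reachable through the same configs
given hours of compute.

Known limitations, beyond scale: the spherical head has no skull
anisotropy or realistic cortical folding, so leadfield correlations are
milder than in BEM/FEM models; the Jansen–Rit columns are uncoupled (no
connectome); time error of cosine-trained networks on this data is
poor — the loss carries no amplitude-profile information and GFP
rescaling ties column amplitudes to the sensor noise floor at
event-free instants, so the summed-activity peak is weakly constrained;
and real-EEG evaluation (co-registration, measured noise covariance,
artifact handling) is an extension point, not a tested path: the
leadfield-import hook and the whitening hook are where it plugs in.
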