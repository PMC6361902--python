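# Methods

This note documents the models implemented in `brainsongs`, the choices
made where the design was genuinely open, and what the synthetic test
bed does and does not establish.

## Whole-brain dynamic mean-field model

Each brain region is a reduced Wong–Wang node: an excitatory (NMDA) and
an inhibitory (GABA-A) population described by gating variables
S_i^(E), S_i^(I). Input currents are

    I_i^(E) = W_E I_0 + w_+ J_NMDA S_i^(E) + G J_NMDA Σ_j C_ij S_j^(E) − J_i S_i^(I)
    I_i^(I) = W_I I_0 + J_NMDA S_i^(E) − S_i^(I)

with firing rates r = H(I) = (aI−b)/(1−exp(−d(aI−b))) per population and
gating dynamics

    dS^(E)/dt = −S^(E)/τ_E + (1−S^(E)) γ r^(E) + σ υ(t)
    dS^(I)/dt = −S^(I)/τ_I + r^(I)/1000 + σ υ(t)

(time in ms; the 1/1000 converts Hz to per-ms units, consistent with
γ = 0.641/1000). C_ij is the structural connectome, G the single global
free parameter. Defaults are the standard calibrated constants:
a_E = 310 nA⁻¹, b_E = 125 Hz, d_E = 0.16 s, a_I = 615, b_I = 177,
d_I = 0.087, τ_E = 100 ms, τ_I = 10 ms, I_0 = 0.382 nA, W_E = 1,
W_I = 0.7, w_+ = 1.4, σ = 0.01 nA. J_NMDA defaults to 0.15 nA (the value
of the model lineage this reduction comes from; it is configurable
because it is not uniquely fixed by the rate constants above).

Numerics: Euler–Maruyama, default dt = 0.1 ms, noise scaled by σ√dt,
the whole noise stream governed by one integer seed (bit-identical
reruns). Gating is clipped to [0, 1] after every step — with additive
noise this is a contract, not a safeguard: excursions outside the
physical range would otherwise occur at a rate set by σ√dt. Rates,
currents and gating are recorded as averages over 1 ms windows
(configurable `record_dt`); recording at dt would cost ~40× the memory
with no information relevant downstream (the hemodynamic model and the
binning pipeline both operate at ≥ 1 ms). The first 2 s are discarded
before any statistic.

The transfer function's removable singularity at aI − b = 0 is evaluated
by the series 1/d + x/2 + dx²/12 for |d·x| < 1e-6; the branch is exact to
double precision at the switch point and keeps H strictly increasing.

### Feedback Inhibition Control

J_i is tuned per region so the excitatory rate sits at a target (3 Hz
default) whatever the coupling. The tuner is a cascaded controller:

1. inner loop: damped Newton step on the mean excitatory current,
   J ← J + η (⟨I^(E)⟩ − I*)/⟨S^(I)⟩, using dI/dJ = −S^(I);
2. per-region step scales η_i adapt Rprop-style (halved when the step
   direction flips, grown 10% otherwise, capped at the initial damping
   0.5) — without this the loop limit-cycles in strongly recurrent
   regimes where network feedback steepens the true gain;
3. outer loop: the current setpoint I* (initially H⁻¹(target), found by
   Brent's method) is nudged to compensate the noise-induced boost of
   the mean rate above its deterministic value; this correction is only
   applied within 5 Hz of the target where the linearisation is valid.

Tuning simulations are 10 s (growing to 40 s if convergence is slow);
convergence requires every region within 0.8·tol of the target, and an
independent 20 s verification simulation must confirm it within tol
(0.5 Hz default), else an error reports the per-region residuals.

A single uncoupled node tuned this way fires at 3.0–3.1 Hz (excitatory).
The inhibitory population then fires at ≈ 4.1 Hz, not the 9 Hz of the
spiking network this reduction descends from: at a 3 Hz excitatory
point, I^(I) = W_I I_0 + J_NMDA S^(E) − S^(I) ≈ 0.20 nA, far below the
≈ 0.28 nA that H^(I) would need for 9 Hz. The 3/9 Hz pair is a property
of the full spiking model; the reduced rate equations reproduce the
excitatory member of the pair only. The package reports what it
computes.

## Hemodynamics

The Balloon–Windkessel model maps the regional excitatory rate to BOLD:
vasodilatory signal ds/dt = c₁r + c₀ − κs − γ_h(f−1), inflow df/dt = s,
volume τ v̇ = f − v^{1/α}, deoxyhemoglobin
τ q̇ = f·E(f)/ρ − q v^{1/α}/v with E(f) = 1 − (1−ρ)^{1/f}, and
B = V₀[k₁(1−q) + k₂(1−q/v) + k₃(1−v)]. Constants follow the standard
calibration: κ = 0.65 s⁻¹, γ_h = 0.41 s⁻¹, τ = 0.98 s, α = 0.32,
ρ = 0.34, V₀ = 0.02, k₁ = 7ρ, k₂ = 2, k₃ = 2ρ − 0.2.

The drive default is c₁ = 0.5, c₀ = 3 (the rate-modified convention of
the whole-brain model); `HemodynamicParameters.standard()` gives the
classical c₁ = 1, c₀ = 0. The offset drive implies a large steady
baseline flow (f* = 1 + (c₁r+c₀)/γ_h ≈ 12 at 3 Hz); this only shifts
the operating point — BOLD fluctuations still track rate fluctuations —
but it is why both conventions are exposed rather than asserted.

Integration is explicit Euler on log f, log v, log q at the neural
recording step (1 ms), which keeps the states positive by construction;
a non-finite state raises with the offending region and step. BOLD is
averaged within each TR window. Because the hemodynamic transient from
rest decays on the κ/2 timescale, pipelines discard the first 20 s of
BOLD (configurable).

Band-pass filtering into the resting band (0.01–0.1 Hz default) is a
zero-phase Butterworth (order 2, second-order sections, forward–
backward). Signals shorter than the filter warm-up are rejected. The
zero-phase property implies time-reversal symmetry away from the edges;
padding transients decay on the 1/f_low timescale, which is why phase
statistics discard 10 samples at each end.

## Working-point fitting

Empirical and simulated BOLD are band-passed, linearly detrended, and
converted to phases via the Hilbert analytic signal; the Kuramoto order
parameter R(t) = |Σ_k e^{iφ_k(t)}|/n summarises global synchrony. For a
grid of G values the model is FIC-tuned, simulated (360 s default),
pushed through the hemodynamics, and the objective
(⟨R⟩_emp − ⟨R⟩_sim)² is minimised by grid argmin. FC similarity
(Pearson correlation of the FC upper triangles) and metastability
(std of R(t)) are computed alongside as diagnostics; they do not drive
the selection. With several empirical recordings, ⟨R⟩ is computed per
recording and then averaged. Per-G failures (e.g. FIC non-convergence
in a super-critical regime) are recorded and skipped; only an all-failed
sweep raises.

On a 20-region synthetic connectome, surrogate BOLD generated by the
model itself at G = 1.0 is recovered within one grid step of a 5-point
grid; the residual step-level uncertainty reflects seed-to-seed
variation of ⟨R⟩ between independent runs at the same G.

## Spacetime-motif extraction

Given any region × time activity at ms resolution: (1) average within
non-overlapping bins of width Δ (the timescale under study; trailing
partial bin dropped); (2) z-score each region (population SD) and mark
events at upward crossings of θ = 1 SD — a Poincaré-section reduction,
which is what makes the result threshold-insensitive; the state before
the first bin is taken as sub-threshold, so a super-threshold first bin
counts; plain thresholding is available but not default; (3) z-score
the binary event matrix row-wise (Eq-13 convention, population SD);
rows with zero variance at either stage are excluded with a warning;
(4) eigendecompose e·eᵀ/N_B and count eigenvalues strictly above the
Marchenko–Pastur bound λ_max = (1 + √(N/N_B))² (ρ² = 1 after
z-scoring; ties at the bound are not counted; N_B ≥ N is required);
(5) project e onto the K significant principal axes and unmix with
FastICA; motif weights are mapped back to region space, unit-normed,
sign-fixed so the dominant weight is positive, and ordered by total
activity. K = 1 needs no unmixing (the motif is the principal axis).
FastICA restarts up to 5 times with fresh internal seeds and
progressively relaxed tolerance before erroring. Motif activity is the
squared projection A_cb = (w_c·e_b)², probabilities
p(c) = Σ_b A_cb / Σ_cb A_cb.

`MotifExtractor` exposes this as a scikit-learn transformer
(X of shape (n_samples, n_regions); fitted attributes `n_motifs_`,
`weights_`, `activities_`, `probabilities_`, `eigenvalues_`,
`mp_bounds_`).

Calibration: on 200 independent binary rasters (N = 30, N_B = 600) the
spurious-component rate is 4%; a planted co-active group of 6 regions
is detected as exactly one component in > 95% of seeds with membership
cosine > 0.9.

## Repertoire metrics and the timescale sweep

Entropy H = −Σ_c p(c) log p(c) (natural log default, bits optional)
measures the richness of motif switching. Cohesiveness
Coh(i) = Σ_c w_ic p(c) (Σ_j w_jc) aggregates participation ×
probability × broadness; hierarchy is its population SD across regions.
Weights enter exactly as extracted (sign-fixed, non-thresholded, no
absolute values). The transition-probability matrix assigns each bin to
its dominant motif (ties → lowest index), counts consecutive-bin
transitions and row-normalises; never-dominant motifs get a uniform row
with a warning.

The timescale sweep runs the full extraction at each bin size of a
grid, skipping sizes that leave fewer bins than regions, and reports
K, entropy, hierarchy, the TPM, and the mean absolute off-diagonal
correlation of the binned (pre-binarisation) signals. The entropy
argmax is the reported optimum; the hierarchy argmax is reported
separately, and both are refined by a parabola through the three
neighbouring grid points on a log-bin axis (the refinement stays at the
grid point when the triple is not locally concave or the argmax is at
an edge).

## Synthetic test bed

`make_connectome` generates community, distance-decay, or
ring-plus-shortcut matrices (symmetric, zero diagonal, nonnegative),
normalised so the largest row sum equals `weight_scale` — this keeps
the informative range of G comparable across families and sizes.
`damage_connectome` zeroes the top k% strongest edges.

`make_planted_raster` is the ground-truth bed for the extraction
pipeline. Background is unit-variance white noise per region plus a
shared global co-fluctuation (OU process, SD 0.15, τ = 1 s) mimicking
the global signal of real recordings. Each assembly is an alternating
renewal process: Erlang dwell times (shape 3 active with mean D, shape
6 inactive) with the inactive mean set so the stationary active
fraction is p = 0.15. Per activation each member participates with
probability 0.75 and its interval is shifted by a uniform jitter of up
to ±1.0·D. The jitter is what gives "characteristic duration" its
operational meaning: members co-occupy bins only at resolutions
comparable to D, so detection fails at much finer bins; the
quasi-regular (Erlang) recurrence removes coarse-bin count
fluctuations, so detection also fades at much coarser bins. Amplitude
is 1.0 background-SD — a weak modulation, individually invisible at ms
resolution, which is the realistic regime for whole-brain co-activation
and the regime in which the binning timescale matters at all. With
these defaults the entropy curve over {25…1600} ms peaks within a
factor of 2 of the planted D for D = 100 and 400 ms in ≈ 90% of seeds,
and the mean-FC curve is monotonically non-decreasing in bin size.

What the bed does not emulate: hemodynamic confounds, scanner noise,
heterogeneous per-region dynamics, assemblies with graded (non-binary)
membership, and any spatial embedding. Passing recovery tests on this
bed therefore validates the pipeline's statistical machinery, not
claims about real brains.

### A structural caveat on hierarchy

On this test bed the hierarchy curve does *not* co-peak with entropy.
This is a property of the statistic, not an implementation artefact:
for a cleanly detected motif of m equal members,
Coh(member) ≈ p(c), so the SD across regions scales with the
probability concentrated on few narrow motifs. Bin sizes where only one
or two assemblies survive detection therefore show *higher* hierarchy
than the bin where all assemblies are resolved (where p is spread),
and at the coarsest bins eigenvector estimation noise — amplified by
the broadness factor Σ_j w_jc — inflates it further. Making extreme-bin
detections broad (global modes, shared rate modulation, overlapping
memberships) reduces but does not invert the effect. The co-peaking of
entropy and hierarchy reported for brain recordings is thus an
empirical property of those data; planted-assembly surrogates of this
family cannot reproduce it, and the corresponding test is expected to
fail by design of the statistic.

## Pipeline

`run_pipeline` chains fit → simulate-at-working-point → timescale
sweep, writing every intermediate, per-stage timings, and a manifest
(config hash + seeds) from which a rerun reproduces the report.
Robustness switches shift the working point (`shift_G`), damage the
strongest edges (`damage_edges`), scale the E/I balance (`W_I`
multiplier) and the NMDA time constant — the manipulations under which
the timescale optimum is expected to degrade.

## Problem sizes

Defaults in tests and examples use 20–30 regions, 100–360 s of
simulated or generated signal, and 5-point G grids; these sizes put
every recovery experiment's statistical power comfortably above the
asserted thresholds while keeping any single experiment under a few
minutes on one core. All experiments scale linearly in duration and
(for the simulator) quadratically in region count.
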