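# Methods

## The model

`synapsim` simulates one glutamatergic synapse as a stochastic particle
system in two phases and provides the single-molecule analysis methods
used to quantify receptor organization and dynamics.

### Phase 1 — organization (1 ms steps, 50 s)

The post-synaptic membrane is a set of concentric discs: a synaptic
membrane patch (radius 560 nm) over which free AMPARs diffuse, a disc
confining free PSD-95 (520 nm), and one nanodomain (radius 50 nm — the
"100 nm domain" corresponding to the AMPAR nanocluster) at the centre.
Particles and reactions:

* **PSD-95** (200 copies) diffuses freely (0.05 µm²/s) and is
  palmitoylated inside the nanodomain (kon = 35 /s, koff = 0.7 /s).
  Palmitoylated PSD-95 is slowly mobile (0.005 µm²/s), confined to the
  nanodomain, and acts as a trapping slot.  PSD-95 can be irreversibly
  inactivated (k6, baseline 0.002 /s), modelling its phosphorylation-
  driven degradation during LTD; an inactivated slot releases its bound
  receptor.
* **AMPARs** (120 copies; 60 surface + 60 internal) diffuse at 0.5 µm²/s
  when free, exchange with the intracellular pool at equal rates
  (k8 = k_exo, baseline 0.005 /s), and bind palmitoylated PSD-95
  (kon = 5 /s per receptor-slot contact within the 25 nm reaction
  radius, koff = k4 = 1 /s).  A trapped receptor-slot pair moves
  together at 0.005 µm²/s, confined to the nanodomain.

Dynamics are a fixed-step tau-leap: Gaussian steps of per-axis variance
2·D·dt with radial reflection at each species' confining disc, and
Bernoulli reaction firing at probability 1 − exp(−k·dt) per step.  At
dt = 1 ms the largest per-step probability is 0.034 (palmitoylation);
the reaction-only subsystems were validated against a Gillespie SSA
oracle and closed forms (see the test suite).  For rare channels the
per-step event count is drawn as an exact Binomial(m, p) over the m
eligible particles with uniform selection — statistically identical to
per-particle Bernoulli draws but far fewer RNG calls.

LTD perturbations multiply one rate: endocytosis ×3 (`endo_x3`),
PSD-95 inactivation ×4 (`inact_x4`), or untrapping ×4 (`untrap_x4`).

### Phase 2 — glutamate response (1 µs steps, 250 ms)

Starting from the equilibrated phase-1 state, five glutamate releases at
20 Hz each insert 2500 point molecules at the cleft roof (a 20 nm slab)
directly above the nanodomain.  Glutamate diffuses in 3D at 0.2 µm²/ms
with reflective cleft faces; beyond the escape radius it is absorbed,
standing in for diffusion into the surrounding neuropil plus transporter
uptake.  Receptors gate through the seven-state CA3 AMPAR scheme of
Jonas, Major & Sakmann (1993): closed states with 0/1/2 glutamate bound,
one open state, and three desensitized states.  The source model used
these constants re-fitted to recorded mEPSCs without publishing them, so
the published 1993 values are the defaults here and every rate is
configurable.  Binding is a per-step proximity reaction: a glutamate
within the 25 nm binding radius of a receptor fires the scheme's binding
transition with probability kon·dt/(N_A·V), V = π·r²·h being the capture
cylinder; this reproduces the bimolecular rate kon·[glu] in the
well-mixed limit (verified against the matrix-exponential solution of
the master equation).  Unbinding returns the glutamate to the cleft at
the receptor position.  All organization reactions and receptor
diffusion continue during the train, so naïve mobile receptors can
replace desensitized ones between pulses; unbound PSD-95 diffusion is
advanced every 16 µs with variance scaled accordingly (it moves ~0.3 nm
per µs; the coarse Brownian increment is exact, and reflection at 16 µs
granularity is immaterial at these step sizes).

The response amplitude of a pulse is the maximum open-channel count in
its 50 ms window — the simulation's reported observable.  (A boxcar-
smoothed readout was evaluated and rejected: it damps the sharp
synchronous pulse-1 transient more than broader later peaks and thereby
biases paired-pulse ratios.)  PPRn/1 is computed per trial and averaged;
trials with a zero first peak are excluded and counted.

## Calibration of the unstated parameters

The source model states the reaction scheme, particle counts, the
palmitoylation/binding constants and the resulting operating point
(~70 palmitoylated PSD-95 in the nanodomain, 20–25 trapped AMPARs), but
not the geometry of its EM-derived mesh, the pool-exchange rate, the
inactivation baseline, or the reaction radius.  These were calibrated
once, by closed-form analysis confirmed with a small simulation grid,
to reproduce the stated operating point — the same "adjusted to reach
the observed distribution" procedure the source model describes — and
then frozen:

* **PSD-95 confinement radius 520 nm.**  With first-order in-nanodomain
  palmitoylation, the steady state obeys
  P/(A−P) = (kon/koff)·(A_nd/A_conf) for A active copies.  P ≈ 70 of
  200 requires a confinement-to-nanodomain area ratio of ~90; a 180 nm
  PSD (area ratio 13) would give P ≈ 159.  In-nanodomain rebinding after
  depalmitoylation (exit time ~12 ms against a 29 ms re-palmitoylation
  time) raises occupancy above the closed form, which the simulation
  grid absorbed into the final radius.
* **Reaction radius 25 nm.**  Receptor-slot binding is read as
  mass-action over receptor-slot pairs (each pair within the reaction
  radius is an independent 5 /s channel — the Gillespie/MCell reading of
  a bimolecular surface reaction).  A single gated first-order 5 /s
  channel per receptor cannot reach the stated 20–25 trapped receptors:
  with ~1% of free-receptor time spent in the nanodomain it saturates
  near 3.
* **Pool exchange 0.005 /s.**  An equilibrated free-pool exchange under
  endocytosis ×3 settles at surface fraction k_exo/(3k_endo + k_exo) =
  0.25 — a ~45–50% depletion of both free and trapped pools,
  double the reported ~25% response depression.  The reported magnitude
  requires the 50 s perturbed phase to re-equilibrate only partially;
  0.005 /s (pool time constant ~100 s, minutes-scale constitutive AMPAR
  recycling, consistent with measured spontaneous endo/exocytosis
  rates) yields a ~20% trapped-pool depletion at 50 s.
* **Inactivation baseline 0.002 /s.**  Control loses < 10% of active
  PSD-95 over 50 s while the ×4 condition loses ~30%, matching the
  experimentally observed PSD-95 depletion scale.
* **Glutamate escape radius 2× synapse radius.**  Absorption at the
  synapse rim clears the cleft in ~0.3 ms, too fast to populate the
  slow-recovery desensitized states (pulse-2 responses then show almost
  no depression at 50 ms, leaving nothing for receptor mobility to act
  on).  The default reproduces the ~1 ms cleft clearance measured at
  central synapses and the retention a full neuropil geometry provides.

## Analysis methods

* **SPT** (`synapsim.spt`): time-averaged MSD over all frame pairs; D
  from an ordinary least-squares line through the first four MSD points
  (D = slope/4 in 2D, intercept free — localization noise adds intercept,
  not slope; negative fits are kept and fall into the lowest log-D bin);
  mobile fraction = % of tracks with D > 0.02 µm²/s; instantaneous D
  from the same fit in a sliding window (default 9 frames, truncated
  edges ≥ 5 points); classes I/II/III (always mobile / always immobile /
  alternating) from the strict all-points rule, with % time immobile.
  The strict rule is estimator-noise-limited: with 30 nm localization
  noise, pure tracks of 200 frames are almost always classified III
  because some window crosses the threshold; class recovery ≥ 0.8 holds
  on noise-free tracks with window 31 (measured in the test suite), and
  the window is the documented trade-off between class purity and
  switch-point localization (± half a window).
* **Tessellation clustering** (`synapsim.clustering`): per-point density
  from the rank-1 Voronoi neighbourhood (own + adjacent cells; border
  cells get zero).  Segmentation keeps points above density_factor × the
  regional average and groups them by Delaunay adjacency — but
  thresholds on the single-cell density 1/A: the smoothed density of a
  uniform field puts ~50% of points above its mean, the site-percolation
  threshold of the Delaunay graph, so spurious components percolate and
  no point-count filter can remove them; the skewed 1/A distribution
  keeps ~35% (subcritical).  min_points defaults (80 level 1, 50
  level 2) are the uniform-field calibration: the largest spurious
  component over 25 uniform calibration fields was 65.  Level 2 re-runs
  the same rule on one cluster's points against the cluster's own
  average density.  Cluster diameter is the mean of the two principal-
  axis FWHMs (2√(2 ln 2)·σ) of the maximum-likelihood 2D Gaussian — the
  sample covariance eigendecomposition, which is the closed-form MLE.
  Molecule counts divide localization counts by the mean localizations
  per isolated emitter (half-up rounding, raw ratio also reported); no
  further blinking correction is applied, a documented limitation.
  Two-colour organization is nearest-centroid distances within a pairing
  radius; chromatic registration is assumed done upstream.
* **Release probability** (`synapsim.fluorescence`): a stimulus is a
  release if the first sample after it exceeds 3 SD of the 200 baseline
  points before the train; probability = successes / stimuli.

## Synthetic data

The generators provide every input with ground truth: two-state Markov
switching Brownian tracks (defaults: D 0.1 / 0.008 µm²/s — the two
observed populations — switch rates 0.3 / 0.7 /s giving 30% stationary
mobile occupancy with seconds-scale dwells, 30 nm localization noise
applied post hoc as a measurement model, 50 Hz, geometric track lengths
of mean 50 frames with a 10-frame floor); blinking-emitter fields
(negative-binomial localizations per emitter, mean 12, shape 5, 10 nm
precision, optional per-channel offsets); and Bernoulli-release sensor
traces with exponential response decay on Gaussian baselines.  They
emulate the statistical structure of uPAINT, dSTORM and glutamate-sensor
data, not their imaging physics: no PSF, no drift, no track-linking
errors, no fluorophore photophysics beyond the localization-count
distribution.  Passing tests therefore demonstrate estimator
correctness under the stated statistical model, not robustness to
acquisition artefacts.

## Problem sizes and numerical choices

Scenario aggregates use 24 paired-seed trials per condition (the full
protocol averages 96–100; trial counts are configurable), eight trials
for the reversibility protocol with segments 50/100/300 s (the restore
segment spans ~2.5 pool time constants; scaffold inactivation is off in
this protocol, which probes the endocytosis pathway alone — with it on,
the baseline itself decays over the several-hundred-second run and
"recovery to baseline" is ill-posed), and final-10-s averages for
steady-state summaries.  Trajectories exported for mobility summaries
are segmented to 50 frames (1 s at 50 Hz), the photobleaching-limited
track length of the tracking technique being emulated; without the cut,
a 10 s track averages over many trap/untrap cycles (trap dwell ~1 s)
and every track fits a supra-threshold D.  Per-trial peak counts are small
integers (~10–15 open channels), so percent-change estimates at this
scale carry Monte-Carlo standard errors of several points; the paired
seed design shares per-trial RNG streams between conditions.  All
randomness derives from a single base seed through `SeedSequence`
spawning; identical (config, seed) reruns are byte-identical.  Particle
kernels are Numba-compiled; the first call in a fresh environment pays
a one-time compilation cost.

## Known limitations

* The synapse is one closed disc system: receptors released from traps
  accumulate in the synaptic free pool instead of dispersing into the
  dendritic membrane, which damps depression under slot loss and the
  mobility-driven facilitation relative to an open neuropil geometry.
* Channel constants are the published 1993 values, not the unpublished
  mEPSC-refitted ones; paired-pulse quantities inherit that uncertainty.
* Glutamate uptake is a hard absorbing rim, not transporter kinetics.
* The cluster segmentation has no multi-emitter blinking correction
  beyond the calibration division.
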