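# Methods

`sparsewave` simulates sheets of conductance-based leaky integrate-and-fire
(LIF) neurons with topographic connectivity and distance-dependent axonal
conduction delays, and analyzes the traveling waves that emerge in the
network's simulated local field potential (LFP). This note documents the
model, the estimation procedures, the default parameters and the reasoning
behind the choices that were genuinely open.

## Neuron and synapse model

Each neuron obeys

    Cm dV/dt = GL (EL - V) + ge (Ee - V) + gi (Ei - V) + I_ext
    tau_e dge/dt = -ge          tau_i dgi/dt = -gi

When `V >= VT` the neuron emits a spike, resets to `Vr`, and is clamped at
`Vr` for the refractory period `tau_r` (the membrane is not updated during
the clamp). Each spike schedules a conductance increment `Ge` (excitatory
source) or `Gi` (inhibitory source) onto each of the neuron's K targets,
delivered after the connection's conduction delay

    tau(i,j) = tau_s + d(i,j) / vc(i,j)

where `d(i,j)` is the torus (periodic) Euclidean distance and `vc` the
axonal conduction velocity, either a constant or drawn per connection from
a uniform range. Delays are quantized to the integration step (never below
one step); the rounding bias is below dt/2 = 0.05 ms, negligible against
delays of 0.5–30 ms.

Integration is forward Euler at dt = 0.1 ms. Within a step the order is
fixed: (1) apply conductance increments due this step, (2) decay
conductances, (3) advance membrane potentials of non-refractory neurons,
(4) register threshold crossings (no sub-step interpolation). Delayed
deliveries run through a ring buffer of per-step accumulators, so an
increment scheduled for step n is applied at exactly step n.

### Default constants

| symbol | value | unit | meaning |
|---|---|---|---|
| Cm | 200 | pF | membrane capacitance |
| GL | 10 | nS | leak conductance (tau_m = 20 ms) |
| EL | -60 | mV | resting potential |
| Ee / Ei | 0 / -80 | mV | synaptic reversal potentials |
| VT / Vr | -50 / -60 | mV | threshold / reset |
| tau_e / tau_i | 10 / 10 | ms | synaptic decay times |
| tau_r | 5 | ms | refractory period |
| tau_s | 0.1 | ms | synaptic release delay |
| Ge / Gi | 1 / 10 | nS | synaptic weights (full-scale reference) |

These are assumptions in the standard conductance-LIF range, not measured
values, and every one is config-exposed. The synaptic decay times deserve
a note: with the classic fast-excitation kinetics (tau_e = 5, tau_i = 10
ms) we found no self-sustained asynchronous-irregular (A-I) state at desk
scales (~28k neurons, K ~ 750) for any weight combination — only silence
or a refractory-locked synchronous oscillation, with a sub-nanosiemens
knife edge between them. Matching the synaptic time constants at 10 ms
lets recurrent excitation bridge inhibition volleys and opens a robust
self-sustained A-I band along the Gi = 10 Ge diagonal, which is exactly
the weight ratio of the reference configuration. We adopt tau_e = tau_i =
10 ms as the package default and flag it as the single most consequential
parameter assumption.

## Network construction

Excitatory neurons (80%) and inhibitory neurons (20%) occupy two
concentric, cell-centred square lattices of common side L with periodic
boundaries (a ring in the 1D variant). Exactly K outgoing synapses per
neuron; targets are drawn either uniformly over the whole sheet ("random"
networks) or from an isotropic 2D Gaussian displacement of SD sigma
wrapped onto the torus and snapped to the nearest lattice site
("topographic" networks), with the target population chosen in proportion
to population size. Self-connections and duplicate pairs are rejected and
redrawn; rejection is performed in vectorized rounds and reproduces
sequential rejection sampling exactly. An optional rewiring step redraws a
fraction of all connections uniformly (with recomputed delays), producing
the mixed local/long-range variant.

The out-degree maintains the density of connections inside the kernel
footprint: K scales with `min(L^2, pi (3 sigma)^2)` and saturates at 3000
(the full-scale value) once the sheet contains the 3-sigma disc of the
reference kernel (L >= 2 mm at sigma = 0.4 mm). A uniform (random) kernel's
footprint is the whole sheet.

## Initialization of self-sustained activity

A configuration is bootstrapped once: from rest, every neuron receives an
external Poisson barrage (100 synapses at 2 spikes/s for 100 ms, weight
Ge) and the network then runs freely (default 2 s). A gentle, extended
kick matters: stronger or shorter kicks synchronize the ignition volley,
which either extinguishes the network through a massive inhibition wave or
locks it into the synchronous oscillation. The final state's population
mean and SD of V, ge and gi form a Gaussian summary ("moments"); if the
final fifth of the settling window contains no spikes the configuration is
flagged not self-sustained. Production runs draw V, ge, gi independently
per neuron from those moments (V clipped into (Ei, VT), conductances at
zero), run 1.2 s and discard the first 200 ms from analysis. Simulations
are bit-reproducible: identical configuration and seed give identical
spike tables, and all randomness derives from named substreams of one
master seed, so e.g. changing the number of analysis shuffles cannot
perturb the simulation.

A sliding-window rate guard (100 ms window; threshold 25 sp/s by default)
aborts runaway simulations, mirroring the early-exit used in large
parameter scans.

## LFP proxy

The LFP of each non-overlapping pool of 10 x 10 excitatory neurons is

    lambda(t) = sum_j Ie_j(t - tau_lag) - alpha * sum_j Ii_j(t)

with tau_lag = 6 ms and alpha = 1.65. Pooled currents are reconstructed
from the pooled conductances times the driving force at the pool-mean
membrane potential; on a test network this agrees with summing per-neuron
currents to better than 1% RMS. Both terms are positive under this sign
convention (the inhibitory driving force is negative), so epochs of high
total conductance — the inhibition-dominated, shunted state — map to
positive z-scored LFP and excitation-dominated epochs to negative values;
the pooled (ge - gi) difference consequently anticorrelates strongly with
the z-scored LFP. Pooled traces are sampled at 1 kHz by averaging within
each 1 ms bin. A framewise 2D Gaussian blur (SD four pool widths by
default) optionally emulates the ~250 um spatial integration of real
electrodes; simulation-internal analyses run on the unsmoothed field.

## Wave analysis

Each pool trace is band-passed 5–100 Hz (4th-order Butterworth,
forward-reverse), converted to its analytic signal, and the phase is
repaired over epochs of negative instantaneous frequency by interpolating
the unwrapped phase across the flagged run (the "generalized phase" of a
wideband signal). One low-band period at each end of the record is marked
invalid against filter transients.

Spatial phase gradients are computed wrap-free as complex multiplications,
`delta phi = arg(L[n+1] conj(L[n]))`, averaged into centred differences in
the interior with one-sided differences at edges (cyclic differences under
periodic analysis). The wavelength at a point is the reciprocal gradient
magnitude read in cycles/mm (so it is a true spatial wavelength in mm),
and the speed is the ratio of instantaneous frequency to gradient
magnitude (the 2 pi cancels; mm/ms = m/s).

Significance of spatial organisation is assessed against a spatial shuffle
of pool positions. The generalized phase of a pool is invariant under
relabeling, so each shuffle permutes the analytic field across space and
reruns the gradient/wavelength pipeline; the 99th percentile of the pooled
shuffle wavelength distribution is the detection threshold and the wave
fraction is the share of points exceeding it. Two properties matter in
practice. First, the threshold is computed on uncapped wavelengths:
capping at the aperture piles observed and shuffled values onto the same
ceiling during near-synchronous frames and empties the strict-exceedance
mask (capping is still applied to reported wavelength fields). Second, the
shuffle tail sets an intrinsic detection floor of roughly 30 x pitch: only
organisation smoother than that is separable from chance, which is also
why wave detection demands wavelengths large relative to electrode
spacing in any recording.

The space–time spectrum transforms each 1D slice of the movie in space and
then in time and divides the power elementwise by the mean spectrum of
spatially and temporally shuffled surrogates; white noise maps to ~1
everywhere while constant-speed propagation concentrates energy along
f = v k. The propagation speed is fitted as the line slope maximizing
on-line mean power; for conduction-delay questions the search is
restricted to the unmyelinated-axon range (0.08–0.8 m/s) and to temporal
frequencies within the analysis band, since slow drifting structure below
5 Hz would otherwise masquerade as an ultra-slow line.

Relative band power between two equal windows of a single trace is the
ratio of sums of squares of the 5–50 Hz filtered signal, in dB.

## Spike statistics

Rates and interspike-interval CVs are measured on a random sample of 5000
neurons (CV requires >= 3 spikes). A network is self-sustained if it
spikes in the final 200 ms and asynchronous-irregular (A-I) if in addition
the mean rate lies in (1, 25) sp/s and the mean CV in (0.7, 1.4).
Pairwise correlation is the mean Pearson correlation of 1 ms-binned,
100 ms boxcar-smoothed trains over 1000 random pairs. Pairwise spike
coherence between two pools sums each pool's 100 trains, cuts the record
into 500 ms epochs stepped by 125 ms, applies a single Slepian taper
(2.5 Hz half-bandwidth), and averages auto-/cross-spectra over epochs
before forming |Sxy| / sqrt(Sxx Syy).

Spike-phase coupling scores each spike with its own pool's generalized
phase at the nearest millisecond; the spike-phase index is the modulus of
the mean resultant vector, and the phase histogram uses 10 equal bins over
(-pi, pi]. The wave-peak modulation statistic converts the histogram to a
per-millisecond spiking probability per phase bin (occupancy-corrected)
and reports the percent increase of the maximal bin over the
occupancy-weighted phase average — 0% for phase-uniform spiking,
(nbins-1) x 100% in the degenerate single-bin limit, and depth x
sinc(1/nbins) x 100% for sinusoidal rate modulation.

## Experiments

Conductance scans rebuild nothing but the weights: the wiring is built
once per scan, each (Ge, Gi) cell runs an independent kicked simulation
whose seed derives from the master seed and the cell coordinates
(execution order cannot change results), and cells are classified by the
A-I criteria with optional wave statistics. Cells that cannot
self-sustain die after the kick, which is precisely the sought
classification. Size series repeat scans across sheet sizes at fixed
neuron density with the out-degree following the footprint rule.

The phase-aligned stimulation experiment replays a spontaneous run
deterministically and snapshots the full dynamical state (including the
in-flight event buffer) whenever the generalized phase of the central pool
enters the target phase bin — the bin of maximal ("depolarized") or
minimal ("hyperpolarized") spontaneous spiking probability. From each
snapshot, a 10 ms Poisson barrage (20 Hz x 100 synapses per neuron) is
applied to every neuron in the central 0.2 x 0.2 mm^2 region and the
branch is integrated over the response window (default 0-30 ms). The gain
of a trial is the region's summed spike count divided by the matching
count of the undisturbed run, which shares its history bit-for-bit to the
onset. The stimulus weight defaults to the network's Ge; a charge-matched
weaker weight (scaling inversely with tau_e) is exposed for probing the
perturbative regime, since with 10 ms kinetics the full-weight barrage
drives essentially every target neuron once regardless of network state.

## Scaled study conditions

The reference ("sparse-wave") configuration is a 6 mm sheet at 28,125
neurons/mm^2 (>1M neurons, K = 3000, sigma = 400 um, vc = 0.2 m/s, outer
1 mm discarded), far beyond desk memory. The package's tests and the
acceptance script therefore run a scaled model: a 1 mm sheet (28,125
neurons) with every length scaled with it — sigma = L/10 = 100 um, K = 212
by the footprint rule — and slightly stronger inhibition (Ge, Gi) =
(1, 14) nS, which at this size yields ~5-10 sp/s at CV ~1.1-1.2. Scaling
sigma is essential: a 400 um kernel on a 1 mm torus reaches the whole
sheet, the LFP becomes globally synchronous and there is no spatial
structure left to detect. The uniform random control keeps the
whole-sheet footprint (K = 750). Under these conditions the topographic
delayed network shows significant wave structure at ~7-10% of points
against ~1% for the random network, spike-phase coupling ~4x the random
network's, and the z-scored LFP tracks the pooled E/I balance at r < -0.7.

Two caveats are measured and documented rather than hidden. At this scale
the delay across one kernel SD (0.5 ms) is small against the synaptic
times, so the detected structure drifts slowly rather than propagating at
the conduction velocity; the conduction-delay spectral line is instead
isolated in the random-with-delay control, where delays span the full
sheet. And the phase-aligned gain contrast — more added spikes when input
arrives in the depolarized state — is present in the absolute evoked
response but does not separate reliably in the gain ratio at n = 40
trials, because the depolarized baseline (the denominator) is itself
elevated and the deep-conductance state of the 10 ms kinetics flattens the
shunting contrast between states.

## What the synthetic fixtures do and do not show

Planar-wave movies with known wavelength, frequency, direction and noise
provide exact ground truth for the phase-gradient pipeline; recovery is
within a few percent at SNR 3 using the robust aggregates (per-pixel
temporal vector-averaging of the gradient; total phase advance for the
frequency). Cosine-modulated inhomogeneous Poisson trains provide the
closed-form spike-phase index depth/2. These fixtures validate the
estimators, not the biology: they contain no conductance dynamics, no
refractoriness and no spatial correlation structure beyond the planted
wave, so passing them shows the analysis stack measures what it claims to
measure, on fields far cleaner than either the simulation or cortex.

## Known limitations

- The biophysical constants are literature-range assumptions; the
  tau_e = tau_i = 10 ms choice is load-bearing for desk-scale
  self-sustained activity (see above).
- The random 1 mm control's spike-phase index varies strongly across
  seeds (0.03-0.14): a seed-dependent global population oscillation and
  the self-coupling of each pool's spikes to the pool's own synaptic
  input (relatively larger at K = 750 than at the full-scale K = 3000)
  both inflate it, so the topographic/random index contrast is a
  qualitative ordering at this scale, not a stable ratio.
- The "dense" preset is an untuned placeholder for a strongly coupled
  contrast network; its published counterpart's parameters are not
  available and no quantitative claims are attached to it.
- Wavelength/speed statistics at the 1 mm scale describe slowly drifting
  topographic structure; quantitative wavelength or speed distributions
  should be compared with recordings only at full scale.
- The event ring buffer holds max-delay x N x 2 float32 accumulators;
  heterogeneous-velocity full-scale networks need several GB.
- No plasticity, no cell-type diversity beyond the E/I split, no
  layered or anisotropic connectivity, and the point-neuron LFP proxy
  carries no volume conduction.
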