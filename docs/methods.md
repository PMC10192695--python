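# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the
numerical decisions a user should know before trusting a number.

## Signals and preprocessing

The unit of analysis is a 10 s, 23-channel window at 256 Hz (2560 samples
per channel, microvolts).  Recordings are split into consecutive
non-overlapping windows; a trailing partial window is dropped.
Preprocessing is a zero-phase 4th-order Butterworth band-pass at
0.5–40 Hz (forward–backward, so the magnitude response is applied twice
and the phase response cancels — instantaneous-phase estimates downstream
depend on this).  The 0.5–40 Hz edges bracket the conventional EEG bands;
the steady-state attenuation of a 60 Hz mains tone is ~1.4% amplitude,
but the 0.5 Hz high-pass edge gives the filter a multi-second impulse
response, so the first/last ~2 s of a filtered window carry boundary
transients.  ICA-based artifact removal, which real scalp studies need,
is exposed only as an identity hook: the synthetic signals carry no
artifacts, and cleaning belongs to acquisition-specific tooling.
Channel counts other than 23 are refused by the network stages unless
explicitly overridden, because the network and oscillator models are
dimensioned at N = 23.

## Hilbert–Huang analysis

EMD sifts each channel into intrinsic mode functions: the mean of the
cubic-spline envelopes through local maxima and minima is subtracted until
the component satisfies both the Cauchy SD criterion
Σ(h_prev − h)²/Σh_prev² < 0.2 and IMF admissibility (extrema and
zero-crossing counts differ by at most one).  Ten sifts are normally
enough; a component that meets the SD criterion while still inadmissible
earns extra sifts up to a hard cap of 50 (admissibility is what licenses
the Hilbert transform, so it is not traded away for speed).  Envelope
splines mirror two extrema past each boundary, which suppresses end
swings.  Decomposition stops at 10 IMFs or a residual with fewer than two
maxima or minima.  Sifting is pure subtraction, so IMFs + residual
reconstruct the input to round-off (~1e-15 relative; tested at 1e-9).

Each IMF's analytic signal comes from the FFT-based Hilbert transform;
instantaneous frequency is the central difference of the unwrapped phase.
Samples whose envelope is below 1e-8 of the maximum get masked (NaN)
instantaneous frequency — the phase derivative there is division noise.
The Hilbert spectrum accumulates |a(t)|² into a 100 time-bin × 80
frequency-bin grid over 0–40 Hz; samples outside the range (or masked)
are discarded and excluded from the conservation total, so grid total =
marginal total = in-range Σ|a|² exactly (rearrangement identities, tested
exactly).  Band fractions assign bins to δ/θ/α/β by bin-center membership;
the gaps between bands mean fractions sum to slightly below 1.

## Symbolic transfer entropy and networks

Ordinal patterns of length m = 3 at lag τ = 1 (6 symbols, stable-sort
tie-break: equal values keep index order, so constant windows map to the
ascending pattern).  STE(J→I) is the plug-in histogram estimate with
single-symbol histories (k = l = 1), in bits, floored at zero.  When the
driver's symbol adds nothing beyond the target's own past — in particular
when J *is* I — every log ratio is exactly 1 and the estimate is exactly
zero (integer count arithmetic, no cancellation error).

The plug-in estimator is biased upward at finite n: at n = 2558 symbols
with 6 states, independent channels show ~0.02 bits on average (max ~0.03
across seeds).  This bias floor is precisely what motivates the 0.02-bit
edge threshold: edges at that level are at the edge of estimability, and
the regime contrast lives in how many pairs rise *above* it.  No
surrogate-based significance correction is applied — the fixed threshold
mirrors the intended network construction, and the independent-channel
floor is documented by test.  At n = 100,000 the floor drops below 0.01
bits.  Direction recovery on unidirectionally coupled AR(1) pairs
(x→y, c = 0.8, n = 10,000) succeeds in ≥95% of seeds.

Networks keep all 23 channel nodes and the directed edges with STE ≥
threshold (0.02 default; 0.08 gives display-sparse graphs).  Metrics are
computed on the symmetrized graph (undirected weight = max of the two
directed weights — the max preserves any detected link):

- mean shortest path: average over reachable unordered pairs, binary hops
  or 1/weight distances; the unreachable fraction is reported, not folded
  into the mean;
- clustering coefficient: mean local fraction of closed triplets, degree-
  <2 nodes contributing 0;
- global efficiency: mean of 1/d over ordered pairs, unreachable pairs
  contributing 0;
- synchronizability: λ₂/λ_max of the combinatorial Laplacian of the
  binarized graph; disconnected graphs return 0 with a flag.

All four are verified against brute-force oracles (Floyd–Warshall, triple
enumeration, dense eigensolver) on every connected graph with ≤6 nodes
(up to isomorphism — the metrics are isomorphism-invariant) and on random
graphs with ≤8 nodes.

## Kuramoto dynamics

dθᵢ/dt = ωᵢ + (K/N) Σⱼ G_ij sin(θⱼ−θᵢ), N = 23, K = 3.5, ωᵢ = i/(N−1)
(the deterministic even grid over [0,1]; a seeded uniform draw is
available), θᵢ(0) seeded uniform on [0, 2π).  Fixed-step RK4 at dt = 0.01
(convergence order ≥3.5 verified; dt = 0.02 is used for long batch runs),
horizon T up to 1000, trajectory saved every 10 steps.  The coupling
matrix is used directed, as given.  Synchronization is quantified by the
mean-field order parameter r(t); time-to-sync is the first time r ≥ 0.9
that is sustained (never dropping below 0.85) to the end of the horizon.

**Coupling scale.**  Raw STE edge weights are 0.02–0.1 bits; with
K = 3.5/N they put every network two orders of magnitude below the
synchronization transition, where time-to-sync is infinite for all
networks and the comparison degenerates.  The pipeline therefore rescales
all coupling matrices by one *common* factor, chosen so the batch-mean
network's total edge weight becomes 300 — at that budget the mean-field
effective coupling of an average network is roughly twice the critical
value K_c = 2/(πg(0)) for [0,1]-spread frequencies, i.e. comfortably
inside the synchronizing regime while preserving the relative coupling
strengths of the two regimes.  An alternative mode forces every network
to the identical budget; that erases the regime difference in coupling
strength and probes topology alone, and in our batches the topology-only
contrast is within noise — the seizure networks' faster synchronization
is carried by their stronger overall coupling, not by their wiring
pattern.

## Synthetic data

Each channel is a sum of per-band amplitude-modulated sinusoids (carrier
drawn inside the band, AM depth 0.3 at 0.2–0.5 Hz, power weights =
`band_weights`) plus pink noise (power ∝ 1/f) at `noise_sd` = 0.5 relative
amplitude (~20% of channel power — scalp EEG has substantial broadband
content, and quasi-deterministic narrowband-only channels would make
ordinal symbols degenerate).  Directed influence adds a 4-sample-lagged,
scaled copy of each driver's intrinsic signal into its receivers — the
simplest mechanism a transfer-entropy estimator provably detects.  The
ground-truth topology is a two-block design: dense unit coupling inside a
six-channel "focus" block plus a weak one-way ring (weight 0.3) over all
channels, scaled by the regime's `coupling_strength`.

Default regimes:

| parameter | interictal | ictal |
|---|---|---|
| band weights (δ,θ,α,β) | 0.70, 0.15, 0.10, 0.05 | 0.15, 0.20, 0.25, 0.40 |
| amplitude scale | 1.0 | 2.0 |
| coupling strength | 0.3 | 0.9 |
| noise sd | 0.5 | 0.5 |

These encode the two contrasts the pipeline is designed to detect:
between-seizure energy concentrated in δ, seizure energy shifted upward
with larger amplitude; and stronger directed coupling during seizures,
concentrated in the focus block.  Per-segment seeds derive from the master
seed via `SeedSequence([master, class, index])`, so datasets are exactly
reconstructable.

**What the generator does not emulate:** spike-wave morphology, artifacts
(blinks, EMG, electrode pops), volume conduction, non-stationarity within
a window, or any claim about the true connectivity of real recordings —
the focus block is a validation construct.  Passing direction checks
therefore show that the *pipeline* recovers contrasts that are present by
construction; they are not evidence about real seizure physiology.

**A consequence worth knowing:** because seizure segments couple more
strongly, their thresholded networks are *denser*, and on near-random
23-node graphs at these densities binary path length, clustering and
efficiency are density-driven — the denser ictal networks necessarily
have shorter paths, higher clustering and higher efficiency here.
Observations on real data of the opposite pattern (longer ictal paths,
lower clustering/efficiency) involve topology changes this generator does
not produce; only the synchronizability and edge-count contrasts are
meaningful validation targets under this design.

## Classifier

Stacks of 23 Hilbert-spectrum images (frequency × time, global per-segment
min–max normalization; an all-constant stack maps to zeros) feed a small
convolutional network: conv 32·3×3 → ReLU → maxpool 2×2 → conv 64·3×3 →
ReLU → maxpool 2×2 → dropout 0.5 → dense 64 → ReLU → softmax(2), trained
with Adam (lr 1e-3) and softmax cross-entropy on a seeded stratified 80/20
split.  The network is implemented directly on numpy arrays (im2col
convolutions with hand-written backward passes and Adam updates); given a
fixed seed, initialization, shuffling and dropout masks are reproducible,
so training is deterministic.  Inputs are average-pooled 2× (to 23×40×50)
before training: at the synthetic regimes' separation the full 80×100
grid adds cost but no accuracy, and the pooled size keeps single-CPU
training in seconds.  Metrics (sensitivity, specificity, accuracy, F1)
follow the confusion-matrix identities exactly; AUC is the rank statistic
(ties count ½), verified against brute-force pair counting.

## Problem sizes

The direction checks run at 50 segments per regime (the classifier trains
on those same 100 stacks; its chance-level control averages 3 shuffled-
label trainings); the time-to-sync comparison uses 20 networks per regime
at T = 200, dt = 0.02; estimator validation uses 50 coupled-AR seeds at
n = 10,000 and 10 independent-symbol runs at n = 100,000.  These sizes
give stable means/medians for the contrasts involved while keeping a full
validation run in minutes on one CPU.

## Known limitations

- EMD has no uniqueness guarantee; mode mixing can occur for signals with
  intermittent components (no ensemble EMD here).
- The STE estimator is the uncorrected plug-in; absolute STE values carry
  the finite-sample bias discussed above and should be compared, not
  interpreted, at n = 2560.
- The Kuramoto coupling-scale choice is a modeling decision; reported
  times-to-sync are meaningful relative to each other, not in physical
  seconds.
- EDF export writes 16-bit samples scaled to the recording's absolute
  maximum; round-trips are exact only to quantization (~2·max/65535).
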