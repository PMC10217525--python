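# Methods

## Model

The MscS mechanosensitive channel is treated as a two-state system: closed
(σ = 0) and open (σ = 1). With the closed-state energy as reference, the
energy of a channel in a membrane under lateral tension γ is

    H(σ, γ) = σ (Δε − γ ΔA)        [kBT]

where Δε is the conformational energy gap (open − closed) and ΔA the
in-plane area expansion upon opening. Tension lowers the energy of the
larger-area open state, so the equilibrium open probability is the logistic

    P_open(γ) = 1 / (1 + exp(Δε − γ ΔA)),

with midpoint γ½ = Δε/ΔA, the tension of maximal uncertainty (one-bit
condition). Gating kinetics follow an Arrhenius law in tension,

    k_open(γ)  = k_open⁰  exp(γ ΔA_cB),     ΔA_cB > 0
    k_close(γ) = k_close⁰ exp(γ ΔA_oB),     ΔA_oB < 0

with ΔA_cB − ΔA_oB = ΔA so that detailed balance,
k_open/k_close = exp(−Δε + γΔA), holds at every tension. Channels are
independent; inactivation (a third, tension-insensitive state that real MscS
enters under sustained stimulation) is outside the model's scope, which is
why erasure ramps beyond ~10 s are experimentally inaccessible while the
simulation can be driven arbitrarily slowly.

### Parameters (packaged defaults)

| parameter | value | units | role |
|---|---|---|---|
| Δε | 22 | kBT | conformational energy gap |
| ΔA | 12 | nm² | open–closed area difference |
| k_open⁰ | 4·10⁻⁶ | s⁻¹ | intrinsic opening rate at γ = 0 |
| k_close⁰ | 9897 | s⁻¹ | intrinsic closing rate at γ = 0 |
| ΔA_cB | +7 | nm² | closed → barrier expansion |
| ΔA_oB | −5 | nm² | open → barrier expansion |

The sign of ΔA_oB is a convention choice: the magnitudes are 7 and 5, and
taking ΔA_oB negative makes closing slow down with tension and the two
barrier areas sum to ΔA = 12 nm².

**Energy-mode choice.** The intrinsic rates imply an energy gap
ln(k_close⁰/k_open⁰) ≈ 21.63 kBT, slightly below the nominal Δε = 22 kBT —
the two were measured by different experiments and are not exactly
consistent. The package exposes both bookkeepings. The default,
`kinetic_consistent`, uses 21.63 kBT in the equilibrium and heat formulas so
that the kinetic and Boltzmann midpoints coincide exactly
(γ½ ≈ 1.8024 kBT/nm²); without this, the simulated quasi-static mean heat
converges to a value displaced from ln2 by the residual entropy mismatch at
the ramp start, and the Landauer comparison is confounded by a bookkeeping
artifact rather than physics. `as_printed` (Δε = 22, γ½ = 1.8333) is kept
for literal parameter reproduction and ships as
`data/literal_reproduction.yaml`.

## Protocol

The restore-to-open stimulus is piecewise linear in tension: a 0.25 s
loading ramp 0 → γ½ (a 0.5 s variant is a config option; neither is
privileged), a 3 s hold at γ½ that thermalises the channel into the 50/50
maximal-entropy mixture (the relaxation time at the midpoint is
1/(k_open+k_close) ≈ 0.41 s, so 3 s suffices), and an erasure ramp
γ½ → 3 kBT/nm² of duration τ ∈ {0.25, 1, 5, 10, …} s. Heat and work are
scored over the erasure ramp only; the load and hold set the initial
condition. A fast path skips the load/hold and initializes the state as
Bernoulli(P_open(γ½)) = Bernoulli(½) at the ramp start — the two routes
agree statistically (tested), and the fast path is the default for
ensembles. Pressure-controlled recordings convert to tension by
proportional calibration γ = (p/p½)·γ½ with γ½ = 7.85 mN/m and
1 kBT/nm² = 4.114 mN/m; Laplace-law calibration (γ = pr/2) is documented
but not implemented because the patch radius is not measured.

## Exact simulation

On a linear segment the active rate is exponential in time,
k(t) = A e^{Bt}, so the integrated hazard is Λ(t) = A(e^{Bt}−1)/B (A·t when
B = 0) and the next transition time is obtained by drawing E ~ Exp(1) and
inverting Λ in closed form. For B < 0 the hazard is bounded by A/|B| and
E ≥ A/|B| means guaranteed survival of the segment. This sampler is exact —
no time-step bias — which matters because the quasi-static Landauer gap
being resolved is O(0.01 kBT). It is validated against a dt = 10⁻⁵ s
Bernoulli-chain discretization (two-sample KS, α = 0.01, 5000 draws per
arm) and against the closed-form first-passage distribution on the fast
ramp. One root seed spawns independent child streams per trajectory
(`numpy` SeedSequence), so ensembles are bit-reproducible.

## Heat and work bookkeeping

Along a trajectory, σ(t) is a step function. Work done on the channel by
the tension source over the scored window is W = −ΔA Σ (γ(t_b) − γ(t_a))
over maximal open intervals [t_a, t_b] (computed exactly from event times);
heat is released in lumps at transitions: an opening at γ_trans releases
γ_trans·ΔA − Δε to the bath, a closing the negative. All reported heats use
the released-to-bath sign (positive = dissipation). The first law
Q_released = W − ΔH holds to < 10⁻⁹ kBT for every simulated trajectory
(tested as an identity). Two consequences worth noting:

* a flicker pair (open at γ₁, close at γ₂) releases ΔA(γ₁−γ₂) regardless of
  Δε — midpoint flickers are nearly athermal;
* averaged over realizations of the erasure, ⟨Q⟩ ≥ kBT·ln2, with equality
  in the quasi-static limit. The package reports the bound both as the
  idealized ln2 and as T(S_i − S_f) from the equilibrium occupancies at the
  window's endpoint tensions (S_f ≈ 10⁻⁵ kB at γ = 3, not exactly zero).

**Averaging conventions.** Summaries report the per-realization mean (one
heat per protocol run — the thermodynamically meaningful average for the
Landauer comparison) and the pooled per-event mean side by side, with both
histograms, because idealized recordings naturally yield events rather than
realizations. At the fastest ramp (τ = 0.25 s) the defaults give a
per-realization mean of ≈2.5 kBT and a pooled per-event mean of ≈4.6 kBT
(openings alone average ≈5.0 kBT): initially-open channels contribute
event-free realizations, and early closings contribute small negative
heats, so the conventions differ materially at fast driving. Experimental
fast-ramp dissipation in this system has been reported above 5 kBT per
event; the packaged kinetic parameters sit a few tenths of a kBT below
that, a model–measurement gap we report rather than tune away.

The finite-time correction is summarized by fitting ⟨Q⟩(τ) = ln2 + C/τ with
the intercept pinned at ln2 (ordinary least squares in 1/τ); C ≈ 0.5 kBT·s
for the defaults.

## Synthetic recordings

The generator renders trajectories into patch-clamp-like traces:
current(t) = baseline + drift·t + i_u · (channels open) + Gaussian noise,
with i_u = 30 pA (1 nS at 30 mV), 10 kHz sampling, and an optional
single-pole low-pass applied to signal plus noise. Defaults for the noise
(3 pA SD, SNR 10) and optional 2 kHz cutoff are benchmarking choices — the
instrument noise of the original recordings is not specified anywhere.
What it does not emulate: 1/f and flicker noise, capacitive transients,
seal-resistance drift, Bessel-filter phase response, and the slow current
sag from adaptation/inactivation. Detection results on synthetic traces
therefore bound performance under idealized, not worst-case, conditions.
Ground-truth events are embedded in the trace file header (JSON comment
lines over a plain two-column CSV), so benchmarks are self-contained.

## Event detection

The idealizer is a difference-of-boxes matched filter: d[i] = mean of the w
samples at/after i minus the mean of the w samples before i. A clean step
of height h gives a triangular response peaking at exactly h at the step
sample, so localization error on noiseless staircases is ≤ 1 sample; at
ramp slope c the tension error is ≤ c/f_s, which at the default settings
keeps per-event heat errors below 0.01 kBT. The noise scale of d is
estimated by MAD (×1.4826); candidates are local maxima of |d| above
`threshold_sigmas` × scale (default 6); non-maximum suppression enforces
`min_separation` (default the kernel span 2w/f_s), keeping the larger |d|
and, on exact ties, the earlier. Levels are quantized by cumulative
polarity from the initial level (nearest integer of the start mean over the
unitary current). In multi-channel patches channel identity is
unobservable; per-event heats need no assignment, and "per-realization"
heat is defined as patch total divided by channel count — a documented
approximation. Benchmarked sensitivity at SNR 10: ≥95% of true events
recovered within 2 ms with ≤5% false positives; settings of the original
third-party detector are unreported, so the benchmark is against synthetic
truth only.

## Problem sizes and numerical choices

Default ensembles are 200 realizations per duration (matching the ~200
events gathered per protocol in the motivating experiments); the
quasi-static check uses τ = 100 s with n = 20,000 (runs in a few seconds —
the exact sampler costs one draw per event), and distributional checks use
5,000 draws per arm. Histogram binning is Freedman–Diaconis unless
overridden. Degenerate inputs are errors, not silent defaults: zero-length
segments, non-monotone erasure ramps, occupancies outside [0,1], negative
tensions. SEM is reported as null for single-realization ensembles.

## Known limitations

* Two-state only: no inactivation, adaptation, or subconductance.
* Tension is noiseless and exactly piecewise linear; real pressure-clamp
  stimuli have finite bandwidth.
* The proportional pressure calibration assumes constant patch curvature.
* The heat bookkeeping charges transitions instantaneously; barrier-crossing
  dynamics within a transition are not resolved.
* Multi-channel per-realization heat divides the patch total evenly across
  channels.
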