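# Methods

## Model and assumptions

The network model is a single-compartment, graded-synapse membrane model
on a fixed wiring diagram.  Every neuron is electrically compact (one
voltage per cell), passive apart from its synaptic interactions, and
identical in its biophysical constants; heterogeneity enters only through
connectivity and the binary excitatory/inhibitory class.  Gap junctions
are ohmic conductances proportional to contact count; chemical synapses
are conductances gated by a presynaptic activation variable that relaxes
toward a sigmoidal function of presynaptic voltage.  There is no spike
generation, no channel noise, and no body or muscle model: the "behavior"
read out here is a neural-state proxy (a planar projection of motorneuron
voltages), not movement.

Units are pF, pS, mV and seconds; with these, conductance/capacitance is
1/s, so voltages in mV integrate consistently and external currents are
carried in model units of pS·mV.  The impulse amplitude of 10 is treated
as a pure number in those units.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `C` | 1 | pF | whole-cell capacitance |
| `Gc` | 10 | pS | leak conductance (leak time constant `C/Gc` = 0.1 s) |
| `Ecell` | −35 | mV | leak reversal |
| `g` | 100 | pS | conductance per synaptic or gap contact |
| `ar`, `ad` | 1, 5 | 1/s | synaptic rise and decay rates |
| `beta` | 0.125 | 1/mV | sigmoid slope |
| `E_exc`, `E_inh` | 0, −45 | mV | synaptic reversal by presynaptic class |
| `vth` | solved | mV | per-neuron threshold (see below) |

`C`, `Gc`, `g`, `ar`, `ad` are the standard constants of this model
family; `Ecell`, `E_exc`, `E_inh` and `beta` follow the established
convention for connectome-scale simulations of this organism and are all
overridable through `ModelParams`.

**Threshold calibration.** `vth` is not free: with the sigmoid pinned at
1/2, the synaptic activations equal `s* = ar/2/(ar/2 + ad)` and the
voltage equations become linear; their solution is taken as the threshold
vector.  This makes `(v*, s*) = (vth, s*)` an exact zero-input fixed
point of the full nonlinear system and centers every neuron's operating
point on the sensitive part of its activation curve.  After ablation the
thresholds are kept (they are a property of the intact network), and the
ablated network's fixed point is re-solved by damped Newton on the
voltage subsystem (tolerance 1e-9 in model units, long-integration
fallback).

## Protocols

**Impulse ensemble.** Each trial draws an i.i.d. Gaussian current vector,
rescales it to Euclidean norm 10, applies it for 10 µs, and records the
free decay back to the fixed point every `Δt = 3e-5 s`.  The recorded
matrix has the fixed point subtracted before decomposition: the constant
background (tens of mV against deviations of ~1e-4 mV) would otherwise
constitute a unit-eigenvalue mode absorbing essentially all energy and
reduce every decomposition to rank one.  Decay duration defaults to
0.5 s, roughly five times the slowest expected timescale.

**Mode decomposition.** Exact DMD with energy-threshold truncation.
"Energy" is, by default, a singular value's share of the singular-value
*sum*; a `sigma2` switch selects the variance convention.  On simulated
decay data the σ convention reproduces the expected mode counts (six for
the reference network family, four for fully random graphs) while σ²
collapses to two, so σ is the default.  Singular values below 1e-12 of
the largest are numerical rank and are dropped before thresholding.
Modes are normalized to unit length with the largest-magnitude entry made
real-positive, so projections are reproducible; the raw scaling is
absorbed into the fitted amplitudes.  Eigenvalues equal to one are
flagged as infinite timescales rather than errors; zero eigenvalues are
excluded from mode projection.

**Driven cycles.** B-class motorneurons receive
`±A sin(ωt − 2πk x)` with `A = 30`, soma position `x ∈ [0, 1]`, ventral
cells positive and dorsal negative (the opposite orientation is a phase
shift of π and is selectable).  The spatial wavenumber `k` is in cycles
per body length, so the drive wavelength is `1/k` body lengths; the
reference is `k = 0.886` (wavelength 1.13).  The temporal frequency is
not dynamically constrained by the model; the default `ω = 25 rad/s`
(period ≈ 0.25 s) sits comfortably above the slowest network timescale
so the cycle settles within a short simulation.  Changing `ω` rescales
the cycle period but not its shape, which the test suite checks.

**Cycle comparison.** Trajectories are projected on the two dominant
singular vectors of the mean-centered reference cycle.  One period is
extracted after discarding the first half of the trace: the period comes
from the dominant peak of the overlap-corrected (unbiased)
autocorrelation of the first coordinate, searched past its first minimum,
then refined to sub-sample accuracy from the spacing of positive-going
mean crossings (the raw autocorrelation peak carries an O(1)-sample bias
whenever the segment holds a non-integer number of periods).  Cycles are
resampled to N = 200 points by periodic cubic splines, oriented
counterclockwise by signed area, and compared by normalized Procrustes
distance — the residual after optimal translation, rotation (reflections
allowed by default, restrictable to proper rotations) and positive
scaling, normalized by the centered sum of squares so values are
scale-free and lie in [0, 1].  Phase alignment minimizes over all N
cyclic shifts.  Unnormalized residuals are recoverable from the
standardized form; the normalized score is what is reported because it is
comparable across drive amplitudes.

**Null models.** Two families: (a) exact degree-sequence-preserving
rewiring of both multigraphs by repeated double-edge swaps on the contact
lists (10 attempted swaps per contact by default; swaps creating
self-loops are rejected), synapse and gap networks randomized
independently; (b) fully random multigraphs conserving only the total
contact counts, synaptic contacts uniform over ordered off-diagonal
pairs and gap contacts over unordered pairs.  Excitatory fraction for
random graphs defaults to the standard network's observed fraction, or
0.8 when none is loaded.  Ensembles are compared per timescale-ranked
mode and statistic by two-sample Kolmogorov-Smirnov tests, reporting
per-family maximum p-values; no multiple-testing correction is applied.

## Synthetic data

The surrogate connectome generator emulates the *statistical* structure
the pipeline consumes — contact totals, E/I mix, uniform soma positions,
alternately dorsal/ventral B-class motorneurons ordered along the body,
and a miniature named motor circuit — but none of the real network's
degree heterogeneity, spatial wiring economy, left/right symmetry or
circuit motifs.  Tests passing on surrogates therefore validate the
machinery (integration, decomposition, statistics, shape comparison),
not claims about the biological network; quantitative statements tied to
the real wiring (specific timescale values, which mode aligns with which
reference direction, wavelength selectivity of the driven response)
require the real tables, which are deliberately not bundled.

The decay-trace generator builds voltages exactly as a sum of decaying
orthonormal modes with known timescales and amplitudes, making it an
end-to-end oracle: the decomposition must return the generating
quantities to near round-off on noiseless input.  Each fixture kind
draws from its own seeded generator stream, so outputs are reproducible
and mutually independent at equal seeds.

## Numerical choices

- Forward Euler with `h = 1e-6 s` for production runs; `h = 1e-5 s` in
  tests after the step-halving property (error ratio ≈ 2 on a linear
  two-neuron fixture) validates first-order convergence.  The recording
  interval must be an integer multiple of `h`.
- Synaptic activations are clipped to [0, 1] each step; voltages beyond
  1e4 mV in magnitude abort with the blow-up time.
- Fixed points: damped Newton with backtracking line search on the
  voltage subsystem after substituting the synaptic equilibrium; analytic
  Jacobian; tolerance 1e-9 on the full vector field.
- Gap tables with directional duplicates are merged by taking the larger
  count per unordered pair (with a warning when directions disagree),
  keeping counts integer; same-direction duplicate rows are summed.
- Trials whose retained mode count deviates from the ensemble's majority
  are excluded from per-rank statistics and counted, since rank
  correspondence across trials is by timescale order.
- Box summaries use quartiles with whiskers at the most extreme
  observations within 1.5 IQR (an exact-extremes option exists); the
  spread statistic is `(Upper − Lower)/(2·Median)`.

## Known limitations

- A least-squares propagator estimated from noisy snapshots has
  eigenvalues biased toward faster decay; the error grows roughly
  quadratically with the noise level (~0.5% timescale error at 0.1%
  relative noise, tens of percent at 1%).  Debiased or forward-backward
  variants are out of scope, so the decomposition should be applied to
  clean simulation output, as it is here.
- The energy threshold makes the retained mode count a step function of
  the spectrum: modes whose energy share hovers near the cut (for random
  graphs, a weakly voltage-expressed synaptic-relaxation cluster near
  `1/(a_r/2 + a_d)`) can enter or leave the retained set from trial to
  trial.  Mode counts at a fixed threshold are therefore statistics of an
  ensemble, not invariants of a single trial.
- Period extraction assumes a dominant fundamental in the first plane
  coordinate; strongly multi-periodic or chaotic responses raise a
  no-cycle error rather than returning a misleading shape.
- The proprioceptive drive uses soma positions as the spatial coordinate,
  a simplification of stretch reception along posterior axons, and the
  model contains no mechanical feedback loop: the drive is open-loop.
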