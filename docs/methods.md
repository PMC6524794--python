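# Methods

## Kernel

The state of every isochromat is advanced per time step by (1) an exact
rotation about the rotating-frame effective field — transverse components
`gamma*B1` at the instantaneous RF phase, longitudinal component the local
off-resonance `gamma*(G.r) + dB0 + chemical shift` — and (2) exponential
relaxation (`E2` on the transverse, `E1` recovery on the longitudinal
component).  This splitting is exact for free precession (the z-rotation
commutes with relaxation) and first-order accurate in `dt` during RF; at the
1 us base raster the splitting error against a 100x-subdivided reference is
at the 1e-5 level for RF episodes with relaxation and at machine precision
otherwise, which the test suite asserts.  Axis conventions: B1 at phase 0
lies along +x, a positive flip rotates +z toward +y, and positive
off-resonance precesses clockwise (`exp(-2 pi i f t)`), which makes the
readout signal the standard `sum pd * exp(-2 pi i k.r)`.

ADC samples, software crushers (instant nulling of all transverse
magnetization) and single-point recorders (per-spin transverse snapshot)
apply at the *start instant* of their step; sampling is instantaneous, not
integrated over the dwell.  Receiver phase follows the transmitter phase in
phase-alternated sequences and is demodulated from the recorded samples.

The compiled (numba) loop caches per-spin rotation/relaxation coefficients
in two slots keyed on the step's `(dt, gx, gy, gz, |B1|, phase)`; RF raster
bins and the alternating sample/idle pattern of a readout then reuse the
cached trigonometry.  Isochromats are processed in chunks whose signals are
summed; results are independent of the chunk size to ~1e-12 (floating-point
reassociation only).  A pure-numpy implementation of the same update rules
(`step_free`, `step_rf`, `step_bm`) is the independent reference the kernel
is tested against.

### Two-pool magnetization transfer

The Bloch-McConnell option adds a semisolid pool per isochromat: pool-size
ratio `F` (0 disables), free-to-semisolid exchange rate `k` (reverse rate
`k/F`, balanced at equilibrium), semisolid `T1s`, and RF saturation at rate
`W = pi (gamma B1)^2 g(0)` where `g` is the absorption lineshape of the
semisolid `T2s` (super-Lorentzian by default, evaluated at a 1 kHz cutoff as
is standard on resonance; Lorentzian available).  The free pool's transverse
components evolve as in the single-pool model (the semisolid pool has no
observable transverse magnetization at microsecond `T2s`); both longitudinal
components are advanced with the exact 2x2 matrix exponential of
exchange + relaxation + saturation.  `F = 0` reduces bitwise to the
single-pool trajectory.  The agar parameter defaults
(`F = 0.0068/0.0136/0.0272`, `k = 20/40/60 1/s`, `T1s = 1 s`,
`T2s = 12 us` for 2/4/8%) are literature-informed configuration inputs; only
the with-MT < without-MT ordering of apparent T1 is treated as a result.

## Sequence builders

**Discretization** renders a sequence onto the uniform base raster
(integer-nanosecond arithmetic; any object boundary off the raster by more
than 1 ns is an error, not a silent rounding).  **Compression** (the fast
algorithm) merges maximal runs with constant gradients, zero B1 and no
flags into single long steps; total duration is conserved exactly and ADC
samples agree with the uncompressed timeline to ~1e-9 (asserted).  Steps
under nonzero B1 are never merged.

**GRE**: per repetition, a 3-lobe sinc (time-bandwidth 4, no apodization by
default) under the slice-select gradient, then one interval carrying the
readout prephaser, phase-encode and slice rephaser simultaneously, then the
centered readout, then a software crusher at the TR end.  The minimum-TE
rule is `TE = RF/2 + prephaser + readout/2` with the prephaser interval
sized by the larger of the readout-prephase and maximum phase-encode areas
at the gradient limit (the slice rephaser shares the interval with an
idealized amplitude — gradients are steep steps throughout).  Phase-encode
ordering is linear; even matrices use the FFT-standard `-N/2 .. N/2-1`
indices, odd matrices are symmetric.  RF pulses are calibrated so the
discrete on-resonance flip equals the nominal angle exactly.

**MOLLI `a(bp)c`**: adiabatic inversions before image 1 and image a+1 (after
b pause beats), one single-shot balanced-SSFP readout per simulated
heartbeat.  Each TR is fully balanced on all three axes, RF/receiver phase
alternates 0/pi, a linear flip-angle ramp of 10 pulses (`(j+0.5)/10` of the
nominal flip) precedes the phase-encode train, and `TE = TR/2`.  Effective
inversion times run from the inversion-pulse center to the k-space-center
echo and are recorded per image.  The inversion times are study conditions
of this package: `TI1 = 100 ms`, `TI2 = 180 ms` (consistent with the
103-183 ms range of the scanner-matched variant it emulates).  A software
crusher after the inversion pulse plays the role of the post-IR spoiler.
With recorders enabled, a single-point recorder sits at the k-center echo of
every image (8 for the 5(3p)3 scheme).

**Adiabatic pulses** are frequency-swept full passages returned as complex
samples (sweep folded into the phase).  Hyperbolic secant
(`mu = 6`, `beta*tau_edge = 5`, peak B1 35 uT over 4.74 ms) and tan/tanh
(`zeta = 10`, `tan(kappa) = 10`, 8 kHz sweep, peak B1 26 uT over 2.56 ms)
defaults were chosen to maximize inversion efficiency: > 0.95 over at least
+-500 Hz off-resonance at infinite relaxation times, verified by Bloch
tests.  A physical limitation matters for short T2: during the passage the
effective field sweeps through the transverse plane, so transverse
relaxation bounds the efficiency at roughly `exp(-c*T_pulse/T2)`; for the
4.74 ms pulse at `T2 = 19 ms` no parametrization we measured exceeds ~0.956.
The apparent MOLLI T1 of very-short-T2 samples therefore sits a few percent
below values generated with an idealized (instantaneous) inversion; see
"Known limitations".

## Phantoms and geometry

Isochromat grids are cell-centered; "diameter" means the support of nonzero
proton density.  Generators: solid cylinder, hollow cylinder (inner radius
`outer/2 - wall`), and a deterministic brain-like slice of seven nested
elliptical shells with one discrete tissue per position and typical 1.5 T
relaxation values — a structural stand-in for a labeled digital head
phantom, not a reproduction of any acquired dataset.  The linear B0 map runs
`-span..+span` across the support along the chosen axis, zero at the center.
Motion is rigid and sinusoidal (zero-mean displacement `D sin(2 pi f t)` or
in-plane rotation `theta_max sin(2 pi f t)` about a center, the conventional
reading of "distance/angle with a frequency"); positions are recomputed
from the initial grid at every time step, and properties travel with the
isochromat (no inflow/outflow).  Coil sensitivities follow the Biot-Savart
law on 360-segment polygonal loops with the reciprocity convention
`B1- = (Bx - i By)/2`; the default array is 8 loops of 60 mm radius evenly
spaced on a ring with normals aimed at the target.

## Quantitative analysis

The MOLLI fit is the standard 3-parameter magnitude model
`S(TI) = A - B exp(-TI/T1*)` with exhaustive polarity restoration (every
count of sign-flipped earliest-TI samples is tried; lowest residual wins,
ties broken toward fewer flips) and Look-Locker correction
`T1 = T1* (B/A - 1)`.  The separable structure is exploited: `(A, B)` solve
in closed form for each candidate `T1*`, which is located on a 60-point log
grid over 0.02-8 s and polished by bounded scalar minimization (tolerance
1e-12); exact-model recovery to 1e-6 is asserted.  Fits with non-positive
`A` or `B` are flagged non-converged and excluded from ROI statistics.

Annular six-segment ROIs: equal 60-degree sectors, segment 1 centered on +y
(the phase-encode axis) and numbering clockwise, so segments 1 and 4 lie on
the B0-gradient axis; each ROI is the central patch of its sector (central
50% radially and angularly — the emulated study does not quantify its ROI
sizes).  Dictionary matching reduces each complex entry to a signed real
evolution (phase-referenced to its most-recovered point), applies the same
polarity restoration to the measured magnitude vector, and selects the
entry maximizing the normalized absolute inner product (scale-invariant L2);
zero-energy vectors are returned as NaN, never silently assigned.
Slice-profile spins (21 positions across the slice direction at full scale)
are summed per (T1, T2) entry, which is what makes 138,621 spins collapse
to 6,601 entries.

## Desk-scale study conditions

The emulated experiments ran at scanner resolution on GPU farms; this
package reproduces them on one CPU at reduced scale.  The recipe defaults
are the package's study conditions:

| experiment | matrix (FE x PE) | FOV (mm) | spacing | isochromats |
|---|---|---|---|---|
| two-cylinder MOLLI | 96 x 72 | 360 x 270 | 1.75 mm | ~5,100 |
| agar MT | 96 x 72 | 360 x 270 | 1.75 mm | ~2,600 |
| hollow cylinder / B0 | 64 x 48 | 180 x 135 | 0.7 mm | ~4,900 |
| bottle (scanner-matched) | 64 x 48 | 240 x 180 | 1.25 mm | ~3,200 |

All phantoms are 2 mm tall single-layer slabs at the isocenter.  The
phase-encode train length is bounded by `TI1` (the k-space-center echo must
precede the first effective inversion time), which is why 72 lines is the
ceiling at `TI1 = 100 ms` and TR 2.06 ms.  Noise: the two-cylinder
experiment states SD 20 on each quadrature channel at its full scale; the
recipes rescale it as `sd * (sum pd / sum pd_ref) * sqrt(n_ref / n_samples)`
(reference density 1 isochromat/mm^3, reference matrix 165 x 123) so the
image-domain SNR is preserved.  The MT, B0 and bottle experiments state no
noise condition and run noiseless.  The bottle's diameter is not printed;
80 mm (a 500 ml bottle cross-section) is the package's choice.

What the synthetic conditions do not emulate: partial-Fourier/GRAPPA
sampling, slice-profile effects in the imaging recipes (phantom spins sit at
the slice center; the dictionary mode does simulate the profile), scanner
B1/B0 calibration error, and physiological heart-rate variability (beats are
exactly periodic).  Passing tests therefore establish the correctness of the
simulation chain under these idealized conditions, not agreement with any
particular scanner.

## Known limitations

* Short-T2 inversion efficiency: with the physical 4.74 ms sech passage the
  apparent MOLLI T1 of the T2 = 19 ms phantom is ~955 ms, about 5% below the
  ~1003 ms an idealized instantaneous inversion yields; the corresponding
  published value evidently assumes near-ideal inversion.  All longer-T2
  results agree within ~1%.
* The operator splitting is first-order during RF with relaxation (see
  Kernel); sub-microsecond rasters reduce the error linearly.
* Timeline compression merges only zero-B1 runs; a long constant-RF interval
  is stepped at the base raster.
* The pulseq subset covers rectangular gradients, sampled RF, ADC and the
  crusher/recorder extensions; shaped/ramped gradients and compressed shapes
  are rejected with explicit errors.  Nominal flip-angle metadata and block
  grouping are not preserved across a round trip (the discretized timeline
  is).
* Reconstruction is plain centered FFT + RSS; no parallel imaging or
  partial-Fourier handling.
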