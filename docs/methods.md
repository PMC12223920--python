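# Methods

## The two-spin simulator

The C1/C2 pair of an anhydroglucose unit is treated as an isolated,
weakly coupled spin-½ pair. States live in the 16-dimensional Cartesian
product-operator space {E/2, Ix, …, 2IzSz}; because each basis operator
factors into single-spin labels (e, x, y, z) ⊗ (e, x, y, z), the state is a
4×4 real coefficient array on which every operation acts orthogonally:

* **Pulses** rotate the target spin's (x, y, z) coefficients right-handedly
  about the in-plane axis (cos φ, sin φ, 0); a 90° phase-x pulse takes
  Iz → −Iy. Selective pulses carry two imperfection scalars: *attenuation*
  (fraction of the nominal flip delivered to the target) and *leakage*
  (fraction delivered to the other spin). The ~50% amplitude loss and the
  off-resonance artifact excitation of the 1-ms, 10%-truncated Gaussian
  pulse are thus collapsed to two numbers; sensible values for both can be
  read off `shaped_pulse_profile`, a piecewise-constant-rotation Bloch
  integration of the actual envelope (2000 steps; on-resonance flip
  calibrated to 1e-3).
* **Free evolution** under 2πJ·IzSz rotates the in-phase/antiphase
  2-planes (Ix ↔ 2IySz, …) by πJt; offsets are z-rotations; multiple-
  quantum and longitudinal terms are J-invariant. T₂′ losses multiply
  every coefficient by exp(−t/T₂′) once per transverse label.
* The **z-filter** is a projector onto Iz and Sz. The 2-ms ¹H CW
  irradiation is described only as destroying transverse ¹³C coherence, so
  the conservative default also discards 2IzSz; `keep_zz=True` retains it.
* **CP** is reduced to the boundary condition Ix + Sx with configurable
  per-spin amplitudes — CP dynamics are sample physics that cancel from
  the ratio being measured.

Phase cycle: flip-down x,x,x,x,x̄,x̄,x̄,x̄ against receiver ȳ,ȳ,ȳ,ȳ,y,y,y,y.
Signals are s = ⟨Ix⟩ + i⟨Iy⟩ (likewise S) and the cycled result is the
mean of s·exp(−iφ_rec). Any component created before the flip-down and not
re-excited by it is constant over the steps while the receiver alternates,
so it cancels exactly — the artifact signals that *are* re-excited by the
selective pulses survive, which is precisely why the control experiment
(perfect echo without its central π/2) and the 1:1 subtraction exist.

The DQ-filtered variant follows the standard refocused-INADEQUATE
selection: the excitation block (flip-down, first echo π, first sandwich
π/2) is stepped through 0°, 90°, 180°, 270° twice, the reconversion π/2
stays on x, and the receiver follows at −2φ (plus a constant 270° so the
transferred signal lands on the same detector phase as the perfect echo's).
Under ideal lossless conditions transfer occurs in exactly 4 of 8 steps and
the cycled per-scan C2 amplitude is half the perfect echo's sin²(2πJτ) —
the quantitative version of the argument for preferring the perfect echo
in a 1D experiment that starts with magnetization on C1 only.

Defaults: J = 46 Hz (typical one-bond glucose C1–C2 coupling; the coupling
is not known precisely for these materials and is a free parameter) and
τ = 4 ms, the echo delay used experimentally. Every composite sequence is
cross-checked in the test suite against an independent dense 4×4
density-matrix propagator (matrix exponentials of the same Hamiltonians)
to 1e-10 on all 16 coefficients.

## Relaxation and the swelling argument

Saturation-recovery curves are fitted to A·(1 − exp(−(t/T)^β)) by bounded
least squares (lmfit). Initialization: A from the last point, T from the
delay where the curve first reaches 1−1/e of its plateau, β = 0.95.
Bounds: T ∈ [10⁻³, 10⁴] s, β ∈ (0.2, 1]. β starts slightly inside the
interior because the bounded-parameter transform has zero gradient exactly
at a bound and the fit would stall there; with β free and the data truly
monoexponential the fit still converges to β = 1 and the monoexponential T.
Fits are invariant under amplitude rescaling; fitted T and β carry
one-standard-deviation uncertainties from the estimated covariance.

The core–shell model describes a spherical particle of radius R with a
radical-wetted shell of thickness d: shell volume fraction
f = 1 − ((R−d)/R)³, shell buildup time T_shell (the radical solution's
3.3 s), core buildup T_core (the dry polymer's 13.3 s ¹H T₁ at 100 K).
The observed curve is the weighted biexponential with shell weight
f·ε_shell (microwaves on, ε_shell = 120 by default) or
f·(1 − depolarization) (off, depolarization 0.6 — an upper bound from the
literature, treated as a parameter), and core weight 1 − f. R is not known
experimentally; the default 39.1 μm is fixed by requiring that a 2.5-μm
shell corresponds to an 18% swelled volume. Spin diffusion between shell
and core is neglected because L = sqrt(D·t) ≈ 0.1 μm for
D ≈ 10⁻¹⁵ m²/s and t < 10 s, far below the particle size (that convention
for L, without the factor √6, is the one that reproduces the 0.1-μm
figure).

Fitting a single buildup time to these curves on a delay grid spanning
0.25–40 s (≈0.02·T_core to 3·T_core) yields the *apparent* T that an
experimenter would report. With microwaves on, the enhanced shell dominates
already at f ≈ 0.18 (apparent T within ~4% of T_shell), so equal on-state
buildup of polymer and radical solution proves nothing about swelling.
With microwaves off, the apparent T decreases monotonically with f and
comes within 5% of T_shell only for f > 0.95 on a 21-point grid — equal
off-state buildup therefore implies near-complete swelling. This is the
quantitative content of the homogeneous-swelling proof, and the package's
`relax` command turns it into an explicit verdict for on/off curve pairs.

DNP bookkeeping: ε_DNP is the per-scan on/off integral ratio over a window;
the Boltzmann-referenced gain is ε·(1 − depolarization) — 120 × 0.4 = 48,
"around a factor of 50".

## Quantification pipeline

Processing order: optional phase correction (φ = ph0 + ph1·(δ−pivot)/span;
real-only data admit only zero-order, via Hilbert reconstruction of the
dispersive part), anchored polynomial baseline on transfer and control
separately, per-scan 1:1 subtraction, trapezoidal integration.

* **Baseline**: order 5, fitted in the ppm coordinate mapped to [−1, 1]
  for conditioning, using only anchor points. Default anchors are
  (190, 115) and (60, 10) ppm — the signal-free stretches between the C1
  peak and its first spinning sidebands (at ±MAS/SF ≈ ±99.4 ppm for 10 kHz
  at 100.6 MHz) — clipped to the axis, with optional exclusion bands
  around listed peak positions. At least 2·(order+1) anchor points are
  required. The correction is idempotent to 1e-8 of the spectrum maximum.
* **Integration**: trapezoidal with linearly interpolated window edges, so
  adjacent windows are exactly additive and the shared 80.4-ppm boundary
  is never double-counted. Windows are (high, low) pairs; the defaults are
  the substituted (90.1–80.4 ppm) and free (80.4–71.9 ppm) C2 regions.
* **Uncertainty**: replicate standard deviation when replicates exist;
  otherwise seeded Monte-Carlo noise propagation or baseline-anchor
  perturbation (±2 ppm jitter by default). A reference sample's relative
  sd can be transferred to samples without replicates, mirroring how a
  single triplicated sample anchors the error bars of a series.
* Negative window integrals (possible at low SNR) are reported as-is with
  a warning; the percent is clamped to [0, 100] only in the rendered
  summary, never in stored values. Every step appends to the provenance
  log because phasing/baseline/subtraction at low SNR is a subjective
  procedure that must remain auditable.

## Synthetic data

The generator emulates what the analysis assumes: Gaussian ring-carbon
lines (FWHM 1.5 ppm) at 103/84/75 ppm, first sidebands at ±MAS/SF with
15% relative amplitude, a broad pseudo-Voigt artifact at 80 ppm (its true
lineshape is unknown; width 3 ppm by default), polynomial drift, and white
Gaussian noise with SNR defined as (max C2 peak height)/σ. Axes default to
8192 points over 230…−30 ppm, a typical processed-1D sampling density.
Gaussian is the default line model because these heavily substituted
ethers are amorphous and inhomogeneously broadened; with Lorentzian lines
the heavy tails leak a few percent of each peak's area across the fixed
80.4-ppm boundary and bias the recovered substitution by up to ≈2.5 points
at p = 30/70% — a genuine limitation of fixed-window integration that
applies equally to real spectra with Lorentzian character. Transfer and
control differ only by the C2 J-transfer peaks and their independent noise
realizations; each pair carries a truth record with every generation
parameter.

What the generator does **not** model: FID-domain effects (apodization,
correlated noise), CP dynamics and ¹H-reservoir physics, MAS recoupling
during the z-filter CW irradiation, J/T₂′ differences between substituted
and free C2, and multi-site chemical-shift distributions. Passing the
synthetic recovery suite therefore demonstrates correctness of the
*procedure* under the stated statistical model, not the accuracy of the
method on arbitrary real samples.

Under those conditions the pipeline recovers true substitutions of
30/50/70% within ±3 percentage points per run at SNR 20 (artifact at 20%
of the C2 area, drift present), and within ±5 points on a 3-seed average
at SNR 5 — consistent with the semi-quantitative error bars that replicate
measurements give at study scale (±12–14 points, dominated by the same
noise-through-integration route).

## Numerical choices

* ppm axes are stored strictly decreasing; all windows are (high, low).
* `ppm_to_index` breaks exact midpoint ties toward the lower (downfield)
  index.
* Internal text format writes 17 significant digits; round trips are
  lossless to 1e-12 relative.
* The Bruker reader accepts integer (`DTYPP=0`, scaled by 2^NC_proc) and
  float64 (`DTYPP=2`) processed arrays, both byte orders, and reconstructs
  the axis as OFFSET − i·(SW_p/SF)/SI.
* All random draws go through `numpy.random.default_rng` with explicit
  seeds; identical seeds give byte-identical outputs.
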