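# etherdnp

Analysis toolkit for measuring **position-specific (C2) substitution in
hydrophilic cellulose ethers** (EHEC, MEHEC) by DNP-enhanced solid-state
¹³C NMR.

Cellulose ethers are rheology modifiers whose resistance to cellulase
degradation depends on *where* on the anhydroglucose unit (AGU) the ether
groups sit. Substitution at C2 shifts the C2 resonance downfield
(≈84 ppm vs ≈75 ppm for free C2), but in 1D CP/MAS spectra the 70–90-ppm
region is hopelessly overlapped. A selective 1D *J*-coupling experiment
solves this: C1 (≈103 ppm) is isolated with selective pulses and a
z-filter, and its magnetization is transferred to the directly bonded C2
through the one-bond ¹³C–¹³C coupling with a perfect echo,
`[τ–π–τ]–π/2–[τ–π–τ]`. Because the selective pulses also excite a small
artifact near 80 ppm, a control experiment without the transfer π/2 pulse
is subtracted (difference spectroscopy) and the difference spectrum is
integrated in two adjacent windows:

```
%C2_sub = 100 · I(90.1–80.4 ppm) / [ I(90.1–80.4) + I(80.4–71.9) ]
```

The package implements, with synthetic ground truth for every stage:

* a **product-operator simulator** of the full pulse sequence (16-operator
  Cartesian basis, 8-step phase cycle, z-filter, shaped-pulse attenuation
  and leakage, T₂′ losses) with perfect-echo, control and
  double-quantum-filtered variants, plus a Bloch-equation excitation
  profile of the truncated-Gaussian selective pulse;
* the **quantification pipeline**: phasing, anchored fifth-order polynomial
  baseline, per-scan control subtraction, windowed integration, and
  replicate / Monte-Carlo / anchor-perturbation uncertainties;
* **relaxation models**: stretched-exponential saturation-recovery fits
  `A·(1−exp(−(t/T)^β))` and the core–shell swelling model that shows why
  equal microwave-*off* buildup times of the polymer and the radical
  solution prove homogeneous swelling (a prerequisite for uniform DNP
  enhancement), plus enhancement-ratio and depolarization-corrected-gain
  bookkeeping;
* **IO** for Bruker TopSpin processed 1D data and a plain two-column text
  format, and a **synthetic-data generator** with seeded, bit-reproducible
  output.

## Worked example

Generate a synthetic transfer/control pair with 59% of C2 positions
substituted (SNR 20, artifact at 20% of the C2 area), then quantify it:

```bash
$ etherdnp synth --p 0.59 --snr 20 --artifact-amp 0.2 --seed 1 --out data
wrote transfer/control pair (true %C2 = 59.0) to data

$ etherdnp quantify --transfer data/transfer.txt --control data/control.txt --out out
C2 substitution quantification
  substituted C2 integral (90.1-80.4 ppm): 0.58813
  free C2 integral        (80.4-71.9 ppm): 0.392093
  % C2 substituted: 60.0
  provenance:
    - baseline order=5 anchors=default
    - control subtracted scale=per-scan
    - integrated sub=(90.1,80.4) free=(80.4,71.9)
```

The pipeline recovers 60.0% against a ground truth of 59% — within the
±3-point accuracy the package guarantees at SNR 20. The two integrals are
the areas of the difference spectrum in the substituted and free C2
windows; the provenance log records every processing choice.

Simulating the double-quantum-filtered variant shows why the perfect echo
was preferred for a 1D experiment that starts with magnetization on C1
only — the DQ cycle transfers in just half of the scans:

```bash
$ etherdnp simulate --variant dq --tau 4 --j 46 --out sim
variant=dq_filter tau=4.0 ms J=46.0 Hz
cycled C1 signal: 0.418833+6.69983e-17j
cycled C2 signal: 0.418833+2.56461e-17j
transferring steps: 4/8
```

(The perfect echo at the same τ and J gives a cycled C2 amplitude of
0.8377 = sin²(2πJτ) — exactly twice the DQ value.)

Library use mirrors the CLI:

```python
from etherdnp import make_transfer_pair, quantify_pair, spin_diffusion_length

transfer, control, truth = make_transfer_pair(0.59, snr=20, artifact_amp=0.2, seed=1)
result = quantify_pair(transfer, control)
print(result.pct_substituted)        # 60.0
print(spin_diffusion_length(1e-15, 10.0))   # 1e-07 m: ~0.1 um in <10 s
```

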