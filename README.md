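# flowtrast

A deterministic forward simulator of **microfluidics-based widefield
fluorescence detection of fluorophore dark states**. Fluorescent molecules
are carried by laminar flow over a stationary flat-top (supergaussian)
488 nm excitation beam; because position along the flow maps to exposure
time (t = x/v), the build-up of long-lived dark states — the triplet T and
the photooxidized radical R⁺ — reshapes the normalized fluorescence profile
recorded by an sCMOS camera. The simulator computes those profiles and
images for carboxyfluorescein (CFl) and its brominated derivatives
(CFl-1Br, CFl-2Br, CFl-4Br/eosin-Y), whose intersystem-crossing rates span
two orders of magnitude due to the internal heavy-atom effect, and
quantifies the three dark-state signatures: **broadening**, **shift** and
**decay** of Fnorm relative to the beam's own profile.

It is aimed at spectroscopists designing TRAST-style (transient-state)
flow experiments who want to predict, before building anything, whether a
dye's dark-state kinetics will be resolvable at given laser powers and flow
rates.

## Model

Each dye is a three-state system S (S0+S1), T, R⁺ evolving by
dP/dt = M·P from P(0) = (1, 0, 0), with

* k01 = σ_exc·I/E_photon — excitation rate at local irradiance I,
* kisc′ = kisc·k01/(k01 + k10) — effective intersystem crossing,
* k10 = 1/τf − kisc′ − k_ox — radiative de-excitation (solved jointly with
  kisc′; see `docs/methods.md`),
* k_T, k_ox, k_red — triplet relaxation, radical formation and return.

The beam is I(x) = I0·exp(−2((x−x0)/w)⁶), stretched uniformly over L across
the flow, with I0 = 3·2^{1/6}·P_eff/(Γ(1/6)·w·L). States advance along the
plug-flow trajectory with exact matrix exponentials per camera pixel, and
the detected signal is F(x) = qD·qF·k10·S(x)·k01/(k01+k10), normalized to
its peak (qD, qF cancel).

## Worked example

Simulate eosin-Y (CFl-4Br) at the highest laser power (300 mW ≈ 3.62 kW/cm²
peak irradiance) and the fastest flow rate, then quantify the dark-state
signatures:

```sh
$ flowtrast simulate --dye CFl-4Br --I0 3.62 --flow 2000 --outdir out --format csv --format tiff
[CFl-4Br] I0=3.62 kW/cm2 Peff=299.2 mW Q=2000 uL/min v=6.667 m/s passage=33.28 us k01(peak)=1.467 /us

$ flowtrast metrics out/CFl-4Br_I0-3.62kWcm2_Q-2000uLmin.csv --out out/metrics.csv
$ cat out/metrics.csv
dye,I0_kW_cm2,Q_uL_min,fwhm_broadening_um,peak_shift_um,decay_fraction
CFl-4Br,3.62,2000,7.79355137,-3.40177116,0.172405733
```

Reading the numbers: at 2000 μL/min the plug-flow velocity is 6.67 m/s, so
a molecule crosses the 221.87 μm field of view in 33 μs. The peak
excitation rate k01 ≈ 1.47 μs⁻¹ drives eosin-Y's strong intersystem
crossing, and the profile comes out **7.8 μm broader** than the beam, its
centroid pulled **3.4 μm upstream** (the signal is depleted later in the
transit), with a **17% in-beam decay** — the triplet dip that makes the
heavy-atom effect visible at high flow rates. The companion TIFF is the
512×512 16-bit grayscale image the camera would see.

Other entry points: `flowtrast sweep` (the full dye × irradiance ×
flow-rate grid), `flowtrast beam` (excitation field + reference profile),
`flowtrast catalog` (the built-in dye constants), or the library API
(`flowtrast.simulate_signal`, `flowtrast.dark_state_metrics`, ...).

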