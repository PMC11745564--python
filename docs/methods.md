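# Methods

## The forward model

`flowtrast` simulates what a widefield fluorescence microscope records when
fluorophores are driven through a stationary flat-top excitation beam by
laminar flow in a microfluidic channel. The observable is the normalized
fluorescence profile along the flow direction, Fnorm(x) = F(x)/max F, and
its 2D image rendering. Because the flow maps position to exposure time
(t = x/v), dark-state build-up during the transit appears as broadening,
a centroid shift, and an in-beam decay of Fnorm relative to the beam's own
normalized profile (the "no dark state" reference curve).

### Electronic-state model

Each dye is a three-manifold system: the singlet manifold S (ground S0 plus
emissive S1), the triplet T, and the photooxidized radical cation R⁺.
Population dynamics follow the linear master equation dP/dt = M·P with

    M = [ −kisc′      k_T        k_red ]
        [  kisc′   −k_ox−k_T      0    ]
        [   0         k_ox      −k_red ]

over P = (S, T, R⁺), starting from P(0) = (1, 0, 0) — molecules enter the
field of view unexcited. Columns of M sum to zero, so probability is
conserved exactly.

S0↔S1 equilibration (antibunching relaxation, ns scale) is treated as
instantaneous relative to the μs–ms dark-state kinetics: the S1 occupancy
within the singlet manifold is the algebraic factor k01/(k01 + k10), where
k01 = σ_exc·I/E_photon is the excitation rate at local irradiance I and
k10 is the radiative de-excitation rate.

### Rate closure

The effective intersystem-crossing rate kisc′ = kisc·k01/(k01 + k10) and the
de-excitation rate k10 = 1/τf − kisc′ − k_ox define each other. They are
closed simultaneously: substituting one relation into the other gives

    k10² + k10·(k01 − a) + k01·(kisc − a) = 0,   a = 1/τf − k_ox,

and the root closest to 1/τf is the physical one (the other root is a
near-zero spurious branch). The simultaneous solve is not optional: for
CFl-4Br the intrinsic kisc (893 μs⁻¹) exceeds 1/τf (892.9 μs⁻¹), so the
naive subtraction k10 = 1/τf − kisc − k_ox would be negative.

### Constant-irradiance solution and its role

At constant irradiance the singlet population is a tri-exponential,
S(t) = A1·e^{λ1 t} + A2·e^{λ2 t} + A3·e^{λ3 t} with λ1 = 0 (A1 the steady
state), λ2 = −(kisc′ + k_T) the fast triplet-equilibration mode, and
λ3 = −k_red − k_ox·kisc′/(kisc′ + k_T) the slow radical mode. The closed
forms for A1–A3 and λ2, λ3 are timescale-separation approximations (they
drop terms of order k_ox/k_T). For the supported dyes they agree with the
exact spectrum of M to better than 0.2% and track the exact S(t) to within
6×10⁻⁴ absolute; they are exposed for constant-irradiance analysis and used
as a cross-check, but the flow engine never relies on them.

### Trajectory propagation

The flow engine uses the exact linear propagator. The along-flow axis is
discretized at the camera's sample-plane pixels; within one pixel the
irradiance is constant, so advancing the state by the pixel residence time
Δt = pixel/v is exact: P ← expm(M(I(x))·Δt)·P. The signal is evaluated at
pixel centers using the half-pixel-propagated state:

    F(x) = qD · qF · k10(x) · S(x) · k01(x)/(k01(x) + k10(x)).

qD (camera detection efficiency) and qF (fluorescence quantum yield) scale
F only and cancel exactly under peak normalization; the implementation
normalizes before applying them so Fnorm is bit-identical for any values.
Because the per-pixel step is an exact matrix exponential, sub-step
refinement changes Fnorm only at round-off level (< 10⁻⁶, verified by a
refinement test); the only discretization left is the pixel-resolution
piecewise-constant irradiance, which is the camera's own resolution.

### Beam model

The excitation beam is a supergaussian flat-top, I(r) = I0·exp(−2|r/w|ⁿ)
with order n = 6 by default, stretched uniformly across the flow over a
span L and zero outside it. Peak irradiance and effective optical power are
exact inverses through the analytic integral

    P_eff = I0 · L · w · 2^{1−1/n} · Γ(1 + 1/n)
          = I0 · L · w · 2^{−1/6} · Γ(1/6)/3      (n = 6),

with Γ(1/6) ≈ 5.566. With the default w = 50 μm, L = 100 μm beam, the
5–300 mW output range of 488 nm CW diode lasers maps to peak irradiances of
0.0605–3.630 kW/cm².

### Flow-to-time mapping

Plug flow is assumed: a single velocity v = Q/(width·height) across the
channel cross-section, so every streamline inside the beam span shares one
history and t = x/v. Parabolic (Poiseuille) profiles, diffusion and Taylor
dispersion are out of scope. The default channel is 100 μm wide (the beam
stretch) and 50 μm high; the imaged length is set by the camera field of
view.

## Dark-state metrics

All three metrics compare Fnorm(x) to the normalized beam reference and are
exactly zero when the two coincide:

* **FWHM broadening** [μm] — full width at half maximum (linear
  interpolation at the 0.5 crossings) of the profile minus that of the
  reference. The reference width is analytic: 2w·(ln2/2)^{1/6} ≈ 83.8 μm
  for the default beam.
* **Peak shift** [μm] — displacement of the intensity-weighted centroid,
  positive downstream. Dark-state build-up depletes the signal later in the
  transit, so in practice the centroid moves *upstream* (negative values,
  growing in magnitude with irradiance and bromination).
* **Decay fraction** — the deepest fractional drop of the profile below the
  reference over the region where the reference is at least half-maximal:
  1 − min(Fnorm/ref). Taking the ratio makes the metric insensitive to edge
  broadening (where Fnorm exceeds the reference) and, for profiles that sag
  over the beam plateau, equal to the plateau dip — the "x% decay" read off
  a plotted normalized signal. A literal minimum of Fnorm over the half-max
  support would instead be dominated by the downstream beam edge and would
  not vanish for the reference itself. The support threshold (default 0.5,
  the FWHM convention) is configurable.

## Parameters that matter

| parameter | default | units | meaning |
|---|---|---|---|
| τf | per dye (1.12–4.04) | ns | fluorescence lifetime |
| σ_exc | per dye (1.65–3.0 ×10⁻¹⁶) | cm² | excitation cross-section at 488 nm |
| kisc | per dye (10.8–893) | μs⁻¹ | intrinsic ISC rate (heavy-atom effect) |
| k_T | per dye (0.58–0.71) | μs⁻¹ | triplet relaxation |
| k_red, k_ox | per dye | μs⁻¹ | radical return / formation |
| n | 6 | — | supergaussian order (2 = Gaussian) |
| w | 50 | μm | beam waist (e⁻² radius) along flow |
| L | 100 | μm | beam stretch across flow |
| λ_exc | 488 | nm | excitation wavelength |
| P_eff | 5–300 (grid of 7) | mW | laser output → I0 via the power integral |
| Q | 100–2000 (grid of 4) | μL/min | volumetric flow rate |
| camera | 2048 px, 6.5 μm, 4×, 60× | — | → 512 px, 0.4333 μm/px, 221.87 μm FOV |

The irradiance grid {5, 10, 25, 50, 100, 150, 300} mW reproduces the
0.06, 1.81 and 3.62(9) kW/cm² values quoted for the reference setup.

## Regimes and phenomenology

Triplet equilibration is fast (1/|λ2| ≈ 0.5–1.5 μs); radical formation is
slow (1/|λ3| ≈ 200 μs – 5 ms, dye-dependent). At 100 μL/min (transit
≈ 0.7 ms) radical build-up dominates the CFl response; at 2000 μL/min
(transit ≈ 33 μs) the triplet dip of brominated dyes dominates. The decay
metric is therefore *non-monotone* in flow rate: it grows through the
experimental range (≈ 2×10⁻⁴ at 100 μL/min to ≈ 0.17 at 2000 μL/min for
CFl-4Br at peak irradiance), peaks near 2×10⁴ μL/min, and only then falls
toward zero in the fast-flow limit where the profile returns to the beam
reference. The upstream peak shift and the FWHM broadening grow
monotonically with irradiance and with bromination number in the ranges
simulated.

## Numerical choices

* Internal units: μs, μm, μs⁻¹, W/cm²; conversions only at public
  boundaries (1 m/s ≡ 1 μm/μs makes the flow mapping a plain division).
* Coordinates: pixel-center sampling, x = i·pixel; beam centered at
  round(N/2)·pixel so the sampled peak equals I0 exactly.
* Propagator: `scipy.linalg.expm` on the 3×3 rate matrix per pixel; exact
  for piecewise-constant irradiance, unconditionally stable, simplex-
  preserving to < 10⁻⁹ over 10⁴ segments.
* The peak normalization uses the computed maximum, so max(Fnorm) is
  exactly 1 by construction.
* Degenerate inputs: zero irradiance everywhere, flat profiles (no half-max
  crossing), empty metric support, and traversal times beyond a configurable
  cap (default 10⁶ μs) all raise informative errors.
* No randomness anywhere: identical inputs give byte-identical outputs.

## What the simulator does not model

Shot noise, camera read noise and dark current (frame averaging is summarized
by the noiseless mean); photobleaching; diffusion and Taylor dispersion;
higher excited singlet/triplet states and stimulated emission; Poiseuille
velocity profiles; axial beam structure, diffraction and aberrations; the
inverse problem of fitting rates from measured profiles. Consequently,
passing tests demonstrate the deterministic forward physics, not detection
performance under real noise: quantitative agreement with a measured image
stack would additionally depend on photon statistics, flow-profile
non-uniformity and bleaching, none of which are represented here.

## Problem sizes

All simulations run on the native 512-pixel grid; a single profile takes a
few tens of milliseconds, the full 4 dyes × 7 irradiances × 4 flow rates
grid a few seconds, so no down-scaling is needed anywhere.
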