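"""Three-state electronic model of a fluorophore under continuous excitation.

The model lumps the ground and first excited singlet (S0, S1) into a single
singlet manifold S, coupled to two dark states: the triplet T (entered by
intersystem crossing, relaxing with ``k_T``) and the photooxidized radical
cation R⁺ (entered from T with ``k_ox``, returning by photoreduction
``k_red``).  Nanosecond S0↔S1 antibunching equilibration is treated as
instantaneous relative to the μs–ms dark-state kinetics, so the S1 occupancy
enters only as the algebraic factor ``k01/(k01 + k10)``.

Internal unit convention: rates in μs⁻¹, times in μs, lengths in μm,
irradiance in W/cm², cross-sections in cm².  All conversions happen at the
public function boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "DyeParams",
    "DerivedRates",
    "StateVector",
    "CouplingMatrix",
    "AnalyticSolution",
    "photon_energy",
    "photon_flux",
    "excitation_rate",
    "solve_derived_rates",
    "coupling_matrix",
    "analytic_solution",
    "singlet_population",
    "propagate_states",
    "steady_state",
]

# CODATA 2018 exact values
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m/s


@dataclass(frozen=True)
class DyeParams:
    """Measured photophysical constants of one dye.

    Parameters
    ----------
    name : str
        Catalog label, e.g. ``"CFl-4Br"``.
    tau_f : float
        Fluorescence lifetime [ns].
    sigma_exc : float
        Excitation cross-section at the laser wavelength [cm²].
    k_isc : float
        Intrinsic intersystem-crossing rate out of S1 [μs⁻¹].
    k_T : float
        Triplet → ground-singlet relaxation rate [μs⁻¹].
    k_red : float
        Radical → ground-singlet photoreduction rate [μs⁻¹].
    k_ox : float
        Triplet → radical photooxidation rate [μs⁻¹].
    """

    name: str
    tau_f: float
    sigma_exc: float
    k_isc: float
    k_T: float
    k_red: float
    k_ox: float

    def __post_init__(self) -> None:
        for attr in ("tau_f", "sigma_exc", "k_isc", "k_T", "k_red", "k_ox"):
            value = getattr(self, attr)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"dye {self.name!r}: {attr} must be strictly positive, got {value!r}"
                )

    @property
    def inv_tau_f(self) -> float:
        """Total S1 depopulation rate 1/τf [μs⁻¹] (τf given in ns)."""
        return 1e3 / self.tau_f


@dataclass(frozen=True)
class DerivedRates:
    """Irradiance-dependent rates derived from a :class:`DyeParams`.

    ``k10`` and the effective ISC rate ``k_isc_eff`` (kisc′) are defined
    through each other: kisc′ = kisc·k01/(k01+k10) while
    k10 = 1/τf − kisc′ − k_ox.  :func:`solve_derived_rates` closes the pair
    self-consistently.
    """

    photon_energy: float  # J
    photon_flux: float  # photons cm⁻² s⁻¹
    k01: float  # μs⁻¹
    k_isc_eff: float  # μs⁻¹
    k10: float  # μs⁻¹

    @property
    def s1_occupancy(self) -> float:
        """Fraction of the singlet manifold residing in S1."""
        if self.k01 == 0.0:
            return 0.0
        return self.k01 / (self.k01 + self.k10)


@dataclass(frozen=True)
class StateVector:
    """Occupation probabilities of the (S, T, R⁺) manifolds; simplex-constrained."""

    S: float
    T: float
    R: float

    _TOL = 1e-9

    def __post_init__(self) -> None:
        for label, value in (("S", self.S), ("T", self.T), ("R", self.R)):
            if value < -self._TOL or value > 1.0 + self._TOL:
                raise ValueError(f"state component {label}={value!r} outside [0, 1]")
        total = self.S + self.T + self.R
        if abs(total - 1.0) > self._TOL:
            raise ValueError(f"state probabilities sum to {total!r}, expected 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.T, self.R], dtype=float)

    @classmethod
    def ground(cls) -> "StateVector":
        """All population in the singlet manifold (not yet photoexcited)."""
        return cls(1.0, 0.0, 0.0)


def photon_energy(wavelength_nm: float) -> float:
    """Energy of one photon, E = hc/λ [J], for a wavelength in nm."""
    if not wavelength_nm > 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm!r}")
    return PLANCK_H * SPEED_OF_LIGHT / (wavelength_nm * 1e-9)


def photon_flux(irradiance: float, wavelength_nm: float) -> float:
    """Photon flux Φ = I/E [photons cm⁻² s⁻¹] for irradiance in W/cm²."""
    if irradiance < 0:
        raise ValueError(f"irradiance must be non-negative, got {irradiance!r}")
    return irradiance / photon_energy(wavelength_nm)


def excitation_rate(sigma_exc: float, irradiance: float, wavelength_nm: float) -> float:
    """Excitation rate k01 = σ_exc · I / E(λ), returned in μs⁻¹.

    ``sigma_exc`` in cm², ``irradiance`` in W/cm².
    """
    if not sigma_exc > 0:
        raise ValueError(f"sigma_exc must be positive, got {sigma_exc!r}")
    return sigma_exc * photon_flux(irradiance, wavelength_nm) * 1e-6


def solve_derived_rates(dye: DyeParams, k01: float,
                        wavelength_nm: float | None = None,
                        irradiance: float | None = None) -> DerivedRates:
    """Self-consistent (kisc′, k10) pair at excitation rate ``k01`` [μs⁻¹].

    Substituting kisc′ = kisc·k01/(k01+k10) into k10 = 1/τf − kisc′ − k_ox
    gives the quadratic

        k10² + k10·(k01 − a) + k01·(k_isc − a) = 0,   a = 1/τf − k_ox.

    The root closest to 1/τf is the physical one (the other is a spurious
    near-zero root).  Solving simultaneously matters: for strongly brominated
    dyes k_isc exceeds 1/τf, so the naive k10 = 1/τf − k_isc − k_ox would be
    negative.
    """
    if k01 < 0:
        raise ValueError(f"k01 must be non-negative, got {k01!r}")
    inv_tau = dye.inv_tau_f
    a = inv_tau - dye.k_ox
    if k01 == 0.0:
        k10 = a
        k_isc_eff = 0.0
    else:
        # k10² + b·k10 + c = 0
        b = k01 - a
        c = k01 * (dye.k_isc - a)
        disc = b * b - 4.0 * c
        if disc < 0:
            raise ValueError(
                f"dye {dye.name!r}: no real de-excitation rate at k01={k01!r}"
            )
        sqrt_disc = float(np.sqrt(disc))
        roots = ((-b + sqrt_disc) / 2.0, (-b - sqrt_disc) / 2.0)
        k10 = min(roots, key=lambda r: abs(r - inv_tau))
        if k10 <= 0:
            raise ValueError(
                f"dye {dye.name!r}: unphysical parameter set, "
                f"k10={k10!r} at k01={k01!r}"
            )
        k_isc_eff = dye.k_isc * k01 / (k01 + k10)
    energy = photon_energy(wavelength_nm) if wavelength_nm else float("nan")
    flux = (k01 * 1e6 / dye.sigma_exc) if k01 else 0.0
    if irradiance is not None and wavelength_nm is not None:
        flux = photon_flux(irradiance, wavelength_nm)
    return DerivedRates(photon_energy=energy, photon_flux=flux,
                        k01=k01, k_isc_eff=k_isc_eff, k10=k10)


@dataclass(frozen=True)
class CouplingMatrix:
    """3×3 transition-rate matrix over (S, T, R⁺); columns sum to zero."""

    M: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.shape != (3, 3):
            raise ValueError(f"coupling matrix must be 3×3, got {M.shape}")
        col_sums = M.sum(axis=0)
        if np.any(np.abs(col_sums) > 1e-9 * max(1.0, np.abs(M).max())):
            raise ValueError(f"coupling-matrix columns must sum to 0, got {col_sums}")
        object.__setattr__(self, "M", M)

    def eigenvalues(self) -> np.ndarray:
        """Exact eigenvalues, sorted by ascending magnitude (λ1 = 0 first)."""
        vals = np.linalg.eigvals(self.M)
        return np.real(vals[np.argsort(np.abs(vals))])


def coupling_matrix(dye: DyeParams, rates: DerivedRates) -> CouplingMatrix:
    """Rate matrix M of dP/dt = M·P over (S, T, R⁺).

    Column S loses population to T at the effective ISC rate kisc′; column T
    splits between relaxation to S (k_T) and oxidation to R⁺ (k_ox); column R
    returns to S by photoreduction (k_red).
    """
    kp = rates.k_isc_eff
    M = np.array(
        [
            [-kp, dye.k_T, dye.k_red],
            [kp, -dye.k_ox - dye.k_T, 0.0],
            [0.0, dye.k_ox, -dye.k_red],
        ]
    )
    return CouplingMatrix(M)


@dataclass(frozen=True)
class AnalyticSolution:
    """Closed-form tri-exponential singlet relaxation S(t) = Σ Aᵢ·exp(λᵢ t).

    λ1 is identically zero (A1 is the steady-state singlet population); λ2 is
    the fast triplet-equilibration mode and λ3 the slow radical mode.  The
    closed forms assume the triplet mode is much faster than the radical one,
    which holds for the supported dyes.
    """

    A1: float
    A2: float
    A3: float
    lam1: float
    lam2: float
    lam3: float

    def amplitudes(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3])

    def eigenvalues(self) -> np.ndarray:
        return np.array([self.lam1, self.lam2, self.lam3])


def analytic_solution(dye: DyeParams, rates: DerivedRates) -> AnalyticSolution:
    """Timescale-separation closed forms for amplitudes and eigenvalues.

    Valid for ``rates.k01 > 0``; the exact propagator
    (:func:`propagate_states`) should be preferred for quantitative work —
    these forms drop terms of order k_ox/k_T.
    """
    if rates.k01 <= 0:
        raise ValueError("analytic solution requires k01 > 0")
    kp, kT, kox, kred = rates.k_isc_eff, dye.k_T, dye.k_ox, dye.k_red
    if kp + kT == 0:
        raise ValueError(f"dye {dye.name!r}: degenerate model, kisc' + k_T = 0")
    denom = kp * (kox + kred) + kred * kT
    A1 = kT * kred / denom
    A2 = kp / (kp + kT)
    A3 = kp * kT * kox / (denom * (kT + kp))
    lam2 = -(kp + kT)
    lam3 = -(kred + kox * kp / (kp + kT))
    return AnalyticSolution(A1=A1, A2=A2, A3=A3, lam1=0.0, lam2=lam2, lam3=lam3)


def singlet_population(t, sol: AnalyticSolution):
    """S(t) from the closed forms; ``t`` in μs, scalar or array, all ≥ 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    s = (
        sol.A1 * np.exp(sol.lam1 * t)
        + sol.A2 * np.exp(sol.lam2 * t)
        + sol.A3 * np.exp(sol.lam3 * t)
    )
    return s if s.ndim else float(s)


def steady_state(dye: DyeParams, rates: DerivedRates) -> StateVector:
    """Exact stationary distribution: the simplex-normalized null vector of M."""
    kp = rates.k_isc_eff
    if kp == 0.0:
        return StateVector.ground()
    # Detailed-balance-like closure of the 3-state chain
    t_over_s = kp / (dye.k_T + dye.k_ox)
    r_over_t = dye.k_ox / dye.k_red
    s = 1.0 / (1.0 + t_over_s * (1.0 + r_over_t))
    return StateVector(S=s, T=s * t_over_s, R=s * t_over_s * r_over_t)


def propagate_states(
    dye: DyeParams,
    state: StateVector | np.ndarray,
    segments: Sequence[tuple[float, float]],
    substeps: int = 1,
) -> np.ndarray:
    """Advance the state through piecewise-constant excitation segments.

    Each segment is ``(k01 [μs⁻¹], duration [μs])``; the derived rates and
    coupling matrix are rebuilt at that segment's excitation rate and the
    state is advanced with the exact linear-system propagator
    ``expm(M·Δt)``, so no accuracy is lost for long segments. ``substeps``
    subdivides each segment (intermediate states are not recorded); since
    the propagator is exact it only matters for refinement checks.

    Returns an ``(len(segments)+1, 3)`` trajectory of states, starting from
    the initial one.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    p = state.as_array() if isinstance(state, StateVector) else np.asarray(state, float)
    traj = np.empty((len(segments) + 1, 3))
    traj[0] = p
    for i, (k01, dt) in enumerate(segments):
        if not dt > 0:
            raise ValueError(f"segment {i}: duration must be positive, got {dt!r}")
        rates = solve_derived_rates(dye, k01)
        M = coupling_matrix(dye, rates).M
        step = expm(M * (dt / substeps))
        for _ in range(substeps):
            p = step @ p
        traj[i + 1] = p
    return traj
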