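"""Normal-mode analysis and quasi-RRHO vibrational entropy.

``normal_modes`` mass-weights a Cartesian Hessian, projects out rigid-body
translations/rotations (5 for linear molecules, detected by the
moment-of-inertia ratio), and maps eigenvalues to wavenumbers; a negative
eigenvalue becomes a negative wavenumber of magnitude sqrt(|lambda|), and a
mode below ``-imaginary_threshold`` flags the structure as a non-minimum.

``quasi_rrho_entropy`` implements Grimme's interpolation between the
harmonic-oscillator and free-rotor entropies,

    S = sum_modes w(v) S_HO(v) + (1 - w(v)) S_FR(v),
    w(v) = 1 / (1 + (v0/v)^alpha),

with the free-rotor moment regularized through mu' = mu B / (mu + B).
Per-mode free-rotor entropies are floored at zero: for very stiff modes the
classical free-rotor expression turns slightly negative, which is an
artifact of the classical rotor picture, not a physical entropy.
Defaults v0 = 100 cm^-1, alpha = 4, B = 1e-44 kg m^2.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import scipy.linalg

from .constants import (BOLTZMANN, C_CM_S, PLANCK, R_KJMOL_K, THETA_PER_CM,
                        WAVENUMBER_PER_SQRT_EIGVAL)

__all__ = [
    "VibrationalAnalysis",
    "FreeEnergyRecord",
    "normal_modes",
    "quasi_rrho_entropy",
    "harmonic_entropy",
    "ImaginaryModeError",
]

logger = logging.getLogger(__name__)


class ImaginaryModeError(ValueError):
    """Entropy was requested for a structure flagged as a non-minimum."""


@dataclasses.dataclass
class VibrationalAnalysis:
    frequencies: np.ndarray        # cm^-1; negative = imaginary mode
    modes: np.ndarray              # (3N, n_modes) mass-weighted eigenvectors
    n_projected: int               # removed rigid-body modes
    has_imaginary: bool
    imaginary_threshold: float     # cm^-1


@dataclasses.dataclass
class FreeEnergyRecord:
    """Decomposed free energy of one optimized structure (all kJ/mol)."""

    e_backend: float               # continuum-QM electronic energy
    e_model: float                 # learned solvent model term
    e_gb: float                    # GB continuum term (entered with minus sign)
    temperature: float             # K
    s_vib: float                   # kJ mol^-1 K^-1 (nan if not a minimum)
    g_total: float
    analysis: VibrationalAnalysis | None = None

    @property
    def electronic(self) -> float:
        return self.e_backend + self.e_model - self.e_gb

    def check(self, tol: float = 1e-10) -> None:
        ts = 0.0 if self.temperature == 0 else self.temperature * self.s_vib
        if abs(self.g_total - (self.electronic - ts)) > tol:
            raise AssertionError("free-energy decomposition inconsistent")


def _rigid_basis(coordinates: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (3N, 3..6)."""
    x = coordinates.reshape(-1, 3)
    n = len(x)
    sq = np.sqrt(masses)
    com = (masses[:, None] * x).sum(0) / masses.sum()
    xc = x - com
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = sq
        vecs.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        r = sq[:, None] * np.cross(np.broadcast_to(e, (n, 3)), xc)
        vecs.append(r.ravel())
    M = np.array(vecs).T
    # drop linearly dependent columns (single atoms, linear molecules)
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def is_linear(coordinates: np.ndarray, masses: np.ndarray,
              ratio_tol: float = 1e-8) -> bool:
    """Linearity via the smallest/largest principal moment-of-inertia ratio."""
    x = coordinates.reshape(-1, 3)
    com = (masses[:, None] * x).sum(0) / masses.sum()
    xc = x - com
    r2 = (xc * xc).sum(1)
    I = (masses[:, None, None]
         * (r2[:, None, None] * np.eye(3)
            - xc[:, :, None] * xc[:, None, :])).sum(0)
    w = np.sort(np.abs(np.linalg.eigvalsh(I)))
    return bool(w[-1] > 0 and w[0] / w[-1] < ratio_tol)


def normal_modes(hessian: np.ndarray, masses: np.ndarray,
                 coordinates: np.ndarray, project_rigid: bool = True,
                 imaginary_threshold: float = 5.0,
                 symmetry_tol: float = 1e-6) -> VibrationalAnalysis:
    """Vibrational frequencies from a Cartesian Hessian.

    hessian in kJ mol^-1 Å^-2, masses in u, coordinates in Å; frequencies
    in cm^-1 with negative values encoding imaginary modes.
    """
    H = np.asarray(hessian, float)
    n3 = 3 * len(masses)
    if H.shape != (n3, n3):
        raise ValueError(f"hessian must be {n3}x{n3}")
    asym = np.abs(H - H.T).max()
    scale = max(1.0, np.abs(H).max())
    if asym > symmetry_tol * scale:
        raise ValueError(f"hessian not symmetric: max asymmetry {asym:.3e}")
    H = 0.5 * (H + H.T)
    inv_sq = 1.0 / np.sqrt(np.repeat(masses, 3))
    Hmw = H * inv_sq[:, None] * inv_sq[None, :]
    if project_rigid:
        rigid = _rigid_basis(coordinates, masses)
        basis = scipy.linalg.null_space(rigid.T)
        n_projected = rigid.shape[1]
    else:
        basis = np.eye(n3)
        n_projected = 0
    Hp = basis.T @ Hmw @ basis
    w, v = np.linalg.eigh(0.5 * (Hp + Hp.T))
    freqs = np.sign(w) * np.sqrt(np.abs(w)) * WAVENUMBER_PER_SQRT_EIGVAL
    modes = basis @ v
    has_imag = bool(np.any(freqs < -imaginary_threshold))
    return VibrationalAnalysis(frequencies=freqs, modes=modes,
                               n_projected=n_projected,
                               has_imaginary=has_imag,
                               imaginary_threshold=imaginary_threshold)


def harmonic_entropy(frequencies: np.ndarray, T: float) -> float:
    """RRHO vibrational entropy (kJ mol^-1 K^-1) of positive modes."""
    nu = np.asarray(frequencies, float)
    nu = nu[nu > 0]
    theta = THETA_PER_CM * nu / T
    s = theta / np.expm1(theta) - np.log1p(-np.exp(-theta))
    return float(R_KJMOL_K * s.sum())


def _free_rotor_entropy_per_mode(nu: np.ndarray, T: float, b_av: float
                                 ) -> np.ndarray:
    """Grimme free-rotor entropy per mode (kJ mol^-1 K^-1), floored at 0."""
    mu = PLANCK / (8.0 * np.pi**2 * C_CM_S * nu)
    mu_eff = mu * b_av / (mu + b_av)
    arg = np.sqrt(8.0 * np.pi**3 * mu_eff * BOLTZMANN * T) / PLANCK
    s = R_KJMOL_K * (0.5 + np.log(arg))
    return np.maximum(s, 0.0)


def quasi_rrho_entropy(analysis: VibrationalAnalysis | np.ndarray, T: float,
                       omega0: float = 100.0, alpha: float = 4.0,
                       b_av: float = 1e-44) -> float:
    """Quasi-RRHO vibrational entropy in kJ mol^-1 K^-1.

    ``analysis`` may be a :class:`VibrationalAnalysis` or a raw frequency
    array in cm^-1.  Frequencies in (-threshold, 0] are treated as numerical
    noise and contribute the zero-frequency (free-rotor) limit; a structure
    flagged ``has_imaginary`` raises :class:`ImaginaryModeError`.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if isinstance(analysis, VibrationalAnalysis):
        if analysis.has_imaginary:
            raise ImaginaryModeError(
                "structure has imaginary modes; exclude it instead of "
                "computing its entropy")
        nu = analysis.frequencies
    else:
        nu = np.asarray(analysis, float)
        if np.any(nu < -5.0):
            raise ImaginaryModeError("imaginary modes present")
    if np.any((nu < 0)):
        logger.warning("flooring %d small negative frequencies to 0",
                       int((nu < 0).sum()))
        warnings.warn("small negative frequencies floored to 0 for entropy",
                      stacklevel=2)
        nu = np.maximum(nu, 0.0)
    s_total = 0.0
    pos = nu > 1e-10
    if np.any(pos):
        nup = nu[pos]
        w = 1.0 / (1.0 + (omega0 / nup) ** alpha)
        theta = THETA_PER_CM * nup / T
        s_ho = R_KJMOL_K * (theta / np.expm1(theta) - np.log1p(-np.exp(-theta)))
        s_fr = _free_rotor_entropy_per_mode(nup, T, b_av)
        s_total += float((w * s_ho + (1.0 - w) * s_fr).sum())
    n_zero = int((~pos).sum())
    if n_zero:
        # omega -> 0+ limit: w -> 0, mu' -> B, pure regularized free rotor
        arg = np.sqrt(8.0 * np.pi**3 * b_av * BOLTZMANN * T) / PLANCK
        s_total += n_zero * max(R_KJMOL_K * (0.5 + np.log(arg)), 0.0)
    return s_total
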