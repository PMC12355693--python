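"""Conformer-ensemble post-processing.

Sorting by free energy, greedy RMSD pruning, gauche/trans rotamer
classification, Boltzmann populations, molecular-balance ΔΔG statistics and
population-weighted Gaussian-broadened IR spectra.

Conventions, all configurable:

* pruning threshold 0.05 nm on the all-atom RMSD after optimal rigid-body
  (Kabsch) superposition, no symmetry-equivalent-atom permutations;
* a rotamer is *gauche* iff the central dihedral lies strictly inside
  (-2.1, 2.1) rad and *trans* otherwise (boundary values are trans);
* weights w_i ∝ exp(-G_i / RT), evaluated with log-sum-exp;
* balance ΔΔG series are mean-centered per balance before the Pearson
  correlation and least-squares slope; a negative slope maps to -inf on the
  log scale; points flagged as upper detection bounds are excluded first;
* IR broadening: unit-area Gaussians of width σ (default 5 cm^-1) at each
  stick, conformers summed with their Boltzmann weights.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import linregress, pearsonr

from .constants import R_KJMOL_K
from .core import MolecularSystem
from .thermo import FreeEnergyRecord

__all__ = [
    "ConformerRecord",
    "BalanceComparison",
    "Spectrum",
    "UndefinedDihedralError",
    "kabsch_rmsd",
    "dihedral_angle",
    "prune_ensemble",
    "classify_rotamer",
    "boltzmann_populations",
    "balance_statistics",
    "ir_spectrum",
]


class UndefinedDihedralError(ValueError):
    """Three consecutive dihedral atoms are collinear."""


@dataclasses.dataclass
class ConformerRecord:
    system: MolecularSystem
    free_energy: FreeEnergyRecord | None = None
    label: str | None = None
    weight: float | None = None

    @property
    def g_total(self) -> float:
        if self.free_energy is None:
            raise ValueError("conformer has no free energy assigned")
        return self.free_energy.g_total


# ---------------------------------------------------------------------------
# RMSD / pruning


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """All-atom RMSD in Å after optimal rigid superposition."""
    a = np.asarray(a, float).reshape(-1, 3)
    b = np.asarray(b, float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("geometries must have the same number of atoms")
    ac = a - a.mean(0)
    bc = b - b.mean(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exactly aligned pairs
        _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def prune_ensemble(conformers: Sequence[ConformerRecord],
                   rmsd_threshold_nm: float = 0.05
                   ) -> list[ConformerRecord]:
    """Greedy keep-lowest-G pruning.

    Conformers are sorted by ascending free energy; each is retained iff its
    minimum RMSD to every already-retained conformer exceeds the threshold
    (given in nm, as is conventional for trajectory tooling).  Idempotent.
    """
    if rmsd_threshold_nm <= 0:
        raise ValueError("threshold must be positive")
    if not conformers:
        return []
    n_atoms = {c.system.n_atoms for c in conformers}
    if len(n_atoms) != 1:
        raise ValueError(f"mismatched atom counts across conformers: {n_atoms}")
    thr = 10.0 * rmsd_threshold_nm          # nm -> Å
    ordered = sorted(conformers, key=lambda c: c.g_total)
    kept: list[ConformerRecord] = []
    for cand in ordered:
        if all(kabsch_rmsd(cand.system.coordinates, k.system.coordinates) > thr
               for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Dihedrals / rotamer states


def dihedral_angle(coordinates: np.ndarray, i: int, j: int, k: int, l: int
                   ) -> float:
    """Signed dihedral i-j-k-l in (-pi, pi]."""
    x = np.asarray(coordinates, float).reshape(-1, 3)
    b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if (np.linalg.norm(n1) < 1e-10 * np.linalg.norm(b1) * np.linalg.norm(b2)
            or np.linalg.norm(n2) < 1e-10 * np.linalg.norm(b2)
            * np.linalg.norm(b3)):
        raise UndefinedDihedralError(
            f"atoms {(i, j, k, l)} contain a collinear triple")
    phi = float(np.arctan2(np.cross(n1, n2) @ b2 / np.linalg.norm(b2),
                           n1 @ n2))
    if phi <= -np.pi:
        phi += 2 * np.pi
    return phi


def classify_rotamer(conformer: ConformerRecord | MolecularSystem,
                     dihedral: tuple[int, int, int, int],
                     window: float = 2.1) -> str:
    """'gauche' iff the dihedral lies strictly inside (-window, window) rad."""
    system = conformer.system if isinstance(conformer, ConformerRecord) \
        else conformer
    phi = dihedral_angle(system.coordinates, *dihedral)
    return "gauche" if -window < phi < window else "trans"


# ---------------------------------------------------------------------------
# Boltzmann populations


def boltzmann_populations(conformers: Sequence[ConformerRecord], T: float
                          ) -> tuple[np.ndarray, dict[str, float]]:
    """Normalized weights w_i ∝ exp(-G_i/RT) and per-label aggregates.

    Weights are written back onto the records; label aggregation uses each
    record's ``label`` ('' for unlabeled).  Log-sum-exp guards overflow.
    """
    if not conformers:
        raise ValueError("empty ensemble")
    if T <= 0:
        raise ValueError("T must be positive")
    g = np.array([c.g_total for c in conformers])
    if not np.all(np.isfinite(g)):
        raise ValueError("all free energies must be finite")
    z = -g / (R_KJMOL_K * T)
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    states: dict[str, float] = {}
    for c, wi in zip(conformers, w):
        c.weight = float(wi)
        states[c.label or ""] = states.get(c.label or "", 0.0) + float(wi)
    return w, states


# ---------------------------------------------------------------------------
# Molecular-balance statistics


@dataclasses.dataclass
class BalanceComparison:
    predicted_centered: np.ndarray     # kJ/mol, mean-centered
    experimental_centered: np.ndarray
    pcc: float
    slope: float
    intercept: float
    log_slope: float                   # log10(slope); -inf for slope <= 0
    excluded: list[int]


def balance_statistics(predicted: Sequence[float],
                       experimental: Sequence[float],
                       exclusions: Sequence[int] = ()) -> BalanceComparison:
    """Mean-centered ΔΔG comparison: Pearson correlation and LSQ slope.

    ``exclusions`` are indices of points to drop before any statistics
    (e.g. populations below an NMR detection limit, which only bound the
    free energy).  At least 3 paired points must remain.
    """
    pred = np.asarray(predicted, float)
    exp_ = np.asarray(experimental, float)
    if pred.shape != exp_.shape:
        raise ValueError("series lengths differ")
    keep = np.ones(len(pred), bool)
    for idx in exclusions:
        keep[idx] = False
    pred, exp_ = pred[keep], exp_[keep]
    if len(pred) < 3:
        raise ValueError(f"need >= 3 paired points, have {len(pred)}")
    pred_c = pred - pred.mean()
    exp_c = exp_ - exp_.mean()
    pcc = float(pearsonr(exp_c, pred_c).statistic)
    fit = linregress(exp_c, pred_c)
    slope = float(fit.slope)
    log_slope = float(np.log10(slope)) if slope > 0 else float("-inf")
    return BalanceComparison(predicted_centered=pred_c,
                             experimental_centered=exp_c, pcc=pcc,
                             slope=slope, intercept=float(fit.intercept),
                             log_slope=log_slope,
                             excluded=[i for i, k in enumerate(keep) if not k])


# ---------------------------------------------------------------------------
# IR spectra


@dataclasses.dataclass
class Spectrum:
    wavenumbers: np.ndarray            # cm^-1 grid
    intensity: np.ndarray              # arbitrary units (unit-area sticks)
    sigma: float                       # cm^-1
    sticks: list[tuple[float, np.ndarray]]  # (weight, mode wavenumbers)

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.wavenumbers))


def ir_spectrum(conformers: Sequence[ConformerRecord | tuple[float, np.ndarray]],
                sigma: float = 5.0,
                grid: np.ndarray | None = None) -> Spectrum:
    """Population-weighted Gaussian-broadened stick spectrum.

    Each conformer contributes unit-area Gaussians of width ``sigma`` at its
    (real) vibrational frequencies, scaled by its Boltzmann weight; mode
    intensities are treated as constant (no dipole derivatives).  Accepts
    either ConformerRecords (weight + vibrational analysis) or raw
    ``(weight, frequencies)`` pairs.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sticks: list[tuple[float, np.ndarray]] = []
    for c in conformers:
        if isinstance(c, ConformerRecord):
            if c.weight is None or c.free_energy is None \
                    or c.free_energy.analysis is None:
                raise ValueError("conformer lacks weight or frequencies")
            nu = c.free_energy.analysis.frequencies
            sticks.append((float(c.weight), np.asarray(nu[nu > 0], float)))
        else:
            w, nu = c
            sticks.append((float(w), np.asarray(nu, float)))
    all_nu = np.concatenate([nu for _, nu in sticks]) if sticks else np.array([])
    if all_nu.size == 0:
        warnings.warn("no vibrational frequencies; empty spectrum")
        grid = grid if grid is not None else np.linspace(0.0, 4000.0, 2)
        return Spectrum(grid, np.zeros_like(grid), sigma, sticks)
    if grid is None:
        lo = max(0.0, all_nu.min() - 6 * sigma)
        hi = all_nu.max() + 6 * sigma
        grid = np.linspace(lo, hi, max(2000, int((hi - lo) / (sigma / 10))))
    intensity = np.zeros_like(grid)
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    for w, nu in sticks:
        if nu.size:
            d = grid[:, None] - nu[None, :]
            intensity += w * norm * np.exp(-0.5 * (d / sigma) ** 2).sum(axis=1)
    return Spectrum(np.asarray(grid, float), intensity, sigma, sticks)
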