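"""Continuum-QM energy backends.

The combined potential needs a backend that supplies the continuum-solvated
electronic energy, its gradient, and (for thermochemistry) a Hessian.  In
production that is an external quantum-chemistry engine; for desk-scale work
and testing this module provides deterministic analytic surrogates:

* ``harmonic-well`` — quadratic well 1/2 (x-x0)^T K (x-x0).  With the default
  diagonal stiffness it is deliberately anchored to the laboratory frame
  (rigid motions cost energy), which makes optimizer tests deterministic;
  built from bond springs instead it is translationally/rotationally
  invariant.  The Hessian is constant and analytic.
* ``pairwise-morse`` — sum of Morse bonds D (1 - e^{-a(r-re)})^2 over given
  pairs (default: all pairs), analytic gradient and Hessian.
* ``polarizable-toy`` — a softened, dielectric-scaled Coulomb attraction plus
  short-range exponential repulsion; its energy depends on the solvent's
  permittivity, mimicking a continuum-solvated electronic energy.

An adapter for an external engine is provided as a seam only: it shells out
to a user-specified command and parses plain-text energy/gradient files
(eV and eV/Å, converted to internal units).  The test suite never requires
an engine.
"""

from __future__ import annotations

import abc
import dataclasses
import shutil
import subprocess
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .constants import COULOMB_KJMOL_A, EV_TO_KJMOL
from .core import MolecularSystem, SolventSpec, write_xyz

__all__ = [
    "ContinuumBackend",
    "BackendCapabilities",
    "HarmonicWellBackend",
    "PairwisePotentialBackend",
    "ExternalBackend",
    "ExternalEngineError",
    "BackendCapabilityError",
    "surrogate_backend",
    "bond_spring_matrix",
]


class BackendCapabilityError(RuntimeError):
    """The backend cannot provide what was asked of it."""


class ExternalEngineError(RuntimeError):
    """The external engine failed or produced unparseable output."""


@dataclasses.dataclass(frozen=True)
class BackendCapabilities:
    analytic_hessian: bool = False
    anchored: bool = False          # energy not invariant under rigid motions
    supported_elements: tuple[str, ...] | None = None


class ContinuumBackend(abc.ABC):
    capabilities: BackendCapabilities = BackendCapabilities()

    @abc.abstractmethod
    def energy_gradient(self, system: MolecularSystem, solvent: SolventSpec
                        ) -> tuple[float, np.ndarray]:
        """Energy in kJ/mol and gradient (N,3) in kJ mol^-1 Å^-1."""

    def energy(self, system, solvent) -> float:
        return self.energy_gradient(system, solvent)[0]

    def hessian(self, system: MolecularSystem, solvent: SolventSpec,
                step: float = 5e-3) -> np.ndarray:
        from .gbneck2 import numerical_hessian
        return numerical_hessian(
            lambda s: self.energy_gradient(s, solvent)[1], system, step)


# ---------------------------------------------------------------------------
# Harmonic well


def bond_spring_matrix(reference: np.ndarray, bonds: Sequence[tuple[int, int]],
                       k: float) -> np.ndarray:
    """Stiffness matrix of harmonic bond springs at the reference geometry.

    Each bond contributes k along the bond direction (the exact Hessian of
    1/2 k (r - r_ref)^2 at r = r_ref); the result is invariant under global
    translation and infinitesimal rotation.
    """
    x = np.asarray(reference, float).reshape(-1, 3)
    n3 = 3 * len(x)
    K = np.zeros((n3, n3))
    for i, j in bonds:
        d = x[i] - x[j]
        u = d / np.linalg.norm(d)
        P = k * np.outer(u, u)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        K[sl_i, sl_i] += P
        K[sl_j, sl_j] += P
        K[sl_i, sl_j] -= P
        K[sl_j, sl_i] -= P
    return K


class HarmonicWellBackend(ContinuumBackend):
    """E = E0 + 1/2 (x - x0)^T K (x - x0) with a constant analytic Hessian."""

    def __init__(self, x0: np.ndarray, k: float | None = None,
                 K: np.ndarray | None = None, e0: float = 0.0,
                 anchored: bool | None = None) -> None:
        self.x0 = np.asarray(x0, float).reshape(-1, 3)
        n3 = self.x0.size
        if K is None:
            if k is None:
                raise ValueError("provide a scalar stiffness k or a matrix K")
            K = k * np.eye(n3)
            anchored = True if anchored is None else anchored
        K = np.asarray(K, float)
        if K.shape != (n3, n3):
            raise ValueError(f"K must be {n3}x{n3}")
        self.K = 0.5 * (K + K.T)
        self.e0 = e0
        self.capabilities = BackendCapabilities(
            analytic_hessian=True,
            anchored=bool(anchored) if anchored is not None else False)

    def energy_gradient(self, system, solvent):
        d = (system.coordinates - self.x0).ravel()
        g = self.K @ d
        return self.e0 + 0.5 * float(d @ g), g.reshape(-1, 3)

    def hessian(self, system, solvent, step=5e-3):
        return self.K.copy()


# ---------------------------------------------------------------------------
# Generic pairwise backends (Morse, polarizable toy)


class PairwisePotentialBackend(ContinuumBackend):
    """Sum over atom pairs of a scalar potential phi(r; i, j, solvent).

    ``phi_fn(r, i, j, system, solvent)`` returns (value, dphi/dr, d2phi/dr2);
    gradient and Hessian are assembled analytically from those.
    """

    def __init__(self, phi_fn: Callable, pairs: Sequence[tuple[int, int]] | None
                 = None) -> None:
        self.phi_fn = phi_fn
        self.pairs = pairs
        self.capabilities = BackendCapabilities(analytic_hessian=True)

    def _iter_pairs(self, n: int):
        if self.pairs is not None:
            yield from self.pairs
        else:
            for i in range(n):
                for j in range(i + 1, n):
                    yield i, j

    def energy_gradient(self, system, solvent):
        x = system.coordinates
        e = 0.0
        g = np.zeros_like(x)
        for i, j in self._iter_pairs(system.n_atoms):
            d = x[i] - x[j]
            r = float(np.linalg.norm(d))
            v, dv, _ = self.phi_fn(r, i, j, system, solvent)
            e += v
            u = d / r
            g[i] += dv * u
            g[j] -= dv * u
        return e, g

    def hessian(self, system, solvent, step=5e-3):
        x = system.coordinates
        n3 = x.size
        H = np.zeros((n3, n3))
        I3 = np.eye(3)
        for i, j in self._iter_pairs(system.n_atoms):
            d = x[i] - x[j]
            r = float(np.linalg.norm(d))
            _, dv, d2v = self.phi_fn(r, i, j, system, solvent)
            u = np.outer(d, d) / (r * r)
            blk = d2v * u + (dv / r) * (I3 - u)
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            H[si, si] += blk
            H[sj, sj] += blk
            H[si, sj] -= blk
            H[sj, si] -= blk
        return H


def _morse_phi(D: float, a: float, r_e: float):
    def phi(r, i, j, system, solvent):
        e = np.exp(-a * (r - r_e))
        v = D * (1.0 - e) ** 2
        dv = 2.0 * D * a * e * (1.0 - e)
        d2v = 2.0 * D * a * a * e * (2.0 * e - 1.0)
        return v, dv, d2v
    return phi


def _polarizable_phi(soft: float, rep_a: float, rep_scale: float):
    def phi(r, i, j, system, solvent):
        qq = COULOMB_KJMOL_A * system.charges[i] * system.charges[j]
        epsf = 1.0 - 1.0 / solvent.epsilon
        den = np.sqrt(r * r + soft * soft)
        v = -epsf * qq / den + rep_scale * np.exp(-rep_a * r)
        dv = epsf * qq * r / den**3 - rep_a * rep_scale * np.exp(-rep_a * r)
        d2v = (epsf * qq * (1.0 / den**3 - 3.0 * r * r / den**5)
               + rep_a * rep_a * rep_scale * np.exp(-rep_a * r))
        return v, dv, d2v
    return phi


def surrogate_backend(kind: str, params: dict | None = None,
                      seed: int | None = None) -> ContinuumBackend:
    """Factory for the deterministic surrogate backends.

    kinds: ``harmonic-well`` (params: x0 [required], k or K or bonds+k, e0),
    ``pairwise-morse`` (params: D, a, r_e, pairs), ``polarizable-toy``
    (params: soft, rep_a, rep_scale, pairs).  ``seed`` randomizes the
    harmonic stiffness matrix if neither k nor K is given.
    """
    params = dict(params or {})
    if kind == "harmonic-well":
        x0 = np.asarray(params.pop("x0"), float).reshape(-1, 3)
        if "bonds" in params:
            K = bond_spring_matrix(x0, params.pop("bonds"), params.pop("k"))
            return HarmonicWellBackend(x0, K=K, anchored=False, **params)
        if "K" not in params and "k" not in params:
            if seed is None:
                raise ValueError("harmonic-well needs k, K, bonds, or a seed")
            rng = np.random.default_rng(seed)
            B = rng.normal(size=(x0.size, x0.size))
            params["K"] = B @ B.T / x0.size + 5.0 * np.eye(x0.size)
            params.setdefault("anchored", True)
        return HarmonicWellBackend(x0, **params)
    if kind == "pairwise-morse":
        phi = _morse_phi(params.get("D", 250.0), params.get("a", 1.5),
                         params.get("r_e", 1.3))
        return PairwisePotentialBackend(phi, pairs=params.get("pairs"))
    if kind == "polarizable-toy":
        phi = _polarizable_phi(params.get("soft", 1.0),
                               params.get("rep_a", 3.0),
                               params.get("rep_scale", 800.0))
        return PairwisePotentialBackend(phi, pairs=params.get("pairs"))
    raise ValueError(f"unknown surrogate backend kind {kind!r}")


# ---------------------------------------------------------------------------
# External engine adapter (seam only; fixture-tested)


class ExternalBackend(ContinuumBackend):
    """Adapter around an external engine invoked per evaluation.

    Contract: the command is run in ``workdir`` with arguments
    ``[input.xyz, solvent_keyword]``; it must write ``energy.txt`` (one
    number, eV) and ``gradient.txt`` (3N whitespace-separated numbers, eV/Å).
    """

    def __init__(self, command: str | Sequence[str], workdir: str | Path,
                 solvent_map: dict[str, str] | None = None) -> None:
        self.command = [command] if isinstance(command, str) else list(command)
        self.workdir = Path(workdir)
        self.solvent_map = solvent_map or {}
        if shutil.which(self.command[0]) is None and not Path(self.command[0]).exists():
            raise BackendCapabilityError(
                f"external engine {self.command[0]!r} not found; use a "
                f"surrogate backend (deltasolv.backends.surrogate_backend)")

    def energy_gradient(self, system, solvent):
        self.workdir.mkdir(parents=True, exist_ok=True)
        inp = self.workdir / "input.xyz"
        write_xyz([system], inp)
        keyword = self.solvent_map.get(solvent.name, solvent.name)
        proc = subprocess.run(self.command + [str(inp), keyword],
                              cwd=self.workdir, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalEngineError(
                f"engine exited with {proc.returncode}: {proc.stderr[-500:]}")
        return (self._parse_energy(self.workdir / "energy.txt"),
                self._parse_gradient(self.workdir / "gradient.txt",
                                     system.n_atoms))

    @staticmethod
    def _parse_energy(path: Path) -> float:
        try:
            return float(path.read_text().split()[0]) * EV_TO_KJMOL
        except (OSError, IndexError, ValueError) as exc:
            raise ExternalEngineError(f"cannot parse energy from {path}: {exc}")

    @staticmethod
    def _parse_gradient(path: Path, n_atoms: int) -> np.ndarray:
        try:
            vals = np.array([float(v) for v in path.read_text().split()])
        except (OSError, ValueError) as exc:
            raise ExternalEngineError(f"cannot parse gradient from {path}: {exc}")
        if vals.size != 3 * n_atoms:
            raise ExternalEngineError(
                f"{path}: expected {3 * n_atoms} gradient components, "
                f"got {vals.size}")
        return vals.reshape(-1, 3) * EV_TO_KJMOL
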