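"""Deterministic generators for test inputs.

Everything test-shaped is produced here from a seed: toy parameterized
molecules, conformer sets with controlled central dihedrals (and therefore
known gauche/trans ground-truth labels), and synthetic delta-force datasets
drawn from a known analytic solvent field so that model training can be
checked against an exact ground truth.

The analytic field is a sum of smooth Gaussian-bump pair terms whose
amplitude depends on atomic charges/radii and on the solvent permittivity
through (1 - 1/eps) — rich enough that a constant predictor fails, simple
enough for desk-scale training to recover it.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Sequence

import numpy as np

from .core import MolecularSystem, SolventSpec, load_parameters
from .ensemble import dihedral_angle

__all__ = [
    "make_toy_system",
    "ConformerSet",
    "make_conformer_set",
    "AnalyticSolventField",
    "make_delta_force_dataset",
    "set_dihedral",
    "checksum",
]


def checksum(array: np.ndarray, decimals: int = 8) -> str:
    """Stable short hash of an array, for pinning fixtures in tests."""
    return hashlib.sha256(
        np.ascontiguousarray(np.round(array, decimals)).tobytes()
    ).hexdigest()[:16]


def make_toy_system(template: str, seed: int = 0) -> MolecularSystem:
    """A parameterized toy molecule.

    Templates: ``diatomic`` (O-H, bond 1.0 Å), ``triatomic`` (water-like),
    ``chain-N`` (zigzag heavy-atom chain, bonds 1.5 ± 0.1 Å, seeded).
    All are charge-neutral.
    """
    rng = np.random.default_rng(seed)
    if template == "diatomic":
        elements = ["O", "H"]
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        charges = np.array([-0.4, 0.4])
    elif template == "triatomic":
        elements = ["O", "H", "H"]
        theta = np.deg2rad(104.5)
        coords = np.array([
            [0.0, 0.0, 0.0],
            [0.96, 0.0, 0.0],
            [0.96 * np.cos(theta), 0.96 * np.sin(theta), 0.0],
        ])
        charges = np.array([-0.8, 0.4, 0.4])
    elif template.startswith("chain-"):
        n = int(template.split("-", 1)[1])
        if n < 2:
            raise ValueError("chain needs at least 2 atoms")
        pool = ["C", "O", "C", "N"]
        elements = [pool[i % len(pool)] for i in range(n)]
        coords = np.zeros((n, 3))
        for i in range(1, n):
            bond = 1.5 + rng.uniform(-0.1, 0.1)
            zig = np.array([1.0, 0.45 * (-1) ** i, 0.25 * rng.uniform(-1, 1)])
            step = zig / np.linalg.norm(zig) * bond
            coords[i] = coords[i - 1] + step
        charges = rng.uniform(-0.5, 0.5, size=n)
        charges -= charges.mean()
    else:
        raise ValueError(f"unknown template {template!r}")
    system = MolecularSystem(elements, coords)
    return load_parameters(system, charges=charges, formal_charge=0.0)


def set_dihedral(system: MolecularSystem, dihedral: tuple[int, int, int, int],
                 target: float) -> MolecularSystem:
    """Rotate all atoms with index > k about the j-k bond to the target
    dihedral (chain-ordered systems)."""
    i, j, k, l = dihedral
    x = system.coordinates.copy()
    phi = dihedral_angle(x, i, j, k, l)
    axis = x[k] - x[j]
    axis /= np.linalg.norm(axis)
    delta = target - phi
    c, s = np.cos(delta), np.sin(delta)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    tail = np.arange(len(x)) > k
    x[tail] = (x[tail] - x[k]) @ R.T + x[k]
    return system.with_coordinates(x)


@dataclasses.dataclass
class ConformerSet:
    systems: list[MolecularSystem]
    labels: list[str]                  # ground-truth gauche/trans labels
    dihedral: tuple[int, int, int, int]
    targets: np.ndarray                # the dihedral values that were set


def make_conformer_set(system: MolecularSystem,
                       dihedral: tuple[int, int, int, int],
                       n: int, seed: int = 0,
                       window: float = 2.1,
                       n_duplicates: int = 0) -> ConformerSet:
    """Conformers covering both rotamer states, with known labels.

    Half the targets fall well inside the gauche window, half well outside
    (trans); optional exact duplicates are appended for pruning tests.
    """
    if max(dihedral) >= system.n_atoms:
        raise ValueError("dihedral indices out of range")
    rng = np.random.default_rng(seed)
    targets = []
    for m in range(n):
        if m % 2 == 0:
            targets.append(rng.uniform(-0.6 * window, 0.6 * window))
        else:
            sign = 1 if rng.random() < 0.5 else -1
            targets.append(sign * rng.uniform(
                window + 0.3 * (np.pi - window), np.pi - 1e-3))
    targets = np.array(targets)
    systems = [set_dihedral(system, dihedral, t) for t in targets]
    labels = ["gauche" if -window < t < window else "trans" for t in targets]
    for d in range(n_duplicates):
        src = int(rng.integers(0, n))
        systems.append(systems[src].copy())
        labels.append(labels[src])
        targets = np.append(targets, targets[src])
    return ConformerSet(systems=systems, labels=labels, dihedral=dihedral,
                        targets=targets)


# ---------------------------------------------------------------------------
# Analytic solvent field + dataset generator


@dataclasses.dataclass
class AnalyticSolventField:
    """Smooth pairwise 'solvent-mean-force' field with known closed form.

    E = (1 - 1/eps) * sum_{i<j} (c_qq q_i q_j + c_rr rho_i rho_j + c_const)
        * exp(-(r_ij - r0)^2 / (2 w^2))
    """

    c_qq: float = 50.0
    c_rr: float = 5.0
    c_const: float = 10.0
    r0: float = 2.5       # Å
    w: float = 0.8        # Å

    def energy_forces(self, system: MolecularSystem, solvent: SolventSpec
                      ) -> tuple[float, np.ndarray]:
        x = system.coordinates
        q, rho = system.charges, system.radii
        epsf = 1.0 - 1.0 / solvent.epsilon
        e = 0.0
        f = np.zeros_like(x)
        for i in range(system.n_atoms):
            for j in range(i + 1, system.n_atoms):
                d = x[i] - x[j]
                r = float(np.linalg.norm(d))
                amp = (self.c_qq * q[i] * q[j] + self.c_rr * rho[i] * rho[j]
                       + self.c_const)
                phi = np.exp(-0.5 * ((r - self.r0) / self.w) ** 2)
                e += epsf * amp * phi
                dv = -epsf * amp * phi * (r - self.r0) / self.w**2
                u = d / r
                f[i] -= dv * u
                f[j] += dv * u
        return e, f


def make_delta_force_dataset(field: AnalyticSolventField,
                             systems: Sequence[MolecularSystem],
                             solvents: Sequence[SolventSpec],
                             n_frames: int,
                             noise_sigma: float = 0.0,
                             seed: int = 0,
                             jitter: float = 0.35,
                             ) -> list[tuple[MolecularSystem, SolventSpec,
                                             np.ndarray]]:
    """Frames of (perturbed system, solvent, target forces + noise).

    Targets are the analytic field's forces plus iid Gaussian noise of the
    requested standard deviation; with ``noise_sigma=0`` the targets equal
    the field exactly, enabling parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    dataset = []
    for m in range(n_frames):
        base = systems[m % len(systems)]
        solvent = solvents[m % len(solvents)]
        x = base.coordinates + rng.normal(scale=jitter,
                                          size=base.coordinates.shape)
        frame = base.with_coordinates(x)
        _, forces = field.energy_forces(frame, solvent)
        if noise_sigma > 0:
            forces = forces + rng.normal(scale=noise_sigma, size=forces.shape)
        dataset.append((frame, solvent, forces))
    return dataset
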