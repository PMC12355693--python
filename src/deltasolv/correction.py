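"""The learned solvent model and the delta correction.

The delta correction is defined as the difference between a learned
explicit-solvent force model and the analytic GB continuum model evaluated
on the same geometry:

    dE_corr = E_model - E_GB,        F_corr = F_model - F_GB.

Everything downstream (the combined potential, free energies) consumes only
this difference, so the learned model is exposed behind a small contract,
:class:`SolventForceModel`, with three implementations:

* :class:`CallableSolventModel` — deterministic mock for wiring tests (in
  particular ``CallableSolventModel.from_gb`` reproduces the GB model
  exactly, making the correction vanish identically);
* :class:`ReferenceGraphModel` — a small trainable graph model: per-atom
  descriptors built from smooth radial-basis message sums over neighbours
  (weighted by charge / radius source channels), expanded through a fixed,
  seeded random tanh layer, with a trainable linear readout.  Energies are
  strictly invariant and forces strictly covariant under rigid motions
  because all descriptors depend on interatomic distances only.  Position
  gradients are analytic; because the readout is linear, force-matching
  training is a linear least-squares problem solved by conjugate-gradient
  iterations (one iteration per reported epoch).
"""

from __future__ import annotations

import abc
import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import MolecularSystem, SolventSpec
from .gbneck2 import GBNeck2Model, numerical_hessian

__all__ = [
    "SolventForceModel",
    "CallableSolventModel",
    "ReferenceGraphModel",
    "ReferenceModelConfig",
    "CorrectionField",
    "DeltaCorrection",
    "UnsupportedSolventError",
    "TrainingDiverged",
    "TrainingResult",
    "build_reference_gnn",
    "train_on_delta_forces",
]


class UnsupportedSolventError(ValueError):
    """The model was not built/trained for the requested solvent."""


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, last_state: np.ndarray):
        super().__init__(message)
        self.last_state = last_state


# ---------------------------------------------------------------------------
# Contract


class SolventForceModel(abc.ABC):
    """Anything that predicts a solvent free-energy contribution and forces."""

    #: solvent names the model supports; None means "any"
    supported_solvents: tuple[str, ...] | None = None

    def supports(self, solvent: SolventSpec) -> bool:
        return (self.supported_solvents is None
                or solvent.name in self.supported_solvents)

    def _require(self, solvent: SolventSpec) -> None:
        if not self.supports(solvent):
            raise UnsupportedSolventError(
                f"model does not support solvent {solvent.name!r}; "
                f"supported: {sorted(self.supported_solvents or [])}")

    @abc.abstractmethod
    def energy_forces(self, system: MolecularSystem, solvent: SolventSpec
                      ) -> tuple[float, np.ndarray]:
        """Energy (kJ/mol) and per-atom forces (kJ mol^-1 Å^-1, = -gradient)."""

    def energy(self, system, solvent) -> float:
        return self.energy_forces(system, solvent)[0]

    def forces(self, system, solvent) -> np.ndarray:
        return self.energy_forces(system, solvent)[1]

    def hessian(self, system: MolecularSystem, solvent: SolventSpec,
                step: float = 5e-3) -> np.ndarray:
        """d2E/dx2 by central differences of -forces."""
        return numerical_hessian(
            lambda s: -self.energy_forces(s, solvent)[1], system, step)


class CallableSolventModel(SolventForceModel):
    """Deterministic mock: delegates to a user-supplied callable."""

    def __init__(self,
                 energy_forces_fn: Callable[[MolecularSystem, SolventSpec],
                                            tuple[float, np.ndarray]],
                 supported_solvents: Sequence[str] | None = None) -> None:
        self._fn = energy_forces_fn
        self.supported_solvents = (tuple(supported_solvents)
                                   if supported_solvents is not None else None)

    def energy_forces(self, system, solvent):
        self._require(solvent)
        e, f = self._fn(system, solvent)
        return float(e), np.asarray(f, dtype=float).reshape(-1, 3)

    @classmethod
    def from_gb(cls, gb: GBNeck2Model) -> "CallableSolventModel":
        """Mock wired to reproduce the GB model (zero correction by design)."""
        return cls(lambda s, _solv: (lambda e, g: (e, -g))(*gb.energy_gradient(s)))


# ---------------------------------------------------------------------------
# Reference graph model


@dataclasses.dataclass
class ReferenceModelConfig:
    n_radial: int = 16            # radial basis functions per source channel
    r_min: float = 0.8            # Å, first basis centre
    cutoff: float = 8.0           # Å, smooth cosine cutoff
    n_hidden: int = 64            # fixed random tanh units
    solvents: tuple[str, ...] = ()  # supported solvent labels (one-hot)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_radial < 2 or self.n_hidden < 1:
            raise ValueError("invalid architecture sizes")
        self.solvents = tuple(self.solvents)


class ReferenceGraphModel(SolventForceModel):
    """Small equivariant graph model with a trainable linear readout.

    Descriptors for atom i: message sums s_{i,a,k} = sum_j a_j g_k(r_ij)
    over source channels a in {1, q_j, rho_j} and radial bases g_k; readout
    basis = skip products {1, q_i, rho_i} x s_{i,a,k} x {1, 1-1/eps} plus a
    fixed random tanh layer over [s_i, q_i, rho_i, 1-1/eps, one-hot solvent].
    The energy is linear in the trainable coefficient vector ``coef``.
    """

    def __init__(self, config: ReferenceModelConfig) -> None:
        self.config = config
        K = config.n_radial
        self.centers = np.linspace(config.r_min, config.cutoff - 0.5, K)
        self.gamma = self.centers[1] - self.centers[0]
        rng = np.random.default_rng(config.seed)
        d_in = 3 * K + 3 + len(config.solvents)
        self.W = rng.normal(scale=1.0 / np.sqrt(d_in),
                            size=(config.n_hidden, d_in))
        self.b = rng.normal(scale=0.1, size=config.n_hidden)
        self.n_skip = 9 * K * 2
        self.n_params = self.n_skip + config.n_hidden
        self.coef = np.zeros(self.n_params)
        self.supported_solvents = config.solvents or None
        self.provenance: dict = {"trained": False}

    # -- descriptor machinery ----------------------------------------------

    def _radial(self, r):
        """g_k(r) and g_k'(r); complex-safe."""
        fc = 0.5 * (np.cos(np.pi * r / self.config.cutoff) + 1.0)
        dfc = -0.5 * np.pi / self.config.cutoff * np.sin(
            np.pi * r / self.config.cutoff)
        inside = (np.real(r) < self.config.cutoff)
        fc = np.where(inside, fc, 0.0)
        dfc = np.where(inside, dfc, 0.0)
        x = (r[..., None] - self.centers) / self.gamma
        g = np.exp(-0.5 * x * x)
        dg = g * (-x / self.gamma)
        val = g * fc[..., None]
        dval = dg * fc[..., None] + g * dfc[..., None]
        return val, dval

    def _solvent_feats(self, solvent: SolventSpec) -> tuple[float, np.ndarray]:
        epsf = 1.0 - 1.0 / solvent.epsilon
        onehot = np.zeros(len(self.config.solvents))
        if self.config.solvents:
            onehot[self.config.solvents.index(solvent.name)] = 1.0
        return epsf, onehot

    def _basis(self, coords, q, rho, solvent):
        """Per-structure readout basis phi (P,) and its position gradient
        dphi (N,3,P).  ``coords`` may be complex (gradient then unused)."""
        n = len(q)
        K = self.config.n_radial
        diff = coords[:, None, :] - coords[None, :, :]
        r2 = (diff * diff).sum(-1)
        np.fill_diagonal(r2, 1.0)
        r = np.sqrt(r2)
        g, dg = self._radial(r)                    # (N,N,K)
        eye = np.eye(n, dtype=bool)
        g = np.where(eye[..., None], 0.0, g)
        dg = np.where(eye[..., None], 0.0, dg)
        chan = np.stack([np.ones(n), q, rho])      # (3,N) source channels
        # s[i, a, k] = sum_j chan[a, j] g[i, j, k]
        s = np.einsum("aj,ijk->iak", chan, g)
        epsf, onehot = self._solvent_feats(solvent)
        mult = np.stack([np.ones(n), q, rho])      # (3,N) centre channels
        skip = np.einsum("mi,iak->imak", mult, s).reshape(n, 9 * K)
        skip = np.concatenate([skip, epsf * skip], axis=1)       # (N, 18K)
        u = np.concatenate([
            s.reshape(n, 3 * K),
            np.stack([q, rho, np.full(n, epsf)], axis=1),
            np.tile(onehot, (n, 1)),
        ], axis=1)
        h = np.tanh(u @ self.W.T + self.b)                       # (N, H)
        phi_atom = np.concatenate([skip, h], axis=1)             # (N, P)
        phi = phi_atom.sum(axis=0)

        if np.iscomplexobj(coords):
            return phi, None
        # position gradients; t[i,j,a,k] = chan[a,j] dg[i,j,k] is the pair
        # derivative of s[i,a,k] wrt r_ij
        rhat = diff / r[..., None]
        rhat = np.where(eye[..., None], 0.0, rhat)
        t = np.einsum("aj,ijk->ijak", chan, dg)
        P = self.n_params
        dphi = np.zeros((n, 3, P))
        W_s = self.W[:, :3 * K]                    # hidden weights on s block
        sech2 = 1.0 - h * h                        # (N, H)
        for i in range(n):
            # d s[i,a,k]/dx_i = sum_j t[i,j,a,k] rhat[i,j,c]
            dsi = np.einsum("jak,jc->cak", t[i], rhat[i])        # (3,3a,K)
            contrib = {i: dsi}
            for j in range(n):
                if j == i:
                    continue
                contrib[j] = -t[i, j][None, :, :] * rhat[i, j][:, None, None]
            m_i = mult[:, i]                       # (3,) centre factors
            for nn, d_s in contrib.items():
                flat = d_s.reshape(3, 3 * K)       # (3, 3K) per coordinate
                dskip = np.einsum("m,ck->cmk", m_i, flat).reshape(3, 9 * K)
                dskip_full = np.concatenate([dskip, epsf * dskip], axis=1)
                dh = (flat @ W_s.T) * sech2[i]     # (3, H)
                dphi[nn, :, :self.n_skip] += dskip_full
                dphi[nn, :, self.n_skip:] += dh
        return phi, dphi

    # -- contract -----------------------------------------------------------

    def energy_forces(self, system: MolecularSystem, solvent: SolventSpec
                      ) -> tuple[float, np.ndarray]:
        self._require(solvent)
        if not system.is_parameterized():
            raise ValueError("system must be parameterized")
        phi, dphi = self._basis(system.coordinates, system.charges,
                                system.radii, solvent)
        energy = float(phi @ self.coef)
        forces = -(dphi @ self.coef)
        return energy, forces

    def design_row(self, system: MolecularSystem, solvent: SolventSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
        """(phi, force design matrix) with forces = -design @ coef."""
        phi, dphi = self._basis(system.coordinates, system.charges,
                                system.radii, solvent)
        return phi, dphi.reshape(-1, self.n_params)

    def energy_complex(self, coords, system: MolecularSystem,
                       solvent: SolventSpec):
        """Energy at (possibly complex) coordinates; complex-step oracle."""
        phi, _ = self._basis(np.asarray(coords).reshape(-1, 3),
                             system.charges, system.radii, solvent)
        return phi @ self.coef

    # -- serialization -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        blob = {
            "config": dataclasses.asdict(self.config) | {
                "solvents": list(self.config.solvents)},
            "coef": self.coef.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceGraphModel":
        blob = json.loads(Path(path).read_text())
        cfg = ReferenceModelConfig(**blob["config"])
        model = cls(cfg)
        model.coef = np.asarray(blob["coef"], dtype=float)
        model.provenance = blob.get("provenance", {})
        return model


def build_reference_gnn(config: ReferenceModelConfig | None = None,
                        **kwargs) -> ReferenceGraphModel:
    """Construct the seeded reference graph model (bit-reproducible)."""
    if config is None:
        config = ReferenceModelConfig(**kwargs)
    return ReferenceGraphModel(config)


# ---------------------------------------------------------------------------
# Training: force matching as conjugate-gradient least squares


@dataclasses.dataclass
class TrainingResult:
    model: ReferenceGraphModel
    loss_trace: list[float]               # train force RMSE per epoch
    rmse_train: float
    rmse_val: float
    rmse_test: float
    target_rms: float


def train_on_delta_forces(model: ReferenceGraphModel,
                          dataset: Sequence[tuple[MolecularSystem, SolventSpec,
                                                  np.ndarray]],
                          epochs: int = 400,
                          seed: int = 0,
                          ridge: float = 1e-9,
                          split: tuple[float, float, float] = (0.8, 0.1, 0.1),
                          ) -> TrainingResult:
    """Fit the readout coefficients to target forces.

    Each epoch performs one conjugate-gradient iteration on the (ridge-
    regularized) normal equations of the force-matching least-squares
    problem, so the recorded training loss is non-increasing and converges
    to the global optimum of the linear model.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    perm = rng.permutation(n)
    n_train = max(1, int(round(split[0] * n)))
    n_val = int(round(split[1] * n))
    idx_train = perm[:n_train]
    idx_val = perm[n_train:n_train + n_val]
    idx_test = perm[n_train + n_val:]

    def stack(idx):
        A_rows, y_rows = [], []
        for k in idx:
            system, solvent, f_target = dataset[k]
            _, D = model.design_row(system, solvent)
            A_rows.append(-D)            # forces = -D @ coef
            y_rows.append(np.asarray(f_target, dtype=float).ravel())
        return np.vstack(A_rows), np.concatenate(y_rows)

    A, y = stack(idx_train)
    target_rms = float(np.sqrt(np.mean(y**2)))
    # column scaling for conditioning
    col = np.sqrt((A * A).mean(axis=0))
    col[col < 1e-12] = 1.0
    As = A / col
    AtA = As.T @ As + ridge * np.eye(As.shape[1])
    Atb = As.T @ y

    c = np.zeros(As.shape[1])
    r = Atb - AtA @ c
    p = r.copy()
    rs = float(r @ r)
    trace: list[float] = []
    for _ in range(epochs):
        Ap = AtA @ p
        denom = float(p @ Ap)
        if denom <= 0 or not np.isfinite(denom):
            break
        alpha = rs / denom
        c = c + alpha * p
        if not np.all(np.isfinite(c)):
            raise TrainingDiverged("training produced non-finite parameters",
                                   last_state=c - alpha * p)
        r = r - alpha * Ap
        rs_new = float(r @ r)
        trace.append(float(np.sqrt(np.mean((As @ c - y) ** 2))))
        if rs_new < 1e-28:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    model.coef = c / col
    model.provenance = {"trained": True, "n_train": int(n_train),
                        "epochs": len(trace), "seed": int(seed)}

    def rmse(idx) -> float:
        if len(idx) == 0:
            return float("nan")
        Ah, yh = stack(idx)
        return float(np.sqrt(np.mean((Ah @ model.coef - yh) ** 2)))

    return TrainingResult(model=model, loss_trace=trace,
                          rmse_train=rmse(idx_train), rmse_val=rmse(idx_val),
                          rmse_test=rmse(idx_test), target_rms=target_rms)


# ---------------------------------------------------------------------------
# The delta correction


@dataclasses.dataclass
class CorrectionField:
    energy_corr: float                    # kJ/mol
    forces_corr: np.ndarray               # (N,3) kJ mol^-1 Å^-1
    hessian_corr: np.ndarray | None = None  # (3N,3N) kJ mol^-1 Å^-2


class DeltaCorrection:
    """The correction term: learned model minus GB continuum model."""

    def __init__(self, model: SolventForceModel, gb: GBNeck2Model,
                 hessian_step: float = 5e-3) -> None:
        self.model = model
        self.gb = gb
        self.hessian_step = hessian_step

    def energy_forces(self, system: MolecularSystem, solvent: SolventSpec
                      ) -> tuple[float, np.ndarray]:
        if not self.model.supports(solvent):
            raise UnsupportedSolventError(
                f"model does not support solvent {solvent.name!r}; supported: "
                f"{sorted(self.model.supported_solvents or [])}")
        e_m, f_m = self.model.energy_forces(system, solvent)
        e_g, g_g = self.gb.energy_gradient(system)
        return e_m - e_g, f_m - (-g_g)

    def evaluate(self, system: MolecularSystem, solvent: SolventSpec,
                 with_hessian: bool = False) -> CorrectionField:
        e, f = self.energy_forces(system, solvent)
        hess = None
        if with_hessian:
            hess = numerical_hessian(
                lambda s: -self.energy_forces(s, solvent)[1],
                system, self.hessian_step)
        return CorrectionField(energy_corr=e, forces_corr=f, hessian_corr=hess)


def correction(system: MolecularSystem, solvent: SolventSpec,
               model: SolventForceModel, gb: GBNeck2Model,
               with_hessian: bool = False) -> CorrectionField:
    """Convenience wrapper: the delta correction at one geometry."""
    return DeltaCorrection(model, gb).evaluate(system, solvent, with_hessian)
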