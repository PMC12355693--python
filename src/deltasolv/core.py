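"""Core domain types and geometry I/O.

:class:`MolecularSystem` is the container every other module operates on:
element symbols, Cartesian coordinates in Å, and the per-atom monopole
parameters (partial charge, intrinsic Born/van der Waals radius, descreening
scale factor) that the generalized-Born model and the learned solvent model
share.  :class:`SolventSpec` names a solvent and carries its relative
dielectric permittivity.

XYZ reading/writing is implemented here directly: the (multi-frame) XYZ
format is line-oriented and the parser must report malformed input with line
numbers, which generic trajectory readers do not do.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from rdkit import Chem

__all__ = [
    "MolecularSystem",
    "SolventSpec",
    "ParameterSet",
    "XYZParseError",
    "ParameterizationError",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "load_parameters",
    "default_parameter_set",
    "atomic_mass",
    "validate_element",
]

_PT = Chem.GetPeriodicTable()


class XYZParseError(ValueError):
    """Malformed XYZ input; the message names the offending line."""


class ParameterizationError(KeyError):
    """An element has no entry in the parameter table."""


def validate_element(symbol: str) -> str:
    """Return the canonical element symbol or raise ``ValueError``."""
    sym = symbol.strip().capitalize()
    try:
        z = _PT.GetAtomicNumber(sym)
    except Exception:
        z = 0
    if z == 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return sym


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in u."""
    return _PT.GetAtomicWeight(validate_element(symbol))


@dataclasses.dataclass
class MolecularSystem:
    """A molecule: geometry plus per-atom monopole parameters.

    coordinates are Å, charges e, radii Å, masses u; ``screen`` is the
    dimensionless descreening scale factor of the HCT/neck family of GB
    models.  Parameter arrays may be None until :func:`load_parameters`
    fills them.
    """

    elements: list[str]
    coordinates: np.ndarray
    charges: np.ndarray | None = None
    radii: np.ndarray | None = None
    screen: np.ndarray | None = None
    masses: np.ndarray | None = None
    formal_charge: float = 0.0
    comment: str = ""

    def __post_init__(self) -> None:
        self.elements = [validate_element(e) for e in self.elements]
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if n < 1:
            raise ValueError("a MolecularSystem needs at least one atom")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n} elements"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.masses is None:
            self.masses = np.array([atomic_mass(e) for e in self.elements])
        for name in ("charges", "radii", "screen", "masses"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"{name} must have shape ({n},)")
                setattr(self, name, arr)
        if self.radii is not None and np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def is_parameterized(self) -> bool:
        return all(x is not None for x in (self.charges, self.radii, self.screen))

    def with_coordinates(self, coords: np.ndarray) -> "MolecularSystem":
        """Copy of this system at new coordinates (parameters shared)."""
        return dataclasses.replace(
            self, coordinates=np.array(coords, dtype=float).reshape(-1, 3)
        )

    def copy(self) -> "MolecularSystem":
        out = dataclasses.replace(self, coordinates=self.coordinates.copy())
        for name in ("charges", "radii", "screen", "masses"):
            arr = getattr(out, name)
            if arr is not None:
                setattr(out, name, arr.copy())
        return out


@dataclasses.dataclass(frozen=True)
class SolventSpec:
    """A solvent label with its relative dielectric permittivity."""

    name: str
    epsilon: float

    def __post_init__(self) -> None:
        if not self.epsilon > 1.0:
            raise ValueError(f"epsilon must exceed 1, got {self.epsilon}")


# a few common solvents for convenience; users pass any SolventSpec
SOLVENTS: dict[str, SolventSpec] = {
    name: SolventSpec(name, eps)
    for name, eps in {
        "water": 78.5,
        "chloroform": 4.81,
        "dmso": 46.7,
        "methanol": 32.7,
        "acetonitrile": 37.5,
        "toluene": 2.38,
    }.items()
}


# ---------------------------------------------------------------------------
# XYZ I/O


def read_xyz(path: str | Path) -> list[MolecularSystem]:
    """Read a (multi-frame) XYZ file.

    Returns one :class:`MolecularSystem` per frame, parameters unset.
    Raises :class:`XYZParseError` naming the line number on malformed input.
    """
    lines = Path(path).read_text().splitlines()
    systems: list[MolecularSystem] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise XYZParseError(
                f"{path}: line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if natoms < 1:
            raise XYZParseError(
                f"{path}: line {i + 1}: atom count must be positive"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        elements: list[str] = []
        coords: list[list[float]] = []
        for k in range(natoms):
            lineno = i + 2 + k
            if lineno >= len(lines):
                raise XYZParseError(f"{path}: line {lineno + 1}: truncated frame")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}: line {lineno + 1}: expected 'El x y z', "
                    f"got {lines[lineno]!r}"
                )
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"{path}: line {lineno + 1}: non-numeric coordinate in "
                    f"{lines[lineno]!r}"
                ) from None
            elements.append(parts[0])
            coords.append(xyz)
        systems.append(
            MolecularSystem(elements=elements, coordinates=np.array(coords),
                            comment=comment)
        )
        i += 2 + natoms
    return systems


def write_xyz(
    systems: Sequence[MolecularSystem] | MolecularSystem,
    path: str | Path,
    comments: Iterable[str] | None = None,
) -> None:
    """Write one or more systems as a multi-frame XYZ file."""
    if isinstance(systems, MolecularSystem):
        systems = [systems]
    if not systems:
        raise ValueError("nothing to write")
    if comments is None:
        comments = [s.comment for s in systems]
    out = []
    for sys_, comment in zip(systems, comments):
        out.append(str(sys_.n_atoms))
        out.append(comment.replace("\n", " "))
        for el, (x, y, z) in zip(sys_.elements, sys_.coordinates):
            out.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_sdf(path: str | Path) -> list[MolecularSystem]:
    """Read an SDF file (one system per molecule) via rdkit.

    Formal charges are taken from the molecule block; other parameters stay
    unset.  Molecules rdkit cannot parse are skipped with a warning.
    """
    import warnings

    systems: list[MolecularSystem] = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False):
        if mol is None or mol.GetNumConformers() == 0:
            warnings.warn(f"{path}: skipping unparseable SDF entry")
            continue
        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        systems.append(MolecularSystem(
            elements, coords,
            formal_charge=float(sum(a.GetFormalCharge()
                                    for a in mol.GetAtoms())),
            comment=mol.GetProp("_Name") if mol.HasProp("_Name") else ""))
    return systems


# ---------------------------------------------------------------------------
# Parameter loading


@dataclasses.dataclass
class ParameterSet:
    """Element-keyed GB parameters plus optional per-atom charge overrides.

    ``elements`` maps a symbol to a dict with at least ``radius`` (Å) and
    ``screen``; GB-model coefficients (alpha/beta/gamma) ride along in the
    same entries and are consumed by the GB module.  ``charges`` maps an
    atom index to a partial charge in e.
    """

    elements: dict[str, dict[str, float]]
    charges: dict[int, float] = dataclasses.field(default_factory=dict)
    formal_charge: float | None = None
    offset: float = 0.195141
    neck_scale: float = 0.826836

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            elements={validate_element(k): dict(v) for k, v in raw["elements"].items()},
            charges={int(k): float(v) for k, v in raw.get("charges", {}).items()},
            formal_charge=raw.get("formal_charge"),
            offset=float(raw.get("offset", 0.195141)),
            neck_scale=float(raw.get("neck_scale", 0.826836)),
        )


def default_parameter_set() -> ParameterSet:
    """The parameter table shipped with the package (H, C, N, O, S, halogens)."""
    ref = importlib.resources.files("deltasolv") / "data" / "gbneck2_params.yaml"
    with importlib.resources.as_file(ref) as path:
        return ParameterSet.from_file(path)


def load_parameters(
    system: MolecularSystem,
    source: ParameterSet | str | Path | None = None,
    charges: Mapping[int, float] | np.ndarray | None = None,
    formal_charge: float | None = None,
) -> MolecularSystem:
    """Populate charges, radii and screen factors from a parameter table.

    Radii and screen factors are looked up per element; charges come from
    (in order of precedence) the ``charges`` argument, the table's per-index
    charge section, or default to zero.  The summed charge must match the
    declared formal charge to 1e-6 e.
    """
    if source is None:
        source = default_parameter_set()
    elif not isinstance(source, ParameterSet):
        source = ParameterSet.from_file(source)
    missing = sorted({e for e in system.elements if e not in source.elements})
    if missing:
        raise ParameterizationError(
            f"no parameters for element(s): {', '.join(missing)}"
        )
    n = system.n_atoms
    radii = np.array([source.elements[e]["radius"] for e in system.elements])
    screen = np.array([source.elements[e]["screen"] for e in system.elements])
    q = np.zeros(n)
    for idx, val in source.charges.items():
        if not 0 <= idx < n:
            raise ParameterizationError(f"charge index {idx} out of range")
        q[idx] = val
    if charges is not None:
        if isinstance(charges, Mapping):
            for idx, val in charges.items():
                q[int(idx)] = float(val)
        else:
            q = np.asarray(charges, dtype=float)
            if q.shape != (n,):
                raise ValueError(f"charges must have shape ({n},)")
    if formal_charge is None:
        formal_charge = (
            source.formal_charge if source.formal_charge is not None
            else system.formal_charge
        )
    total = float(q.sum())
    if abs(total - formal_charge) > 1e-6:
        raise ParameterizationError(
            f"total charge {total:.6f} does not match declared formal charge "
            f"{formal_charge:.6f}"
        )
    out = system.copy()
    out.charges, out.radii, out.screen = q, radii, screen
    out.formal_charge = formal_charge
    return out
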