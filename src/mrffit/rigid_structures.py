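"""Atomic subunits, rigid transforms, and orientation-space sampling.

Conventions fixed once for the whole package:

* quaternions are scalar-first ``(w, x, y, z)``, unit norm, right-handed,
  and act as *active* rotations: ``x -> R(q) x + t``;
* a subunit's "center" is the unweighted centroid of its C-alpha atoms;
* hydrogens are dropped on reading, altloc conflicts keep the
  highest-occupancy conformer.

The default orientation sampling set contains exactly 7,416 near-uniform
rotations, generated deterministically with the super-Fibonacci spiral
construction on the unit quaternion sphere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Subunit",
    "RigidTransform",
    "RotationSet",
    "read_structure",
    "write_structure",
    "apply_transform",
    "random_transform",
    "rotation_set",
    "centroid",
    "quat_to_matrix",
    "rotation_angle_deg",
    "DEFAULT_ROTATION_COUNT",
]

DEFAULT_ROTATION_COUNT = 7416


@dataclass
class Subunit:
    """One rigid protein chain: parallel per-atom arrays plus Cα bookkeeping."""

    id: str
    atom_names: list
    elements: list
    res_names: list
    res_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.calpha) < 1:
            raise ValueError(f"subunit {self.id!r} has no C-alpha atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def calpha(self) -> np.ndarray:
        """Ordered Cα coordinates, one per residue."""
        idx = [i for i, n in enumerate(self.atom_names) if n == "CA"]
        return self.coords[idx]

    @property
    def residue_count(self) -> int:
        return len({int(r) for r in self.res_ids})

    @property
    def sequence(self) -> tuple:
        """Residue names in residue order (identity key for chain permutations)."""
        seen = {}
        for rid, rname in zip(self.res_ids, self.res_names):
            seen.setdefault(int(rid), rname)
        return tuple(seen[k] for k in sorted(seen))

    def with_coords(self, coords: np.ndarray) -> "Subunit":
        return Subunit(self.id, self.atom_names, self.elements,
                       self.res_names, self.res_ids, coords)


@dataclass
class RigidTransform:
    """Rigid motion x -> R(q) x + t with unit quaternion q = (w, x, y, z)."""

    q: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).reshape(4)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        n = np.linalg.norm(self.q)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {n:g} is not 1")
        self.q = self.q / n

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.array([1.0, 0, 0, 0]), np.zeros(3))

    @classmethod
    def from_matrix(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        q = Rotation.from_matrix(R).as_quat(scalar_first=True)
        return cls(q, t)

    def matrix(self) -> np.ndarray:
        return quat_to_matrix(self.q)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.matrix().T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        R1, R2 = self.matrix(), other.matrix()
        return RigidTransform.from_matrix(R1 @ R2, R1 @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        R = self.matrix()
        return RigidTransform.from_matrix(R.T, -R.T @ self.t)

    def to_json(self) -> str:
        return json.dumps({"q": list(self.q), "t": list(self.t)})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(np.asarray(d["q"]), np.asarray(d["t"]))


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a scalar-first unit quaternion."""
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True).as_matrix()


def rotation_angle_deg(q1: np.ndarray, q2: np.ndarray | None = None) -> float:
    """Geodesic rotation angle (degrees, in [0, 180]) between two rotations.

    With a single argument, the angle of that rotation from the identity.
    """
    q1 = np.asarray(q1, dtype=float)
    if q2 is None:
        dot = abs(q1[0]) / np.linalg.norm(q1)
    else:
        q2 = np.asarray(q2, dtype=float)
        dot = abs(float(q1 @ q2)) / (np.linalg.norm(q1) * np.linalg.norm(q2))
    return float(np.degrees(2.0 * np.arccos(np.clip(dot, -1.0, 1.0))))


@dataclass
class RotationSet:
    """A near-uniform sample of SO(3) stored as unit quaternions (w first)."""

    quaternions: np.ndarray
    coverage_deg: float

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        norms = np.linalg.norm(self.quaternions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("rotation set quaternions must be unit norm")

    def __len__(self) -> int:
        return len(self.quaternions)

    def __iter__(self):
        return iter(self.quaternions)

    def with_extra(self, quats) -> "RotationSet":
        """Append extra rotations (e.g. planted ground-truth orientations)."""
        extra = np.atleast_2d(np.asarray(quats, dtype=float))
        return RotationSet(np.vstack([self.quaternions, extra]), self.coverage_deg)


# super-Fibonacci spiral constants: phi = sqrt(2), psi is the real root of
# psi^4 = psi + 4 (Alexa's low-discrepancy double-spiral on S^3)
_SF_PHI = np.sqrt(2.0)
_SF_PSI = 1.533751168755204288118041


def _super_fibonacci(n: int) -> np.ndarray:
    s = np.arange(n) + 0.5
    t = s / n
    d = 2.0 * np.pi * s
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    alpha = d / _SF_PHI
    beta = d / _SF_PSI
    q = np.stack(
        [r * np.sin(alpha), r * np.cos(alpha), big_r * np.sin(beta), big_r * np.cos(beta)],
        axis=1,
    )
    # canonical sign: first nonzero component positive, so q and -q collapse
    flip = q[:, 0] < 0
    q[flip] *= -1.0
    return q


def _estimate_coverage_deg(quats: np.ndarray, n_probe: int = 2000) -> float:
    rng = np.random.default_rng(20220419)
    probes = rng.normal(size=(n_probe, 4))
    probes /= np.linalg.norm(probes, axis=1, keepdims=True)
    dots = np.abs(probes @ quats.T)
    nearest = 2.0 * np.degrees(np.arccos(np.clip(dots.max(axis=1), -1.0, 1.0)))
    # empirical covering radius with a safety margin for unprobed pockets
    return float(nearest.max() * 1.25)


def rotation_set(n_target: int = DEFAULT_ROTATION_COUNT) -> RotationSet:
    """Generate a deterministic near-uniform set of ~n_target rotations.

    The default size is exactly 7,416 orientations, the cardinality used for
    whole-orientation-space sampling in the fitting search.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target == 1:
        return RotationSet(np.array([[1.0, 0, 0, 0]]), 180.0)
    quats = _super_fibonacci(int(n_target))
    return RotationSet(quats, _estimate_coverage_deg(quats))


def random_transform(rng_seed, max_shift: float) -> RigidTransform:
    """A reproducible random rigid transform: Haar-uniform rotation plus a
    translation uniform in the cube [-max_shift, max_shift]^3 (Å)."""
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    rng = np.random.default_rng(rng_seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    t = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(q, t)


def apply_transform(s: Subunit, T: RigidTransform) -> Subunit:
    """Return the subunit with all atom coordinates rigidly moved by ``T``."""
    return s.with_coords(T.apply(s.coords))


def centroid(s: Subunit) -> np.ndarray:
    """Unweighted mean of the Cα coordinates (the subunit center)."""
    return s.calpha.mean(axis=0)


_STANDARD_HYDROGENS = {"H", "D"}


def read_structure(path: str) -> list[Subunit]:
    """Read a PDB file into one Subunit per chain.

    Altloc conflicts keep the highest-occupancy conformer; hydrogens are
    dropped; chains without Cα atoms are skipped with a warning.  Raises
    ``ValueError`` if no usable chain remains.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    subunits: list[Subunit] = []
    model = next(structure.get_models(), None)
    if model is None:
        raise ValueError(f"{path}: no models found (not a PDB file?)")
    for chain in model:
        names, elements, res_names, res_ids, coords = [], [], [], [], []
        for res in chain:
            if res.id[0] != " ":  # skip waters / heteroatoms
                continue
            for atom in res:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0)
                elem = (atom.element or "").strip().upper()
                if elem in _STANDARD_HYDROGENS:
                    continue
                names.append(atom.get_name())
                elements.append(elem or "C")
                res_names.append(res.get_resname())
                res_ids.append(res.id[1])
                coords.append(atom.get_coord())
        if not names or "CA" not in names:
            warnings.warn(f"chain {chain.id!r} has no C-alpha atoms; skipped")
            continue
        subunits.append(
            Subunit(str(chain.id), names, elements, res_names,
                    np.asarray(res_ids), np.asarray(coords, dtype=float))
        )
    if not subunits:
        raise ValueError(f"{path}: no protein chains with C-alpha atoms")
    return subunits


def write_structure(subunits: list[Subunit], path: str) -> None:
    """Write subunits as a multi-chain PDB file."""
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("m")
    builder.init_model(0)
    builder.init_seg("    ")
    serial = 1
    for s in subunits:
        builder.init_chain(str(s.id)[:1] if len(str(s.id)) == 1 else "A")
        current_res = None
        for name, elem, rname, rid, xyz in zip(
            s.atom_names, s.elements, s.res_names, s.res_ids, s.coords
        ):
            if current_res != int(rid):
                builder.init_residue(rname, " ", int(rid), " ")
                current_res = int(rid)
            builder.init_atom(name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                              name.center(4), serial, element=elem)
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
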