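"""Backbone geometry for short peptides.

Builds peptide backbones (N, CA, C, O) from (phi, psi, omega) dihedrals with
fixed textbook bond lengths and angles, measures dihedrals back from
coordinates, and provides the geometric observables used throughout the
pipeline: optimal-superposition (Kabsch) RMSD, radius of gyration, helix
parameters from an axis fit, and centre-of-mass distances.

Internal length unit is Angstrom; centre-of-mass distances and the
free-energy-surface axes downstream are reported in nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import minimize

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

# Fixed backbone geometry (Angstrom / degrees); textbook values.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
ANGLE_CA_C_O = 120.8

ATOM_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class GeometryError(ValueError):
    """Invalid geometry input (length mismatch, degenerate configuration...)."""


@dataclass(frozen=True)
class PeptideSequence:
    """A named peptide given as one-letter amino-acid codes."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


@dataclass
class DihedralTrace:
    """Per-residue (phi, psi, omega) in degrees, NaN where undefined.

    phi is undefined at the first residue; psi and omega at the last.
    omega(i) is the peptide-bond torsion CA(i)-C(i)-N(i+1)-CA(i+1).
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = len(self.phi)
        if len(self.psi) != n or len(self.omega) != n:
            raise GeometryError("phi/psi/omega length mismatch")
        for arr in (self.phi, self.psi, self.omega):
            defined = arr[np.isfinite(arr)]
            if np.any((defined <= -180.0) | (defined > 180.0)):
                raise GeometryError("dihedral outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0
                ) -> "DihedralTrace":
        p = np.full(n, float(phi))
        s = np.full(n, float(psi))
        w = np.full(n, float(omega))
        p[0] = np.nan
        s[-1] = np.nan
        w[-1] = np.nan
        return cls(p, s, w)


@dataclass
class HelixParameters:
    rise_per_residue: float        # Angstrom
    residues_per_turn: float
    handedness: str                # "right" | "left"

    def __post_init__(self) -> None:
        if self.rise_per_residue <= 0:
            raise ValueError("rise must be positive")
        if self.residues_per_turn <= 2:
            raise ValueError("residues per turn must exceed 2")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")


@dataclass
class BackboneStructure:
    """Backbone coordinates (Angstrom) of one conformation of one peptide.

    ``atoms`` maps atom name (N, CA, C, O, optionally H) to an (n, 3) array.
    Amide-H rows may be NaN where no hydrogen is present.
    """

    sequence: PeptideSequence
    atoms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in BACKBONE_ATOMS:
            if name not in self.atoms:
                raise GeometryError(f"missing backbone atom {name}")
        for name, xyz in self.atoms.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (n, 3):
                raise GeometryError(f"{name} coordinates must be ({n}, 3)")
            self.atoms[name] = xyz

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def coords(self, name: str) -> np.ndarray:
        return self.atoms[name]

    def has_hydrogens(self) -> bool:
        return "H" in self.atoms and bool(np.any(np.isfinite(self.atoms["H"])))

    def all_atom_coords(self, include_h: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (coords, masses); NaN (absent H) rows are dropped."""
        xyz, masses = [], []
        for name, arr in self.atoms.items():
            if name == "H" and not include_h:
                continue
            element = name[0]
            keep = np.all(np.isfinite(arr), axis=1)
            xyz.append(arr[keep])
            masses.append(np.full(keep.sum(), ATOM_MASSES[element]))
        return np.concatenate(xyz), np.concatenate(masses)

    def validate_bonds(self) -> None:
        """Check bonded backbone distances fall in [1.0, 2.0] Angstrom."""
        n_ca = np.linalg.norm(self.atoms["CA"] - self.atoms["N"], axis=1)
        ca_c = np.linalg.norm(self.atoms["C"] - self.atoms["CA"], axis=1)
        c_n = np.linalg.norm(self.atoms["N"][1:] - self.atoms["C"][:-1], axis=1)
        for name, d in (("N-CA", n_ca), ("CA-C", ca_c), ("C-N", c_n)):
            if np.any((d < 1.0) | (d > 2.0)):
                raise GeometryError(f"bonded {name} distance outside [1, 2] A")


# ---------------------------------------------------------------------------
# internal-coordinate chain building (NeRF), batched over frames
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """Natural-extension placement of atom D bonded to c.

    Works on (..., 3) stacks. |c-D| = bond, angle(b, c, D) = angle_deg and
    torsion(a, b, c, D) = torsion_deg.
    """
    theta = np.deg2rad(angle_deg)
    tau = np.deg2rad(np.asarray(torsion_deg))
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(norm < 1e-9):
        raise GeometryError("colinear reference atoms: torsion undefined")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.stack(
        [np.broadcast_to(-bond * np.cos(theta), tau.shape),
         bond * np.sin(theta) * np.cos(tau),
         bond * np.sin(theta) * np.sin(tau)], axis=-1)
    return c + (d_local[..., 0:1] * bc + d_local[..., 1:2] * m
                + d_local[..., 2:3] * n)


def build_backbone_batch(phi: np.ndarray, psi: np.ndarray,
                         omega: np.ndarray) -> dict[str, np.ndarray]:
    """Build a batch of backbones from dihedral arrays of shape (F, n).

    NaNs are accepted at the positions where a torsion is undefined
    (phi[:, 0], psi[:, -1], omega[:, -1]). Returns atom name -> (F, n, 3).
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    n_frames, n = phi.shape
    if psi.shape != phi.shape or omega.shape != phi.shape:
        raise GeometryError("phi/psi/omega shape mismatch")
    interior = np.concatenate([phi[:, 1:].ravel(), psi[:, :-1].ravel(),
                               omega[:, :-1].ravel()])
    if not np.all(np.isfinite(interior)):
        raise GeometryError("non-finite dihedral at a defined position")

    N = np.empty((n_frames, n, 3))
    CA = np.empty_like(N)
    C = np.empty_like(N)
    O = np.empty_like(N)

    # canonical frame for residue 1: N at origin, CA on +x, C in the xy plane
    N[:, 0] = 0.0
    CA[:, 0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[:, 0] = CA[:, 0] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])

    for i in range(n - 1):
        N[:, i + 1] = _place_atom(N[:, i], CA[:, i], C[:, i],
                                  BOND_C_N, ANGLE_CA_C_N, psi[:, i])
        CA[:, i + 1] = _place_atom(CA[:, i], C[:, i], N[:, i + 1],
                                   BOND_N_CA, ANGLE_C_N_CA, omega[:, i])
        C[:, i + 1] = _place_atom(C[:, i], N[:, i + 1], CA[:, i + 1],
                                  BOND_CA_C, ANGLE_N_CA_C, phi[:, i + 1])
        # carbonyl O of residue i, anti to the next amide N
        O[:, i] = _place_atom(N[:, i], CA[:, i], C[:, i],
                              BOND_C_O, ANGLE_CA_C_O, psi[:, i] + 180.0)
    # last residue: psi undefined; place O at the trans-like default
    O[:, n - 1] = _place_atom(N[:, n - 1], CA[:, n - 1], C[:, n - 1],
                              BOND_C_O, ANGLE_CA_C_O, 0.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def build_from_dihedrals(seq: PeptideSequence,
                         trace: DihedralTrace) -> BackboneStructure:
    """Build one backbone conformation from its dihedral trace."""
    if len(trace) != len(seq):
        raise GeometryError(
            f"trace length {len(trace)} != sequence length {len(seq)}")
    if len(seq) == 1:
        atoms = build_backbone_batch(np.array([[np.nan]]),
                                     np.array([[np.nan]]),
                                     np.array([[np.nan]]))
        return BackboneStructure(seq, {k: v[0] for k, v in atoms.items()})
    omega = np.where(np.isfinite(trace.omega), trace.omega, 180.0)
    omega[-1] = np.nan
    atoms = build_backbone_batch(trace.phi[None, :], trace.psi[None, :],
                                 omega[None, :])
    return BackboneStructure(seq, {k: v[0] for k, v in atoms.items()})


# ---------------------------------------------------------------------------
# dihedral measurement
# ---------------------------------------------------------------------------

def dihedral_angle(a, b, c, d) -> np.ndarray:
    """Signed torsion a-b-c-d in degrees, IUPAC convention; (..., 3) stacks."""
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-9) or \
       np.any(np.linalg.norm(n2, axis=-1) < 1e-9):
        raise GeometryError("colinear atoms: dihedral undefined")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2u)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = -np.rad2deg(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def measure_dihedrals_batch(atoms: Mapping[str, np.ndarray]
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, psi, omega) of shape (F, n) from batched atom arrays."""
    N, CA, C = atoms["N"], atoms["CA"], atoms["C"]
    n_frames, n, _ = N.shape
    phi = np.full((n_frames, n), np.nan)
    psi = np.full((n_frames, n), np.nan)
    omega = np.full((n_frames, n), np.nan)
    if n > 1:
        phi[:, 1:] = dihedral_angle(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
        psi[:, :-1] = dihedral_angle(N[:, :-1], CA[:, :-1], C[:, :-1],
                                     N[:, 1:])
        omega[:, :-1] = dihedral_angle(CA[:, :-1], C[:, :-1], N[:, 1:],
                                       CA[:, 1:])
    return phi, psi, omega


def measure_dihedrals(s: BackboneStructure) -> DihedralTrace:
    """Measure the (phi, psi, omega) trace of a backbone structure."""
    atoms = {k: s.atoms[k][None, ...] for k in ("N", "CA", "C")}
    phi, psi, omega = measure_dihedrals_batch(atoms)
    return DihedralTrace(phi[0], psi[0], omega[0])


# ---------------------------------------------------------------------------
# superposition RMSD and radius of gyration
# ---------------------------------------------------------------------------

def _gather_selection(s: BackboneStructure, selection: Iterable[str]
                      ) -> np.ndarray:
    sel = list(selection)
    missing = [a for a in sel if a not in s.atoms]
    if missing:
        raise GeometryError(f"selection atoms missing: {missing}")
    return np.concatenate([s.atoms[a] for a in sel], axis=0)


def kabsch_rmsd_xyz(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Minimum RMSD between point sets after optimal rigid superposition.

    ``p`` may be a batch (F, N, 3); ``q`` is (N, 3). Returns (F,) or scalar.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    single = p.ndim == 2
    if single:
        p = p[None]
    n_pts = p.shape[1]
    pc = p - p.mean(axis=1, keepdims=True)
    qc = q - q.mean(axis=0)
    # batched Kabsch via SVD of the covariance
    h = np.einsum("fni,nj->fij", pc, qc)
    u, sv, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", u, vt))
    sv = sv.copy()
    sv[:, -1] *= np.sign(det)
    e0 = np.sum(pc ** 2, axis=(1, 2)) + np.sum(qc ** 2)
    msd = np.maximum(e0 - 2.0 * sv.sum(axis=1), 0.0) / n_pts
    rmsd = np.sqrt(msd)
    return rmsd[0] if single else rmsd


def kabsch_rmsd(a: BackboneStructure, b: BackboneStructure,
                selection: Iterable[str] = ("CA",)) -> float:
    """Optimal-superposition RMSD (Angstrom) over the selected atoms."""
    if len(a) != len(b):
        raise GeometryError("structures differ in residue count")
    pa = _gather_selection(a, selection)
    pb = _gather_selection(b, selection)
    if pa.shape[0] < 3:
        raise GeometryError("need at least 3 selected atoms")
    return float(kabsch_rmsd_xyz(pa, pb))


def radius_of_gyration_xyz(xyz: np.ndarray,
                           masses: np.ndarray | None = None) -> np.ndarray:
    """Rg of (..., N, 3) coordinates, optionally mass weighted."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-2] == 0:
        raise GeometryError("empty structure")
    if masses is None:
        masses = np.ones(xyz.shape[-2])
    masses = np.asarray(masses, dtype=float)
    w = masses / masses.sum()
    com = np.einsum("...ni,n->...i", xyz, w)
    d2 = np.sum((xyz - com[..., None, :]) ** 2, axis=-1)
    return np.sqrt(np.einsum("...n,n->...", d2, w))


def radius_of_gyration(s: BackboneStructure, mass_weighted: bool = True
                       ) -> float:
    """Radius of gyration (Angstrom) over the backbone heavy atoms."""
    xyz, masses = s.all_atom_coords()
    return float(radius_of_gyration_xyz(xyz, masses if mass_weighted else None))


# ---------------------------------------------------------------------------
# helix parameters
# ---------------------------------------------------------------------------

def _axis_from_direction(theta: float, phi_ang: float) -> np.ndarray:
    return np.array([np.sin(theta) * np.cos(phi_ang),
                     np.sin(theta) * np.sin(phi_ang),
                     np.cos(theta)])


def _perpendicular_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)        # (e1, e2, axis) is right-handed
    return e1, e2


def _lsq_circle_center(pts: np.ndarray) -> np.ndarray:
    """Least-squares (Kasa) circle centre of 2D points."""
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:2]


def _cylinder_residual(ca: np.ndarray, axis: np.ndarray) -> float:
    e1, e2 = _perpendicular_basis(axis)
    pts = np.column_stack([ca @ e1, ca @ e2])
    center = _lsq_circle_center(pts)
    r = np.linalg.norm(pts - center, axis=1)
    return float(np.var(r))


def fit_helix_axis(ca: np.ndarray) -> np.ndarray:
    """Direction of the least-squares cylinder through a CA trace.

    Initialised from consecutive cross products of the trace's second
    differences (exact for an ideal helix, where second differences point
    radially inward), then refined by minimising the spread of the radial
    distances about the best-fitting circle centre. A full cylinder fit is
    needed because a short helix covers partial turns: its centroid sits
    off the axis and the principal axis of the coordinates is tilted.
    """
    second = np.diff(ca, n=2, axis=0)
    cross = np.cross(second[:-1], second[1:])
    norms = np.linalg.norm(cross, axis=1)
    good = norms > 1e-9
    if np.any(good):
        directed = cross[good] / norms[good, None]
        directed *= np.sign(directed @ directed[0])[:, None]
        axis0 = directed.mean(axis=0)
        axis0 /= np.linalg.norm(axis0)
    else:
        centred = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis0 = vt[0]

    def objective(params):
        return _cylinder_residual(ca, _axis_from_direction(*params))

    theta0 = float(np.arccos(np.clip(axis0[2], -1, 1)))
    phi0 = float(np.arctan2(axis0[1], axis0[0]))
    res = minimize(objective, x0=[theta0, phi0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 4000})
    return _axis_from_direction(*res.x)


def helix_twist_profile(ca: np.ndarray, axis: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(per-step rise, per-step twist in degrees) about the fitted axis.

    Twist sign is taken about the axis oriented from the N to the C
    terminus, so a right-handed helix twists positively.
    """
    t = ca @ axis
    if np.mean(np.diff(t)) < 0:
        axis = -axis
        t = -t
    e1, e2 = _perpendicular_basis(axis)
    pts = np.column_stack([ca @ e1, ca @ e2])
    center = _lsq_circle_center(pts)
    rel = pts - center
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < 1e-3):
        raise GeometryError("collinear CA trace: no helical twist defined")
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    twist = np.rad2deg(np.diff(np.unwrap(angles)))
    return np.diff(t), twist


def helix_parameters(s: BackboneStructure) -> HelixParameters:
    """Rise per residue, residues per turn and handedness from the CA trace."""
    ca = s.atoms["CA"]
    if ca.shape[0] < 6:
        raise GeometryError("need at least 6 residues for a helix fit")
    axis = fit_helix_axis(ca)
    rise_steps, twist = helix_twist_profile(ca, axis)
    rise = float(np.mean(rise_steps))
    mean_twist = float(np.mean(twist))
    if abs(mean_twist) < 1e-6:
        raise GeometryError("no helical twist: structure is not a helix")
    return HelixParameters(
        rise_per_residue=rise,
        residues_per_turn=360.0 / abs(mean_twist),
        handedness="right" if mean_twist > 0 else "left",
    )


# ---------------------------------------------------------------------------
# centre-of-mass distance
# ---------------------------------------------------------------------------

def com_distance(coords_a: np.ndarray, masses_a: np.ndarray,
                 coords_b: np.ndarray, masses_b: np.ndarray) -> float:
    """Distance between mass-weighted centroids, in nm (inputs in Angstrom)."""
    for coords, masses in ((coords_a, masses_a), (coords_b, masses_b)):
        if len(np.atleast_2d(coords)) == 0:
            raise GeometryError("empty atom group")
        if len(np.atleast_2d(coords)) != len(np.atleast_1d(masses)):
            raise GeometryError("coords/masses length mismatch")
    com_a = np.average(np.atleast_2d(coords_a), axis=0,
                       weights=np.atleast_1d(masses_a))
    com_b = np.average(np.atleast_2d(coords_b), axis=0,
                       weights=np.atleast_1d(masses_b))
    return float(np.linalg.norm(com_a - com_b)) / 10.0


def ideal_helix(seq: PeptideSequence, phi: float = -57.0, psi: float = -47.0
                ) -> BackboneStructure:
    """Reference structure built at the ideal alpha-helix dihedral centres."""
    return build_from_dihedrals(seq, DihedralTrace.uniform(len(seq), phi, psi))
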