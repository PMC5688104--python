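"""DSSP-style secondary-structure assignment and Ramachandran regions.

Implements amide-hydrogen placement by the standard convention (N-H
anti-parallel to the preceding carbonyl), the Kabsch-Sander electrostatic
hydrogen-bond energy, the turn/helix/bridge pattern rules of DSSP over the
labels {H, G, I, E, T, S, C}, and a wrap-aware classifier of (phi, psi)
points into the canonical Ramachandran regions (alpha, beta, PPII, left
alpha).

Isolated single bridges (DSSP label B) are folded into E; bends (S) use the
standard CA-curvature criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BackboneStructure

DSSP_LABELS = ("H", "G", "I", "E", "T", "S", "C")
REGION_LABELS = ("alpha", "beta", "ppii", "alphaL", "other")

# Ramachandran region centres (phi, psi) in degrees.
RAMA_CENTERS = {
    "alpha": (-60.0, -45.0),
    "beta": (-135.0, 135.0),
    "ppii": (-75.0, 150.0),
    "alphaL": (60.0, 45.0),
}
_REGION_PRIORITY = ("alpha", "beta", "ppii", "alphaL")

# Kabsch-Sander electrostatic model: E in kcal/mol, distances in Angstrom.
KS_COUPLING = 0.084 * 332.0
HBOND_ENERGY_CUTOFF = -0.5
_CLAMP_DISTANCE = 0.5
_CLAMP_ENERGY = -9.9


class HBondError(ValueError):
    """Degenerate hydrogen-bond geometry (overlapping atoms)."""


@dataclass
class SSAssignment:
    """Per-residue DSSP label and Ramachandran region label."""

    dssp: str
    region: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.dssp) != len(self.region):
            raise ValueError("dssp/region length mismatch")
        if set(self.dssp) - set(DSSP_LABELS):
            raise ValueError("unknown DSSP label")
        if set(self.region) - set(REGION_LABELS):
            raise ValueError("unknown region label")

    def __len__(self) -> int:
        return len(self.dssp)

    @property
    def helix_fraction(self) -> float:
        """Fraction of residues labelled H (alpha helix)."""
        return self.dssp.count("H") / len(self.dssp)


@dataclass
class HBondRecord:
    donor: int        # residue index (0-based) donating N-H
    acceptor: int     # residue index providing C=O
    energy: float     # kcal/mol
    distance: float   # H...O, Angstrom

    def __post_init__(self) -> None:
        if abs(self.donor - self.acceptor) < 2:
            raise ValueError("backbone h-bond requires |donor - acceptor| >= 2")
        if not np.isfinite(self.energy):
            raise ValueError("non-finite energy")


# ---------------------------------------------------------------------------
# amide hydrogens
# ---------------------------------------------------------------------------

def place_amide_hydrogens_batch(atoms: dict[str, np.ndarray],
                                residues: str) -> dict[str, np.ndarray]:
    """Add an 'H' entry to batched atom arrays (F, n, 3); NaN where absent.

    Residue 1 and prolines carry no amide hydrogen. Existing finite H
    coordinates are preserved.
    """
    N, C, O = atoms["N"], atoms["C"], atoms["O"]
    n_frames, n, _ = N.shape
    h = atoms.get("H")
    h = np.full((n_frames, n, 3), np.nan) if h is None else h.copy()
    co = C[:, :-1] - O[:, :-1]
    co /= np.linalg.norm(co, axis=-1, keepdims=True)
    placed = N[:, 1:] + co
    for i in range(1, n):
        if residues[i] == "P":
            continue
        missing = ~np.all(np.isfinite(h[:, i]), axis=-1)
        h[missing, i] = placed[missing, i - 1]
    out = dict(atoms)
    out["H"] = h
    return out


def place_amide_hydrogens(s: BackboneStructure) -> BackboneStructure:
    """Return a structure carrying amide hydrogens (1.0 A from N, anti to C=O)."""
    batched = {k: v[None] for k, v in s.atoms.items()}
    out = place_amide_hydrogens_batch(batched, s.sequence.residues)
    return BackboneStructure(s.sequence, {k: v[0] for k, v in out.items()})


# ---------------------------------------------------------------------------
# Kabsch-Sander hydrogen-bond energies
# ---------------------------------------------------------------------------

def kabsch_sander_energy(donor_n: np.ndarray, donor_h: np.ndarray,
                         acceptor_c: np.ndarray, acceptor_o: np.ndarray
                         ) -> float:
    """Electrostatic h-bond energy (kcal/mol) of one donor/acceptor pair."""
    r_on = np.linalg.norm(acceptor_o - donor_n)
    r_ch = np.linalg.norm(acceptor_c - donor_h)
    r_oh = np.linalg.norm(acceptor_o - donor_h)
    r_cn = np.linalg.norm(acceptor_c - donor_n)
    r = np.array([r_on, r_ch, r_oh, r_cn])
    if np.any(r < _CLAMP_DISTANCE):
        raise HBondError("overlapping atoms: energy clamped regime")
    return float(KS_COUPLING * (1.0 / r_on + 1.0 / r_ch
                                - 1.0 / r_oh - 1.0 / r_cn))


def hbond_energy_matrix(atoms: dict[str, np.ndarray], residues: str
                        ) -> np.ndarray:
    """E[d, a]: energy of residue d's N-H donating to residue a's C=O.

    Operates on one frame (atom name -> (n, 3)). Entries are +inf where the
    pair is not a candidate (|d - a| < 2, missing H) and clamped to -9.9
    where atoms overlap, following the reference DSSP policy.
    """
    N, H = atoms["N"], atoms["H"]
    C, O = atoms["C"], atoms["O"]
    n = N.shape[0]
    e = np.full((n, n), np.inf)
    has_h = np.all(np.isfinite(H), axis=-1)
    r_on = np.linalg.norm(O[None, :] - N[:, None], axis=-1)
    r_ch = np.linalg.norm(C[None, :] - H[:, None], axis=-1)
    r_oh = np.linalg.norm(O[None, :] - H[:, None], axis=-1)
    r_cn = np.linalg.norm(C[None, :] - N[:, None], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh
                              - 1.0 / r_cn)
    overlap = np.minimum.reduce([r_on, r_ch, r_oh, r_cn]) < _CLAMP_DISTANCE
    vals = np.where(overlap, _CLAMP_ENERGY, vals)
    d_idx, a_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    candidate = (np.abs(d_idx - a_idx) >= 2) & has_h[:, None]
    e[candidate] = vals[candidate]
    return e


# ---------------------------------------------------------------------------
# DSSP assignment
# ---------------------------------------------------------------------------

def _dssp_labels_from_bonds(bond: np.ndarray, ca: np.ndarray) -> str:
    """Pattern rules over the accepted h-bond matrix.

    ``bond[a, d]`` is True when the C=O of residue ``a`` accepts from the
    N-H of residue ``d``. Priorities follow DSSP: H, then E (ladders,
    isolated bridges folded in), then G, I, then T, then S.
    """
    n = bond.shape[0]

    def turn(i: int, k: int) -> bool:
        return i + k < n and bond[i, i + k]

    label = np.array(["C"] * n, dtype="U1")

    # 4-helix (H): two consecutive 4-turns at i-1 and i -> residues i..i+3
    helix4 = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if turn(i - 1, 4) and turn(i, 4):
            helix4[i:i + 4] = True

    # bridges -> strand (E); isolated bridges are folded into E
    strand = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (bond[i - 1, j] and bond[j, i + 1]) or \
                   (bond[j - 1, i] and bond[i, j + 1])
            anti = (bond[i, j] and bond[j, i]) or \
                   (bond[i - 1, j + 1] and bond[j - 1, i + 1])
            if para or anti:
                strand[i] = strand[j] = True

    # 3-helix (G) and 5-helix (I) where not already stronger structure
    helix3 = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if turn(i - 1, 3) and turn(i, 3):
            helix3[i:i + 3] = True
    helix5 = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if turn(i - 1, 5) and turn(i, 5):
            helix5[i:i + 5] = True

    # turns (T): residues strictly inside any single n-turn
    turn_t = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in range(n):
            if turn(i, k):
                turn_t[i + 1:i + k] = True

    # bends (S): CA chain curvature > 70 degrees
    bend = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) > 70.0:
            bend[i] = True

    label[bend] = "S"
    label[turn_t] = "T"
    label[helix3] = "G"
    label[strand & ~helix4] = "E"
    label[helix4] = "H"
    # pi-helix outranks alpha where both patterns hold (DSSP >= 3 convention)
    label[helix5] = "I"
    return "".join(label)


def assign_dssp(s: BackboneStructure) -> SSAssignment:
    """DSSP labels plus Ramachandran region labels for one structure."""
    from .geometry import measure_dihedrals  # local import to avoid cycle

    n = len(s)
    if n < 3:
        regions = tuple("other" for _ in range(n))
        return SSAssignment("C" * n, regions)
    if not s.has_hydrogens():
        s = place_amide_hydrogens(s)
    energy = hbond_energy_matrix(s.atoms, s.sequence.residues)
    # bond[a, d]: acceptor a's C=O bound by donor d's N-H
    bond = energy.T < HBOND_ENERGY_CUTOFF
    dssp = _dssp_labels_from_bonds(bond, s.atoms["CA"])
    trace = measure_dihedrals(s)
    regions = tuple(
        classify_rama_region(phi, psi) if np.isfinite(phi) and np.isfinite(psi)
        else "other"
        for phi, psi in zip(trace.phi, trace.psi)
    )
    return SSAssignment(dssp, regions)


# ---------------------------------------------------------------------------
# Ramachandran region classification
# ---------------------------------------------------------------------------

def _wrap_delta(a: float, b: float) -> float:
    d = (a - b) % 360.0
    return d - 360.0 if d > 180.0 else d


def classify_rama_region(phi: float, psi: float,
                         half_width: float = 30.0) -> str:
    """Nearest Ramachandran region centre within a +-half_width box.

    Distance is the wrap-aware Chebyshev distance on the torus (mirroring the
    box windows used to define the ideal helix); ties break by the fixed
    priority alpha > beta > ppii > alphaL; 'other' when no centre is close.
    """
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("non-finite dihedral")
    best = "other"
    best_d = np.inf
    for name in _REGION_PRIORITY:
        c_phi, c_psi = RAMA_CENTERS[name]
        d = max(abs(_wrap_delta(phi, c_phi)), abs(_wrap_delta(psi, c_psi)))
        if d <= half_width and d < best_d - 1e-12:
            best, best_d = name, d
    return best


def classify_rama_regions_array(phi: np.ndarray, psi: np.ndarray,
                                half_width: float = 30.0) -> np.ndarray:
    """Vectorised region classification; NaN pairs map to 'other'."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    out = np.full(phi.shape, "other", dtype="U6")
    dist = np.full(phi.shape, np.inf)
    for name in reversed(_REGION_PRIORITY):
        c_phi, c_psi = RAMA_CENTERS[name]
        d_phi = np.abs((phi - c_phi + 180.0) % 360.0 - 180.0)
        d_psi = np.abs((psi - c_psi + 180.0) % 360.0 - 180.0)
        d = np.maximum(d_phi, d_psi)
        better = (d <= half_width) & (d <= dist)
        out[better] = name
        dist[better] = d[better]
    out[~(np.isfinite(phi) & np.isfinite(psi))] = "other"
    return out
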