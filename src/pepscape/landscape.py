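"""Ensemble statistics: helicity metrics, free-energy surfaces, basins.

An :class:`Ensemble` is an ordered stack of backbone conformations of one
peptide. Three helicity statistics summarise it: (i) the mean percentage of
residues in an alpha-helical (DSSP H) state, (ii) the percentage of frames
that are at least 70% helical, and (iii) the percentage of frames within
2 A CA RMSD of an ideal helix built at (-57, -47).

Free-energy surfaces are -ln(population) over two order parameters, shifted
so the global minimum is zero, with empty bins masked. Basins on those
surfaces are extracted by steepest-descent assignment on the grid and
reported as clusters with populations and representative frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (BackboneStructure, GeometryError, PeptideSequence,
                       ideal_helix, kabsch_rmsd_xyz,
                       measure_dihedrals_batch, radius_of_gyration_xyz)
from .secondary import (SSAssignment, assign_dssp,
                        place_amide_hydrogens_batch)


@dataclass
class Ensemble:
    """Ordered conformations of one sequence, as batched (F, n, 3) arrays."""

    sequence: PeptideSequence
    atoms: dict[str, np.ndarray]
    weights: np.ndarray | None = None
    ss: list[SSAssignment] | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        shapes = {k: np.asarray(v).shape for k, v in self.atoms.items()}
        f = next(iter(shapes.values()))[0]
        for k, shape in shapes.items():
            if shape != (f, n, 3):
                raise GeometryError(f"{k} must have shape ({f}, {n}, 3)")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (f,) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be non-negative with sum > 0")
            self.weights = w

    @property
    def n_frames(self) -> int:
        return self.atoms["N"].shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> BackboneStructure:
        return BackboneStructure(
            self.sequence, {k: v[i] for k, v in self.atoms.items()})

    @classmethod
    def from_structures(cls, structures: list[BackboneStructure],
                        name: str | None = None) -> "Ensemble":
        if not structures:
            raise ValueError("empty structure list")
        seq = structures[0].sequence
        if any(s.sequence.residues != seq.residues for s in structures):
            raise ValueError("all frames must share one sequence")
        if name is not None:
            seq = PeptideSequence(name, seq.residues)
        keys = set.intersection(*(set(s.atoms) for s in structures))
        atoms = {k: np.stack([s.atoms[k] for s in structures]) for k in keys}
        return cls(seq, atoms)

    # -- cached per-frame quantities ------------------------------------

    def dihedrals(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return measure_dihedrals_batch(self.atoms)

    def assign_secondary_structure(self) -> list[SSAssignment]:
        """Assign (and cache) DSSP + region labels for every frame."""
        if self.ss is None:
            self.ss = [assign_dssp(self.frame(i))
                       for i in range(self.n_frames)]
        return self.ss

    def helix_fraction_per_frame(self) -> np.ndarray:
        ss = self.assign_secondary_structure()
        return np.array([a.helix_fraction for a in ss])

    def rmsd_to(self, reference: BackboneStructure,
                selection: str = "CA") -> np.ndarray:
        """Per-frame optimal-superposition RMSD to a reference (Angstrom)."""
        if len(reference) != self.n_residues:
            raise GeometryError("reference length mismatch")
        return kabsch_rmsd_xyz(self.atoms[selection],
                               reference.atoms[selection])

    def rg_per_frame(self, mass_weighted: bool = True) -> np.ndarray:
        """Per-frame backbone radius of gyration (Angstrom)."""
        names = [k for k in self.atoms if k != "H"]
        xyz = np.concatenate([self.atoms[k] for k in names], axis=1)
        if mass_weighted:
            from .geometry import ATOM_MASSES
            masses = np.concatenate([
                np.full(self.n_residues, ATOM_MASSES[k[0]]) for k in names])
        else:
            masses = None
        return radius_of_gyration_xyz(xyz, masses)


@dataclass(frozen=True)
class HelicityMetrics:
    """The three helicity statistics, all percentages in [0, 100]."""

    pct_residues_alpha: float
    pct_frames_ge70: float
    pct_frames_within_2A: float

    def __post_init__(self) -> None:
        for v in (self.pct_residues_alpha, self.pct_frames_ge70,
                  self.pct_frames_within_2A):
            if not 0.0 <= v <= 100.0:
                raise ValueError("metrics must lie in [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_residues_alpha": self.pct_residues_alpha,
            "pct_frames_ge70": self.pct_frames_ge70,
            "pct_frames_within_2A": self.pct_frames_within_2A,
        }


def compute_helicity_metrics(e: Ensemble,
                             ideal_ref: BackboneStructure | None = None,
                             helix_frame_fraction: float = 0.70,
                             rmsd_cut_angstrom: float = 2.0
                             ) -> HelicityMetrics:
    """The three helicity statistics of an ensemble.

    ``ideal_ref`` defaults to the same-length ideal helix at (-57, -47).
    """
    if e.n_frames == 0:
        raise ValueError("empty ensemble")
    if ideal_ref is None:
        ideal_ref = ideal_helix(e.sequence)
    if len(ideal_ref) != e.n_residues:
        raise GeometryError("ideal reference length mismatch")
    frac = e.helix_fraction_per_frame()
    rmsd = e.rmsd_to(ideal_ref)
    return HelicityMetrics(
        pct_residues_alpha=float(np.mean(frac) * 100.0),
        pct_frames_ge70=float(np.mean(frac >= helix_frame_fraction) * 100.0),
        pct_frames_within_2A=float(np.mean(rmsd < rmsd_cut_angstrom) * 100.0),
    )


# ---------------------------------------------------------------------------
# free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FES2D:
    """-ln(population) over two order parameters; empty bins masked.

    ``values`` is NaN on masked bins; the minimum over unmasked bins is 0.
    ``samples`` keeps the pooled (x, y) observations so basin populations
    can be traced back to frames.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    x_name: str = "x"
    y_name: str = "y"
    units: tuple[str, str] = ("", "")
    samples: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        unmasked = self.values[~self.mask]
        if unmasked.size == 0:
            raise ValueError("all bins are empty")
        if not np.all(np.isfinite(unmasked)):
            raise ValueError("non-finite value on unmasked bin")
        if abs(float(unmasked.min())) > 1e-9:
            raise ValueError("unmasked minimum must be 0")

    @classmethod
    def from_samples(cls, x: np.ndarray, y: np.ndarray,
                     x_edges: np.ndarray, y_edges: np.ndarray,
                     x_name: str = "x", y_name: str = "y",
                     units: tuple[str, str] = ("", "")) -> "FES2D":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
        mask = counts == 0
        with np.errstate(divide="ignore"):
            values = -np.log(counts / counts.max())
        values[mask] = np.nan
        return cls(np.asarray(x_edges), np.asarray(y_edges), values, mask,
                   x_name, y_name, units, samples=(x, y))

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def sample_bins(self) -> tuple[np.ndarray, np.ndarray]:
        """Bin indices (ix, iy) of each stored sample."""
        if self.samples is None:
            raise ValueError("surface carries no samples")
        x, y = self.samples
        ix = np.clip(np.searchsorted(self.x_edges, x, side="right") - 1,
                     0, len(self.x_edges) - 2)
        iy = np.clip(np.searchsorted(self.y_edges, y, side="right") - 1,
                     0, len(self.y_edges) - 2)
        return ix, iy

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (x_center, y_center, value, masked)."""
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame({
            self.x_name: xc.ravel(),
            self.y_name: yc.ravel(),
            "free_energy": self.values.ravel(),
            "masked": self.mask.ravel(),
        })


def ramachandran_fes(e: Ensemble, bin_width: float = 10.0) -> FES2D:
    """Pooled (phi, psi) free-energy surface over the full torus."""
    if abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError("bin width must divide 360 degrees")
    phi, psi, _ = e.dihedrals()
    ok = np.isfinite(phi) & np.isfinite(psi)
    if not np.any(ok):
        raise ValueError("no defined (phi, psi) pair")
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    return FES2D.from_samples(phi[ok], psi[ok], edges, edges,
                              x_name="phi", y_name="psi",
                              units=("deg", "deg"))


def rmsd_rg_fes(e: Ensemble, reference: BackboneStructure,
                bin_width_nm: tuple[float, float] = (0.05, 0.05)) -> FES2D:
    """Per-frame (CA RMSD to reference, Rg) surface, axes in nm."""
    if e.n_frames == 0:
        raise ValueError("empty ensemble")
    rmsd_nm = e.rmsd_to(reference) / 10.0
    rg_nm = e.rg_per_frame() / 10.0
    wx, wy = bin_width_nm

    def edges(v: np.ndarray, w: float) -> np.ndarray:
        lo = np.floor(v.min() / w) * w
        hi = max(np.ceil(v.max() / w) * w, lo + w)
        return np.arange(lo, hi + w / 2, w)

    return FES2D.from_samples(rmsd_nm, rg_nm, edges(rmsd_nm, wx),
                              edges(rg_nm, wy), x_name="rmsd", y_name="rg",
                              units=("nm", "nm"))


# ---------------------------------------------------------------------------
# basins as clusters
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A populated basin on a free-energy surface."""

    centre: tuple[float, float]
    population: float              # percent of all samples
    representative_frame: int      # index into the pooled samples
    depth: float                   # basin-minimum free energy

    def as_dict(self) -> dict:
        return {"centre": list(self.centre), "population": self.population,
                "representative_frame": self.representative_frame,
                "depth": self.depth}


def _descend_to_minimum(values: np.ndarray, mask: np.ndarray,
                        start: tuple[int, int]) -> tuple[int, int]:
    """Follow the steepest-descent path on the grid to a local minimum."""
    nx, ny = values.shape
    cur = start
    for _ in range(values.size):
        cx, cy = cur
        best = cur
        best_v = values[cx, cy]
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                nx_, ny_ = cx + dx, cy + dy
                if 0 <= nx_ < nx and 0 <= ny_ < ny and not mask[nx_, ny_]:
                    if values[nx_, ny_] < best_v:
                        best, best_v = (nx_, ny_), values[nx_, ny_]
        if best == cur:
            return cur
        cur = best
    return cur


def extract_basins(f: FES2D, depth_cut: float = 1.0,
                   min_pop_pct: float = 1.0) -> list[Cluster]:
    """Basins of a surface as clusters with populations from frame counts.

    Local minima within ``depth_cut`` of the global minimum seed basins;
    every sample's bin is assigned by steepest descent; basins holding less
    than ``min_pop_pct`` percent of the samples are discarded.
    """
    if np.all(f.mask):
        raise ValueError("all-masked surface")
    values = np.where(f.mask, np.inf, f.values)
    ix, iy = f.sample_bins()
    n_samples = len(ix)

    # map every occupied bin to its steepest-descent local minimum
    occupied = sorted(set(zip(ix.tolist(), iy.tolist())))
    sink: dict[tuple[int, int], tuple[int, int]] = {}
    for cell in occupied:
        sink[cell] = _descend_to_minimum(values, f.mask, cell)

    seeds = {m for m in set(sink.values())
             if values[m] <= depth_cut + 1e-12}

    assignments = np.full(n_samples, -1)
    seed_list = sorted(seeds)
    seed_index = {m: k for k, m in enumerate(seed_list)}
    for s_idx, cell in enumerate(zip(ix.tolist(), iy.tolist())):
        m = sink[cell]
        if m in seed_index:
            assignments[s_idx] = seed_index[m]

    x, y = f.samples
    clusters: list[Cluster] = []
    for k, m in enumerate(seed_list):
        members = assignments == k
        pop = members.sum() / n_samples * 100.0
        if pop < min_pop_pct:
            continue
        cx = float(np.mean(x[members]))
        cy = float(np.mean(y[members]))
        # representative: member sample nearest the basin centroid
        d2 = (x[members] - cx) ** 2 + (y[members] - cy) ** 2
        rep = int(np.flatnonzero(members)[np.argmin(d2)])
        clusters.append(Cluster(centre=(cx, cy), population=float(pop),
                                representative_frame=rep,
                                depth=float(values[m])))
    clusters.sort(key=lambda c: -c.population)
    return clusters


# ---------------------------------------------------------------------------
# hydrogen-bond occupancy
# ---------------------------------------------------------------------------

def hbond_occupancy(e: Ensemble, cutoff: float = 2.8) -> pd.DataFrame:
    """Backbone H...O occupancy table over the ensemble.

    A donor/acceptor pair (|i - j| >= 2) counts as bonded in a frame when
    the amide-H to carbonyl-O distance is at most ``cutoff`` Angstrom.
    Returns columns (donor, acceptor, occupancy_pct), 1-based residue
    indices, sorted by descending occupancy; unobserved pairs are omitted.
    """
    if e.n_frames == 0:
        raise ValueError("empty ensemble")
    atoms = place_amide_hydrogens_batch(e.atoms, e.sequence.residues)
    h = atoms["H"]            # (F, n, 3), NaN where absent
    o = atoms["O"]
    n = e.n_residues
    with np.errstate(invalid="ignore"):
        dist = np.linalg.norm(h[:, :, None, :] - o[:, None, :, :], axis=-1)
    d_idx, a_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    candidate = np.abs(d_idx - a_idx) >= 2
    bonded = (dist <= cutoff) & candidate[None, :, :]
    bonded &= np.isfinite(dist)
    occ = bonded.mean(axis=0) * 100.0
    rows = [
        {"donor": i + 1, "acceptor": j + 1, "occupancy_pct": float(occ[i, j])}
        for i in range(n) for j in range(n) if occ[i, j] > 0.0
    ]
    df = pd.DataFrame(rows, columns=["donor", "acceptor", "occupancy_pct"])
    if len(df):
        df = df.sort_values("occupancy_pct", ascending=False,
                            kind="stable").reset_index(drop=True)
    return df
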