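"""Synthetic peptide ensembles and pulling replicates.

This module is a statistical emulator, not a force-field sampler: it
produces conformational ensembles and steered-pulling time series with a
prescribed statistical structure so that every analysis stage can be tested
against known ground truth.

Equilibrium ensembles are block mixtures of four dihedral states -- alpha
helix (-57, -47), beta (-135, 135), polyproline II (-75, 150) and coil
(uniform) -- with Gaussian angular noise. Residues are segmented into
contiguous state blocks because secondary-structure assignment keys on
hydrogen-bond runs: independently drawn per-residue states would almost
never satisfy the two-consecutive-turn rule.

Pulling replicate sets emulate constant-velocity centre-of-mass pulling
away from a receptor: the centre-of-mass distance grows deterministically
from 1.33 nm while the per-frame helical residue count decays along a
logistic unwinding curve with replicate-level integer noise. Presets
reproduce the qualitative behaviours seen for helicity-retaining
(p53-P27S-like) and helicity-losing (12/1-like) peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PeptideSequence, build_backbone_batch
from .landscape import Ensemble
from .pulling import PullReplicateSet

STATE_CENTERS = {
    "H": (-57.0, -47.0),     # alpha helix
    "E": (-135.0, 135.0),    # beta
    "P": (-75.0, 150.0),     # polyproline II
}
STATE_ORDER = ("H", "E", "P", "C")


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a synthetic equilibrium ensemble."""

    sequence: PeptideSequence
    n_frames: int
    weights: tuple[float, float, float, float]   # helix, beta, ppii, coil
    noise_sd: float = 10.0          # degrees
    mean_block_len: float = 8.0     # residues; geometric block lengths
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be 4 non-negative values summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.mean_block_len < 1:
            raise ValueError("mean block length must be >= 1")


@dataclass
class SyntheticEnsemble:
    """Generator output: the ensemble plus its ground-truth bookkeeping.

    ``state_labels`` records the dihedral state each residue was drawn from
    (H/E/P/C). ``expected_ss`` is the secondary-structure string the
    assignment stage is expected to produce: helix blocks keep their H
    labels except where chain termini cut off the hydrogen-bond pattern
    (the first and last chain residue of a terminal run cannot complete a
    turn), and all other states map to non-H.
    """

    ensemble: Ensemble
    spec: EnsembleSpec
    state_labels: np.ndarray     # (F, n) of "H"/"E"/"P"/"C"
    expected_ss: np.ndarray      # (F, n) of "H"/"-"

    def realized_state_fractions(self) -> dict[str, float]:
        f = self.state_labels.size
        return {s: float(np.sum(self.state_labels == s)) / f
                for s in STATE_ORDER}

    def expected_helix_fraction(self) -> float:
        return float(np.mean(self.expected_ss == "H"))


def _sample_blocks(n: int, weights: np.ndarray, mean_len: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Segment n residues into contiguous blocks with categorical states."""
    labels = np.empty(n, dtype="U1")
    i = 0
    p_stop = 1.0 / mean_len
    while i < n:
        length = int(rng.geometric(p_stop)) if mean_len > 1 else 1
        length = max(1, min(length, n - i))
        state = STATE_ORDER[rng.choice(4, p=weights)]
        labels[i:i + length] = state
        i += length
    return labels


def _expected_ss_row(labels: np.ndarray) -> np.ndarray:
    """DSSP-expected H pattern for one frame's state labels.

    Interior helix runs of length >= 4 are recovered in full by the
    hydrogen-bond pattern rules; runs touching a chain terminus lose their
    outermost residue (no phi at residue 1 / no complete turn at the end),
    and runs shorter than 4 cannot produce two consecutive turns at all.
    """
    n = len(labels)
    out = np.full(n, "-", dtype="U1")
    i = 0
    while i < n:
        if labels[i] != "H":
            i += 1
            continue
        j = i
        while j < n and labels[j] == "H":
            j += 1
        start, end = i, j            # run = [start, end)
        if start == 0:
            start += 1
        if end == n:
            end -= 1
        if end - start >= 4:
            out[start:end] = "H"
        i = j
    return out


def generate_ensemble(spec: EnsembleSpec) -> SyntheticEnsemble:
    """Draw a synthetic ensemble; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    n = len(spec.sequence)
    f = spec.n_frames
    weights = np.asarray(spec.weights, dtype=float)

    labels = np.stack([
        _sample_blocks(n, weights, spec.mean_block_len, rng)
        for _ in range(f)])

    phi = np.empty((f, n))
    psi = np.empty((f, n))
    # Structured states get anti-correlated (crankshaft) angular noise
    # within each block: delta-psi(i) = -delta-phi(i+1), the coupling seen
    # in thermal libration of real helices. It keeps each angle's marginal
    # at N(0, sd) while preserving the hydrogen-bond pattern that
    # secondary-structure assignment keys on; independent per-angle noise
    # of the same width would break an appreciable fraction of the bonds.
    for fr in range(f):
        i = 0
        while i < n:
            state = labels[fr, i]
            j = i
            while j < n and labels[fr, j] == state:
                j += 1
            if state == "C":
                phi[fr, i:j] = rng.uniform(-180.0, 180.0, j - i)
                psi[fr, i:j] = rng.uniform(-180.0, 180.0, j - i)
            else:
                c_phi, c_psi = STATE_CENTERS[state]
                d = rng.normal(0.0, spec.noise_sd, j - i + 1)
                phi[fr, i:j] = c_phi + d[:-1]
                psi[fr, i:j] = c_psi - d[1:]
            i = j
    phi = _wrap_angle(phi)
    psi = _wrap_angle(psi)
    phi[:, 0] = np.nan
    psi[:, -1] = np.nan
    omega = np.full((f, n), 180.0)
    omega[:, -1] = np.nan

    atoms = build_backbone_batch(phi, psi, omega)
    ensemble = Ensemble(spec.sequence, atoms)
    expected = np.stack([_expected_ss_row(row) for row in labels])
    return SyntheticEnsemble(ensemble, spec, labels, expected)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    wrapped = (a + 180.0) % 360.0 - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


# ---------------------------------------------------------------------------
# pulling replicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PullSpec:
    """Recipe for a set of synthetic constant-velocity pulling replicates.

    The unwinding model is a logistic decay of the helical residue count
    with centre-of-mass distance: fraction(d) = floor + (1 - floor) /
    (1 + exp(steepness * (d - midpoint))).
    """

    name: str
    n_residues: int = 12
    helical_start: int = 9          # helical residues in the bound form
    n_replicates: int = 10
    n_frames: int = 120
    start_distance: float = 1.33    # nm
    pull_rate: float = 0.01         # nm per frame
    midpoint: float = 1.65          # nm
    steepness: float = 10.0         # 1/nm
    floor: float = 0.0              # retained helical fraction at infinity
    noise_sd: float = 0.7           # residues
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.start_distance <= 0:
            raise ValueError("start distance must be positive")
        if self.midpoint <= self.start_distance and self.floor > 0:
            raise ValueError("degenerate preset: decay midpoint before the "
                             "start distance with a non-zero floor")
        if not 0 <= self.floor <= 1:
            raise ValueError("floor must lie in [0, 1]")


def preset_p53_like(seed: int = 0) -> PullSpec:
    """Helicity-retaining preset (p53-P27S-like): late, shallow unwinding."""
    return PullSpec(name="p53-like", midpoint=2.3, floor=0.5, seed=seed)


def preset_12_1_like(seed: int = 0) -> PullSpec:
    """Helicity-losing preset (12/1-like): unwinds around 1.65 nm."""
    return PullSpec(name="12/1-like", midpoint=1.65, floor=0.0, seed=seed)


def unwinding_fraction(d: np.ndarray, spec: PullSpec) -> np.ndarray:
    """The noiseless logistic unwinding curve of a spec."""
    logistic = 1.0 / (1.0 + np.exp(spec.steepness * (d - spec.midpoint)))
    return spec.floor + (1.0 - spec.floor) * logistic


def generate_pulling_replicates(spec: PullSpec) -> PullReplicateSet:
    """Synthetic replicate set; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    frames = np.arange(spec.n_frames)
    distance = spec.start_distance + spec.pull_rate * frames
    clean = spec.helical_start * unwinding_fraction(distance, spec)
    rows = []
    for rep in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, spec.n_frames)
        count = np.clip(np.rint(clean + noise), 0, spec.n_residues)
        rows.append(pd.DataFrame({
            "replicate": rep,
            "frame": frames,
            "com_distance_nm": distance,
            "helical_count": count.astype(int),
        }))
    table = pd.concat(rows, ignore_index=True)
    return PullReplicateSet(table, name=spec.name,
                            n_residues=spec.n_residues)
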