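"""Hamiltonian replica exchange with solute tempering, at desk scale.

Implements the bookkeeping of replica exchange with solute tempering
(REST): an equally spaced ladder of coupling values starting at 0, the
scaled Hamiltonian E(lambda) = (1 - lambda) E_ss + sqrt(1 - lambda) E_sw +
E_ww (solute-solute and solute-solvent terms damped, solvent-solvent
untouched; lambda = 0 is the physical Hamiltonian), and Metropolis swaps
of adjacent replicas.

The scheme is exercised on a one-dimensional periodic double well on a
dihedral-like coordinate -- the minimal system exhibiting
lambda-accelerated barrier crossing -- with within-replica Metropolis
moves alternating with adjacent-pair exchange sweeps. A direct
single-chain Metropolis sampler is provided as the independent check that
the lambda = 0 marginal is Boltzmann.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class LambdaLadder:
    """Equally spaced coupling values from 0 to lambda_max."""

    lambdas: tuple[float, ...]

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas)
        if len(lam) < 2:
            raise ValueError("ladder needs at least 2 rungs")
        if lam[0] != 0.0:
            raise ValueError("first rung must be lambda = 0")
        spacings = np.diff(lam)
        if np.any(spacings <= 0) or not np.allclose(spacings, spacings[0]):
            raise ValueError("rungs must be strictly increasing and equally "
                             "spaced")

    def __len__(self) -> int:
        return len(self.lambdas)

    def __iter__(self):
        return iter(self.lambdas)


def make_lambda_ladder(n: int = 8, lambda_max: float = 0.5) -> LambdaLadder:
    """n equally spaced rungs: lambda_i = lambda_max * i / (n - 1)."""
    if n < 2:
        raise ValueError("need at least 2 replicas")
    if not 0.0 < lambda_max < 1.0:
        raise ValueError("lambda_max must lie in (0, 1)")
    return LambdaLadder(tuple(lambda_max * i / (n - 1) for i in range(n)))


@dataclass
class ReplicaState:
    """One replica: its rung, current configuration and energy terms."""

    replica_id: int
    lam: float
    configuration: float
    e_ss: float
    e_sw: float
    e_ww: float

    def __post_init__(self) -> None:
        for v in (self.e_ss, self.e_sw, self.e_ww):
            if not np.isfinite(v):
                raise ValueError("non-finite energy")


@dataclass
class ExchangeLog:
    """Record of exchange attempts and per-pair acceptance ratios."""

    attempts: list[tuple[int, float, bool]] = field(default_factory=list)

    def record(self, pair: int, delta: float, accepted: bool) -> None:
        self.attempts.append((pair, float(delta), bool(accepted)))

    def acceptance_ratio(self, pair: int | None = None) -> float:
        rows = [a for a in self.attempts if pair is None or a[0] == pair]
        if not rows:
            return float("nan")
        return sum(1 for a in rows if a[2]) / len(rows)

    def per_pair_ratios(self) -> dict[int, float]:
        pairs = sorted({a[0] for a in self.attempts})
        return {p: self.acceptance_ratio(p) for p in pairs}


def scaled_energy(e_ss: float, e_sw: float, e_ww: float, lam: float) -> float:
    """REST-scaled total energy; reduces to the plain sum at lambda = 0."""
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must lie in [0, 1)")
    return (1.0 - lam) * e_ss + np.sqrt(1.0 - lam) * e_sw + e_ww


def exchange_probability(a: ReplicaState, b: ReplicaState,
                         beta: float = 1.0) -> float:
    """Metropolis probability of swapping the configurations of a and b.

    Delta = [E_a(x_b) + E_b(x_a)] - [E_a(x_a) + E_b(x_b)], with each
    replica's energy evaluated at its own rung.
    """
    if a.lam == b.lam:
        raise ValueError("replicas must sit on distinct rungs")
    e_a_xa = scaled_energy(a.e_ss, a.e_sw, a.e_ww, a.lam)
    e_b_xb = scaled_energy(b.e_ss, b.e_sw, b.e_ww, b.lam)
    e_a_xb = scaled_energy(b.e_ss, b.e_sw, b.e_ww, a.lam)
    e_b_xa = scaled_energy(a.e_ss, a.e_sw, a.e_ww, b.lam)
    delta = (e_a_xb + e_b_xa) - (e_a_xa + e_b_xb)
    if not np.isfinite(delta):
        raise ValueError("non-finite exchange energy")
    return float(min(1.0, np.exp(-beta * delta)))


# ---------------------------------------------------------------------------
# toy potential and samplers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubleWellPotential:
    """Periodic double well on a dihedral-like coordinate theta in (-pi, pi].

    Solute-solute term: barrier * (1 - cos 2 theta) / 2 -- wells at 0 and
    pi separated by ``barrier``. Solute-solvent term: tilt * (1 - cos
    theta) / 2 -- lifts the well at pi by ``tilt``. Solvent-solvent term is
    a constant offset (unscaled by construction).
    """

    barrier: float = 4.0
    tilt: float = 1.0
    e_ww: float = 0.0

    def e_ss(self, theta):
        return self.barrier * 0.5 * (1.0 - np.cos(2.0 * theta))

    def e_sw(self, theta):
        return self.tilt * 0.5 * (1.0 - np.cos(theta))

    def scaled(self, theta, lam: float):
        return scaled_energy(self.e_ss(theta), self.e_sw(theta),
                             self.e_ww, lam)


def _wrap(theta):
    return (theta + np.pi) % (2.0 * np.pi) - np.pi


@dataclass
class RestResult:
    ladder: LambdaLadder
    samples: np.ndarray          # (n_rungs, n_samples) lambda-resolved
    log: ExchangeLog
    move_acceptance: np.ndarray  # per-rung within-replica acceptance


def run_toy_rest(potential: DoubleWellPotential, ladder: LambdaLadder,
                 n_sweeps: int, exchange_interval: int = 10,
                 seed: int = 0, proposal_sd: float = 0.6,
                 beta: float = 1.0, sample_stride: int = 1) -> RestResult:
    """Metropolis sampling at every rung with adjacent-pair exchanges.

    Within-replica moves are Gaussian angular steps accepted by the
    Metropolis rule on the rung's scaled Hamiltonian; every
    ``exchange_interval`` sweeps, adjacent pairs (alternating parity)
    attempt a configuration swap via :func:`exchange_probability`.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lams = np.asarray(list(ladder))
    n_rungs = len(lams)
    theta = np.zeros(n_rungs)
    kept = []
    log = ExchangeLog()
    accepted_moves = np.zeros(n_rungs)
    parity = 0
    for sweep in range(n_sweeps):
        prop = _wrap(theta + rng.normal(0.0, proposal_sd, n_rungs))
        e_old = (1.0 - lams) * potential.e_ss(theta) \
            + np.sqrt(1.0 - lams) * potential.e_sw(theta) + potential.e_ww
        e_new = (1.0 - lams) * potential.e_ss(prop) \
            + np.sqrt(1.0 - lams) * potential.e_sw(prop) + potential.e_ww
        accept = rng.random(n_rungs) < np.exp(-beta * (e_new - e_old))
        theta = np.where(accept, prop, theta)
        accepted_moves += accept

        if (sweep + 1) % exchange_interval == 0:
            for i in range(parity, n_rungs - 1, 2):
                a = ReplicaState(i, lams[i], theta[i],
                                 float(potential.e_ss(theta[i])),
                                 float(potential.e_sw(theta[i])),
                                 potential.e_ww)
                b = ReplicaState(i + 1, lams[i + 1], theta[i + 1],
                                 float(potential.e_ss(theta[i + 1])),
                                 float(potential.e_sw(theta[i + 1])),
                                 potential.e_ww)
                p = exchange_probability(a, b, beta)
                ok = rng.random() < p
                if ok:
                    theta[i], theta[i + 1] = theta[i + 1], theta[i]
                with np.errstate(divide="ignore"):
                    delta = -np.log(p) / beta if p < 1.0 else 0.0
                log.record(i, delta, ok)
            parity = 1 - parity

        if sweep % sample_stride == 0:
            kept.append(theta.copy())

    move_acc = accepted_moves / n_sweeps
    if np.any(move_acc == 0):
        raise RuntimeError("a replica accepted no moves: non-ergodic "
                           "parameterisation")
    return RestResult(ladder=ladder, samples=np.array(kept).T, log=log,
                      move_acceptance=move_acc)


def direct_metropolis(potential: DoubleWellPotential, n_sweeps: int,
                      seed: int = 0, proposal_sd: float = 0.6,
                      beta: float = 1.0, lam: float = 0.0,
                      sample_stride: int = 1) -> np.ndarray:
    """Single-chain Metropolis sampler; the independent Boltzmann check."""
    rng = np.random.default_rng(seed)
    theta = 0.0
    kept = []
    for sweep in range(n_sweeps):
        prop = float(_wrap(theta + rng.normal(0.0, proposal_sd)))
        de = potential.scaled(prop, lam) - potential.scaled(theta, lam)
        if rng.random() < np.exp(-beta * de):
            theta = prop
        if sweep % sample_stride == 0:
            kept.append(theta)
    return np.asarray(kept)
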