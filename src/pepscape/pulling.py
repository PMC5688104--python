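"""Pulling-trajectory analysis: profiles, jackknife errors, classification.

A pulling replicate set holds per-frame records of (centre-of-mass
distance, helical residue count) for several replicate trajectories of the
same peptide pulled away from its receptor. The analysis averages the
helical count across replicates at each time point (or distance bin),
attaches leave-one-out jackknife standard errors, and classifies the
profile as retaining or losing helicity by comparing the count at a probe
distance with the count at the starting distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("replicate", "frame", "com_distance_nm", "helical_count")


@dataclass
class PullReplicateSet:
    """Long-format table of pulling replicates for one peptide."""

    table: pd.DataFrame
    name: str
    n_residues: int

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if self.table["replicate"].nunique() < 1:
            raise ValueError("empty replicate set")
        for rep, grp in self.table.groupby("replicate"):
            d = grp.sort_values("frame")["com_distance_nm"].to_numpy()
            if np.any(np.diff(d) < -1e-9):
                raise ValueError(
                    f"replicate {rep}: COM distance must be non-decreasing")

    @property
    def n_replicates(self) -> int:
        return int(self.table["replicate"].nunique())

    @classmethod
    def from_tsv(cls, path, name: str, n_residues: int) -> "PullReplicateSet":
        return cls(pd.read_csv(path, sep="\t"), name=name,
                   n_residues=n_residues)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class PullProfile:
    """Replicate-averaged helicity profile with jackknife errors."""

    grid: np.ndarray                # time indices or distance-bin centres
    mean_helical_count: np.ndarray
    jackknife_se: np.ndarray        # NaN where undefined (single replicate)
    mean_com_distance: np.ndarray   # nm
    align_by: str = "time_index"

    def __post_init__(self) -> None:
        n = len(self.grid)
        for arr in (self.mean_helical_count, self.jackknife_se,
                    self.mean_com_distance):
            if len(arr) != n:
                raise ValueError("profile arrays must share one length")
        defined = self.jackknife_se[np.isfinite(self.jackknife_se)]
        if np.any(defined < 0):
            raise ValueError("standard errors must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid": self.grid,
            "mean_com_distance_nm": self.mean_com_distance,
            "mean_helical_count": self.mean_helical_count,
            "jackknife_se": self.jackknife_se,
        })

    def count_at_distance(self, distance_nm: float) -> float:
        """Mean helical count at a COM distance, linearly interpolated."""
        d = self.mean_com_distance
        lo, hi = float(np.min(d)), float(np.max(d))
        if not lo - 1e-9 <= distance_nm <= hi + 1e-9:
            raise ValueError(
                f"distance {distance_nm} nm outside profile support "
                f"[{lo:.3f}, {hi:.3f}] nm")
        order = np.argsort(d)
        return float(np.interp(distance_nm, d[order],
                               self.mean_helical_count[order]))


def jackknife_se(values) -> float:
    """Leave-one-out jackknife standard error of the mean of replicates."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("jackknife needs at least 2 replicates")
    loo = (v.sum() - v) / (n - 1)
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


def helicity_profile(p: PullReplicateSet, align_by: str = "time_index",
                     bin_width_nm: float = 0.05) -> PullProfile:
    """Average the helical residue count across replicates.

    ``time_index`` mode requires all replicates to share a frame grid and
    averages per frame (the pulling schedule makes frame index and distance
    interchangeable). ``distance_bin`` mode bins by COM distance and keeps
    only bins covered by every replicate.
    """
    if align_by not in ("time_index", "distance_bin"):
        raise ValueError("align_by must be 'time_index' or 'distance_bin'")
    tab = p.table
    n_rep = p.n_replicates

    if align_by == "time_index":
        counts = tab.pivot_table(index="frame", columns="replicate",
                                 values="helical_count")
        if counts.isna().any().any():
            raise ValueError("replicates do not share a common time grid")
        dists = tab.pivot_table(index="frame", columns="replicate",
                                values="com_distance_nm")
        grid = counts.index.to_numpy(dtype=float)
        mean = counts.mean(axis=1).to_numpy()
        mean_d = dists.mean(axis=1).to_numpy()
        se = _rowwise_jackknife(counts.to_numpy(), n_rep)
    else:
        d = tab["com_distance_nm"].to_numpy()
        bins = np.arange(np.floor(d.min() / bin_width_nm) * bin_width_nm,
                         d.max() + bin_width_nm, bin_width_nm)
        tab = tab.assign(_bin=pd.cut(tab["com_distance_nm"], bins))
        per_rep = (tab.groupby(["_bin", "replicate"], observed=True)
                   .agg(count=("helical_count", "mean"),
                        dist=("com_distance_nm", "mean")).reset_index())
        counts = per_rep.pivot(index="_bin", columns="replicate",
                               values="count")
        covered = counts.dropna()
        if covered.empty:
            raise ValueError("replicates have disjoint distance supports")
        dists = per_rep.pivot(index="_bin", columns="replicate",
                              values="dist").loc[covered.index]
        grid = np.array([iv.mid for iv in covered.index])
        mean = covered.mean(axis=1).to_numpy()
        mean_d = dists.mean(axis=1).to_numpy()
        se = _rowwise_jackknife(covered.to_numpy(), n_rep)

    return PullProfile(grid=grid, mean_helical_count=mean,
                       jackknife_se=se, mean_com_distance=mean_d,
                       align_by=align_by)


def _rowwise_jackknife(values: np.ndarray, n_rep: int) -> np.ndarray:
    if n_rep < 2:
        return np.full(values.shape[0], np.nan)
    return np.array([jackknife_se(row) for row in values])


def classify_retention(profile: PullProfile, start_distance: float = 1.33,
                       probe_distance: float = 1.8,
                       retain_fraction: float = 0.5) -> str:
    """'retains_helicity' or 'loses_helicity' under the 50%-at-1.8-nm rule.

    The peptide retains helicity when the mean helical count at the probe
    distance is at least ``retain_fraction`` of the count at the start.
    """
    start = profile.count_at_distance(start_distance)
    probe = profile.count_at_distance(probe_distance)
    retained = probe >= retain_fraction * start
    return "retains_helicity" if retained else "loses_helicity"
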