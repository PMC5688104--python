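#!/usr/bin/env python
"""Conformational landscapes of the simulated ensembles.

For each ensemble written by 02_simulate_ensembles.py: the three helicity
statistics, the Ramachandran free-energy surface, the RMSD-vs-Rg surface
with its basins (clusters), and backbone hydrogen-bond occupancies at the
2.8 A cutoff. The helicity-dominated ensemble concentrates in a deep
low-RMSD basin while the promiscuous one spreads over a rugged surface
with several shallow basins.

Writes per-peptide files under results/landscape_<name>/.
"""

from pathlib import Path

from pepscape.geometry import ideal_helix
from pepscape.io import RunConfig, read_multimodel_pdb, write_outputs
from pepscape.landscape import (compute_helicity_metrics, extract_basins,
                                hbond_occupancy, ramachandran_fes,
                                rmsd_rg_fes)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pdbs = sorted((ROOT / "ensembles").glob("*.pdb"))
    if not pdbs:
        raise SystemExit("run 02_simulate_ensembles.py first")
    for pdb in pdbs:
        ens = read_multimodel_pdb(pdb)
        ref = ideal_helix(ens.sequence)
        metrics = compute_helicity_metrics(ens, ref)
        rama = ramachandran_fes(ens)
        surface = rmsd_rg_fes(ens, ref)
        clusters = extract_basins(surface, depth_cut=3.0, min_pop_pct=2.0)
        hbonds = hbond_occupancy(ens)
        cfg = RunConfig(out_dir=str(ROOT / f"landscape_{pdb.stem}"))
        write_outputs({"metrics": metrics.as_dict(), "rama_fes": rama,
                       "rmsd_rg_fes": surface, "clusters": clusters,
                       "hbonds": hbonds.head(20)}, cfg)
        print(f"{pdb.stem}: "
              f"{metrics.pct_residues_alpha:.1f}% residues helical, "
              f"{metrics.pct_frames_ge70:.1f}% frames >=70% helical, "
              f"{metrics.pct_frames_within_2A:.1f}% frames within 2 A of "
              f"the ideal helix; {len(clusters)} clusters "
              + str([round(c.population, 1) for c in clusters]))


if __name__ == "__main__":
    main()
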