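"""File formats, run configuration and result writing.

Ensembles travel as multi-model PDB (human-inspectable and standard at
this scale), sequences as FASTA, pulling data and profiles as TSV,
metrics/clusters/design reports as JSON. A :class:`RunConfig` collects the
pipeline thresholds -- the 70% per-frame helicity cut, the 2 A ideal-helix
RMSD cut, the 2.8 A hydrogen-bond cutoff and the 50%/1.8 nm retention rule
-- in one place.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import numpy as np
import yaml
from Bio import SeqIO

from .geometry import (BACKBONE_ATOMS, ONE_LETTER, THREE_LETTER,
                       PeptideSequence)
from .landscape import FES2D, Cluster, Ensemble


class PDBFormatError(ValueError):
    """Malformed or inconsistent multi-model PDB content."""


@dataclass
class RunConfig:
    """Thresholds, bin widths and seeds for one pipeline run."""

    seed: int = 0
    out_dir: str = "results"
    helix_frame_fraction: float = 0.70   # metric ii cut
    rmsd_cut_angstrom: float = 2.0       # metric iii cut
    hbond_cutoff_angstrom: float = 2.8
    retention_fraction: float = 0.5
    retention_start_nm: float = 1.33
    retention_probe_nm: float = 1.8
    rama_bin_deg: float = 10.0
    fes_bin_nm: float = 0.05
    first_residue_number: int = 1        # PDB numbering offset

    def __post_init__(self) -> None:
        for name in ("helix_frame_fraction", "rmsd_cut_angstrom",
                     "hbond_cutoff_angstrom", "retention_fraction",
                     "retention_start_nm", "retention_probe_nm",
                     "rama_bin_deg", "fes_bin_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def _check_model_records(path) -> None:
    """Require MODEL/ENDMDL records to pair up; report the offending line."""
    depth = 0
    opened_at = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                if depth:
                    raise PDBFormatError(
                        f"line {lineno}: MODEL opened before ENDMDL closed "
                        f"the model started at line {opened_at}")
                depth, opened_at = 1, lineno
            elif line.startswith("ENDMDL"):
                if not depth:
                    raise PDBFormatError(f"line {lineno}: ENDMDL without MODEL")
                depth = 0
    if depth:
        raise PDBFormatError(
            f"truncated file: MODEL at line {opened_at} never closed "
            f"by ENDMDL")


def read_multimodel_pdb(path, name: str | None = None) -> Ensemble:
    """Read a backbone ensemble from a multi-model PDB file.

    Frames are ordered by MODEL number; every model must carry the same
    sequence and the full N/CA/C/O backbone.
    """
    path = Path(path)
    _check_model_records(path)
    stack = pdb_io.PDBFile.read(str(path)).get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    res_ids = np.unique(first.res_id)
    residues = []
    for rid in res_ids:
        res_names = set(first.res_name[first.res_id == rid])
        if len(res_names) != 1:
            raise PDBFormatError(f"residue {rid}: inconsistent residue name")
        three = res_names.pop()
        if three not in ONE_LETTER:
            raise PDBFormatError(f"residue {rid}: unknown residue {three}")
        residues.append(ONE_LETTER[three])
    seq = PeptideSequence(name or path.stem, "".join(residues))

    n_frames = stack.stack_depth()
    n = len(seq)
    atoms: dict[str, np.ndarray] = {}
    names = list(BACKBONE_ATOMS)
    if np.any(first.atom_name == "H"):
        names.append("H")
    for atom_name in names:
        coords = np.full((n_frames, n, 3), np.nan)
        for i, rid in enumerate(res_ids):
            sel = (first.res_id == rid) & (first.atom_name == atom_name)
            count = int(sel.sum())
            if count == 0:
                if atom_name == "H":
                    continue
                raise PDBFormatError(
                    f"residue {rid}: missing backbone atom {atom_name}")
            if count > 1:
                raise PDBFormatError(
                    f"residue {rid}: duplicate atom {atom_name}")
            coords[:, i] = stack.coord[:, sel, :][:, 0, :]
        atoms[atom_name] = coords
    return Ensemble(seq, atoms)


def write_multimodel_pdb(e: Ensemble, path,
                         first_residue_number: int = 1) -> None:
    """Write an ensemble as a multi-model PDB (coordinates in Angstrom)."""
    n = e.n_residues
    names = [a for a in ("N", "CA", "C", "O", "H") if a in e.atoms]
    arrays = []
    for f in range(e.n_frames):
        rows = []
        for i in range(n):
            for atom_name in names:
                xyz = e.atoms[atom_name][f, i]
                if not np.all(np.isfinite(xyz)):
                    continue
                rows.append((i, atom_name, xyz))
        arr = struc.AtomArray(len(rows))
        for k, (i, atom_name, xyz) in enumerate(rows):
            arr.coord[k] = xyz
            arr.chain_id[k] = "A"
            arr.res_id[k] = i + first_residue_number
            arr.res_name[k] = THREE_LETTER[e.sequence.residues[i]]
            arr.atom_name[k] = atom_name
            arr.element[k] = atom_name[0]
        arrays.append(arr)
    shapes = {len(a) for a in arrays}
    if len(shapes) == 1:
        stack = struc.stack(arrays)
        out = pdb_io.PDBFile()
        out.set_structure(stack)
        out.write(str(path))
    else:
        # frames differ in present hydrogens: write models manually
        lines = []
        for f, arr in enumerate(arrays, start=1):
            lines.append(f"MODEL     {f:4d}")
            single = pdb_io.PDBFile()
            single.set_structure(arr)
            lines.extend(l for l in single.lines if l.startswith(("ATOM",
                                                                  "HETATM")))
            lines.append("ENDMDL")
        Path(path).write_text("\n".join(lines) + "\n")


def read_fasta_sequences(path) -> list[PeptideSequence]:
    return [PeptideSequence(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta_sequences(seqs: list[PeptideSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def write_fes_tsv(f: FES2D, path) -> None:
    f.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_clusters_json(clusters: list[Cluster], path) -> None:
    payload = [c.as_dict() for c in clusters]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True)
                          + "\n")


def write_outputs(results: dict, config: RunConfig) -> list[Path]:
    """Write the deterministic file set of a pipeline run.

    ``results`` may carry any of: 'metrics' (dict), 'rama_fes' /
    'rmsd_rg_fes' (FES2D), 'clusters' (list of Cluster), 'hbonds'
    (DataFrame), 'pull_profile' (PullProfile), 'pull_classification'
    (dict), 'design_report' (dict). Only present stages produce files; a
    run log records the seed and thresholds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        target = out / name
        writer(target)
        written.append(target)

    if "metrics" in results:
        emit("metrics.json", lambda p: write_json(results["metrics"], p))
    if "rama_fes" in results:
        emit("fes_rama.tsv", lambda p: write_fes_tsv(results["rama_fes"], p))
    if "rmsd_rg_fes" in results:
        emit("fes_rmsd_rg.tsv",
             lambda p: write_fes_tsv(results["rmsd_rg_fes"], p))
    if "clusters" in results:
        emit("clusters.json",
             lambda p: write_clusters_json(results["clusters"], p))
    if "hbonds" in results:
        emit("hbonds.tsv", lambda p: results["hbonds"].to_csv(
            p, sep="\t", index=False, float_format="%.6g"))
    if "pull_profile" in results:
        emit("pull_profile.tsv", lambda p: results["pull_profile"].to_frame()
             .to_csv(p, sep="\t", index=False, float_format="%.6g"))
    if "pull_classification" in results:
        emit("pull_classification.json",
             lambda p: write_json(results["pull_classification"], p))
    if "design_report" in results:
        emit("design_report.json",
             lambda p: write_json(results["design_report"], p))

    from . import __version__
    log = {"pepscape_version": __version__, "config": asdict(config)}
    emit("run_log.json", lambda p: write_json(log, p))
    return written
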