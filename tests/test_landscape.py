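"""Helicity metrics, free-energy surfaces, basin extraction, h-bonds."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepscape.geometry import (BackboneStructure, DihedralTrace,
                               PeptideSequence, build_from_dihedrals)
from pepscape.landscape import (Ensemble, FES2D, compute_helicity_metrics,
                                extract_basins, hbond_occupancy,
                                ramachandran_fes, rmsd_rg_fes)
from pepscape.synthetic import EnsembleSpec, generate_ensemble


def _stack(structures, name=None):
    return Ensemble.from_structures(structures, name=name)


@pytest.fixture(scope="module")
def coil_ensemble():
    seq = PeptideSequence("coil", "A" * 12)
    spec = EnsembleSpec(seq, 50, (0.0, 0.0, 0.0, 1.0), seed=2)
    return generate_ensemble(spec).ensemble


class TestHelicityMetrics:
    def test_all_coil_is_zero(self, coil_ensemble):
        m = compute_helicity_metrics(coil_ensemble)
        assert m.pct_residues_alpha < 5.0       # rare chance helices only
        assert m.pct_frames_ge70 == 0.0

    def test_ideal_copies_score_100_on_rmsd_metric(self, alpha_helix_20):
        e = _stack([alpha_helix_20] * 8)
        m = compute_helicity_metrics(e, alpha_helix_20)
        assert m.pct_frames_within_2A == 100.0
        assert m.pct_frames_ge70 == 100.0

    def test_mixed_frames_count_correctly(self, alpha_helix_20, extended_20):
        e = _stack([alpha_helix_20] * 5 + [extended_20] * 5)
        m = compute_helicity_metrics(e, alpha_helix_20)
        assert m.pct_frames_within_2A == 50.0
        assert m.pct_frames_ge70 == 50.0

    def test_recovery_of_generator_helicity(self):
        """Metric i recovers the generator's realized helical fraction."""
        seq = PeptideSequence("rec", "QETFSDLWKLLSQETFSDLWKLLSQETFSD")
        synth = generate_ensemble(
            EnsembleSpec(seq, 1000, (0.30, 0.25, 0.25, 0.20), seed=7))
        m = compute_helicity_metrics(synth.ensemble)
        realized = synth.expected_helix_fraction() * 100.0
        assert m.pct_residues_alpha == pytest.approx(realized, abs=3.0)

    def test_permutation_and_rigid_invariance(self, alpha_helix_20,
                                              extended_20):
        frames = [alpha_helix_20] * 3 + [extended_20] * 2
        m1 = compute_helicity_metrics(_stack(frames), alpha_helix_20)
        rot = Rotation.from_euler("xyz", [11.0, 22.0, 33.0], degrees=True)
        moved = [BackboneStructure(
            s.sequence, {k: v @ rot.as_matrix().T + 4.0
                         for k, v in s.atoms.items()}) for s in frames]
        m2 = compute_helicity_metrics(_stack(moved[::-1]), alpha_helix_20)
        assert m1.as_dict() == pytest.approx(m2.as_dict(), abs=1e-9)


class TestRamachandranFES:
    def test_single_conformation_occupies_single_pattern(self,
                                                         alpha_helix_20):
        f = ramachandran_fes(_stack([alpha_helix_20]))
        occupied = ~f.mask
        assert occupied.sum() >= 1
        assert np.nanmin(f.values) == 0.0
        # all (phi, psi) identical -> exactly one occupied bin
        assert occupied.sum() == 1

    def test_two_state_depth_difference_is_log_ratio(self):
        seq = PeptideSequence("two", "A" * 10)
        a = build_from_dihedrals(seq, DihedralTrace.uniform(10, -57.0, -47.0))
        b = build_from_dihedrals(seq, DihedralTrace.uniform(10, -135.0, 135.0))
        f = ramachandran_fes(_stack([a] * 8 + [b] * 2))
        vals = np.sort(f.values[~f.mask])
        assert vals[0] == 0.0
        assert vals[-1] == pytest.approx(np.log(4.0), abs=1e-9)

    def test_uniform_angles_stay_shallow(self):
        """With 1e5 pooled uniform samples, multinomial fluctuations keep
        every unmasked bin below 1.0."""
        rng = np.random.default_rng(9)
        n, frames = 12, 10000
        phi = rng.uniform(-179.9, 180.0, (frames, n))
        psi = rng.uniform(-179.9, 180.0, (frames, n))
        phi[:, 0] = np.nan
        psi[:, -1] = np.nan
        omega = np.full((frames, n), 180.0)
        omega[:, -1] = np.nan
        from pepscape.geometry import build_backbone_batch
        atoms = build_backbone_batch(phi, psi, omega)
        f = ramachandran_fes(Ensemble(PeptideSequence("u", "A" * n), atoms))
        assert np.nanmax(f.values[~f.mask]) < 1.0

    def test_bad_bin_width_rejected(self, alpha_helix_20):
        with pytest.raises(ValueError):
            ramachandran_fes(_stack([alpha_helix_20]), bin_width=7.0)


class TestRmsdRgFES:
    def test_reference_copies_single_bin(self, alpha_helix_20):
        f = rmsd_rg_fes(_stack([alpha_helix_20] * 5), alpha_helix_20)
        assert (~f.mask).sum() == 1
        x, y = f.samples
        assert np.allclose(x, 0.0, atol=1e-9)

    def test_requested_bin_spacing(self, alpha_helix_20, extended_20):
        f = rmsd_rg_fes(_stack([alpha_helix_20] * 3 + [extended_20] * 3),
                        alpha_helix_20, bin_width_nm=(0.05, 0.05))
        assert np.allclose(np.diff(f.x_edges), 0.05)
        assert np.allclose(np.diff(f.y_edges), 0.05)


class TestBasins:
    @staticmethod
    def _two_state_surface(seed=11, n=5000, p=0.7):
        rng = np.random.default_rng(seed)
        lab = rng.random(n) < p
        x = np.where(lab, rng.normal(0.15, 0.04, n),
                     rng.normal(0.55, 0.04, n))
        y = np.where(lab, rng.normal(0.65, 0.04, n),
                     rng.normal(0.85, 0.04, n))
        f = FES2D.from_samples(x, y, np.arange(0, 1.2, 0.05),
                               np.arange(0.4, 1.2, 0.05),
                               "rmsd", "rg", ("nm", "nm"))
        return f, lab

    def test_single_gaussian_single_cluster(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.3, 0.05, 3000)
        y = rng.normal(0.7, 0.05, 3000)
        f = FES2D.from_samples(x, y, np.arange(0, 1, 0.05),
                               np.arange(0.3, 1.2, 0.05))
        clusters = extract_basins(f)
        assert len(clusters) == 1
        assert clusters[0].population == pytest.approx(100.0, abs=1.0)

    def test_planted_mixture_populations(self):
        f, lab = self._two_state_surface()
        clusters = extract_basins(f)
        assert len(clusters) == 2
        realized = lab.mean() * 100.0
        assert clusters[0].population == pytest.approx(realized, abs=3.0)
        assert clusters[1].population == pytest.approx(100.0 - realized,
                                                       abs=3.0)

    def test_min_pop_filter(self):
        f, _ = self._two_state_surface()
        assert len(extract_basins(f, min_pop_pct=50.0)) == 1

    def test_representative_frame_is_member(self):
        f, lab = self._two_state_surface()
        for c in extract_basins(f):
            x, y = f.samples
            rx, ry = x[c.representative_frame], y[c.representative_frame]
            assert np.hypot(rx - c.centre[0], ry - c.centre[1]) < 0.1

    def test_populations_sum_bounded(self):
        f, _ = self._two_state_surface()
        total = sum(c.population for c in extract_basins(f, min_pop_pct=0.0))
        assert total <= 100.0 + 1e-9

    def test_surface_invariants(self):
        f, _ = self._two_state_surface()
        assert np.nanmin(f.values[~f.mask]) == 0.0
        assert np.all(np.isfinite(f.values[~f.mask]))


class TestHbondOccupancy:
    def test_ideal_helix_i_to_i4_saturated(self, alpha_helix_20):
        table = hbond_occupancy(_stack([alpha_helix_20] * 3))
        # every interior i -> i+4 pair is bonded in every frame and sits in
        # the saturated top block of the table
        i4 = table[table["donor"] - table["acceptor"] == 4]
        assert len(i4) == 16
        assert np.all(i4["occupancy_pct"] == 100.0)
        n_sat = int((table["occupancy_pct"] == 100.0).sum())
        assert np.all(table.head(n_sat)["occupancy_pct"] == 100.0)

    def test_extended_chain_empty(self, extended_20):
        assert hbond_occupancy(_stack([extended_20] * 2)).empty

    def test_zero_cutoff_empty(self, alpha_helix_20):
        assert hbond_occupancy(_stack([alpha_helix_20]), cutoff=0.0).empty
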