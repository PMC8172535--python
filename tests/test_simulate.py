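import numpy as np
import nibabel as nib
import pytest
from scipy import stats

import lesionatoms as la
from lesionatoms.parcellation import compute_lesion_loads


class TestAtlasPhantom:
    def test_forced_partition_2x2x2(self):
        labels, scheme = la.generate_atlas_phantom((2, 2, 2), 8, seed=0)
        assert sorted(labels.ravel()) == list(range(1, 9))
        assert 0 not in labels
        assert len(scheme) == 8

    def test_seeded_determinism(self):
        a, _ = la.generate_atlas_phantom((10, 10, 10), 4, seed=1)
        b, _ = la.generate_atlas_phantom((10, 10, 10), 4, seed=1)
        assert np.array_equal(a, b)

    def test_label_histogram(self):
        labels, _ = la.generate_atlas_phantom((10, 10, 10), 4, seed=2)
        counts = np.bincount(labels.ravel(), minlength=5)
        assert counts[1:5].sum() <= 1000
        assert np.all(counts[1:5] >= 1)

    def test_regions_contiguous_blocks(self):
        labels, _ = la.generate_atlas_phantom((6, 7, 8), 11, seed=3)
        for lab in range(1, 12):
            idx = np.argwhere(labels == lab)
            lo, hi = idx.min(axis=0), idx.max(axis=0)
            block = labels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
            assert np.all(block == lab)  # bounding box holds only the label

    def test_too_many_regions_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            la.generate_atlas_phantom((2, 2, 2), 9, seed=0)


class TestBasis:
    def test_identity_like_when_square(self):
        basis = la.generate_basis(6, 6, block_structure=True, seed=0)
        assert np.allclose(np.linalg.norm(basis, axis=1), 1.0)
        assert np.all((basis > 0).sum(axis=1) == 1)  # unit vectors

    def test_rows_unit_norm(self):
        basis = la.generate_basis(10, 129, seed=7)
        assert np.allclose(np.linalg.norm(basis, axis=1), 1.0, atol=1e-12)

    def test_pairwise_cosines_bounded(self):
        basis = la.generate_basis(10, 129, seed=7)
        gram = basis @ basis.T
        off = gram[~np.eye(10, dtype=bool)]
        assert np.all(off <= 0.3)

    def test_too_many_atoms_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            la.generate_basis(11, 10)


class TestCohort:
    def test_seeded_determinism(self):
        cfg = la.SimConfig(n_patients=80, seed=9)
        c1, l1, _ = la.generate_cohort(cfg)
        c2, l2, _ = la.generate_cohort(la.SimConfig(n_patients=80, seed=9))
        assert c1.equals(c2)
        assert np.array_equal(l1.values, l2.values)

    def test_degenerate_outcome_mean(self):
        """All effects zero, tiny noise: NIHSS concentrates at the
        intercept."""
        cfg = la.SimConfig(
            n_patients=2000, seed=1,
            beta_female=(0.0,) * 10, beta_male=(0.0,) * 10,
            covariate_effects={}, intercept=5.0, noise_sd=0.01)
        cohort, _, _ = la.generate_cohort(cfg)
        assert 4.9 <= cohort["nihss"].mean() <= 5.1

    def test_female_count_within_binomial_interval(self, default_cohort):
        """38% women at n=555: the observed count sits inside the central
        99% binomial interval."""
        _, cohort, _, _ = default_cohort
        lo, hi = stats.binom.ppf([0.005, 0.995], 555, 0.38)
        assert lo <= cohort["sex"].sum() <= hi

    def test_ages_truncated(self, default_cohort):
        _, cohort, _, _ = default_cohort
        assert cohort["age"].between(18, 100).all()

    def test_log1p_reconstruction(self, default_cohort):
        """log1p of the integer loads stays close to the planted
        low-rank pattern (relative Frobenius error <= 0.15)."""
        _, _, loads, truth = default_cohort
        target = truth.scores_true @ truth.basis_true
        err = np.linalg.norm(np.log1p(loads.values) - target)
        assert err / np.linalg.norm(target) <= 0.15

    def test_oracle_outcome_reproducible_from_truth(self, default_cohort):
        """The emitted oracle design reproduces the outcome up to the
        planted Gaussian noise scale."""
        cfg, _, _, truth = default_cohort
        inp = truth.oracle_input
        beta_by_patient = truth.beta_true[inp.sex.astype(int)]
        pred = ((inp.atom_scores * beta_by_patient).sum(axis=1)
                + inp.covariate_matrix() @ truth.covariate_beta_true)
        resid = inp.outcome - (pred - pred.mean())
        assert np.std(resid) == pytest.approx(cfg.noise_sd, rel=0.2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            la.SimConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            la.SimConfig(frac_female=1.5)
        with pytest.raises(ValueError):
            la.SimConfig(intercept=float("nan"))


class TestFixtureMasks:
    @pytest.fixture()
    def small_cohort_loads(self, scheme, small_atlases):
        gm, wm = small_atlases
        sizes = np.array([
            (gm == lab).sum() if src == "gm" else (wm == lab).sum()
            for src, lab in zip(scheme.table["source_atlas"],
                                scheme.table["atlas_label"])])
        rng = np.random.default_rng(11)
        values = rng.integers(0, sizes + 1, size=(4, scheme.n_parcels))
        values[0] = 0  # all-zero row
        return la.LesionLoadMatrix([f"p{i}" for i in range(4)], values,
                                   scheme), sizes

    def test_round_trip_exact(self, scheme, small_atlases, tmp_path,
                              small_cohort_loads):
        gm, wm = small_atlases
        loads, _ = small_cohort_loads
        paths = la.write_fixture_masks(loads, gm, wm, tmp_path, seed=11)
        for i, path in enumerate(paths):
            mask = np.asarray(nib.load(path).dataobj)
            got = compute_lesion_loads(mask, gm, wm, scheme)
            assert np.array_equal(got, loads.values[i])

    def test_zero_row_gives_zero_mask(self, small_atlases, tmp_path,
                                      small_cohort_loads):
        gm, wm = small_atlases
        loads, _ = small_cohort_loads
        paths = la.write_fixture_masks(loads, gm, wm, tmp_path, seed=1)
        assert np.asarray(nib.load(paths[0]).dataobj).sum() == 0

    def test_full_parcel_row(self, scheme, small_atlases, tmp_path):
        gm, wm = small_atlases
        label = int(scheme.table["atlas_label"].iloc[3])
        values = np.zeros((1, scheme.n_parcels), dtype=int)
        values[0, 3] = (gm == label).sum()
        loads = la.LesionLoadMatrix(["p0"], values, scheme)
        (path,) = la.write_fixture_masks(loads, gm, wm, tmp_path, seed=0)
        mask = np.asarray(nib.load(path).dataobj).astype(bool)
        assert np.array_equal(mask, gm == label)

    def test_oversized_request_names_parcel(self, scheme, small_atlases,
                                            tmp_path):
        gm, wm = small_atlases
        values = np.zeros((1, scheme.n_parcels), dtype=int)
        values[0, 0] = gm.size + 1
        loads = la.LesionLoadMatrix(["p0"], values, scheme)
        pid = str(scheme.table["parcel_id"].iloc[0])
        with pytest.raises(ValueError, match=f"parcel {pid}"):
            la.write_fixture_masks(loads, gm, wm, tmp_path, seed=0)
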