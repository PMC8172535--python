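import numpy as np
import pytest

import lesionatoms as la
from lesionatoms.design import ModelInput


def brute_force_hpdi(samples, mass=0.90):
    """Exhaustive scan over every contiguous sorted window."""
    s = np.sort(np.asarray(samples, float))
    n = s.size
    window = int(np.ceil(mass * n))
    best = None
    for i in range(n - window + 1):
        width = s[i + window - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + window - 1])
    return best[1], best[2]


def toy_input(n=60, n_atoms=4, seed=0, outcome=None):
    rng = np.random.default_rng(seed)
    sex = (np.arange(n) % 2).astype(float)
    scores = rng.normal(size=(n, n_atoms))
    if outcome is None:
        outcome = rng.normal(size=n)
    zeros = np.zeros(n)
    return ModelInput(outcome=outcome, atom_scores=scores,
                      age_z=rng.normal(size=n),
                      age_z_sq=rng.normal(size=n) ** 2, sex=sex,
                      hypertension=zeros, diabetes=zeros,
                      atrial_fibrillation=zeros,
                      coronary_artery_disease=zeros, log_wmhv=zeros)


class TestHPDI:
    def test_standard_normal_endpoints(self):
        rng = np.random.default_rng(123)
        draws = rng.standard_normal(100_000)
        lo, hi = la.hpdi(draws, 0.90)
        assert lo == pytest.approx(-1.645, abs=0.03)
        assert hi == pytest.approx(1.645, abs=0.03)

    def test_constant_samples_degenerate(self):
        lo, hi = la.hpdi(np.full(50, 2.5))
        assert (lo, hi) == (2.5, 2.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:
            samples = rng.standard_normal(200)
        elif kind == 1:
            samples = rng.exponential(2.0, 150)
        else:  # bimodal
            samples = np.r_[rng.normal(-3, 0.5, 80), rng.normal(3, 1.0, 90)]
        mass = [0.5, 0.9, 0.95][seed % 3]
        assert la.hpdi(samples, mass) == brute_force_hpdi(samples, mass)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="20"):
            la.hpdi(np.arange(10))

    def test_invalid_mass(self):
        with pytest.raises(ValueError, match="mass"):
            la.hpdi(np.arange(30), 1.2)


class TestSummaries:
    @pytest.fixture()
    def summary(self, single_effect_fit):
        _, post = single_effect_fit
        return post, la.summarize_posterior(post)

    def test_means_equal_direct_means(self, summary):
        post, summ = summary
        row = summ.row("alpha")
        assert row["mean"] == pytest.approx(post.draws["alpha"].mean(),
                                            abs=1e-12)
        row = summ.row("beta_atoms[female,10]")
        assert row["mean"] == pytest.approx(
            post.atom_draws("female")[:, 9].mean(), abs=1e-12)

    def test_relevance_flags(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0.5, 1.5, 500)
        sym = rng.normal(0, 1, 500)
        post = la.PosteriorSamples(
            draws={"alpha": pos, "eps": np.abs(sym) + 0.1,
                   "beta_age": sym},
            group_names=[])
        summ = la.summarize_posterior(post)
        assert bool(summ.row("alpha")["relevant"]) is True
        assert bool(summ.row("beta_age")["relevant"]) is False


class TestDifferenceDistribution:
    def test_identical_draws(self):
        x = np.random.default_rng(0).normal(size=400)
        d = la.difference_distribution(x, x)
        assert np.all(d["draws"] == 0)
        assert d["flag"] is False

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=300), rng.normal(1.0, 1, 300)
        dab = la.difference_distribution(a, b)
        dba = la.difference_distribution(b, a)
        assert np.allclose(dab["draws"], -dba["draws"])
        assert dab["mean"] == pytest.approx(-dba["mean"])

    def test_tail_prob_counts_opposing_signs(self):
        draws_m = np.r_[np.full(90, 2.0), np.full(10, -1.0)]
        d = la.difference_distribution(draws_m, np.zeros(100))
        assert d["tail_prob"] == pytest.approx(0.10)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            la.difference_distribution(np.zeros(30), np.zeros(31))


class TestHierarchicalFit:
    def test_recovers_planted_female_effect(self, single_effect_fit):
        """Planted female-only effect of 3 NIHSS units on atom 10 at
        n=555 (38% women): recovered within 0.75 and flagged."""
        truth, post = single_effect_fit
        bf = post.atom_draws("female")
        assert bf[:, 9].mean() == pytest.approx(3.0, abs=0.75)
        lo, hi = la.hpdi(bf[:, 9])
        assert lo > 0
        bm = post.atom_draws("male")
        assert np.max(np.abs(bm.mean(axis=0))) <= 0.5
        tab = la.sex_difference_table(post)
        assert bool(tab.loc[9, "flag"]) is True

    def test_diagnostics_reported(self, single_effect_fit):
        _, post = single_effect_fit
        diag = post.diagnostics
        assert 0 < diag["acceptance_fraction"] < 1
        assert diag["max_rhat"] < 1.05
        assert "beta[female,10]" in diag["rhat"]

    def test_degenerate_zero_outcome(self):
        """All-zero outcome: every coefficient posterior sits at zero."""
        inp = toy_input(n=100, outcome=np.zeros(100))
        post = la.fit_hierarchical_model(
            inp, la.ModelSpec(draws=800, warmup=600, seed=2))
        beta = post.draws["beta_atoms"]
        assert np.max(np.abs(beta.mean(axis=0))) < 0.1

    def test_pooled_consistent_with_by_sex_average(self):
        """With identical generative coefficients in the two sexes the
        pooled atom means track the average of the sex-specific ones."""
        common = (0.0, 1.5, 0.0, 1.9, 0.0, 1.2, 3.2, 2.4, 0.0, 0.0)
        cfg = la.SimConfig(seed=21, beta_female=common, beta_male=common)
        _, _, truth = la.generate_cohort(cfg)
        pooled = la.fit_hierarchical_model(
            truth.oracle_input,
            la.ModelSpec(hierarchy="pooled", draws=1200, seed=5))
        by_sex = la.fit_hierarchical_model(
            truth.oracle_input,
            la.ModelSpec(hierarchy="by_sex", draws=1200, seed=5))
        bp = pooled.atom_draws("all").mean(axis=0)
        bs = 0.5 * (by_sex.atom_draws("male").mean(axis=0)
                    + by_sex.atom_draws("female").mean(axis=0))
        assert np.max(np.abs(bp - bs)) <= 0.3

    def test_empty_group_rejected(self):
        inp = toy_input(n=30)
        inp.sex = np.zeros(30)
        with pytest.raises(ValueError, match="empty"):
            la.fit_hierarchical_model(
                inp, la.ModelSpec(draws=100, warmup=10))

    def test_seeded_reproducibility(self):
        inp = toy_input(n=50, seed=4)
        spec = la.ModelSpec(draws=300, warmup=200, seed=9)
        a = la.fit_hierarchical_model(inp, spec)
        b = la.fit_hierarchical_model(inp, spec)
        assert np.array_equal(a.draws["beta_atoms"], b.draws["beta_atoms"])
        assert np.array_equal(a.draws["eps"], b.draws["eps"])

    def test_near_uninformative_data_keeps_prior_scale(self):
        """With two patients the atom-coefficient posterior stays on the
        prior's scale instead of the data-driven ~0.1."""
        inp = toy_input(n=2, n_atoms=2, seed=6)
        inp.sex = np.array([0.0, 1.0])
        post = la.fit_hierarchical_model(
            inp, la.ModelSpec(draws=1500, warmup=1500, seed=3))
        sds = post.draws["beta_atoms"].std(axis=0)
        assert np.all(sds > 1.0)

    def test_flat_atom_priors_still_recover(self):
        """With the hierarchy switched off (independent wide priors on the
        atom coefficients) a strong planted effect is still recovered."""
        cfg = la.SimConfig(n_patients=300, seed=44,
                           beta_female=(0.0,) * 9 + (3.0,),
                           beta_male=(0.0,) * 10)
        _, _, truth = la.generate_cohort(cfg)
        post = la.fit_hierarchical_model(
            truth.oracle_input,
            la.ModelSpec(draws=1200, seed=4, atom_prior_via_hierarchy=False))
        assert post.atom_draws("female")[:, 9].mean() == pytest.approx(
            3.0, abs=0.9)

    def test_scale_draws_positive(self, single_effect_fit):
        _, post = single_effect_fit
        assert np.all(post.draws["eps"] > 0)
        assert np.all(post.draws["sigma_beta"] > 0)
        assert np.all(post.draws["hyper_sigma_beta"] > 0)


class TestStratifiedFit:
    def test_single_stratum_reduces_to_by_sex(self):
        cfg = la.SimConfig(n_patients=300, seed=31,
                           beta_female=(0.0,) * 9 + (3.0,),
                           beta_male=(0.0,) * 10)
        _, _, truth = la.generate_cohort(cfg)
        inp = truth.oracle_input
        inp.stratum = np.array(["A"] * inp.n_patients)
        strat = la.fit_stratified_model(
            inp, la.ModelSpec(hierarchy="stratified_by_sex", draws=1200,
                              seed=7))
        flat = la.fit_hierarchical_model(
            inp, la.ModelSpec(hierarchy="by_sex", draws=1200, seed=7))
        for sex in ("male", "female"):
            diff = (strat.atom_draws(f"A:{sex}").mean(axis=0)
                    - flat.atom_draws(sex).mean(axis=0))
            assert np.max(np.abs(diff)) <= 0.3

    def test_stratum_specific_effect_detected(self):
        """Female-only effect planted in stratum A only is flagged there
        and not in stratum B."""
        rng = np.random.default_rng(17)
        parts = []
        for stratum, delta in (("A", 3.0), ("B", 0.0)):
            cfg = la.SimConfig(
                n_patients=400, seed=int(rng.integers(2 ** 31)),
                beta_female=(0.0,) * 9 + (delta,),
                beta_male=(0.0,) * 10)
            _, _, truth = la.generate_cohort(cfg)
            parts.append((stratum, truth.oracle_input))
        inp = _concat_inputs(parts)
        post = la.fit_stratified_model(
            inp, la.ModelSpec(hierarchy="stratified_by_sex", draws=1500,
                              seed=13))
        d_a = la.difference_distribution(post.atom_draws("A:male")[:, 9],
                                         post.atom_draws("A:female")[:, 9])
        d_b = la.difference_distribution(post.atom_draws("B:male")[:, 9],
                                         post.atom_draws("B:female")[:, 9])
        assert d_a["flag"] is True
        assert d_b["flag"] is False

    def test_small_cell_rejected(self):
        inp = toy_input(n=30)
        inp.stratum = np.array(["A"] * 29 + ["B"])
        with pytest.raises(ValueError, match="B:"):
            la.fit_stratified_model(
                inp, la.ModelSpec(hierarchy="stratified_by_sex",
                                  draws=100, warmup=10))


def _concat_inputs(parts):
    fields = ("outcome", "atom_scores", "age_z", "age_z_sq", "sex",
              "hypertension", "diabetes", "atrial_fibrillation",
              "coronary_artery_disease", "log_wmhv")
    kwargs = {f: np.concatenate([getattr(inp, f) for _, inp in parts])
              for f in fields}
    kwargs["stratum"] = np.concatenate(
        [np.full(inp.n_patients, s) for s, inp in parts])
    return ModelInput(**kwargs)
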