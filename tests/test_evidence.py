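"""Grid engine: discretization, RB, LRSE, regions, strength, Bayes factor."""

import numpy as np
import pytest
from scipy import stats

import relbelief as rb
from relbelief.evidence import DEFAULT_GRID_SIZE

# exact reference quantities for the packaged 20-flip / beta(4,4) analysis,
# computed by root-finding on the closed-form RB curve and exact beta cdfs
EXACT_RB_HALF = 1.42101778302874
EXACT_STRENGTH = 0.3105262032912090
EXACT_REGION = (0.2265040030797680, 0.5926348590572834)


def two_cell_belief(prior=(0.5, 0.5), posterior=(0.75, 0.25)):
    return rb.DiscretizedBelief(
        edges=np.array([0.0, 0.5, 1.0]),
        prior_mass=np.array(prior),
        posterior_mass=np.array(posterior),
    )


class TestDiscretize:
    def test_masses_normalized(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=2000, bounds=(0, 1))
        assert belief.prior_mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert belief.posterior_mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_data_prior_equals_posterior(self):
        m = rb.BetaBernoulli(4, 4, 0, 0)
        belief = rb.discretize(m, grid_size=512)
        assert np.allclose(belief.prior_mass, belief.posterior_mass)

    def test_cell_mass_matches_cdf_oracle(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=4096, bounds=(0, 1))
        i_lo = belief.cell_index(0.45)
        i_hi = belief.cell_index(0.55)
        mass = belief.posterior_mass[i_lo : i_hi + 1].sum()
        post = stats.beta(12, 16)
        oracle = post.cdf(belief.edges[i_hi + 1]) - post.cdf(belief.edges[i_lo])
        assert mass == pytest.approx(oracle, rel=1e-6)

    def test_truncating_bounds_recorded_as_warning(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=256, bounds=(0.3, 0.5))
        assert any("capture" in w for w in belief.warnings)

    def test_posterior_mass_on_zero_prior_cell_rejected(self):
        with pytest.raises(ValueError, match="zero-prior"):
            rb.DiscretizedBelief(
                edges=np.array([0.0, 0.5, 1.0]),
                prior_mass=np.array([1.0, 0.0]),
                posterior_mass=np.array([0.5, 0.5]),
            )


class TestRelativeBelief:
    def test_prior_equals_posterior_gives_unit_rb(self):
        belief = two_cell_belief(posterior=(0.5, 0.5))
        assert np.allclose(rb.relative_belief(belief).rb, 1.0)

    def test_two_cell_forced_arithmetic(self):
        rbf = rb.relative_belief(two_cell_belief())
        assert np.allclose(rbf.rb, [1.5, 0.5])

    def test_reference_value_in_cell_containing_half(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=DEFAULT_GRID_SIZE, bounds=(0, 1))
        rbf = rb.relative_belief(belief)
        assert rbf.rb[belief.cell_index(0.5)] == pytest.approx(1.421, abs=2e-3)

    def test_normalization_invariant(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=1024)
        rbf = rb.relative_belief(belief)
        total = np.sum(rbf.rb[rbf.defined_mask] * belief.prior_mass[rbf.defined_mask])
        assert total == pytest.approx(1.0, abs=1e-6)


class TestLrse:
    def test_reference_estimate_is_sample_mean(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=DEFAULT_GRID_SIZE, bounds=(0, 1))
        est = rb.lrse(rb.relative_belief(belief))
        assert est.psi == pytest.approx(0.400, abs=1 / DEFAULT_GRID_SIZE)
        assert not est.tied

    def test_total_tie_returns_first_cell_with_flag(self):
        belief = two_cell_belief(posterior=(0.5, 0.5))
        est = rb.lrse(rb.relative_belief(belief))
        assert est.psi == pytest.approx(0.25)
        assert est.tied

    def test_unique_max_two_cells(self):
        est = rb.lrse(rb.relative_belief(two_cell_belief()))
        assert est.psi == pytest.approx(0.25)
        assert not est.tied


@pytest.fixture(scope="module")
def coin_grid(coin_model):
    belief = rb.discretize(coin_model, grid_size=DEFAULT_GRID_SIZE, bounds=(0, 1))
    return belief, rb.relative_belief(belief)


class TestCredibleRegion:
    def test_reference_95_region(self, coin_grid):
        belief, rbf = coin_grid
        region = rb.credible_region(rbf, belief, 0.95)
        assert len(region.intervals) == 1
        (lo, hi), = region.intervals
        w = 1 / DEFAULT_GRID_SIZE
        assert lo == pytest.approx(EXACT_REGION[0], abs=w)
        assert hi == pytest.approx(EXACT_REGION[1], abs=w)
        assert region.content >= 0.95
        assert (hi - lo) == pytest.approx(0.366, abs=2e-3)

    def test_gamma_zero_is_lrse_cell(self, coin_grid):
        belief, rbf = coin_grid
        region = rb.credible_region(rbf, belief, 0.0)
        est = rb.lrse(rbf)
        assert est.psi in region
        assert region.total_length <= 2 / DEFAULT_GRID_SIZE

    def test_gamma_one_is_all_defined_cells(self, coin_grid):
        belief, rbf = coin_grid
        region = rb.credible_region(rbf, belief, 1.0)
        covered = sum(
            belief.cell_widths[rbf.defined_mask & (rbf.rb >= region.threshold)]
        )
        assert region.total_length == pytest.approx(covered)
        assert region.content == pytest.approx(1.0, abs=1e-9)

    def test_nesting_in_gamma_and_lrse_membership(self, coin_grid):
        belief, rbf = coin_grid
        est = rb.lrse(rbf)
        prev_lo, prev_hi = None, None
        for gamma in (0.0, 0.25, 0.5, 0.75, 0.9, 0.99, 1.0):
            region = rb.credible_region(rbf, belief, gamma)
            assert est.psi in region
            lo = min(iv[0] for iv in region.intervals)
            hi = max(iv[1] for iv in region.intervals)
            if prev_lo is not None:
                assert lo <= prev_lo + 1e-12 and hi >= prev_hi - 1e-12
            prev_lo, prev_hi = lo, hi


class TestStrength:
    def test_reference_strength(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=DEFAULT_GRID_SIZE, bounds=(0, 1))
        rbf = rb.relative_belief(belief)
        st = rb.strength(rbf, belief, 0.5)
        assert st.strength == pytest.approx(0.309, abs=3e-3)
        assert st.strength == pytest.approx(EXACT_STRENGTH, abs=1e-3)

    def test_at_lrse_strength_is_one(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=1024, bounds=(0, 1))
        rbf = rb.relative_belief(belief)
        est = rb.lrse(rbf)
        st = rb.strength(rbf, belief, est.psi)
        assert st.strength == pytest.approx(1.0, abs=1e-9)

    def test_two_cell_forced_arithmetic(self):
        belief = two_cell_belief()
        rbf = rb.relative_belief(belief)
        st = rb.strength(rbf, belief, 0.75)  # the rb = 0.5 cell
        assert st.strength == pytest.approx(0.25)
        assert st.tie_mass == pytest.approx(0.25)

    def test_markov_chain_inequality_randomized(self):
        # tie mass <= strength <= RB(psi0) over random configurations
        rng = np.random.default_rng(20160107)
        for _ in range(200):
            a0, b0 = rng.uniform(0.5, 8, size=2)
            n = int(rng.integers(1, 60))
            s = int(rng.integers(0, n + 1))
            m = rb.BetaBernoulli(a0, b0, n, s)
            belief = rb.discretize(m, grid_size=512)
            rbf = rb.relative_belief(belief)
            psi0 = float(
                rng.uniform(belief.edges[5], belief.edges[-6])
            )
            r0 = rbf.at(psi0)
            st = rb.strength(rbf, belief, psi0)
            assert st.tie_mass <= st.strength + 1e-12
            assert st.strength <= r0 * (1 + 1e-6) + 1e-9

    def test_undefined_cell_rejected(self):
        belief = rb.DiscretizedBelief(
            edges=np.array([0.0, 0.5, 1.0]),
            prior_mass=np.array([1.0, 0.0]),
            posterior_mass=np.array([1.0, 0.0]),
        )
        rbf = rb.relative_belief(belief)
        with pytest.raises(ValueError):
            rb.strength(rbf, belief, 0.75)


class TestBayesFactor:
    def test_forced_odds_ratio(self):
        belief = two_cell_belief()
        bf = rb.bayes_factor(belief, [True, False])
        assert bf == pytest.approx(3.0)

    def test_full_space_undefined(self):
        belief = two_cell_belief()
        assert np.isnan(rb.bayes_factor(belief, [True, True]))

    def test_interval_matches_cdf_oracle(self, coin_model):
        belief = rb.discretize(coin_model, grid_size=4096, bounds=(0, 1))
        i_lo, i_hi = belief.cell_index(0.45), belief.cell_index(0.55)
        mask = np.zeros(belief.n_cells, dtype=bool)
        mask[i_lo : i_hi + 1] = True
        lo_e, hi_e = belief.edges[i_lo], belief.edges[i_hi + 1]
        post, prior = stats.beta(12, 16), stats.beta(4, 4)
        qa = post.cdf(hi_e) - post.cdf(lo_e)
        pa = prior.cdf(hi_e) - prior.cdf(lo_e)
        oracle = (qa / (1 - qa)) / (pa / (1 - pa))
        assert rb.bayes_factor(belief, mask) == pytest.approx(oracle, rel=1e-5)


class TestGridConvergence:
    def test_refinement_is_cauchy(self, coin_model):
        # doubling the grid moves RB(1/2), the strength, and the region
        # endpoints by less than the coarser grid's cell width
        results = {}
        for size in (2048, 4096):
            belief = rb.discretize(coin_model, grid_size=size, bounds=(0, 1))
            rbf = rb.relative_belief(belief)
            region = rb.credible_region(rbf, belief, 0.95)
            results[size] = (
                rbf.at(0.5),
                rb.strength(rbf, belief, 0.5).strength,
                region.intervals[0],
            )
        w = 1 / 2048
        assert abs(results[2048][0] - results[4096][0]) < w
        assert abs(results[2048][1] - results[4096][1]) < w
        for a, b in zip(results[2048][2], results[4096][2]):
            assert abs(a - b) <= w + 1e-12

    def test_reparameterization_invariance(self, coin_model):
        # RB of psi = g(theta) at g-transformed grid points equals RB of
        # theta at the matching points: the Jacobian cancels in the
        # mass ratio, so corresponding cells carry identical ratios
        edges = np.linspace(0.01, 0.99, 1025)
        prior, post = coin_model.prior_dist(), coin_model.posterior_dist()

        def belief_from_edges(e_theta):
            pm = np.diff(prior.cdf(e_theta))
            qm = np.diff(post.cdf(e_theta))
            return rb.DiscretizedBelief(
                edges=np.sort(e_theta) if e_theta[0] < e_theta[-1] else e_theta,
                prior_mass=pm / pm.sum(),
                posterior_mass=qm / qm.sum(),
            )

        base = belief_from_edges(edges)
        rbf_theta = rb.relative_belief(base)
        # strictly monotone smooth map g(theta) = theta**2
        g_edges = edges**2
        transformed = rb.DiscretizedBelief(
            edges=g_edges,
            prior_mass=base.prior_mass,
            posterior_mass=base.posterior_mass,
        )
        rbf_psi = rb.relative_belief(transformed)
        assert np.allclose(rbf_theta.rb, rbf_psi.rb, rtol=1e-12)


class TestMonteCarloMarginal:
    def test_matches_closed_form_at_identity(self, coin_model):
        belief = rb.mc_marginal_belief(
            prior_sampler=lambda rng, k: rng.beta(4, 4, size=k),
            likelihood=lambda t: t**8 * (1 - t) ** 12,
            psi_map=lambda t: t,
            bins=200,
            draws=1_000_000,
            seed=11,
        )
        rbf = rb.relative_belief(belief)
        r_half = rbf.at(0.5)
        assert r_half == pytest.approx(1.421, abs=0.05)
        # within 3 binomial-ish standard errors of the closed form
        i = belief.cell_index(0.5)
        n_prior = belief.prior_mass[i] * 1_000_000
        se = 1.421 / np.sqrt(n_prior)
        assert abs(r_half - coin_model.rb(0.5)) < 3 * se

    def test_constant_likelihood_gives_unit_rb(self):
        belief = rb.mc_marginal_belief(
            prior_sampler=lambda rng, k: rng.beta(2, 5, size=k),
            likelihood=lambda t: np.ones_like(t),
            psi_map=lambda t: t,
            bins=50,
            draws=200_000,
            seed=3,
        )
        rbf = rb.relative_belief(belief)
        assert np.allclose(rbf.rb[rbf.defined_mask], 1.0, atol=1e-9)

    def test_mirror_symmetry_of_transformed_parameter(self, coin_model):
        # psi = 1 - theta with s and n - s swapped mirror-images the
        # identity-case RB curve
        kwargs = dict(bins=100, draws=400_000, seed=5)
        direct = rb.mc_marginal_belief(
            prior_sampler=lambda rng, k: rng.beta(4, 4, size=k),
            likelihood=lambda t: t**8 * (1 - t) ** 12,
            psi_map=lambda t: t,
            **kwargs,
        )
        mirrored = rb.mc_marginal_belief(
            prior_sampler=lambda rng, k: rng.beta(4, 4, size=k),
            likelihood=lambda t: t**12 * (1 - t) ** 8,
            psi_map=lambda t: 1 - t,
            **kwargs,
        )
        rbf_d = rb.relative_belief(direct)
        rbf_m = rb.relative_belief(mirrored)
        for psi in (0.3, 0.4, 0.5, 0.6):
            assert rbf_d.at(psi) == pytest.approx(rbf_m.at(psi), abs=0.1)

    def test_deterministic_given_seed(self):
        def build():
            return rb.mc_marginal_belief(
                prior_sampler=lambda rng, k: rng.beta(4, 4, size=k),
                likelihood=lambda t: t**2,
                psi_map=lambda t: t,
                bins=20,
                draws=10_000,
                seed=42,
            )

        a, b = build(), build()
        assert np.array_equal(a.posterior_mass, b.posterior_mass)

    def test_low_ess_warning(self):
        belief = rb.mc_marginal_belief(
            prior_sampler=lambda rng, k: rng.beta(1, 1, size=k),
            likelihood=lambda t: (t > 0.9999).astype(float) + 1e-300,
            psi_map=lambda t: t,
            bins=10,
            draws=10_000,
            seed=1,
        )
        assert any("effective sample size" in w for w in belief.warnings)
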