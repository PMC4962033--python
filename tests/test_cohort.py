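"""Cohort analyses: reference band, LDI, tau distributions, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.mixture import GaussianMixture

from lungflow4d import (
    DiseaseConfig,
    SubjectSummary,
    cluster_phenotypes,
    compare_groups,
    distribution_stats,
    fit_reference,
    lung_disease_index,
)
from lungflow4d.pipeline import simulate_endpoint_metrics

SEVERE = dict(diseased_tau_mean=0.35, diseased_tau_sd=0.02)  # non-emptying regions


def frame(tv_norm, pef_norm, v_ee=1.0):
    n = len(tv_norm)
    return pd.DataFrame({
        "endpoint_id": np.arange(n),
        "tv_norm": tv_norm,
        "pef_norm": pef_norm,
        "v_ee": np.broadcast_to(v_ee, (n,)).astype(float),
        "missing": False,
        "non_ventilated": False,
    })


@pytest.fixture(scope="module")
def healthy_model():
    dfs = [simulate_endpoint_metrics(256, DiseaseConfig.healthy(seed=100 + s))[0]
           for s in range(6)]
    return fit_reference(pd.concat(dfs, ignore_index=True)), dfs


class TestFitReference:
    def test_noiseless_quadratic_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.05, 0.3, 80)
        y = 2.0 - 3.0 * x + 10.0 * x**2
        model = fit_reference(frame(x, y), degree=2)
        assert np.allclose(model.coefficients, [10.0, -3.0, 2.0], atol=1e-8)
        below = y < model.lower_bound(x)
        assert not below.any()

    def test_default_level_99(self):
        x = np.linspace(0.05, 0.3, 30)
        model = fit_reference(frame(x, 1 + x), degree=1)
        assert model.level == 0.99

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_reference(frame(np.full(30, 0.2), np.linspace(1, 2, 30)))

    def test_lower_tail_mass_matches_direct_simulation(self):
        """Fraction of fresh healthy draws below the lower 99% two-sided
        prediction bound ~ 0.5% (Monte-Carlo oracle, 10^4 draws)."""
        rng = np.random.default_rng(7)
        sigma = 0.4
        x = rng.uniform(0.05, 0.3, 2000)
        y = 8.0 - 10.0 * x + 5.0 * x**2 + rng.normal(scale=sigma, size=x.size)
        model = fit_reference(frame(x, y), degree=2)
        xf = rng.uniform(0.05, 0.3, 10_000)
        yf = 8.0 - 10.0 * xf + 5.0 * xf**2 + rng.normal(scale=sigma, size=xf.size)
        below = (yf < model.lower_bound(xf)).mean()
        assert 0.001 <= below <= 0.012

    def test_serialization_round_trip(self, tmp_path, healthy_model):
        model, _ = healthy_model
        p = tmp_path / "model.txt"
        model.to_text(p)
        from lungflow4d.cohort import CohortModel

        back = CohortModel.from_text(p)
        x = np.linspace(*model.support, 20)
        assert np.allclose(back.lower_bound(x), model.lower_bound(x))


class TestLungDiseaseIndex:
    def test_all_above_bound_zero(self, healthy_model):
        model, _ = healthy_model
        x = np.linspace(*model.support, 50)
        df = frame(x, model.predict(x) + 1.0)
        assert lung_disease_index(df, model) == 0.0

    def test_constructed_thirty_percent(self, healthy_model):
        model, _ = healthy_model
        x = np.full(10, np.mean(model.support))
        pef = np.r_[np.full(3, -100.0), model.predict(x[:7]) + 5.0]
        v_ee = np.full(10, 10.0)
        df = frame(x, pef, v_ee=1.0)
        df["v_ee"] = v_ee  # 30 below / 100 total
        assert lung_disease_index(df, model) == pytest.approx(30.0)

    def test_invariant_to_volume_rescaling(self, healthy_model):
        model, dfs = healthy_model
        df = dfs[0].copy()
        a = lung_disease_index(df, model)
        df["v_ee"] *= 37.0
        assert lung_disease_index(df, model) == pytest.approx(a)

    def test_zero_total_volume_rejected(self, healthy_model):
        model, _ = healthy_model
        df = frame(np.linspace(0.1, 0.2, 5), np.full(5, 8.0), v_ee=0.0)
        with pytest.raises(ValueError):
            lung_disease_index(df, model)

    def test_healthy_cohort_near_zero(self, healthy_model):
        model, dfs = healthy_model
        for df in dfs:
            assert lung_disease_index(df, model) <= 2.0

    def test_planted_fraction_recovered_and_monotone(self, healthy_model):
        """Severely degraded endpoints supplying 40% of volume give
        LDI = 40 +- 5; LDI is monotone in the planted fraction."""
        model, _ = healthy_model
        ldis = []
        for frac in (0.1, 0.2, 0.4):
            dis = DiseaseConfig(diseased_volume_fraction=frac, seed=777, **SEVERE)
            df, _ = simulate_endpoint_metrics(256, dis)
            ldis.append(lung_disease_index(df, model))
        assert ldis == sorted(ldis)
        assert ldis[2] == pytest.approx(40.0, abs=5.0)


class TestDistributionStats:
    def test_constant_list_zero_sd(self):
        st = distribution_stats([0.12, 0.12, 0.12])
        assert st.sd == 0.0 and st.median == 0.12

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            distribution_stats([0.1])

    def test_histogram_counts_match_manual_tally(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.01, 0.29, 200)
        st = distribution_stats(vals, bin_width=0.02, t_exp=0.30)
        for i, (lo, hi) in enumerate(zip(st.bin_edges[:-1], st.bin_edges[1:])):
            manual = np.sum((vals >= lo) & (vals < hi)) if i < len(st.counts) - 1 \
                else np.sum((vals >= lo) & (vals <= hi))
            assert st.counts[i] == manual

    def test_healthy_tau_population_recovered(self):
        """Configured healthy population (mean 0.12 s, sd 0.022 s) is
        recovered from the drawn tau values within 3 standard errors at
        256 endpoints (a sampling property of the generator)."""
        from lungflow4d import VentilationProtocol, generate_tree, simulate_compartments

        tree = generate_tree(8, domain=((0, 0, 0), (1e6, 1e6, 1e6)), seed=0)
        sim = simulate_compartments(tree, VentilationProtocol(),
                                    DiseaseConfig.healthy(seed=21))
        st = distribution_stats(sim.taus)
        n = len(sim.taus)
        assert abs(st.mean - 0.12) < 3 * 0.022 / np.sqrt(n)
        assert abs(st.sd - 0.022) < 3 * 0.022 / np.sqrt(2 * (n - 1))

    def test_bimodal_population_modes_recovered(self):
        """Two-component Gaussian fit on the drawn tau population of a
        diseased subject recovers both configured modes within 0.02 s."""
        from lungflow4d import VentilationProtocol, generate_tree, simulate_compartments

        tree = generate_tree(9, domain=((0, 0, 0), (1e6, 1e6, 1e6)), seed=0)
        sim = simulate_compartments(
            tree, VentilationProtocol(),
            DiseaseConfig.bimodal_diseased(seed=2, blockage_fraction=0.0))
        gm = GaussianMixture(2, random_state=0, n_init=5).fit(sim.taus.reshape(-1, 1))
        means = np.sort(gm.means_.ravel())
        assert means[0] == pytest.approx(0.13, abs=0.02)
        assert means[1] == pytest.approx(0.22, abs=0.02)


def summaries_from(points, group="healthy"):
    return [SubjectSummary(f"s{i}", group, float(m), float(s), float(m), float(m),
                           0.0, 1000.0)
            for i, (m, s) in enumerate(points)]


class TestClustering:
    def planted(self, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0.10, 0.01], [0.20, 0.01], [0.10, 0.05], [0.22, 0.06]])
        pts, labels = [], []
        for k, c in enumerate(centers):
            pts.append(c + rng.normal(scale=0.003, size=(8, 2)))
            labels += [k] * 8
        return np.vstack(pts), np.array(labels), centers

    def test_planted_clusters_recovered_up_to_permutation(self):
        pts, labels, centers = self.planted()
        res = cluster_phenotypes(summaries_from(pts), k=4, seed=3)
        # every planted group lands in exactly one recovered cluster
        for k in range(4):
            assert len(set(res.labels[labels == k])) == 1
        assert len(set(res.labels)) == 4

    def test_centroids_match_lloyd_from_planted_centers(self):
        """Recovered centroids equal a brute-force Lloyd iteration started
        at the planted centers (independent oracle)."""
        pts, _, centers = self.planted()
        res = cluster_phenotypes(summaries_from(pts), k=4, seed=3)
        c = centers.astype(float).copy()
        for _ in range(100):
            d = ((pts[:, None, :] - c[None]) ** 2).sum(axis=2)
            lab = d.argmin(axis=1)
            c_new = np.array([pts[lab == k].mean(axis=0) for k in range(4)])
            if np.allclose(c_new, c):
                break
            c = c_new
        got = sorted(map(tuple, np.round(res.centers, 10)))
        want = sorted(map(tuple, np.round(c, 10)))
        assert np.allclose(got, want, atol=1e-8)

    def test_angle_zero_on_positive_median_axis(self):
        """A subject whose sd equals the cohort-mean sd and whose median
        exceeds the cohort-mean median sits at angle 0 from P."""
        # four symmetric subjects with mean sd 0.02, plus the probe at the
        # same sd: P_sd = 0.02, so the probe lies on the +median axis
        pts = np.array([[0.10, 0.01], [0.10, 0.03], [0.14, 0.01], [0.14, 0.03],
                        [0.30, 0.02]])
        res = cluster_phenotypes(summaries_from(pts), k=2, seed=0)
        assert res.point_p[1] == pytest.approx(0.02)
        assert pts[-1, 0] > res.point_p[0]
        assert res.angles[-1] == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        pts, _, _ = self.planted(seed=5)
        a = cluster_phenotypes(summaries_from(pts), k=4, seed=11)
        b = cluster_phenotypes(summaries_from(pts), k=4, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.centers, b.centers)

    def test_k_exceeding_subjects_rejected(self):
        pts = np.array([[0.1, 0.02], [0.2, 0.03]])
        with pytest.raises(ValueError):
            cluster_phenotypes(summaries_from(pts), k=4)


class TestCompareGroups:
    def test_identical_groups(self):
        t, df, p = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_pooled_t_closed_form(self):
        """{1,2,3} vs {2,3,4}: pooled-variance t = -1.2247 on 4 degrees of
        freedom; two-sided p from the t-distribution tail."""
        t, df, p = compare_groups([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224745, abs=1e-5)
        assert df == 4
        # oracle: pooled t and the t(4) tail, p = 2 * (1 - F_t4(1.2247))
        assert p == pytest.approx(0.28786, abs=1e-4)

    def test_welch_option(self):
        t, df, p = compare_groups([1, 2, 3], [2, 3, 4, 10, 20], welch=True)
        assert np.isfinite(t) and 0 < p < 1

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
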