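"""Rarefaction, specificity, Bray-Curtis, NMDS, Mantel, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from vtaxa import community_stats as cs
from vtaxa.occurrence import IncidenceMatrix


def im(cols: dict) -> IncidenceMatrix:
    return IncidenceMatrix(counts=pd.DataFrame(cols))


class TestRarefaction:
    labels = ["v1"] * 10 + ["v2"] * 5 + ["v3"] * 2 + ["v4"]

    def test_full_depth_equals_observed_richness(self):
        curve = cs.rarefaction(self.labels, n_iter=50, seed=1)
        assert curve.mean_richness[-1] == 4
        assert curve.ci_high[-1] - curve.ci_low[-1] == 0

    def test_depth_one_expects_one(self):
        curve = cs.rarefaction(self.labels, n_iter=50, seed=1, depths=[1])
        assert curve.mean_richness[0] == 1.0
        assert curve.expected[0] == pytest.approx(1.0)

    def test_monotone_nondecreasing_mean(self):
        curve = cs.rarefaction(self.labels, n_iter=200, seed=2)
        assert (np.diff(curve.mean_richness) >= -1e-12).all()

    def test_randomized_agrees_with_hypergeometric(self):
        curve = cs.rarefaction(self.labels, n_iter=1000, seed=3)
        dev = np.abs(curve.mean_richness - curve.expected)
        assert (dev <= 3 * curve.mc_se + 1e-9).all()

    def test_depth_beyond_total_raises(self):
        with pytest.raises(ValueError):
            cs.rarefaction(["a", "b"], depths=[5])


class TestSpecificity:
    def test_all_single_column(self):
        overall, _ = cs.specificity(im({"c1": [1, 2, 3], "c2": [0, 0, 0]}))
        assert overall == 1.0

    def test_three_of_four_specific(self):
        m = im({"c1": [1, 0, 0, 2], "c2": [0, 1, 0, 1], "c3": [0, 0, 4, 0]})
        overall, per_col = cs.specificity(m)
        assert overall == 0.75

    def test_per_column_fraction(self):
        # c1 holds 4 VTs, 2 exclusive
        m = im({"c1": [1, 1, 1, 1], "c2": [1, 1, 0, 0]})
        _, per_col = cs.specificity(m)
        assert per_col["c1"] == 0.5

    def test_overall_equals_mean_indicator(self):
        rng = np.random.default_rng(0)
        m = im({f"c{i}": rng.integers(0, 3, 12) for i in range(4)})
        pres = m.presence
        occupied = pres[pres.sum(axis=1) > 0]
        overall, _ = cs.specificity(m)
        assert overall == pytest.approx((occupied.sum(axis=1) == 1).mean())

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            cs.specificity(im({"c1": [0, 0]}))


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        dm = cs.bray_curtis(im({"a": [1, 2], "b": [1, 2]}))
        assert dm["a", "b"] == 0.0

    def test_disjoint_support_one(self):
        dm = cs.bray_curtis(im({"a": [3, 0], "b": [0, 5]}))
        assert dm["a", "b"] == 1.0

    def test_formula_example(self):
        dm = cs.bray_curtis(im({"a": [1, 2], "b": [2, 1]}))
        assert dm["a", "b"] == pytest.approx(1 / 3)

    def test_matches_scipy_oracle(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 10, (6, 4)), columns=list("abcd"))
        dm = cs.bray_curtis(IncidenceMatrix(counts=counts), by="columns")
        for a in "abcd":
            for b in "abcd":
                if a < b:
                    assert dm[a, b] == pytest.approx(
                        braycurtis(counts[a], counts[b])
                    )

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 5, (8, 5)))
        dm = cs.bray_curtis(IncidenceMatrix(counts=counts))
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(dm.data, dm.data.T)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            cs.bray_curtis(pd.DataFrame({"a": [-1, 2], "b": [1, 1]}))


class TestNMDS:
    def _embeddable(self, n=12, seed=1):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, 2))
        D = squareform(pdist(pts))
        return DistanceMatrix(D, [f"u{i}" for i in range(n)])

    def test_embeddable_configuration_recovers_low_stress(self):
        res = cs.nmds(self._embeddable(), k=2, seed=0)
        assert res.stress < 0.01

    def test_reported_stress_matches_reevaluation(self):
        dm = self._embeddable(seed=3)
        res = cs.nmds(dm, k=2, seed=0)
        again = cs.stress1(res.points, squareform(dm.data, checks=False))
        assert abs(res.stress - again) < 1e-8

    def test_seed_determinism(self):
        dm = self._embeddable(seed=4)
        r1 = cs.nmds(dm, k=2, seed=5)
        r2 = cs.nmds(dm, k=2, seed=5)
        assert np.array_equal(r1.points, r2.points)
        assert r1.stress == r2.stress

    def test_best_start_not_worse_than_single_start(self):
        rng = np.random.default_rng(6)
        X = rng.random((10, 4))
        D = squareform(pdist(X))
        dm = DistanceMatrix(D, [f"u{i}" for i in range(10)])
        multi = cs.nmds(dm, k=2, n_starts=10, seed=7)
        single = cs.nmds(dm, k=2, n_starts=1, seed=7)
        assert multi.stress <= single.stress + 1e-12

    def test_k_must_be_smaller_than_n(self):
        with pytest.raises(ValueError):
            cs.nmds(self._embeddable(n=3), k=3)


class TestMantel:
    def _random_dm(self, n, rng):
        X = rng.random((n, 3))
        return DistanceMatrix(squareform(pdist(X)), [f"u{i}" for i in range(n)])

    def test_self_comparison(self):
        rng = np.random.default_rng(1)
        dm = self._random_dm(10, rng)
        res = cs.mantel(dm, dm, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        dm = self._random_dm(10, rng)
        dm2 = DistanceMatrix(2.0 * dm.data + 0.1 * (1 - np.eye(10)), dm.ids)
        res = cs.mantel(dm, dm2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_mismatched_labels_rejected(self):
        rng = np.random.default_rng(3)
        dm1 = self._random_dm(5, rng)
        dm2 = DistanceMatrix(dm1.data, [f"x{i}" for i in range(5)])
        with pytest.raises(ValueError):
            cs.mantel(dm1, dm2)

    def test_agrees_with_skbio(self):
        """Observed statistic matches the independent skbio implementation."""
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(4)
        dm1, dm2 = self._random_dm(12, rng), self._random_dm(12, rng)
        ours = cs.mantel(dm1, dm2, n_perm=99, seed=0)
        theirs_r, _, _ = skbio_mantel(dm1, dm2, permutations=0)
        assert ours.r == pytest.approx(float(theirs_r), abs=1e-12)

    def test_null_pvalues_roughly_uniform(self):
        """KS test on null p-values does not reject uniformity at alpha=0.01."""
        from scipy import stats

        rng = np.random.default_rng(5)
        pvals = []
        for i in range(200):
            dm1 = self._random_dm(12, rng)
            dm2 = self._random_dm(12, rng)
            pvals.append(cs.mantel(dm1, dm2, n_perm=199, seed=i).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRegressions:
    def test_collinear_points_r2_one(self):
        from conftest import planted_dataset  # noqa: F401  (fixture helpers live there)

        res = cs._ols(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        assert res.r_squared == pytest.approx(1.0)

    def test_closed_form_ols(self):
        res = cs._ols(np.array([1.0, 2, 3]), np.array([1.0, 3, 5]))
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_host_range_vs_geo_planted_association(self):
        """VTs seeded across more host orders also span more locations."""
        from vtaxa.vt_delimit import VTAssignment
        from vtaxa.occurrence import validate_metadata
        from test_occurrence import meta_row

        rng = np.random.default_rng(8)
        hosts = ["Poales", "Rosales", "Fabales", "Asterales", "Lamiales"]
        rows, members = [], {}
        s = 0
        for v in range(50):
            breadth = 1 + v % 5
            ids = []
            for j in range(breadth * 2):
                sid = f"s{s}"
                s += 1
                ids.append(sid)
                rows.append(
                    meta_row(
                        sid,
                        host_order=hosts[j % breadth],
                        location_id=f"L{(v + j * 7) % (breadth * 3) :03d}",
                    )
                )
            members[f"VT{v:04d}"] = ids
        assignment = VTAssignment(
            members=members,
            representatives={vt: mem[0] for vt, mem in members.items()},
            provenance={i: "singleton" for mem in members.values() for i in mem},
        )
        meta = validate_metadata(pd.DataFrame(rows))
        res = cs.host_range_vs_geo(assignment, meta)
        assert res.slope > 0
        assert res.p_value < 0.05

    def test_host_range_needs_three_vts(self):
        from vtaxa.vt_delimit import VTAssignment
        from vtaxa.occurrence import validate_metadata
        from test_occurrence import meta_row

        assignment = VTAssignment(
            members={"VT1": ["s1"]}, representatives={"VT1": "s1"},
            provenance={"s1": "singleton"},
        )
        meta = validate_metadata(pd.DataFrame([meta_row("s1")]))
        with pytest.raises(ValueError):
            cs.host_range_vs_geo(assignment, meta)


class TestCompositionSimilarityRegression:
    def test_identical_matrices_r2_one(self):
        m = im({"c1": [1, 2, 0], "c2": [0, 1, 3], "c3": [2, 0, 1], "c4": [1, 1, 1]})
        res = cs.composition_similarity_regression(m, m)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_pair_count_for_four_categories(self):
        m = im({"c1": [1, 2, 0], "c2": [0, 1, 3], "c3": [2, 0, 1], "c4": [1, 1, 1]})
        res = cs.composition_similarity_regression(m, m)
        assert res.n == 6

    def test_planted_coupling_recovered(self):
        rng = np.random.default_rng(9)
        plant = pd.DataFrame(rng.integers(0, 20, (10, 6)),
                             columns=[f"c{i}" for i in range(6)])
        noise = rng.integers(0, 2, plant.shape)
        vt = plant + noise
        res = cs.composition_similarity_regression(
            IncidenceMatrix(counts=vt), IncidenceMatrix(counts=plant)
        )
        assert res.slope > 0
        assert res.r_squared > 0.5

    def test_too_few_categories_rejected(self):
        m = im({"c1": [1, 0], "c2": [0, 1]})
        with pytest.raises(ValueError):
            cs.composition_similarity_regression(m, m)
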