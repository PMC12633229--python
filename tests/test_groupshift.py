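"""Within-group correlation shifts, Mahalanobis separation, group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import anchoromics as am
from anchoromics.correlation import EXCL_TOO_FEW
from anchoromics.groupshift import _exact_ranksum_pvalue


class TestWithinGroupR:
    def test_identical_vectors_per_group(self):
        x = np.arange(12, dtype=float)
        groups = ["Control"] * 6 + ["AD"] * 6
        out = am.within_group_r(x, x, groups, keep=["Control", "AD"])
        assert out["Control"].r == pytest.approx(1.0)
        assert out["AD"].r == pytest.approx(1.0)

    def test_small_group_excluded_others_returned(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        groups = ["Control"] * 6 + ["MCI"] * 2
        out = am.within_group_r(x, y, groups, keep=["Control", "MCI"])
        assert out["Control"].ok
        assert out["MCI"].excluded_reason == EXCL_TOO_FEW

    def test_absent_group_hard_error(self, rng):
        with pytest.raises(ValueError, match="absent"):
            am.within_group_r(rng.normal(size=4), rng.normal(size=4),
                              ["Control"] * 4, keep=["AD"])

    def test_matches_global_brute_force(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        groups = np.array(["Control", "MCI", "AD"] * 20)
        out = am.within_group_r(x, y, groups, keep=["Control", "MCI", "AD"])
        for g in ("Control", "MCI", "AD"):
            sel = groups == g
            expected = np.corrcoef(x[sel], y[sel])[0, 1]
            assert out[g].r == pytest.approx(expected, abs=1e-12)


class TestMahalanobis:
    def test_identical_centroids_zero(self, rng):
        a = rng.normal(size=(50, 2))
        b = a - a.mean(axis=0) + a.mean(axis=0)  # same centroid by construction
        assert am.mahalanobis_separation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_limit_identity_covariance(self, rng):
        # orthonormalized clouds with exactly unit sample covariance
        def unit_cloud(n, center):
            z = rng.normal(size=(n, 2))
            z = z - z.mean(axis=0)
            cov = np.cov(z, rowvar=False)
            L = np.linalg.cholesky(cov)
            return z @ np.linalg.inv(L).T + center

        a = unit_cloud(40, np.array([0.0, 0.0]))
        b = unit_cloud(40, np.array([3.0, 4.0]))
        assert am.mahalanobis_separation(a, b) == pytest.approx(5.0, abs=1e-10)

    def test_matches_explicit_solver(self, rng):
        for _ in range(200):
            a = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 2))
            b = rng.normal(size=(12, 2)) + rng.normal(size=2)
            ca, cb = np.cov(a, rowvar=False), np.cov(b, rowvar=False)
            S = (9 * ca + 11 * cb) / 20
            d = a.mean(axis=0) - b.mean(axis=0)
            expected = math.sqrt(d @ np.linalg.inv(S) @ d)
            assert am.mahalanobis_separation(a, b) == pytest.approx(expected, abs=1e-10)

    def test_affine_invariance(self, rng):
        a = rng.normal(size=(30, 2))
        b = rng.normal(size=(25, 2)) + [1.0, 0.5]
        d0 = am.mahalanobis_separation(a, b)
        for _ in range(20):
            A = rng.normal(size=(2, 2))
            while abs(np.linalg.det(A)) < 1e-3:
                A = rng.normal(size=(2, 2))
            shift = rng.normal(size=2) * 10
            d1 = am.mahalanobis_separation(a @ A + shift, b @ A + shift)
            assert abs(d1 - d0) < 1e-8

    def test_singular_covariance_error(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # rank 1
        b = a + [5.0, 1.0]
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            am.mahalanobis_separation(a, b)


class TestConfidenceEllipse:
    def test_unit_covariance_circle_radius(self, rng):
        # exact unit sample covariance -> circle of radius sqrt(chi2_0.95(2))
        z = rng.normal(size=(200, 2))
        z = z - z.mean(axis=0)
        L = np.linalg.cholesky(np.cov(z, rowvar=False))
        pts = z @ np.linalg.inv(L).T
        ell = am.confidence_ellipse(pts, coverage=0.95)
        q = stats.chi2.ppf(0.95, df=2)
        assert ell.semi_axes[0] == pytest.approx(math.sqrt(q), abs=1e-8)
        assert ell.semi_axes[1] == pytest.approx(math.sqrt(q), abs=1e-8)

    def test_zero_coverage_degenerate_point(self, rng):
        ell = am.confidence_ellipse(rng.normal(size=(10, 2)), coverage=0.0)
        assert ell.semi_axes == (0.0, 0.0)

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(size=(100, 2)) @ np.diag([3.0, 1.0])
        e0 = am.confidence_ellipse(pts)
        for theta in (15, 40, 77):
            c, s = math.cos(math.radians(theta)), math.sin(math.radians(theta))
            R = np.array([[c, -s], [s, c]])
            e1 = am.confidence_ellipse(pts @ R.T)
            diff = (e1.angle_deg - e0.angle_deg - theta) % 180
            assert min(diff, 180 - diff) < 1e-6
            assert e1.semi_axes == pytest.approx(e0.semi_axes, abs=1e-8)


class TestClassification:
    # every (r_ref -> r_alt) transcript- and protein-layer pair printed in
    # the study's within-group comparison, with its verbal label
    PAIRS = [
        (0.69, 0.54, "decorrelated"),   # BDNF transcript
        (0.36, 0.36, "stable"),         # BDNF RNA-protein
        (0.57, 0.53, "decorrelated"),   # VGF transcript
        (0.30, 0.31, "stable"),         # VGF RNA-protein
        (0.57, 0.36, "decorrelated"),   # SCG2 transcript
        (0.28, 0.25, "decorrelated"),   # SCG2 RNA-protein
        (0.51, 0.30, "decorrelated"),   # SST transcript
        (0.31, 0.37, "over_correlated"),  # SST RNA-protein
        (0.53, 0.32, "decorrelated"),   # SERTM1 transcript
        (0.24, 0.26, "over_correlated"),  # SERTM1 RNA-protein
        (0.59, 0.58, "stable"),         # DUSP4 transcript
        (0.34, 0.22, "decorrelated"),   # DUSP4 RNA-protein
        (0.56, 0.42, "decorrelated"),   # EGR4 transcript
        (0.23, 0.08, "decorrelated"),   # EGR4 RNA-protein
    ]
    # every printed Mahalanobis D with its verbal separation label
    DS = [
        (1.03, "strong"), (0.72, "moderate"), (0.97, "strong"),
        (0.81, "moderate"), (0.99, "strong"), (1.04, "strong"),
        (0.86, "moderate"), (0.78, "moderate"), (1.00, "strong"),
        (0.54, "little"), (0.53, "little"), (0.98, "strong"),
    ]

    @pytest.mark.parametrize("r_ref,r_alt,expected", PAIRS)
    def test_decorrelation_labels(self, r_ref, r_alt, expected):
        assert am.classify_decorrelation(r_ref, r_alt) == expected

    @pytest.mark.parametrize("D,expected", DS)
    def test_separation_labels(self, D, expected):
        assert am.classify_separation(D) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            am.classify_separation(-0.1)


class TestCompareGroups:
    def test_identical_multisets_exact_p_one(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array(["Control"] * 3 + ["AD"] * 3)
        out = am.compare_groups(vals, groups).table.set_index(["group_a", "group_b"])
        assert out.loc[("Control", "AD"), "p"] == pytest.approx(1.0)

    def test_separated_groups_exact_enumeration(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = np.array(["Control"] * 3 + ["AD"] * 3)
        out = am.compare_groups(vals, groups).table.set_index(["group_a", "group_b"])
        # 20 equally likely assignments; only the two extremes are as deviant
        assert out.loc[("Control", "AD"), "p"] == pytest.approx(0.1)

    def test_exact_path_matches_fresh_enumeration(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:5].sum()
        expect = 5 * 12 / 2.0
        count = sum(
            1
            for combo in itertools.combinations(range(11), 5)
            if abs(ranks[list(combo)].sum() - expect) >= abs(w_obs - expect) - 1e-9
        )
        expected = count / math.comb(11, 5)
        assert _exact_ranksum_pvalue(a, b) == pytest.approx(expected)

    def test_large_n_uses_tie_corrected_normal(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.8, 1, size=30)
        out = am.compare_groups(
            np.concatenate([a, b]),
            np.array(["Control"] * 30 + ["AD"] * 30),
        ).table.set_index(["group_a", "group_b"])
        expected = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert out.loc[("Control", "AD"), "p"] == pytest.approx(float(expected))

    def test_bh_composition_and_undefined_contrast(self, rng):
        vals = np.concatenate([rng.normal(size=10), rng.normal(2, 1, size=10)])
        groups = np.array(["Control"] * 10 + ["AD"] * 10)  # MCI empty
        out = am.compare_groups(vals, groups).table
        assert len(out) == 3
        defined = out["p"].notna()
        assert defined.sum() == 1
        np.testing.assert_allclose(
            out.loc[defined, "fdr"], am.bh_adjust(out.loc[defined, "p"].to_numpy())
        )


class TestGroupShiftAnalysis:
    def test_planted_shift_gives_strong_separation(self):
        cfg = am.SimConfig(seed=3)
        cfg.n_per_group = {"Control": 60, "MCI": 0, "AD": 60, "Other": 0}
        cfg.anchor_protein_shift = {"Control": 0.0, "AD": -1.2}
        d = am.simulate_dataset(cfg)
        prot = am.rollup_peptides(d.peptides)
        res = am.group_shift_analysis(
            d.rna.feature("NPTX2").loc[prot.sample_ids],
            prot.feature("NPTX2"),
            d.metadata["group"],
            gene_id="NPTX2", layer="rna_protein",
        )
        assert res.separation_class == "strong"
        assert res.D >= 0.9
        assert set(res.centroid_by_group) == {"Control", "AD"}
        # AD centroid sits lower on both axes (planted decline)
        assert res.centroid_by_group["AD"][1] < res.centroid_by_group["Control"][1]

    def test_separation_monotone_in_planted_shift(self):
        ds = []
        for shift in (0.0, 0.6, 1.2, 1.8):
            cfg = am.SimConfig(seed=5)
            cfg.n_per_group = {"Control": 80, "MCI": 0, "AD": 80, "Other": 0}
            cfg.anchor_group_shift = {"Control": 0.0, "AD": 0.0}
            cfg.anchor_protein_shift = {"Control": 0.0, "AD": -shift}
            d = am.simulate_dataset(cfg)
            prot = am.rollup_peptides(d.peptides)
            res = am.group_shift_analysis(
                d.rna.feature("NPTX2").loc[prot.sample_ids],
                prot.feature("NPTX2"), d.metadata["group"],
            )
            ds.append(res.D)
        assert all(a < b for a, b in zip(ds, ds[1:]))
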