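"""Driver inference: BIOENV, Mantel, collinearity, CCA, PLS-VIP."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import bioenv as skbio_bioenv
from skbio.stats.distance import mantel as skbio_mantel

from estmeio import drivers
from estmeio.drivers import (
    DriverError,
    bioenv,
    cca,
    cca_stepwise_aic,
    filter_collinear,
    mantel,
    normalize_env,
    pls_vip,
    spearman_matrix_corr,
)


def random_distance(n, rng, ids=None):
    pts = rng.normal(size=(n, 3))
    d = squareform(pdist(pts))
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


class TestNormalizeEnv:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        E = pd.DataFrame(rng.normal(5, 3, (20, 4)),
                         columns=list("abcd"))
        Z = normalize_env(E)
        np.testing.assert_allclose(Z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(ddof=1), 1.0, atol=1e-12)

    def test_constant_column_named(self):
        E = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        with pytest.raises(DriverError, match="b"):
            normalize_env(E)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        E = pd.DataFrame({"a": rng.normal(size=15)})
        Z1 = normalize_env(E)
        Z2 = normalize_env(E * 7.3 - 2.0)
        np.testing.assert_allclose(Z1.values, Z2.values, atol=1e-12)


class TestSpearmanMatrixCorr:
    def test_monotone_transform_gives_one(self):
        rng = np.random.default_rng(2)
        D1 = random_distance(7, rng)
        D2 = DistanceMatrix(np.sqrt(D1.data), ids=D1.ids)
        assert spearman_matrix_corr(D1, D2) == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        rng = np.random.default_rng(3)
        D1 = random_distance(6, rng)
        m = D1.data.max()
        rev = m + 1 - D1.data
        np.fill_diagonal(rev, 0.0)
        D2 = DistanceMatrix((rev + rev.T) / 2, ids=D1.ids)
        assert spearman_matrix_corr(D1, D2) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        D1, D2 = random_distance(6, rng), random_distance(6, rng)
        obs = spearman_matrix_corr(D1, D2)
        a = pd.Series(D1.condensed_form()).rank()
        b = pd.Series(D2.condensed_form()).rank()
        expect = np.corrcoef(a, b)[0, 1]
        assert obs == pytest.approx(expect, abs=1e-12)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        D1 = random_distance(5, rng)
        D2 = random_distance(5, rng, ids=list("vwxyz"))
        with pytest.raises(DriverError):
            spearman_matrix_corr(D1, D2)


class TestBioenv:
    def test_subset_enumeration_count(self):
        rng = np.random.default_rng(6)
        D = random_distance(8, rng)
        E = pd.DataFrame(rng.normal(size=(8, 8)),
                         index=D.ids,
                         columns=[f"v{j}" for j in range(8)])
        res = bioenv(D, E)
        assert res.n_subsets_evaluated == 2 ** 8 - 1

    def test_top_k_rows_reported(self):
        rng = np.random.default_rng(7)
        D = random_distance(10, rng)
        E = pd.DataFrame(rng.normal(size=(10, 6)),
                         index=D.ids,
                         columns=[f"v{j}" for j in range(6)])
        res = bioenv(D, E, top_k=10)
        assert len(res.table) == 10
        rho = res.table["correlation"].values
        assert (np.diff(rho) <= 1e-12).all()
        assert res.table["variables"].is_unique

    def test_best_per_size_matches_skbio(self):
        """Independent oracle: scikit-bio's BIOENV reports the best
        subset of each size; our exhaustive ranking must agree."""
        rng = np.random.default_rng(8)
        D = random_distance(12, rng)
        E = pd.DataFrame(rng.normal(size=(12, 5)),
                         index=D.ids,
                         columns=[f"v{j}" for j in range(5)])
        res = bioenv(D, E, top_k=2 ** 5 - 1)
        tbl = res.table
        oracle = skbio_bioenv(D, E)
        for vars_str, row in oracle.iterrows():
            size = int(row["size"])
            ours = tbl[tbl["n_variables"] == size].iloc[0]
            assert ours["correlation"] == pytest.approx(
                row["correlation"], abs=1e-10
            )
            assert set(ours["variables"]) == set(vars_str.split(", "))

    def test_combinatorial_guard(self):
        rng = np.random.default_rng(9)
        D = random_distance(6, rng)
        E = pd.DataFrame(rng.normal(size=(6, 22)), index=D.ids,
                         columns=[f"v{j}" for j in range(22)])
        with pytest.raises(DriverError, match="allow_large"):
            bioenv(D, E)
        res = bioenv(D, E, max_subset_size=1)
        assert res.n_subsets_evaluated == 22

    def test_station_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        D = random_distance(5, rng)
        E = pd.DataFrame(rng.normal(size=(5, 3)),
                         index=list("vwxyz"))
        with pytest.raises(DriverError):
            bioenv(D, E)


class TestMantel:
    def test_self_comparison(self):
        rng = np.random.default_rng(11)
        D = random_distance(8, rng)
        res = mantel(D, D, n_perm=99, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_p_floor_with_999_perms(self):
        rng = np.random.default_rng(12)
        D1 = random_distance(10, rng)
        D2 = DistanceMatrix(np.sqrt(D1.data), ids=D1.ids)
        res = mantel(D1, D2, n_perm=999, seed=1)
        assert res.p_value >= 1 / 1000

    def test_rho_matches_skbio(self):
        rng = np.random.default_rng(13)
        D1, D2 = random_distance(9, rng), random_distance(9, rng)
        ours = mantel(D1, D2, n_perm=99, seed=2)
        rho, _, _ = skbio_mantel(D1, D2, method="spearman",
                                 permutations=0)
        assert ours.rho == pytest.approx(rho, abs=1e-12)


class TestFilterCollinear:
    def test_perfectly_correlated_pair_reduced(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=30)
        E = pd.DataFrame({"a": a, "b": 2 * a + 1,
                          "c": rng.normal(size=30)})
        reduced, log = filter_collinear(E)
        assert reduced.shape[1] == 2
        assert "c" in reduced.columns
        assert len(log) == 1 and log[0]["abs_r"] > 0.99

    def test_below_threshold_unchanged(self):
        rng = np.random.default_rng(15)
        E = pd.DataFrame(rng.normal(size=(200, 4)),
                         columns=list("abcd"))
        reduced, log = filter_collinear(E)
        assert list(reduced.columns) == list("abcd")
        assert log == []

    def test_preferred_retained_set_representable(self):
        """With retention priority on {mean velocity, D50, salinity
        range}, those variables survive the 0.7 filter whenever each
        conflict pairs them with a non-preferred variable."""
        rng = np.random.default_rng(16)
        base = rng.normal(size=30)
        E = pd.DataFrame(
            {
                "mean_velocity": base + rng.normal(0, 0.1, 30),
                "max_velocity": base + rng.normal(0, 0.05, 30),
                "d50": rng.normal(size=30),
                "d10": None,
                "salinity_range": rng.normal(size=30),
                "spring_tidal_range": None,
            }
        )
        E["d10"] = E["d50"] * 0.9 + rng.normal(0, 0.1, 30)
        E["spring_tidal_range"] = (
            E["salinity_range"] + rng.normal(0, 0.1, 30)
        )
        reduced, _ = filter_collinear(
            E, prefer=["mean_velocity", "d50", "salinity_range"]
        )
        assert set(reduced.columns) == {
            "mean_velocity", "d50", "salinity_range"
        }


def random_community(rng, n=12, m=20):
    Y = rng.poisson(3.0, size=(n, m)).astype(float)
    Y[Y.sum(axis=1) == 0, 0] += 1
    Y[:, Y.sum(axis=0) == 0] += 1
    return pd.DataFrame(
        Y, index=[f"s{i}" for i in range(n)],
        columns=[f"t{j}" for j in range(m)],
    )


class TestCca:
    def test_total_inertia_equals_chisquare_over_total(self):
        rng = np.random.default_rng(17)
        Y = random_community(rng)
        E = pd.DataFrame(rng.normal(size=(12, 3)), index=Y.index,
                         columns=list("abc"))
        res = cca(Y, E)
        chi2 = stats.chi2_contingency(Y.values)[0]
        assert res.total_inertia == pytest.approx(
            chi2 / Y.values.sum(), abs=1e-10
        )

    def test_constrained_not_exceeding_total(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            Y = random_community(rng)
            E = pd.DataFrame(rng.normal(size=(12, 4)), index=Y.index,
                             columns=list("abcd"))
            res = cca(Y, E)
            assert res.constrained_inertia <= res.total_inertia + 1e-10
            assert (res.eigenvalues >= -1e-12).all()
            assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_block_indicator_captures_first_axis(self):
        """A two-block community with an indicator variable for the
        block: the single constrained axis carries ~all constrained
        inertia."""
        rng = np.random.default_rng(19)
        n = 12
        Y = np.zeros((n, 20))
        Y[:6, :10] = rng.poisson(5.0, (6, 10))
        Y[6:, 10:] = rng.poisson(5.0, (6, 10))
        Y += 0.01
        Yd = pd.DataFrame(Y, index=[f"s{i}" for i in range(n)])
        E = pd.DataFrame(
            {"block": np.repeat([0.0, 1.0], 6)}, index=Yd.index
        )
        res = cca(Yd, E)
        assert res.eigenvalues[0] / res.constrained_inertia >= 0.99
        # the constrained axis separates the two blocks
        scores = res.site_scores["CCA1"].values
        assert set(np.sign(scores[:6])) != set(np.sign(scores[6:]))

    def test_rank_deficient_design_names_column(self):
        rng = np.random.default_rng(20)
        Y = random_community(rng)
        a = rng.normal(size=12)
        E = pd.DataFrame({"a": a, "b": 2 * a}, index=Y.index)
        with pytest.raises(DriverError, match="b"):
            cca(Y, E)

    def test_matches_vegan_style_oracle(self):
        """Constrained inertia agrees with an independent projection
        oracle: sum of squares of the chi-square standardised table
        projected on the weighted design."""
        rng = np.random.default_rng(21)
        Y = random_community(rng)
        E = pd.DataFrame(rng.normal(size=(12, 3)), index=Y.index,
                         columns=list("abc"))
        res = cca(Y, E)
        # oracle via explicit hat matrix
        Yv = Y.values
        P = Yv / Yv.sum()
        r, c = P.sum(1), P.sum(0)
        Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        X = E.values - (r[:, None] * E.values).sum(0)
        Xw = np.sqrt(r)[:, None] * X
        H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
        expect = float(((H @ Q) ** 2).sum())
        assert res.constrained_inertia == pytest.approx(expect,
                                                        abs=1e-10)


class TestCcaStepwise:
    def test_empty_candidate_outcome(self):
        rng = np.random.default_rng(22)
        Y = random_community(rng)
        E = pd.DataFrame({"noise": rng.normal(0, 1e-8, 12) * 0},
                         index=Y.index)
        res = cca_stepwise_aic(Y, E, n_perm=9, seed=0)
        assert res.variables == []
        assert res.constrained_inertia == 0.0

    def test_single_driver_selected_among_noise(self):
        """A community structured by one variable among noise
        variables: the stepwise AIC selects that variable alone in
        most runs (50 seeds)."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n, m = 20, 50
            x = np.linspace(-1, 1, n)
            b = rng.normal(0, 1.2, m)
            lam = np.exp(1.5 + b[None, :] * x[:, None])
            Y = pd.DataFrame(
                rng.poisson(lam) + 1e-3,
                index=[f"s{i}" for i in range(n)],
            )
            E = pd.DataFrame(
                {
                    "driver": x,
                    "n1": rng.normal(size=n),
                    "n2": rng.normal(size=n),
                    "n3": rng.normal(size=n),
                },
                index=Y.index,
            )
            res = cca_stepwise_aic(Y, E, n_perm=9, seed=seed)
            hits += res.variables == ["driver"]
        assert hits >= 40

    def test_permutation_p_granularity(self):
        rng = np.random.default_rng(23)
        Y = random_community(rng)
        E = pd.DataFrame(
            {"a": np.linspace(0, 1, 12)}, index=Y.index
        )
        res = cca_stepwise_aic(Y, E, n_perm=199, seed=3)
        for p in (res.variable_p or {}).values():
            assert p >= 1 / 200


class TestPlsVip:
    def test_single_predictor_vip_is_one(self):
        rng = np.random.default_rng(24)
        X = pd.DataFrame({"a": rng.normal(size=15)})
        y = pd.Series(rng.normal(size=15))
        res = pls_vip(X, y, n_components=1, n_perm=None)
        assert res.table.loc["a", "vip1"] == pytest.approx(1.0)

    def test_orthonormal_design_closed_form(self):
        """X orthonormal, y = x1: one component gives VIP1 -> sqrt(p)
        and 0 for the rest, R^2 = 1."""
        n, p = 16, 4
        rng = np.random.default_rng(25)
        A = rng.normal(size=(n, p))
        A -= A.mean(axis=0)   # centred span excludes the ones vector
        Qm, _ = np.linalg.qr(A)
        X = pd.DataFrame(Qm, columns=[f"x{j}" for j in range(p)])
        y = pd.Series(Qm[:, 0])
        res = pls_vip(X, y, n_components=1, n_perm=None)
        vips = res.table["vip1"]
        assert vips["x0"] == pytest.approx(np.sqrt(p), abs=1e-6)
        assert (vips.drop("x0") < 1e-6).all()
        assert res.r2_components[0] == pytest.approx(1.0, abs=1e-10)

    def test_association_sign_tracks_slope(self):
        rng = np.random.default_rng(26)
        x = rng.normal(size=20)
        X = pd.DataFrame({"up": x, "noise": rng.normal(size=20)})
        y = pd.Series(-2.0 * x + rng.normal(0, 0.1, 20))
        res = pls_vip(X, y, n_perm=None)
        assert res.table.loc["up", "sign"] == -1.0

    def test_r2_components_cumulative_bounded(self):
        rng = np.random.default_rng(27)
        X = pd.DataFrame(rng.normal(size=(20, 6)),
                         columns=[f"x{j}" for j in range(6)])
        y = pd.Series(X.values @ rng.normal(size=6)
                      + rng.normal(size=20))
        res = pls_vip(X, y, n_components=3, n_perm=None)
        r2 = res.r2_components
        assert (r2 >= -1e-12).all()
        assert r2.sum() <= 1 + 1e-9

    def test_zero_variance_response_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(DriverError):
            pls_vip(X, pd.Series([5.0, 5.0, 5.0]))
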