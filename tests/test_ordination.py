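import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from reefcomposite.ordination import (
    RDA,
    chain_adjacency_weights,
    great_circle_km,
    morans_i,
    partial_rda,
    rda,
)


def random_instance(n=6, p=3, q=2, seed=0):
    rng = np.random.default_rng(seed)
    Y = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"y{j}" for j in range(p)])
    X = pd.DataFrame(rng.normal(size=(n, q)), columns=[f"x{j}" for j in range(q)])
    return Y, X


def hat_matrix_proportion(Y, X):
    """Independent oracle: explicit hat-matrix projection of the centred
    response onto [1, standardized X]."""
    Yc = Y - Y.mean(axis=0)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    D = np.column_stack([np.ones(len(Y)), Xs])
    H = D @ np.linalg.pinv(D.T @ D) @ D.T
    Yhat = H @ np.asarray(Yc)
    return np.trace(Yhat.T @ Yhat) / np.trace(np.asarray(Yc).T @ np.asarray(Yc))


class TestRDA:
    def test_exact_linear_response_fully_explained(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        B = rng.normal(size=(2, 4))
        Y = pd.DataFrame(X.to_numpy() @ B)
        res = rda(Y, X, n_perm=0)
        assert res.constrained_proportion == pytest.approx(1.0, abs=1e-10)

    def test_residualized_response_unexplained(self):
        Y, X = random_instance(n=20, p=4, q=2, seed=2)
        Yc = Y - Y.mean(axis=0)
        D = np.column_stack([np.ones(len(Y)), X])
        H = D @ np.linalg.pinv(D.T @ D) @ D.T
        Yres = pd.DataFrame(np.asarray(Yc) - H @ np.asarray(Yc))
        res = rda(Yres, X, n_perm=0)
        assert res.constrained_proportion == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hat_matrix_oracle(self, seed):
        Y, X = random_instance(seed=seed)
        res = rda(Y, X, n_perm=0)
        assert res.constrained_proportion == pytest.approx(
            hat_matrix_proportion(Y.to_numpy(), X.to_numpy()), abs=1e-10)

    def test_invariant_to_predictor_scaling(self):
        Y, X = random_instance(n=12, seed=3)
        res1 = rda(Y, X, n_perm=0)
        X2 = X * np.array([100.0, 0.001])
        res2 = rda(Y, X2, n_perm=0)
        assert res1.constrained_proportion == pytest.approx(
            res2.constrained_proportion, abs=1e-12)

    def test_monotone_in_added_traits(self):
        Y, X = random_instance(n=15, p=4, q=3, seed=4)
        props = [rda(Y, X.iloc[:, :q], n_perm=0).constrained_proportion
                 for q in (1, 2, 3)]
        assert props[0] <= props[1] + 1e-12 <= props[2] + 2e-12

    def test_eigenvalues_nonincreasing_nonnegative(self):
        Y, X = random_instance(n=15, p=5, q=3, seed=5)
        res = rda(Y, X, n_perm=0)
        e = res.eigenvalues
        assert (e >= -1e-12).all()
        assert (np.diff(e) <= 1e-12).all()

    def test_permutation_p_detects_real_structure(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(25, 2)))
        Y = pd.DataFrame(X.to_numpy() @ rng.normal(size=(2, 4))
                         + 0.2 * rng.normal(size=(25, 4)))
        res = rda(Y, X, n_perm=199, seed=0)
        assert res.p_perm <= 0.01  # add-one minimum is 1/200

    def test_matches_vegan_reference(self, tmp_path):
        """Cross-check the constrained proportion against vegan::rda."""
        Y, X = random_instance(n=8, p=3, q=2, seed=7)
        Y.to_csv(tmp_path / "Y.csv", index=False)
        X.to_csv(tmp_path / "X.csv", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- read.csv("{tmp_path}/Y.csv"); X <- read.csv("{tmp_path}/X.csv")
            fit <- rda(Y ~ ., data=X)
            cat(fit$CCA$tot.chi / fit$tot.chi)
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        res = rda(Y, X, n_perm=0)
        assert res.constrained_proportion == pytest.approx(
            float(out.stdout.strip()), abs=1e-6)


class TestPartialRDA:
    def test_empty_covariates_identical_to_plain(self):
        Y, X = random_instance(n=12, seed=8)
        a = rda(Y, X, n_perm=0)
        b = partial_rda(Y, X, None, n_perm=0)
        assert a.constrained_proportion == pytest.approx(
            b.constrained_proportion, abs=1e-12)

    def test_predictors_inside_covariate_span_explain_nothing(self):
        Y, X = random_instance(n=14, seed=9)
        Z = pd.DataFrame({"z1": X.iloc[:, 0] * 2, "z2": X.iloc[:, 1] + 1})
        res = partial_rda(Y, X, Z, n_perm=0)
        assert res.constrained_proportion == pytest.approx(0.0, abs=1e-10)
        assert res.partial

    def test_matches_two_step_oracle(self):
        Y, X = random_instance(n=16, p=4, q=2, seed=10)
        rng = np.random.default_rng(10)
        Z = pd.DataFrame(rng.normal(size=(16, 2)), columns=["z1", "z2"])
        res = partial_rda(Y, X, Z, n_perm=0)
        # oracle: residualize by hand, then hat-matrix proportion
        Zs = (Z - Z.mean()) / Z.std(ddof=1)
        D = np.column_stack([np.ones(16), Zs])
        H = D @ np.linalg.pinv(D.T @ D) @ D.T
        Yc = np.asarray(Y - Y.mean(axis=0))
        Xs = np.asarray((X - X.mean()) / X.std(ddof=1))
        Yres, Xres = Yc - H @ Yc, Xs - H @ Xs
        D2 = np.column_stack([np.ones(16), Xres])
        H2 = D2 @ np.linalg.pinv(D2.T @ D2) @ D2.T
        expected = np.trace((H2 @ Yres).T @ (H2 @ Yres)) / np.trace(Yres.T @ Yres)
        assert res.constrained_proportion == pytest.approx(expected, abs=1e-10)


class TestMoransI:
    def brute_force(self, x, w):
        n = len(x)
        z = x - x.mean()
        num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        return n / w.sum() * num / (z @ z)

    def test_line_adjacency_hand_case(self):
        # x = [1,2,3,4] on a chain: I = (4/6) * 2.5 / 5 = 1/3
        w = chain_adjacency_weights([0, 1, 2, 3])
        res = morans_i(np.array([1.0, 2, 3, 4]), weights=w, n_perm=0)
        assert res.morans_i == pytest.approx(1 / 3, abs=1e-12)
        assert res.expected == pytest.approx(-1 / 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        x = rng.normal(size=n)
        w = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(w, 0.0)
        res = morans_i(x, weights=w, n_perm=0)
        assert res.morans_i == pytest.approx(self.brute_force(x, w), abs=1e-10)

    def test_permutation_null_mean_at_closed_form(self):
        rng = np.random.default_rng(0)
        n = 8
        x = rng.normal(size=n)
        w = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(w, 0.0)
        stats = [morans_i(x[rng.permutation(n)], weights=w, n_perm=0).morans_i
                 for _ in range(3000)]
        se = np.std(stats) / np.sqrt(len(stats))
        assert abs(np.mean(stats) - (-1 / (n - 1))) < 4 * se

    def test_inverse_distance_weights_from_coords(self):
        coords = np.array([[20.0, 204.0], [21.0, 203.0], [24.0, 198.0],
                           [28.0, 178.0]])
        d = great_circle_km(coords)
        assert d[0, 1] == pytest.approx(151.0, rel=0.05)  # ~1 deg lat + lon
        res = morans_i(np.array([1.0, 2, 4, 3]), coords=coords, n_perm=99,
                       seed=0)
        assert res.weight_spec["type"] == "inverse_great_circle_distance"
        assert 0 < res.p_perm <= 1

    def test_constant_values_rejected(self):
        w = chain_adjacency_weights([0, 1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.full(4, 2.0), weights=w)

    def test_nonfinite_weight_rejected(self):
        w = chain_adjacency_weights([0, 1, 2, 3]).astype(float)
        w[0, 1] = np.inf
        with pytest.raises(ValueError, match="finite"):
            morans_i(np.array([1.0, 2, 3, 4]), weights=w)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(1)
        w = chain_adjacency_weights(list(range(8)))
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            res = morans_i(rng.normal(size=8), weights=w, n_perm=99,
                           seed=int(rng.integers(2**31)))
            hits += res.p_perm <= 0.05
        # binomial 3-sigma band around 5%
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_rep) <= hits / n_rep \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_matches_ape_reference(self):
        """Cross-check against ape::Moran.I (row-standardized weights)."""
        rng = np.random.default_rng(3)
        n = 7
        x = rng.normal(size=n)
        w = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(w, 0.0)
        xs = ",".join(f"{float(v):.17g}" for v in x)
        ws = ",".join(f"{float(v):.17g}" for v in w.ravel(order="F"))
        script = (
            "suppressMessages(library(ape));"
            f"x <- c({xs}); w <- matrix(c({ws}), nrow={n});"
            "res <- Moran.I(x, w, scaled=FALSE);"
            "cat(res$observed)"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        # ape::Moran.I row-normalizes the weight matrix internally
        res = morans_i(x, weights=w, n_perm=0, row_standardize=True)
        assert res.morans_i == pytest.approx(float(out.stdout.strip()), abs=1e-6)
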