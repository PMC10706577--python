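import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from spongenet import diffexpr
from spongenet.io import CountMatrix
from spongenet.synthetic import SimConfig, simulate_counts


def _matrix(counts, groups=("a", "a", "b", "b")):
    counts = np.asarray(counts)
    return CountMatrix(
        feature_ids=[f"mRNA_{i}" for i in range(counts.shape[0])],
        classes=["mRNA"] * counts.shape[0],
        sample_ids=[f"s{i}" for i in range(counts.shape[1])],
        groups=list(groups),
        counts=counts,
    )


class TestTMM:
    def test_identical_columns(self):
        col = np.random.default_rng(0).poisson(50, 100)
        m = _matrix(np.tile(col[:, None], (1, 4)))
        assert np.allclose(diffexpr.tmm_factors(m), 1.0)

    def test_scaled_column(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, size=(500, 1))
        cols = np.tile(base, (1, 4))
        cols[:, 3] *= 2  # pure library-size doubling
        m = _matrix(cols)
        f = diffexpr.tmm_factors(m)
        # TMM absorbs a global scaling into the library size, not the factor
        assert np.allclose(f, 1.0, atol=1e-6)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_composition_bias_detected(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=(400, 4))
        counts[:20, 3] *= 50  # a few huge features inflate sample 3's library
        m = _matrix(counts)
        f = diffexpr.tmm_factors(m)
        # the majority of features are unchanged in absolute counts, so the
        # trimmed factor must shrink sample 3's effective library back: after
        # normalization the unchanged features are comparable across samples
        norm = diffexpr.normalized_counts(m, f)
        ratio = norm[20:, 3].mean() / norm[20:, 0].mean()
        assert ratio == pytest.approx(1.0, abs=0.05)
        naive = counts[20:, 3].sum() / counts[20:, 0].sum() * (
            counts[:, 0].sum() / counts[:, 3].sum()
        )
        assert abs(ratio - 1) < abs(naive - 1)  # better than library-size-only
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_single_feature_errors(self):
        m = _matrix([[5, 5, 5, 5]])
        with pytest.raises(ValueError, match="insufficient features"):
            diffexpr.tmm_factors(m)


class TestLog2FC:
    def test_equal_means_zero(self, toy_matrix):
        counts = np.tile(np.arange(1, 41)[:, None] * 10, (1, 6))
        m = _matrix(counts, groups=["a"] * 3 + ["b"] * 3)
        fc = diffexpr.log2_fold_change(m, np.ones(6))
        assert np.allclose(fc, 0.0)

    def test_doubled_group(self):
        # one doubled feature inside a matrix with equal column sums
        counts = np.full((10, 6), 100)
        counts[0, 3:] = 200
        counts[1, 3:] = 0  # compensate to keep library sizes equal
        counts[1, :3] = 100
        m = _matrix(counts, groups=["a"] * 3 + ["b"] * 3)
        fc = diffexpr.log2_fold_change(m, np.ones(6), prior=0.0)
        assert fc[0] == pytest.approx(1.0)

    def test_prior_symmetry_both_zero(self):
        counts = np.full((5, 6), 50)
        counts[2] = 0
        m = _matrix(counts, groups=["a"] * 3 + ["b"] * 3)
        fc = diffexpr.log2_fold_change(m, np.ones(6), prior=0.5)
        assert fc[2] == 0.0


class TestExactTest:
    def test_identical_counts_p_one(self):
        m = _matrix(np.full((3, 6), 10), groups=["a"] * 3 + ["b"] * 3)
        p = diffexpr.nb_exact_test(m, np.ones(6), dispersion=0.0)
        assert np.allclose(p, 1.0)

    def test_extreme_split_matches_binomial_tail_oracle(self):
        counts = np.full((20, 6), 30)
        counts[0] = [0, 0, 0, 20, 20, 20]
        m = _matrix(counts, groups=["a"] * 3 + ["b"] * 3)
        p = diffexpr.nb_exact_test(m, np.ones(6), dispersion=0.0)[0]
        # brute-force two-sided binomial tail by direct summation
        s, prob = 60, 0.5
        pmf = np.array([stats.binom.pmf(y, s, prob) for y in range(s + 1)])
        expected = pmf[pmf <= pmf[0] * (1 + 1e-12)].sum()
        assert p == pytest.approx(expected, rel=1e-9)

    def test_phi_zero_matches_scipy_binom_test(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(40, size=(30, 6))
        # equalize library sizes so no rescaling occurs
        counts[-1] += counts.sum(0).max() - counts.sum(0)
        m = _matrix(counts, groups=["a"] * 3 + ["b"] * 3)
        p = diffexpr.nb_exact_test(m, np.ones(6), dispersion=0.0)
        for i in range(counts.shape[0]):
            ya = counts[i, :3].sum()
            s = counts[i].sum()
            ref = stats.binomtest(int(ya), int(s), 0.5).pvalue
            assert p[i] == pytest.approx(ref, abs=1e-9)

    def test_negative_dispersion_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            diffexpr.nb_exact_test(toy_matrix, np.ones(6), dispersion=-0.1)

    def test_null_type1_error_poisson(self):
        """Under the null the test is close to (and not above) nominal level."""
        cfg = SimConfig(
            n_mrna=940, n_lncrna=20, n_circrna=20, n_mirna=20,
            n_sponge_modules=0, background_de_frac=0.0, dispersion=0.0, seed=42,
        )
        m, _ = simulate_counts(cfg)
        f = diffexpr.tmm_factors(m)
        p = diffexpr.nb_exact_test(m, f, dispersion=0.0)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / p.size)
        assert rate <= 0.05 + 2 * se
        assert rate >= 0.03


class TestBH:
    def test_hand_computed_stepup(self):
        assert np.allclose(
            diffexpr.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        assert np.allclose(diffexpr.bh_adjust(np.ones(5)), 1.0)

    def test_single_p(self):
        assert diffexpr.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust(np.array([0.1, np.nan]))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_stepup_definition(self, pvals):
        """BH equals the brute-force step-up definition and statsmodels."""
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        got = diffexpr.bh_adjust(p)
        n = p.size
        # brute force: q_i = min over j with p_(j) >= p_i of p_(j) * n / j
        order = np.argsort(p, kind="stable")
        brute = np.empty(n)
        sorted_p = p[order]
        adj = sorted_p * n / np.arange(1, n + 1)
        for i in range(n):
            brute[order[i]] = min(1.0, adj[i:].min())
        assert np.allclose(got, brute)
        assert np.allclose(got, multipletests(p, method="fdr_bh")[1])


class TestClassify:
    @pytest.mark.parametrize(
        "cls,p,fdr,fc,call",
        [
            ("mRNA", 0.001, 0.04, 1.2, "up"),
            ("miRNA", 0.04, 0.20, -1.5, "down"),
            ("lncRNA", 0.001, 0.04, 0.9, "ns"),
            ("circRNA", 0.06, 0.50, 2.0, "ns"),
            ("mRNA", 0.001, 0.04, 1.0, "ns"),  # strict: |log2FC| > 1
        ],
    )
    def test_gates(self, cls, p, fdr, fc, call):
        df = pd.DataFrame(
            {"feature_id": ["f"], "class": [cls], "log2fc": [fc],
             "pvalue": [p], "fdr": [fdr]}
        )
        assert diffexpr.classify_de(df)["call"].iloc[0] == call

    def test_unknown_class(self):
        df = pd.DataFrame(
            {"feature_id": ["f"], "class": ["piRNA"], "log2fc": [2.0],
             "pvalue": [0.01], "fdr": [0.01]}
        )
        with pytest.raises(ValueError):
            diffexpr.classify_de(df)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["mRNA", "lncRNA", "circRNA", "miRNA"]),
                st.floats(min_value=0, max_value=1),
                st.floats(min_value=0, max_value=1),
                st.floats(min_value=-4, max_value=4),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_never_calls_weak_fold_changes(self, rows):
        df = pd.DataFrame(rows, columns=["class", "pvalue", "fdr", "log2fc"])
        df["feature_id"] = [f"f{i}" for i in range(len(df))]
        out = diffexpr.classify_de(df)
        called = out[out["call"] != "ns"]
        assert (called["log2fc"].abs() > 1.0).all()


def test_run_de_recovers_planted_calls(default_dataset):
    cfg, m, truth, _, _ = default_dataset
    table = diffexpr.run_de(m)
    de_ids = set(table.loc[table["call"] != "ns", "feature_id"])
    planted_members = {t for pair in truth.sponge_pairs for t in pair}
    assert len(de_ids & planted_members) / len(planted_members) >= 0.9
    # planted sponge members are suppressed in group 2: calls must be "down"
    calls = table.set_index("feature_id").loc[sorted(de_ids & planted_members), "call"]
    assert (calls == "down").all()
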