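"""Multifactor differential testing and the permutation background."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nascentq import diff
from nascentq.errors import ConfigError


def nb_counts(rng, mean, disp=0.05, size=None):
    """Negative-binomial draws parameterized by mean and dispersion."""
    n = 1.0 / disp
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def batch_design(n_per_cell=2):
    rows = []
    for cond in ("ctrl", "treat"):
        for batch in ("b1", "b2"):
            for i in range(n_per_cell):
                rows.append(
                    {
                        "sample_id": f"{cond}_{batch}_{i}",
                        "condition": cond,
                        "batch": batch,
                    }
                )
    return pd.DataFrame(rows)


def simulate_batch_study(rng, n_null=200, n_true=50, base_mean=500.0, fold=2.0, batch_fold=3.0):
    """Counts with a strong gene-specific batch effect and planted 2-fold
    condition effects; returns (counts, design frame, truth mask)."""
    meta = batch_design()
    n_genes = n_null + n_true
    truth = np.zeros(n_genes, dtype=bool)
    truth[n_null:] = True
    batch_affected = rng.random(n_genes) < 0.5
    batch_dir = rng.choice([1.0, -1.0], size=n_genes)
    cols = {}
    for _, row in meta.iterrows():
        mult = np.ones(n_genes)
        if row["condition"] == "treat":
            mult[truth] *= fold
        bmult = np.where(batch_affected, batch_fold ** batch_dir, 1.0)
        if row["batch"] == "b2":
            mult = mult * bmult
        cols[row["sample_id"]] = nb_counts(rng, base_mean * mult)
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return counts, meta, truth


class TestFitDifferential:
    def test_identical_counts_give_null_result(self):
        rng = np.random.default_rng(0)
        base = nb_counts(rng, 300.0, size=50)
        counts = pd.DataFrame({s: base for s in ("a1", "a2", "b1", "b2")})
        design = diff.DesignTable(
            pd.DataFrame(
                {
                    "sample_id": ["a1", "a2", "b1", "b2"],
                    "condition": ["A", "A", "B", "B"],
                }
            )
        )
        res = diff.fit_differential(counts, design, ("B", "A"))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["fdr"].fillna(1.0) >= 0.05).all()

    def test_doubled_gene_recovers_log2fc_of_one(self):
        rng = np.random.default_rng(1)
        n = 100
        counts = pd.DataFrame(
            {s: nb_counts(rng, 5_000.0, disp=0.001, size=n) for s in ("a1", "a2", "b1", "b2")},
            index=[f"g{i}" for i in range(n)],
        )
        counts.loc["g0", ["b1", "b2"]] = (2 * counts.loc["g0", ["b1", "b2"]]).astype(int)
        design = diff.DesignTable(
            pd.DataFrame(
                {"sample_id": ["a1", "a2", "b1", "b2"], "condition": ["A", "A", "B", "B"]}
            )
        )
        res = diff.fit_differential(counts, design, ("B", "A")).set_index("feature")
        assert res.loc["g0", "log2fc"] == pytest.approx(1.0, abs=0.1)

    def test_swapping_contrast_negates_log2fc(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            {s: nb_counts(rng, 400.0, size=60) for s in ("a1", "a2", "b1", "b2")},
            index=[f"g{i}" for i in range(60)],
        )
        design = diff.DesignTable(
            pd.DataFrame(
                {"sample_id": ["a1", "a2", "b1", "b2"], "condition": ["A", "A", "B", "B"]}
            )
        )
        fwd = diff.fit_differential(counts, design, ("B", "A"))
        rev = diff.fit_differential(counts, design, ("A", "B"))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-6)

    def test_batch_covariate_rescues_power(self):
        """With a strong batch effect, the batch-aware model recovers >=80%
        of planted 2-fold genes at FDR<0.05 and strictly beats the
        batch-free model; null false calls stay <=5%."""
        rng = np.random.default_rng(42)
        counts, meta, truth = simulate_batch_study(rng)
        with_batch = diff.DesignTable(meta.copy(), covariates=("batch",))
        without_batch = diff.DesignTable(meta.copy())
        res_with = diff.fit_differential(counts, with_batch, ("treat", "ctrl"))
        res_without = diff.fit_differential(counts, without_batch, ("treat", "ctrl"))
        called_with = res_with["fdr"].fillna(1.0).to_numpy() < 0.05
        called_without = res_without["fdr"].fillna(1.0).to_numpy() < 0.05
        recovery_with = called_with[truth].mean()
        recovery_without = called_without[truth].mean()
        assert recovery_with >= 0.80
        assert called_with[truth].sum() > called_without[truth].sum()
        # nominal 5% with two binomial standard errors of sampling noise
        tol = 2 * np.sqrt(0.05 * 0.95 / (~truth).sum())
        assert called_with[~truth].mean() <= 0.05 + tol
        assert recovery_without < recovery_with

    def test_all_zero_features_excluded_and_reported(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            {s: nb_counts(rng, 200.0, size=20) for s in ("a1", "a2", "b1", "b2")},
            index=[f"g{i}" for i in range(20)],
        )
        counts.loc["g0"] = 0
        design = diff.DesignTable(
            pd.DataFrame(
                {"sample_id": ["a1", "a2", "b1", "b2"], "condition": ["A", "A", "B", "B"]}
            )
        )
        res = diff.fit_differential(counts, design, ("B", "A"))
        assert "g0" not in set(res["feature"])
        assert res.attrs["excluded_all_zero"] == ["g0"]

    def test_confounded_design_fatal(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "condition": ["A", "A", "B", "B"],
                "batch": ["x", "x", "y", "y"],  # batch == condition
            }
        )
        design = diff.DesignTable(meta, covariates=("batch",))
        counts = pd.DataFrame(
            {s: [10, 20] for s in ("a1", "a2", "b1", "b2")}, index=["g0", "g1"]
        )
        with pytest.raises(ConfigError, match="confounded"):
            diff.fit_differential(counts, design, ("B", "A"))

    def test_single_replicate_fatal_unless_allowed(self):
        meta = pd.DataFrame(
            {"sample_id": ["a1", "b1", "b2"], "condition": ["A", "B", "B"]}
        )
        design = diff.DesignTable(meta)
        counts = pd.DataFrame({s: [10, 20, 30] for s in ("a1", "b1", "b2")})
        with pytest.raises(ConfigError, match="replicate"):
            diff.fit_differential(counts, design, ("B", "A"))


class TestClassification:
    @pytest.mark.parametrize(
        "fdr,lfc,expected",
        [
            (0.01, 0.5, "up"),
            (0.01, -0.5, "down"),
            (0.2, 2.0, "unchanged"),
            (0.05, 1.0, "unchanged"),  # boundary FDR: strict inequality
            (0.01, 0.3, "unchanged"),  # boundary LFC: strict inequality
            (np.nan, 3.0, "unchanged"),
        ],
    )
    def test_threshold_rules(self, fdr, lfc, expected):
        res = pd.DataFrame({"fdr": [fdr], "log2fc": [lfc]})
        assert diff.classify_dysregulated(res).iloc[0] == expected


class TestPermutationNull:
    def _design(self):
        return diff.DesignTable(
            pd.DataFrame(
                {"sample_id": ["a1", "a2", "b1", "b2"], "condition": ["A", "A", "B", "B"]}
            )
        )

    def test_symmetric_feature_has_p_near_one(self):
        counts = pd.DataFrame(
            {"a1": [500], "a2": [500], "b1": [500], "b2": [500]}, index=["g0"]
        )
        res = diff.permutation_null(counts, self._design(), ("B", "A"), n_perm=100, seed=0)
        assert res["perm_pvalue"].iloc[0] > 0.9

    def test_minimum_attainable_p(self):
        """An extreme effect against a balanced background reaches the
        permutation floor of 1/(n_perm + 1)."""
        rng = np.random.default_rng(10)
        n = 40
        counts = pd.DataFrame(
            {s: rng.poisson(2_000, n) for s in ("a1", "a2", "b1", "b2")},
            index=[f"g{i}" for i in range(n)],
        )
        counts.loc["g0", ["b1", "b2"]] = [8_000, 8_400]
        res = diff.permutation_null(counts, self._design(), ("B", "A"), n_perm=100, seed=0)
        assert res.set_index("feature").loc["g0", "perm_pvalue"] == pytest.approx(1 / 101)

    def test_planted_fourfold_effect_hits_floor(self):
        rng = np.random.default_rng(4)
        n = 50
        counts = pd.DataFrame(
            {
                "a1": rng.poisson(1_000, n), "a2": rng.poisson(1_000, n),
                "b1": rng.poisson(1_000, n), "b2": rng.poisson(1_000, n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        counts.loc["g0", ["b1", "b2"]] = rng.poisson(4_000, 2)
        res = diff.permutation_null(counts, self._design(), ("B", "A"), n_perm=100, seed=0)
        assert res.set_index("feature").loc["g0", "perm_pvalue"] == pytest.approx(1 / 101)

    def test_null_pvalues_roughly_uniform(self):
        """Kolmogorov-Smirnov sanity check on permutation p-values under
        a pure null (seed-fixed)."""
        rng = np.random.default_rng(5)
        n = 300
        counts = pd.DataFrame(
            {s: rng.poisson(800, n) for s in ("a1", "a2", "b1", "b2")},
            index=[f"g{i}" for i in range(n)],
        )
        res = diff.permutation_null(counts, self._design(), ("B", "A"), n_perm=100, seed=1)
        p = sps.kstest(res["perm_pvalue"], "uniform").pvalue
        assert p > 0.01
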