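"""Chip QC, IBS kinship, GLM/MLM association and Bonferroni correction."""

import numpy as np
import pytest

from lofscreen.association import (
    KinshipMatrix,
    bonferroni_adjust,
    chip_qc_filter,
    glm_assoc,
    ibs_kinship,
    mlm_assoc,
)
from lofscreen.variants import MISSING, GenotypeMatrix, VariantSite


def chip_from_calls(calls, samples=None):
    calls = np.asarray(calls, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(calls.shape[0])]
    sites = [VariantSite("chip", j + 1, "A", "C", f"snp{j}") for j in range(calls.shape[1])]
    return GenotypeMatrix(sites, samples, calls)


class TestChipQC:
    def test_planted_failures_removed(self):
        """100 SNPs with 10 planted QC failures leave 90, each failure
        re-checked against the three rules independently."""
        rng = np.random.default_rng(42)
        n = 200
        calls = rng.choice([0, 1, 2], size=(n, 100), p=[0.45, 0.4, 0.15]).astype(np.int8)
        low_maf = range(0, 4)  # near-monomorphic
        low_cr = range(4, 7)  # mostly missing
        hwe_bad = range(7, 10)  # het deficit
        for j in low_maf:
            calls[:, j] = 0
            calls[: 2, j] = 1
        for j in low_cr:
            calls[rng.choice(n, size=int(n * 0.5), replace=False), j] = MISSING
        for j in hwe_bad:
            calls[:, j] = np.where(rng.random(n) < 0.5, 0, 2)  # no hets at q=0.5
        chip = chip_from_calls(calls)
        filtered, report = chip_qc_filter(chip)
        assert filtered.n_sites == 90
        assert report.n_maf_fail == 4
        assert report.n_snp_callrate_fail == 3
        assert report.n_hwe_fail == 3
        kept_ids = {s.site_id for s in filtered.sites}
        assert kept_ids.isdisjoint({f"snp{j}" for j in range(10)})

    def test_animal_call_rate_filter(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 1, 2], size=(30, 60)).astype(np.int8)
        calls[0, :40] = MISSING  # 33% call rate
        filtered, report = chip_qc_filter(chip_from_calls(calls))
        assert "s0" not in filtered.samples
        assert report.n_animal_callrate_fail == 1

    def test_all_removed_raises(self):
        calls = np.zeros((20, 5), dtype=np.int8)  # all monomorphic
        with pytest.raises(ValueError, match="every SNP"):
            chip_qc_filter(chip_from_calls(calls))


class TestIbsKinship:
    def test_identical_vectors(self):
        k = ibs_kinship(chip_from_calls([[0, 1, 2, 1], [0, 1, 2, 1]]))
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes(self):
        k = ibs_kinship(chip_from_calls([[0, 2, 0, 2], [2, 0, 2, 0]]))
        assert k.values[0, 1] == pytest.approx(0.0)

    def test_het_vs_hom_shares_half(self):
        k = ibs_kinship(chip_from_calls([[1], [0]]))
        assert k.values[0, 1] == pytest.approx(0.5)

    def test_symmetric_and_snp_order_invariant(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2], size=(6, 40)).astype(np.int8)
        k1 = ibs_kinship(chip_from_calls(calls))
        perm = rng.permutation(40)
        k2 = ibs_kinship(chip_from_calls(calls[:, perm]))
        np.testing.assert_allclose(k1.values, k1.values.T)
        np.testing.assert_allclose(k1.values, k2.values)

    def test_no_shared_snps_flagged_nan(self):
        calls = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        k = ibs_kinship(chip_from_calls(calls))
        assert np.isnan(k.values[0, 1])
        assert k.values[0, 0] == 1.0


class TestGlm:
    def test_perfect_separation_r2_one(self):
        dose = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([100.0, 100.0, 90.0, 90.0, 80.0, 80.0])
        r = glm_assoc(dose, y)
        assert r.r2 == pytest.approx(1.0)
        assert r.genotype_means["het"][0] == pytest.approx(90.0)

    def test_single_genotype_class_untestable(self):
        r = glm_assoc(np.zeros(10), np.random.default_rng(0).normal(size=10))
        assert not r.testable and r.p_nominal is None

    def test_matches_manual_anova(self):
        """F and p agree with the hand-computed one-way ANOVA decomposition."""
        rng = np.random.default_rng(8)
        dose = rng.choice([0, 1, 2], size=80).astype(float)
        y = rng.normal(100, 20, size=80) + 5 * dose
        r = glm_assoc(dose, y)
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        ss_within = sum(
            ((y[dose == g] - y[dose == g].mean()) ** 2).sum() for g in np.unique(dose)
        )
        k = len(np.unique(dose))
        f = ((ss_total - ss_within) / (k - 1)) / (ss_within / (len(y) - k))
        from scipy import stats as sps

        assert r.p_nominal == pytest.approx(float(sps.f.sf(f, k - 1, len(y) - k)), rel=1e-9)
        assert r.r2 == pytest.approx(1 - ss_within / ss_total, rel=1e-9)

    def test_null_rejection_rate(self):
        """Independent genotype and phenotype: p uniform, 5% rejection."""
        rng = np.random.default_rng(99)
        reps, n = 2000, 500
        rej = 0
        for _ in range(reps):
            dose = rng.choice([0, 1, 2], size=n, p=[0.49, 0.42, 0.09]).astype(float)
            y = rng.normal(100, 20, size=n)
            r = glm_assoc(dose, y)
            if r.p_nominal < 0.05:
                rej += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * se

    def test_matches_permutation_oracle(self):
        """The F-test p equals the permutation p-value on exchangeable data."""
        rng = np.random.default_rng(5)
        n, n_perm = 200, 5000
        dose = rng.choice([0, 1, 2], size=n, p=[0.5, 0.4, 0.1]).astype(float)
        y = rng.normal(100, 20, size=n) + 4.0 * dose
        r = glm_assoc(dose, y)

        def fstat(yv):
            ss_total = ((yv - yv.mean()) ** 2).sum()
            ss_within = sum(
                ((yv[dose == g] - yv[dose == g].mean()) ** 2).sum()
                for g in np.unique(dose)
            )
            return (ss_total - ss_within) / max(ss_within, 1e-300)

        obs = fstat(y)
        perm_ge = sum(fstat(rng.permutation(y)) >= obs for _ in range(n_perm))
        p_perm = (perm_ge + 1) / (n_perm + 1)
        assert abs(r.p_nominal - p_perm) < 0.02


class TestMlm:
    def test_identity_kinship_reduces_to_glm(self):
        rng = np.random.default_rng(12)
        n = 60
        dose = rng.choice([0, 1, 2], size=n).astype(float)
        y = rng.normal(100, 20, size=n) + 3 * dose
        samples = [f"s{i}" for i in range(n)]
        kin = KinshipMatrix(samples, np.eye(n))
        g = glm_assoc(dose, y)
        m = mlm_assoc(dose, y, kin, samples=samples)
        assert m.p_nominal == pytest.approx(g.p_nominal, abs=1e-6)

    def test_reml_at_local_maximum(self):
        """Perturbing the fitted variance ratio by +/-10% lowers the REML
        log-likelihood."""
        from lofscreen.association import _reml_neg_loglik

        rng = np.random.default_rng(21)
        n = 120
        samples = [f"s{i}" for i in range(n)]
        blocks = np.kron(np.eye(n // 10), np.full((10, 10), 0.5))
        np.fill_diagonal(blocks, 1.0)
        kin = KinshipMatrix(samples, blocks)
        L = np.linalg.cholesky(blocks + 1e-9 * np.eye(n))
        y = 100 + 15 * (L @ rng.standard_normal(n)) + 10 * rng.standard_normal(n)
        dose = rng.choice([0, 1, 2], size=n).astype(float)
        m = mlm_assoc(dose, y, kin, samples=samples)
        delta = (1 - m.h2) / m.h2
        s_eig, u = np.linalg.eigh(blocks)
        import pandas as pd

        from lofscreen.association import GENOTYPE_LABELS

        dummies = pd.get_dummies(pd.Series(dose.astype(int)).map(GENOTYPE_LABELS), drop_first=True)
        X = np.column_stack([np.ones(n), dummies.astype(float).to_numpy()])
        args = (np.clip(s_eig, 0, None), u.T @ y, u.T @ X)
        nll_hat = _reml_neg_loglik(np.log(delta), *args)
        assert nll_hat <= _reml_neg_loglik(np.log(delta * 1.1), *args) + 1e-6
        assert nll_hat <= _reml_neg_loglik(np.log(delta * 0.9), *args) + 1e-6

    def test_missing_kinship_coverage_raises(self):
        kin = KinshipMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError, match="kinship does not cover"):
            mlm_assoc(np.array([0.0, 1.0, 2.0]), np.zeros(3), kin, samples=["a", "b", "c"])


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [
            (0.00003, 15, 0.00045),  # the significant splice variant
            (0.2, 10, 1.0),  # capped at 1
            (0.007, 1, 0.007),  # identity at m=1
        ],
    )
    def test_values(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected, rel=1e-9)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(2)
        ps = np.sort(rng.random(20))
        for m in (1, 5, 50):
            adj = [bonferroni_adjust(p, m) for p in ps]
            assert all(b >= a for a, b in zip(adj, adj[1:]))
            assert all(0 <= a <= 1 for a in adj)
        p = 0.01
        by_m = [bonferroni_adjust(p, m) for m in range(1, 200, 10)]
        assert all(b >= a for a, b in zip(by_m, by_m[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5, 3)
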