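"""Probe filtering, effective test numbers, BY control, targeted scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crossqtl as cq
from crossqtl.config import SimConfig
from crossqtl.containers import ExpressionMatrix
from crossqtl.eqtlscan import (
    bracket_classify,
    by_fdr,
    cross_tissue_correlation,
    effective_tests,
    filter_probes,
    targeted_eqtl_scan,
)
from crossqtl.mixedlm import SpectralBasis, build_fixed_design, fit_single_trait, lr_test
from crossqtl.simpop import default_probe_plan


def _expr(values, probes=None, genes=None, scale="log2"):
    values = np.atleast_2d(np.asarray(values, float))
    probes = probes or [f"p{i+1}" for i in range(values.shape[0])]
    ann = pd.DataFrame(
        {"probe": probes,
         "gene": genes or probes,
         "chrom": "1", "mb": 1.0}
    )
    df = pd.DataFrame(values, index=probes,
                      columns=[f"s{j+1}" for j in range(values.shape[1])])
    return ExpressionMatrix(df, ann, scale=scale)


class TestFilterProbes:
    def test_constant_probe_fails(self):
        expr = _expr(np.full((1, 10), 8.0))
        _, report = filter_probes(expr)
        assert report.status["p1"] == "fail-foldchange"

    def test_exact_boundary_fraction_excluded(self):
        # exactly 20% of samples deviate -> excluded (strict 'more than')
        base = np.full(10, 8.0)
        base[:2] = 8.0 + 2.0  # 2/10 deviate by > log2(1.5)
        expr = _expr(base[None, :])
        _, report = filter_probes(expr, fraction=0.20)
        assert report.status["p1"] == "fail-foldchange"

    def test_thirty_percent_at_twice_median_kept_linear_scale(self):
        vals = np.full(10, 5.0)
        vals[:3] = 10.0  # 30% at 2 x median
        expr = _expr(vals[None, :], scale="linear")
        kept, report = filter_probes(expr)
        assert report.status["p1"] == "kept"
        assert "p1" in kept.probes

    def test_log2_rule_matches_fold_semantics(self):
        vals = np.full(20, 8.0)
        vals[:6] = 8.0 + np.log2(1.5) * 1.01  # 30% just over the fold
        expr = _expr(vals[None, :])
        _, report = filter_probes(expr)
        assert report.status["p1"] == "kept"

    def test_duplicate_probes_collapse_to_highest_mean(self):
        v1 = np.r_[np.full(5, 8.0), np.full(5, 10.0)]
        v2 = v1 + 1.0
        expr = _expr([v1, v2], probes=["a", "b"], genes=["G", "G"])
        kept, report = filter_probes(expr)
        assert report.status["a"] == "collapsed-duplicate"
        assert report.status["b"] == "kept"
        assert kept.probes == ["b"]


class TestEffectiveTests:
    def test_uncorrelated_items_give_m(self):
        # rows of an orthogonal harmonic basis have exactly zero
        # pairwise sample correlation
        t = np.arange(40)
        items = np.array(
            [np.sin(2 * np.pi * (k + 1) * t / 40) for k in range(10)]
        )
        out = effective_tests(items)
        assert out.meff == pytest.approx(10.0, abs=1e-8)

    def test_perfectly_correlated_items_give_one(self):
        v = np.random.default_rng(0).standard_normal(30)
        items = np.array([v, -v, 2 * v + 1])
        out = effective_tests(items)
        assert out.meff == pytest.approx(1.0, abs=1e-8)

    def test_two_items_r06_hand_value(self):
        # construct exact sample correlation 0.6 from an orthonormal pair
        t = np.arange(50)
        z1 = np.sin(2 * np.pi * t / 50)
        z2 = np.cos(2 * np.pi * t / 50)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = (z2 - z2.mean()) / z2.std()
        items = np.array([z1, 0.6 * z1 + 0.8 * z2])
        out = effective_tests(items)
        np.testing.assert_allclose(sorted(out.eigenvalues), [0.4, 1.6], atol=1e-8)
        assert out.meff == pytest.approx(1.64, abs=1e-8)

    def test_constant_item_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        items = np.vstack([rng.standard_normal((3, 20)), np.zeros(20)])
        with pytest.warns(UserWarning, match="constant"):
            out = effective_tests(items)
        assert out.m == 3

    def test_invariance_to_order_and_sign(self):
        rng = np.random.default_rng(2)
        items = rng.standard_normal((8, 25))
        base = effective_tests(items).meff
        perm = rng.permutation(8)
        flipped = items[perm] * np.where(np.arange(8) % 2 == 0, 1, -1)[:, None]
        assert effective_tests(flipped).meff == pytest.approx(base, abs=1e-10)


def bh_oracle(p, m, q):
    """Brute-force Benjamini-Hochberg step-up (c = 1)."""
    p = np.asarray(p, float)
    best_cut = -1.0
    for k, pk in enumerate(np.sort(p), start=1):
        if pk <= k * q / m:
            best_cut = pk
    return p <= best_cut if best_cut >= 0 else np.zeros(p.size, bool)


class TestByFdr:
    def test_hand_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        flags = by_fdr(p, m_effective=5, q=0.20)
        np.testing.assert_array_equal(flags, [True, True, True, False, False])

    def test_all_ones_no_discoveries(self):
        assert not by_fdr(np.ones(4), 4, q=0.2).any()

    def test_single_effective_test_reduces_to_threshold(self):
        assert by_fdr(np.array([0.15]), 1, q=0.2)[0]
        assert not by_fdr(np.array([0.25]), 1, q=0.2)[0]

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            by_fdr(np.array([0.1]), 1, q=1.5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_stricter_than_bh_oracle(self, plist):
        """BY's harmonic constant only shrinks the thresholds, so its
        discovery set is always a subset of Benjamini-Hochberg's."""
        p = np.array(plist)
        m = len(p)
        by = by_fdr(p, m, q=0.2)
        bh = bh_oracle(p, m, q=0.2)
        assert not np.any(by & ~bh)


class TestBracketClassify:
    def test_gene_inside(self):
        assert bracket_classify("1", 10.0, 20.0, "1", 15.0)

    def test_other_chromosome(self):
        assert not bracket_classify("1", 10.0, 20.0, "2", 15.0)

    def test_boundary_is_inside(self):
        assert bracket_classify("1", 10.0, 20.0, "1", 20.0)
        assert bracket_classify("1", 10.0, 20.0, "1", 10.0)


class TestCrossTissueCorrelation:
    def _pair(self, a, b):
        return (
            _expr(a[None, :]),
            _expr(b[None, :]),
        )

    def test_identical_vectors(self):
        v = np.random.default_rng(0).standard_normal(20)
        ea, eb = self._pair(v, v)
        out = cross_tissue_correlation(ea, eb)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_sampling_distribution_around_true_correlation(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(30):
            z = rng.standard_normal((2, 40))
            a = z[0]
            b = 0.8 * z[0] + np.sqrt(1 - 0.64) * z[1]
            ea, eb = self._pair(a, b)
            r = cross_tissue_correlation(ea, eb)["r"].iloc[0]
            hits += abs(r - 0.8) <= 0.15
        assert hits >= 27

    def test_minimal_collinear_triple(self):
        a = np.array([0.0, 1.0, 2.0])
        ea, eb = self._pair(a, 2 * a + 1)
        out = cross_tissue_correlation(ea, eb)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_paired_samples_rejected(self):
        ea = _expr(np.zeros((1, 2)))
        eb = _expr(np.zeros((1, 2)))
        with pytest.raises(ValueError, match="paired"):
            cross_tissue_correlation(ea, eb)

    def test_zero_variance_flagged(self):
        ea = _expr(np.full((1, 10), 3.0))
        eb = _expr(np.random.default_rng(0).standard_normal((1, 10)))
        with pytest.warns(UserWarning, match="zero variance"):
            out = cross_tissue_correlation(ea, eb)
        assert np.isnan(out["r"].iloc[0])


@pytest.fixture(scope="module")
def eqtl_dataset():
    config = SimConfig(
        n_bc=157, missing_rate=0.0, mendel_error_rate=0.0, seed=61,
    )
    plan = default_probe_plan(
        n_null=30,
        regulated=[dict(probe="cis_1", gene="CIS1", gene_chrom="1",
                        gene_mb=45 * 0.67, reg_chrom="1", reg_cm=45.0,
                        effect=1.5, sharing=1.0)],
    )
    ds = cq.simulate_dataset(config, probe_plan=plan)
    A = cq.numerator_relationship(ds.pedigree)
    lop = cq.line_origin_posteriors(ds, "1")
    return ds, A, lop


class TestTargetedScan:
    def test_linkage_window_recovers_cis_probe(self, eqtl_dataset):
        ds, A, lop = eqtl_dataset
        res = targeted_eqtl_scan(
            ds, ds.expression["muscle"], [{"chrom": "1", "lo": 30.0, "hi": 60.0}],
            A, mode="linkage", lop_by_chrom={"1": lop},
        )
        row = res[res["probe"] == "cis_1"].iloc[0]
        assert row["discovered"]
        assert abs(row["best_pos_cm"] - 45.0) <= 8.0
        assert row["brackets_gene"]
        # discovery flag re-derivable from p and the multiplicity
        flags = by_fdr(res["p"].to_numpy(), row["multiplicity"], q=0.20)
        np.testing.assert_array_equal(flags, res["discovered"].to_numpy())

    def test_empty_window_empty_result(self, eqtl_dataset):
        ds, A, lop = eqtl_dataset
        res = targeted_eqtl_scan(
            ds, ds.expression["muscle"], [{"chrom": "1", "lo": 900.0, "hi": 950.0}],
            A, mode="linkage", lop_by_chrom={"1": lop},
        )
        assert len(res) == 0

    def test_single_snp_window_matches_direct_animal_model(self, eqtl_dataset):
        """Association mode on a one-SNP window must equal the plain
        per-SNP animal-model LR computed directly for the probe."""
        ds, A, lop = eqtl_dataset
        geno = ds.genotypes
        j = int((geno.snps["cm"] - 45.0).abs().idxmin())
        mb = geno.snps["mb"].iloc[j]
        res = targeted_eqtl_scan(
            ds, ds.expression["muscle"],
            [{"chrom": "1", "lo": mb - 1e-6, "hi": mb + 1e-6}],
            A, mode="association",
        )
        row = res[res["probe"] == "cis_1"].iloc[0]

        from crossqtl.qtlscan import lambda_coding

        expr = ds.expression["muscle"]
        samples = expr.samples
        phen = ds.phenotypes.table.set_index("id").loc[samples].reset_index()
        basis = SpectralBasis.from_relationship(A, samples)
        F, _ = build_fixed_design(phen)
        y = expr.values.loc["cis_1", samples].to_numpy(float)
        id_rows = {ind: k for k, ind in enumerate(geno.ids)}
        lam = lambda_coding(ds, j)[[id_rows[s] for s in samples]]
        red = fit_single_trait(y, F, basis)
        full = fit_single_trait(y, np.column_stack([F, lam]), basis)
        t = lr_test(full, red, df=1)
        assert row["lr"] == pytest.approx(t.lr, abs=1e-4)

    def test_mode_validated(self, eqtl_dataset):
        ds, A, lop = eqtl_dataset
        with pytest.raises(ValueError, match="mode"):
            targeted_eqtl_scan(ds, ds.expression["muscle"], [], A, mode="banana")
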