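"""Scans, q-values, confidence intervals, TAS regions, decision trees."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crossqtl as cq
from crossqtl.config import QtlSpec, SimConfig
from crossqtl.mixedlm import chisq_pvalue
from crossqtl.qtlscan import (
    ScanResult,
    bivariate_linkage_scan,
    call_tas_regions,
    gwas_scan,
    lambda_coding,
    linkage_scan,
    mangin_ci,
    multitrait_refine,
    pleiotropy_decision_gwas,
    pleiotropy_decision_linkage,
    storey_qvalues,
)


def brute_force_stepup(p):
    """Independent oracle for the q-value step-up with pi0 = 1."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = []
        for j, pj in enumerate(np.sort(p)):
            if pj >= pi - 1e-15:
                candidates.append(m * pj / (j + 1))
        q[i] = min(min(candidates), 1.0)
    return q


class TestStoreyQvalues:
    def test_hand_example(self):
        q = storey_qvalues(np.array([0.01, 0.02, 0.8, 0.9]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.9, 0.9], atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(storey_qvalues(np.ones(5)), 1.0)

    def test_single_p(self):
        assert storey_qvalues(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.1, 1.5]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_brute_force_oracle_small_m(self, plist):
        """For m < 100 the pi0 = 1 fallback applies, so the result must
        equal an independent brute-force step-up."""
        p = np.array(plist)
        np.testing.assert_allclose(
            storey_qvalues(p), brute_force_stepup(p), atol=1e-10
        )

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=300)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _profile_scan(lrs, step=1.0):
    table = pd.DataFrame(
        {
            "chrom": "1",
            "pos_cm": np.arange(len(lrs), dtype=float) * step,
            "lr": np.asarray(lrs, float),
            "df": 1,
            "p": np.nan,
        }
    )
    return ScanResult("linkage", ("bf",), 1, table)


class TestManginCI:
    def test_single_spike_bounded_by_neighbors(self):
        scan = _profile_scan([0, 0, 30, 0, 0])
        ci = mangin_ci(scan, 2.0, df=1)
        assert (ci.lower_cm, ci.peak_cm, ci.upper_cm) == (1.0, 2.0, 3.0)

    def test_flat_profile_spans_scan(self):
        scan = _profile_scan([5, 5, 5, 5])
        ci = mangin_ci(scan, 0.0, df=1)
        assert ci.lower_cm == 0.0 and ci.upper_cm == 3.0

    def test_toy_profile_drop_excludes_far_flanks(self):
        scan = _profile_scan([1, 5, 9, 5, 1])
        ci = mangin_ci(scan, 2.0, df=1)
        assert (ci.lower_cm, ci.upper_cm) == (1.0, 3.0)

    def test_wrong_peak_rejected(self):
        scan = _profile_scan([1, 5, 9, 5, 1])
        with pytest.raises(ValueError, match="argmax"):
            mangin_ci(scan, 1.0, df=1)


class TestLambdaCoding:
    def test_iberian_enriched_allele_positive(self, fixed_line_dataset):
        ds, _ = fixed_line_dataset
        lam = lambda_coding(ds, 0)
        dos = ds.genotypes.dosage(0)
        ok = ~np.isnan(dos)
        # allele A fixed in Iberian founders: hom-A -> +1, het -> 0, hom-B -> -1
        np.testing.assert_allclose(lam[ok], dos[ok] - 1.0)

    def test_reversed_when_landrace_enriched(self, fixed_line_dataset):
        ds, _ = fixed_line_dataset
        geno = ds.genotypes
        flipped = cq.GenotypeMatrix(
            geno.snps, geno.ids, np.where(geno.calls >= 0, 2 - geno.calls, -1).astype(np.int8)
        )
        ds2 = cq.Dataset(genotypes=flipped, pedigree=ds.pedigree,
                         phenotypes=ds.phenotypes)
        lam = lambda_coding(ds2, 0)
        dos = flipped.dosage(0)
        ok = ~np.isnan(dos)
        np.testing.assert_allclose(lam[ok], 1.0 - dos[ok])


class TestTasRegions:
    def _scan(self, cms, qs, snps=None):
        n = len(cms)
        table = pd.DataFrame(
            {
                "snp": snps if snps is not None else [f"s{i+1}" for i in range(n)],
                "chrom": "1",
                "cm": cms,
                "mb": np.asarray(cms) * 0.67,
                "lr": 10.0,
                "df": 1,
                "p": 1e-4,
                "effect": 0.5,
                "se": 0.1,
                "q": qs,
            }
        )
        return ScanResult("gwas", ("bf",), 1, table)

    def test_three_close_significant_snps_form_region(self, manual_dataset_factory):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(8, 3)).astype(np.int8)
        ds = manual_dataset_factory(calls, cm=[10.0, 10.8, 11.9])
        scan = self._scan([10.0, 10.8, 11.9], [0.01, 0.01, 0.01])
        regions = call_tas_regions(scan, ds.genotypes)
        assert len(regions) == 1
        assert regions[0].n == 3

    def test_two_significant_snps_insufficient(self, manual_dataset_factory):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(8, 3)).astype(np.int8)
        ds = manual_dataset_factory(calls, cm=[10.0, 10.8, 11.9])
        scan = self._scan([10.0, 10.8, 11.9], [0.01, 0.01, 0.5])
        assert call_tas_regions(scan, ds.genotypes) == []

    def test_fully_linked_cluster_rejected(self, manual_dataset_factory):
        col = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=np.int8)
        calls = np.tile(col[:, None], (1, 3))
        ds = manual_dataset_factory(calls, cm=[10.0, 10.8, 11.9])
        scan = self._scan([10.0, 10.8, 11.9], [0.01, 0.01, 0.01])
        assert call_tas_regions(scan, ds.genotypes) == []

    def test_gap_splits_clusters(self, manual_dataset_factory):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        cms = [1.0, 1.5, 2.0, 10.0, 10.5, 11.0]
        ds = manual_dataset_factory(calls, cm=cms)
        scan = self._scan(cms, [0.01] * 6)
        regions = call_tas_regions(scan, ds.genotypes)
        assert len(regions) == 2
        assert regions[0].cm_hi < regions[1].cm_lo  # never overlap

    def test_input_order_invariance(self, manual_dataset_factory):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(8, 4)).astype(np.int8)
        cms = [5.0, 5.5, 6.0, 6.5]
        ds = manual_dataset_factory(calls, cm=cms)
        scan = self._scan(cms, [0.01] * 4)
        shuffled = ScanResult(
            "gwas", ("bf",), 1,
            scan.table.sample(frac=1.0, random_state=3).reset_index(drop=True),
        )
        a = call_tas_regions(scan, ds.genotypes)
        b = call_tas_regions(shuffled, ds.genotypes)
        assert [r.snps for r in a] == [r.snps for r in b]


class TestScans:
    def test_linkage_scan_recovers_simulated_qtl(self, clean_dataset, clean_A):
        lop = cq.line_origin_posteriors(clean_dataset, "1")
        scan = linkage_scan(clean_dataset, "bf", lop, clean_A)
        t = scan.table
        peak = t.loc[t["lr"].idxmax()]
        assert abs(peak["pos_cm"] - 45.0) <= 10.0
        assert peak["q"] < 0.05
        # q monotone in p within the scan
        ok = t["p"].notna()
        order = np.argsort(t.loc[ok, "p"].to_numpy())
        assert np.all(np.diff(t.loc[ok, "q"].to_numpy()[order]) >= -1e-12)

    def test_degenerate_pa_gives_missing_tests(self, clean_dataset, clean_A):
        lop = cq.line_origin_posteriors(clean_dataset, "1")
        lop.probs[:, :, 1] = 0.5
        lop.probs[:, :, 2] = 0.5
        scan = linkage_scan(clean_dataset, "bf", lop, clean_A)
        assert scan.table["p"].isna().all()

    def test_gwas_flags_causal_marker(self):
        m = 21
        config = SimConfig(
            n_bc=400, chromosomes=[("1", 100.0, m)],
            founder_freqs=np.tile([1.0, 0.0], (m, 1)),
            qtl_architecture=[QtlSpec("1", 50.0, 0.8, 0.8, "pleiotropic")],
            missing_rate=0.0, mendel_error_rate=0.0, seed=31,
        )
        ds = cq.simulate_dataset(config)
        A = cq.numerator_relationship(ds.pedigree)
        scan = gwas_scan(ds, "bf", A)
        t = scan.table
        causal = t.loc[(t["cm"] - 50.0).abs().idxmin()]
        assert causal["q"] < 0.05

    def test_gwas_null_fdr_controlled(self):
        config = SimConfig(
            n_bc=157, chromosomes=[("1", 200.0, 400)],
            missing_rate=0.0, mendel_error_rate=0.0, seed=37,
        )
        ds = cq.simulate_dataset(config)
        A = cq.numerator_relationship(ds.pedigree)
        scan = gwas_scan(ds, "bf", A)
        discoveries = (scan.table["q"] < 0.05).sum()
        assert discoveries <= 4  # ~1% of tested SNPs

    def test_linkage_equals_gwas_at_fully_informative_marker(self):
        """At a line-fixed marker the lambda coding equals P_a, so the
        two engines must produce the same LR."""
        m = 11
        config = SimConfig(
            n_bc=150, chromosomes=[("1", 100.0, m)],
            founder_freqs=np.tile([1.0, 0.0], (m, 1)),
            qtl_architecture=[QtlSpec("1", 50.0, 0.5, 0.5, "pleiotropic")],
            missing_rate=0.0, mendel_error_rate=0.0, seed=41,
        )
        ds = cq.simulate_dataset(config)
        A = cq.numerator_relationship(ds.pedigree)
        lop = cq.line_origin_posteriors(
            ds, "1", positions=ds.genotypes.snps["cm"].to_numpy(),
            emission_slack=0.0,
        )
        lscan = linkage_scan(ds, "bf", lop, A)
        gscan = gwas_scan(ds, "bf", A)
        np.testing.assert_allclose(
            lscan.table["lr"].to_numpy(), gscan.table["lr"].to_numpy(), atol=1e-4
        )


@pytest.fixture(scope="module")
def pleio_call():
    config = SimConfig(
        n_bc=300, qtl_architecture=[QtlSpec("1", 45.0, 0.7, 0.7, "pleiotropic")],
        missing_rate=0.0, mendel_error_rate=0.0, seed=51,
    )
    ds = cq.simulate_dataset(config)
    A = cq.numerator_relationship(ds.pedigree)
    lop = cq.line_origin_posteriors(ds, "1", grid_step=2.0)
    return pleiotropy_decision_linkage(ds, ("bf", "imf"), "1", lop, A)


class TestDecisionTrees:
    def test_pleiotropic_architecture_classified(self, pleio_call):
        assert pleio_call.classification == "pleiotropic"
        assert abs(pleio_call.positions["pleiotropic"] - 45.0) <= 10.0

    def test_classification_rederivable_from_stored_tests(self, pleio_call):
        """Audit property: the stored LR tests alone reproduce the call."""
        t = pleio_call.tests
        assert t["pleio_vs_trait1_only"].p < 0.05
        assert t["pleio_vs_trait2_only"].p < 0.05
        assert t["two_qtl_vs_pleio"].p >= 0.05
        for test in t.values():
            assert test.p == pytest.approx(chisq_pvalue(test.lr, test.df))

    def test_tissue_specific_architecture(self):
        config = SimConfig(
            n_bc=300, qtl_architecture=[QtlSpec("1", 45.0, 0.9, 0.0, "trait1-only")],
            missing_rate=0.0, mendel_error_rate=0.0, seed=53,
        )
        ds = cq.simulate_dataset(config)
        A = cq.numerator_relationship(ds.pedigree)
        lop = cq.line_origin_posteriors(ds, "1", grid_step=2.0)
        call = pleiotropy_decision_linkage(ds, ("bf", "imf"), "1", lop, A)
        assert call.classification == "trait1-specific"

    def test_gwas_decision_pleiotropic_snp(self):
        # 1 cM marker spacing so significant SNPs can satisfy the
        # < 1.5 cM TAS clustering rule
        m = 31
        config = SimConfig(
            n_bc=300, chromosomes=[("1", 30.0, m)],
            founder_freqs=np.tile([1.0, 0.0], (m, 1)),
            qtl_architecture=[QtlSpec("1", 15.0, 0.5, 0.5, "pleiotropic")],
            missing_rate=0.0, mendel_error_rate=0.0, seed=55,
        )
        ds = cq.simulate_dataset(config)
        A = cq.numerator_relationship(ds.pedigree)
        from crossqtl.qtlscan import bivariate_gwas_scan

        scan = bivariate_gwas_scan(ds, ("bf", "imf"), A)
        regions = call_tas_regions(scan, ds.genotypes)
        assert regions, "expected a significant bivariate TAS region"
        region = max(regions, key=lambda r: r.n)
        call = pleiotropy_decision_gwas(ds, ("bf", "imf"), region, A)
        assert call.classification == "pleiotropic"

    def test_gwas_decision_missing_snp_rejected(self, clean_dataset, clean_A):
        from crossqtl.qtlscan import TASRegion

        region = TASRegion("1", 0, 1, 0, 1, ["nope"], "nope", 1e-5, 0.5, 0.1)
        with pytest.raises(ValueError, match="absent"):
            pleiotropy_decision_gwas(clean_dataset, ("bf", "imf"), region, clean_A)


class TestMultitraitRefine:
    def test_pairwise_refine_matches_bivariate_scan(self, clean_dataset, clean_A):
        lop = cq.line_origin_posteriors(clean_dataset, "1", grid_step=5.0)
        scan2, _, _, _ = bivariate_linkage_scan(
            clean_dataset, ("bf", "imf"), lop, clean_A
        )
        refined, ci = multitrait_refine(clean_dataset, ["bf", "imf"], "1", lop, clean_A)
        np.testing.assert_allclose(
            refined.table["lr"].to_numpy(), scan2.table["lr"].to_numpy(), atol=1e-2
        )
        assert ci is not None and ci.lower_cm <= ci.peak_cm <= ci.upper_cm

    def test_trait_count_guard(self, clean_dataset, clean_A):
        lop = cq.line_origin_posteriors(clean_dataset, "1", grid_step=10.0)
        with pytest.raises(ValueError, match="traits"):
            multitrait_refine(
                clean_dataset, ["bf", "imf"] * 3, "1", lop, clean_A
            )
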