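"""Genome scans, confidence intervals, FDR control, TAS regions, and the
pleiotropy decision trees.

Linkage scans test the line-origin additive coefficient P_a on a cM grid
(df = 1 per position); GWAS tests a per-SNP indicator lambda coded +1
for the homozygote of the Iberian-enriched allele, -1 for the opposite
homozygote and 0 for heterozygotes.  Bivariate models share the tested
position (or SNP) across the two tissues with separate effects; the
decision trees compare the pleiotropic model against tissue-specific
reductions and against a two-linked-QTL alternative.

Multiplicity within a scan is controlled by Storey q-values; the staged
decision-tree contrasts after the scan gate use nominal 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .containers import Dataset, GenotypeMatrix
from .lineorigin import LineOriginProbs, estimate_line_frequencies
from .mixedlm import (
    FitResult,
    LRTest,
    SpectralBasis,
    build_fixed_design,
    chisq_pvalue,
    fit_multitrait,
    fit_single_trait,
    lr_test,
)
from .pedkin import RelationshipMatrix


@dataclass
class ScanResult:
    kind: str  # 'linkage' or 'gwas'
    traits: tuple
    df: int
    table: pd.DataFrame  # one row per position/SNP


@dataclass
class ConfidenceInterval:
    chromosome: str
    peak_cm: float
    lower_cm: float
    upper_cm: float


@dataclass
class TASRegion:
    chromosome: str
    cm_lo: float
    cm_hi: float
    mb_lo: float
    mb_hi: float
    snps: list
    top_snp: str
    top_p: float
    top_effect: float
    top_se: float

    @property
    def n(self) -> int:
        return len(self.snps)


@dataclass
class QTLCall:
    chromosome: str
    traits: tuple
    classification: str  # none / trait1-specific / trait2-specific /
    #                      pleiotropic / two-linked-QTL
    tests: Dict[str, LRTest] = field(default_factory=dict)
    positions: dict = field(default_factory=dict)
    intervals: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    scan: Optional[ScanResult] = None


# ---------------------------------------------------------------------------
# FDR

def storey_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) with a
    cubic-spline smoother evaluated at the largest lambda, clamped to
    (0, 1]; for fewer than 100 p-values the conservative pi0 = 1 is
    used.  q_(i) = pi0 * min_{j >= i} m p_(j) / j.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if m < 100:
        pi0 = 1.0
    else:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        try:
            spl = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(spl(lam[-1]))
        except Exception:
            pi0 = float(pi0_lam[-1])
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(pi0 * q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# scans

def _phenotyped(dataset: Dataset, traits: Sequence[str]) -> pd.DataFrame:
    phen = dataset.phenotypes.table
    return phen[phen[list(traits)].notna().any(axis=1)].reset_index(drop=True)


def linkage_scan(
    dataset: Dataset,
    trait: str,
    lop: LineOriginProbs,
    A: RelationshipMatrix,
    basis: Optional[SpectralBasis] = None,
) -> ScanResult:
    """Single-trait single-QTL scan on the line-origin grid (df = 1)."""
    phen = _phenotyped(dataset, [trait])
    phen = phen[phen[trait].notna()].reset_index(drop=True)
    ids = list(phen["id"])
    if basis is None:
        basis = SpectralBasis.from_relationship(A, ids)
    F, fnames = build_fixed_design(phen)
    y = phen[trait].to_numpy(float)
    reduced = fit_single_trait(y, F, basis, names=fnames)

    row_idx = [lop.ids.index(i) for i in ids]
    pa = lop.p_a[row_idx]  # (n, n_pos)
    rows = []
    for j, pos in enumerate(lop.positions):
        col = pa[:, j]
        if np.ptp(col) < 1e-12:
            rows.append((lop.chromosome, pos, np.nan, 1, np.nan, np.nan, np.nan))
            continue
        X = np.column_stack([F, col])
        full = fit_single_trait(y, X, basis, names=fnames + ["a_qtl"])
        t = lr_test(full, reduced, df=1)
        eff, se = full.effect("a_qtl")
        rows.append((lop.chromosome, pos, t.lr, 1, t.p, eff, se))
    table = pd.DataFrame(
        rows, columns=["chrom", "pos_cm", "lr", "df", "p", "effect", "se"]
    )
    ok = table["p"].notna()
    table["q"] = np.nan
    table.loc[ok, "q"] = storey_qvalues(table.loc[ok, "p"].to_numpy())
    return ScanResult("linkage", (trait,), 1, table)


def lambda_coding(
    dataset: Dataset, snp_index: int, freqs: Optional[pd.DataFrame] = None
) -> np.ndarray:
    """Per-animal SNP indicator: +1 hom for the Iberian-enriched allele,
    -1 the opposite homozygote, 0 het, NaN missing."""
    if freqs is None:
        freqs = estimate_line_frequencies(dataset)
    dos = dataset.genotypes.dosage(snp_index)
    ib = freqs["freq_iberian"].iloc[snp_index]
    ld = freqs["freq_landrace"].iloc[snp_index]
    lam = dos - 1.0
    if ib < ld:
        lam = -lam
    return lam


def gwas_scan(
    dataset: Dataset,
    trait: str,
    A: RelationshipMatrix,
    snp_indices: Optional[Sequence[int]] = None,
) -> ScanResult:
    """Per-SNP association scan under the animal model (df = 1).

    Animals missing a SNP are dropped for that test (the no-SNP reduced
    model is refitted per missingness pattern and cached)."""
    phen = _phenotyped(dataset, [trait])
    phen = phen[phen[trait].notna()].reset_index(drop=True)
    ids = list(phen["id"])
    geno = dataset.genotypes
    freqs = estimate_line_frequencies(dataset)
    id_rows = {ind: k for k, ind in enumerate(geno.ids)}
    rows_geno = np.array([id_rows[i] for i in ids])
    y_all = phen[trait].to_numpy(float)
    F_all, fnames = build_fixed_design(phen)

    if snp_indices is None:
        snp_indices = range(geno.n_snps)

    basis_cache: Dict[bytes, tuple] = {}
    out = []
    for j in snp_indices:
        lam_all = lambda_coding(dataset, j, freqs)[rows_geno]
        ok = ~np.isnan(lam_all)
        snp_row = geno.snps.iloc[j]
        if ok.sum() < 3 or np.ptp(lam_all[ok]) < 1e-12:
            out.append(
                (snp_row["snp"], snp_row["chrom"], snp_row["cm"], snp_row["mb"],
                 np.nan, 1, np.nan, np.nan, np.nan)
            )
            continue
        key = ok.tobytes()
        if key not in basis_cache:
            sub_ids = [i for i, k in zip(ids, ok) if k]
            b = SpectralBasis.from_relationship(A, sub_ids)
            red = fit_single_trait(y_all[ok], F_all[ok], b, names=fnames)
            basis_cache[key] = (b, red)
        b, red = basis_cache[key]
        X = np.column_stack([F_all[ok], lam_all[ok]])
        full = fit_single_trait(y_all[ok], X, b, names=fnames + ["g_snp"])
        t = lr_test(full, red, df=1)
        eff, se = full.effect("g_snp")
        out.append(
            (snp_row["snp"], snp_row["chrom"], snp_row["cm"], snp_row["mb"],
             t.lr, 1, t.p, eff, se)
        )
    table = pd.DataFrame(
        out, columns=["snp", "chrom", "cm", "mb", "lr", "df", "p", "effect", "se"]
    )
    ok = table["p"].notna()
    table["q"] = np.nan
    table.loc[ok, "q"] = storey_qvalues(table.loc[ok, "p"].to_numpy())
    return ScanResult("gwas", (trait,), 1, table)


def bivariate_gwas_scan(
    dataset: Dataset,
    trait_pair: Tuple[str, str],
    A: RelationshipMatrix,
    snp_indices: Optional[Sequence[int]] = None,
) -> ScanResult:
    """Shared-SNP bivariate association scan (two effects, df = 2)."""
    phen = _phenotyped(dataset, trait_pair)
    ids = list(phen["id"])
    geno = dataset.genotypes
    freqs = estimate_line_frequencies(dataset)
    id_rows = {ind: k for k, ind in enumerate(geno.ids)}
    rows_geno = np.array([id_rows[i] for i in ids])
    Y_all = phen[list(trait_pair)].to_numpy(float)
    F_all, fnames = build_fixed_design(phen)
    if snp_indices is None:
        snp_indices = range(geno.n_snps)

    cache: Dict[bytes, tuple] = {}
    warm: Optional[np.ndarray] = None
    out = []
    for j in snp_indices:
        lam_all = lambda_coding(dataset, j, freqs)[rows_geno]
        ok = ~np.isnan(lam_all) & ~np.isnan(Y_all).any(axis=1)
        snp_row = geno.snps.iloc[j]
        if ok.sum() < 4 or np.ptp(lam_all[ok]) < 1e-12:
            out.append(
                (snp_row["snp"], snp_row["chrom"], snp_row["cm"], snp_row["mb"],
                 np.nan, 2, np.nan, np.nan, np.nan, np.nan, np.nan)
            )
            continue
        key = ok.tobytes()
        if key not in cache:
            sub_ids = [i for i, k in zip(ids, ok) if k]
            b = SpectralBasis.from_relationship(A, sub_ids)
            red = fit_multitrait(Y_all[ok], [F_all[ok]] * 2, b)
            cache[key] = (b, red)
        b, red = cache[key]
        X = np.column_stack([F_all[ok], lam_all[ok]])
        names = [f"{t}:{nm}" for t in trait_pair for nm in fnames + ["g_snp"]]
        full = fit_multitrait(
            Y_all[ok], [X, X], b, names=names,
            x0=warm if warm is not None else red.varcomp.get("theta"),
        )
        warm = full.varcomp.get("theta")
        t = lr_test(full, red, df=2)
        e1, s1 = full.effect(f"{trait_pair[0]}:g_snp")
        e2, s2 = full.effect(f"{trait_pair[1]}:g_snp")
        out.append(
            (snp_row["snp"], snp_row["chrom"], snp_row["cm"], snp_row["mb"],
             t.lr, 2, t.p, e1, s1, e2, s2)
        )
    table = pd.DataFrame(
        out,
        columns=["snp", "chrom", "cm", "mb", "lr", "df", "p",
                 "effect1", "se1", "effect2", "se2"],
    )
    ok = table["p"].notna()
    table["q"] = np.nan
    table.loc[ok, "q"] = storey_qvalues(table.loc[ok, "p"].to_numpy())
    return ScanResult("gwas", tuple(trait_pair), 2, table)


# ---------------------------------------------------------------------------
# confidence intervals

def mangin_ci(
    scan: ScanResult, peak_cm: float, df: int, level: float = 0.95
) -> ConfidenceInterval:
    """LR-drop confidence interval around the scan peak.

    The interval covers every grid position with LR >= LR_max -
    chi2(level, df) and, because the true crossing of the drop threshold
    lies between grid points, its endpoints are placed at the first
    position *below* the threshold on each side (clipped to the scanned
    range) -- the conservative convention standard for profile-LOD
    intervals on a discrete grid."""
    table = scan.table
    pos = table["pos_cm"].to_numpy() if "pos_cm" in table else table["cm"].to_numpy()
    lr = table["lr"].to_numpy(float)
    ok = np.isfinite(lr)
    pos, lr = pos[ok], lr[ok]
    peak_idx = int(np.nanargmax(lr))
    if not np.isclose(pos[peak_idx], peak_cm):
        raise ValueError(
            f"peak {peak_cm} is not the scan argmax ({pos[peak_idx]})"
        )
    thr = lr.max() - stats.chi2.ppf(level, df)
    inside = np.flatnonzero(lr >= thr)
    lo_idx = max(inside.min() - 1, 0)
    hi_idx = min(inside.max() + 1, len(pos) - 1)
    return ConfidenceInterval(
        chromosome=str(table["chrom"].iloc[0]),
        peak_cm=float(pos[peak_idx]),
        lower_cm=float(pos[lo_idx]), upper_cm=float(pos[hi_idx]),
    )


# ---------------------------------------------------------------------------
# TAS regions

def call_tas_regions(
    scan: ScanResult,
    genotypes: GenotypeMatrix,
    q_max: float = 0.05,
    gap_max_cm: float = 1.5,
    min_snps: int = 3,
) -> List[TASRegion]:
    """Cluster significant SNPs into trait-associated regions.

    Consecutive significant SNPs (q < q_max) closer than ``gap_max_cm``
    join a cluster; clusters need at least ``min_snps`` members that are
    not all in complete mutual LD (every pairwise dosage r2 = 1 rejects
    the cluster).  Invariant to SNP input order; regions never overlap.
    """
    table = scan.table.sort_values(["chrom", "cm", "snp"], kind="stable")
    sig = table[table["q"] < q_max]
    snp_col = {s: i for i, s in enumerate(genotypes.snps["snp"])}
    regions: List[TASRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        cms = grp["cm"].to_numpy()
        split = np.flatnonzero(np.diff(cms) >= gap_max_cm)
        starts = np.concatenate(([0], split + 1))
        ends = np.concatenate((split + 1, [len(grp)]))
        for s, e in zip(starts, ends):
            cluster = grp.iloc[s:e]
            if len(cluster) < min_snps:
                continue
            cols = [snp_col[s_] for s_ in cluster["snp"] if s_ in snp_col]
            D = genotypes.dosages()[:, cols]
            fully_linked = True
            for a in range(len(cols)):
                for b in range(a + 1, len(cols)):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        try:
                            from .snpqc import ld_r2

                            r2 = ld_r2(D[:, a], D[:, b])
                        except ValueError:
                            r2 = np.nan
                    if np.isfinite(r2) and r2 < 1.0 - 1e-9:
                        fully_linked = False
                        break
                if not fully_linked:
                    break
            if fully_linked:
                continue
            top = cluster.loc[cluster["p"].idxmin()]
            eff_col = "effect" if "effect" in cluster else "effect1"
            se_col = "se" if "se" in cluster else "se1"
            regions.append(
                TASRegion(
                    chromosome=str(chrom),
                    cm_lo=float(cluster["cm"].min()),
                    cm_hi=float(cluster["cm"].max()),
                    mb_lo=float(cluster["mb"].min()),
                    mb_hi=float(cluster["mb"].max()),
                    snps=list(cluster["snp"]),
                    top_snp=str(top["snp"]),
                    top_p=float(top["p"]),
                    top_effect=float(top[eff_col]),
                    top_se=float(top[se_col]),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# pleiotropy decision trees

def bivariate_linkage_scan(
    dataset: Dataset,
    trait_pair: Tuple[str, str],
    lop: LineOriginProbs,
    A: RelationshipMatrix,
    basis: Optional[SpectralBasis] = None,
) -> Tuple[ScanResult, FitResult, SpectralBasis, dict]:
    """Shared-position bivariate scan (pleiotropic model, df = 2 vs null).

    Returns the scan, the null fit, the basis and a context dict reused
    by the decision tree (designs, phenotypes, warm-start parameters)."""
    phen = _phenotyped(dataset, trait_pair)
    ids = list(phen["id"])
    if basis is None:
        basis = SpectralBasis.from_relationship(A, ids)
    F, fnames = build_fixed_design(phen)
    Y = phen[list(trait_pair)].to_numpy(float)
    null = fit_multitrait(Y, [F, F], basis)
    row_idx = [lop.ids.index(i) for i in ids]
    pa = lop.p_a[row_idx]
    warm = null.varcomp.get("theta")
    rows = []
    fits = {}
    for j, pos in enumerate(lop.positions):
        col = pa[:, j]
        if np.ptp(col) < 1e-12:
            rows.append((lop.chromosome, pos, np.nan, 2, np.nan,
                         np.nan, np.nan, np.nan, np.nan))
            continue
        X = np.column_stack([F, col])
        names = [f"{t}:{nm}" for t in trait_pair for nm in fnames + ["a_qtl"]]
        full = fit_multitrait(Y, [X, X], basis, names=names, x0=warm)
        warm = full.varcomp.get("theta")
        t = lr_test(full, null, df=2)
        e1, s1 = full.effect(f"{trait_pair[0]}:a_qtl")
        e2, s2 = full.effect(f"{trait_pair[1]}:a_qtl")
        rows.append((lop.chromosome, pos, t.lr, 2, t.p, e1, s1, e2, s2))
        fits[pos] = full
    table = pd.DataFrame(
        rows, columns=["chrom", "pos_cm", "lr", "df", "p",
                       "effect1", "se1", "effect2", "se2"],
    )
    ok = table["p"].notna()
    table["q"] = np.nan
    table.loc[ok, "q"] = storey_qvalues(table.loc[ok, "p"].to_numpy())
    scan = ScanResult("linkage", tuple(trait_pair), 2, table)
    ctx = {"phen": phen, "F": F, "fnames": fnames, "Y": Y, "pa": pa,
           "ids": ids, "fits": fits, "null": null}
    return scan, null, basis, ctx


def pleiotropy_decision_linkage(
    dataset: Dataset,
    trait_pair: Tuple[str, str],
    chromosome: str,
    lop: LineOriginProbs,
    A: RelationshipMatrix,
    alpha: float = 0.05,
    q_gate: float = 0.05,
    coarse_factor: int = 2,
) -> QTLCall:
    """Staged pleiotropy-vs-linked-QTL classification on one chromosome.

    (i) shared-position bivariate scan, Storey q gate at the peak;
    (ii) pleiotropic model against each single-tissue reduction at the
    peak (df = 1 each; both must reject, otherwise the call is
    tissue-specific toward the surviving tissue); (iii) two-QTL model
    (independent positions, one per trait, profiled over a coarsened
    position grid with variance components held at the pleiotropic-peak
    estimates, then refitted exactly at the best pair) against the
    pleiotropic model, df = 1.  All intermediate tests are stored, and
    the two-QTL model's df = 3 contrast against the null is recorded for
    transparency alongside the nested df = 1 contrast used to decide.
    """
    scan, null, basis, ctx = bivariate_linkage_scan(dataset, trait_pair, lop, A)
    call = QTLCall(chromosome=chromosome, traits=tuple(trait_pair), scan=scan,
                   classification="none")
    table = scan.table
    ok = table["p"].notna()
    if not ok.any():
        return call
    peak_row = table.loc[table.loc[ok, "lr"].idxmax()]
    peak_pos = float(peak_row["pos_cm"])
    call.positions["pleiotropic"] = peak_pos
    if not (peak_row["q"] < q_gate):
        return call

    F, fnames, Y = ctx["F"], ctx["fnames"], ctx["Y"]
    pa = ctx["pa"]
    positions = lop.positions
    jpeak = int(np.argmin(np.abs(positions - peak_pos)))
    col = pa[:, jpeak]
    X = np.column_stack([F, col])
    pleio = ctx["fits"][positions[jpeak]]
    warm = pleio.varcomp.get("theta")
    t1, t2 = trait_pair

    only1 = fit_multitrait(
        Y, [X, F], basis,
        names=[f"{t1}:{nm}" for nm in fnames + ["a_qtl"]]
        + [f"{t2}:{nm}" for nm in fnames],
        x0=warm,
    )
    only2 = fit_multitrait(
        Y, [F, X], basis,
        names=[f"{t1}:{nm}" for nm in fnames]
        + [f"{t2}:{nm}" for nm in fnames + ["a_qtl"]],
        x0=warm,
    )
    test_vs1 = lr_test(pleio, only1, df=1)  # tests the trait2 effect
    test_vs2 = lr_test(pleio, only2, df=1)  # tests the trait1 effect
    call.tests["pleio_vs_null"] = lr_test(pleio, null, df=2)
    call.tests["pleio_vs_trait1_only"] = test_vs1
    call.tests["pleio_vs_trait2_only"] = test_vs2
    call.effects = {
        t1: pleio.effect(f"{t1}:a_qtl"),
        t2: pleio.effect(f"{t2}:a_qtl"),
    }
    call.intervals["pleiotropic"] = mangin_ci(scan, peak_pos, df=2)

    if not (test_vs1.p < alpha and test_vs2.p < alpha):
        if test_vs1.p >= alpha and test_vs2.p >= alpha:
            call.classification = (
                "trait1-specific" if only1.loglik >= only2.loglik else "trait2-specific"
            )
        elif test_vs1.p >= alpha:
            # trait2 effect dispensable -> QTL specific to trait1
            call.classification = "trait1-specific"
        else:
            call.classification = "trait2-specific"
        return call

    # step (iii): two-QTL alternative.  Position profiling holds the
    # variance components at the pleiotropic-peak estimates (fast mode)
    # on a coarsened product grid with local refinement; the selected
    # pair is then refitted by full ML.
    from .mixedlm import _mt_profile

    G0, R0 = pleio.varcomp["G0"], pleio.varcomp["R0"]
    Yt = basis.U.T @ Y
    Ft = basis.U.T @ F
    pat = basis.U.T @ pa
    d = basis.d
    informative = [j for j in range(len(positions)) if np.ptp(pa[:, j]) >= 1e-12]
    coarse = informative[::coarse_factor]

    def fast_ll(j1, j2):
        X1 = np.column_stack([Ft, pat[:, j1]])
        X2 = np.column_stack([Ft, pat[:, j2]])
        return _mt_profile(G0, R0, Yt, [X1, X2], d)[0]

    best = (None, None, -np.inf)
    for j1 in coarse:
        for j2 in coarse:
            ll = fast_ll(j1, j2)
            if ll > best[2]:
                best = (j1, j2, ll)
    j1, j2, _ = best
    window = coarse_factor + 1
    local1 = [j for j in informative if abs(j - j1) <= window]
    local2 = [j for j in informative if abs(j - j2) <= window]
    for jj1 in local1:
        for jj2 in local2:
            ll = fast_ll(jj1, jj2)
            if ll > best[2]:
                best = (jj1, jj2, ll)
    j1, j2, _ = best
    X1 = np.column_stack([F, pa[:, j1]])
    X2 = np.column_stack([F, pa[:, j2]])
    two = fit_multitrait(
        Y, [X1, X2], basis,
        names=[f"{t1}:{nm}" for nm in fnames + ["a_qtl"]]
        + [f"{t2}:{nm}" for nm in fnames + ["a_qtl"]],
        x0=warm,
    )
    test_two = lr_test(two, pleio, df=1)
    call.tests["two_qtl_vs_pleio"] = test_two
    call.tests["two_qtl_vs_null"] = lr_test(two, null, df=3)
    call.positions["two_qtl"] = (float(positions[j1]), float(positions[j2]))
    if test_two.p < alpha:
        call.classification = "two-linked-QTL"
        call.effects = {
            t1: two.effect(f"{t1}:a_qtl"),
            t2: two.effect(f"{t2}:a_qtl"),
        }
    else:
        call.classification = "pleiotropic"
    return call


def pleiotropy_decision_gwas(
    dataset: Dataset,
    trait_pair: Tuple[str, str],
    tas_region: TASRegion,
    A: RelationshipMatrix,
    alpha: float = 0.05,
) -> QTLCall:
    """Classify a bivariate TAS region: pleiotropic or tissue-specific.

    The region's most significant SNP is tested against each reduced
    single-tissue SNP model (df = 1 each); both rejections are required
    for a pleiotropic call."""
    geno = dataset.genotypes
    snp_ids = list(geno.snps["snp"])
    if tas_region.top_snp not in snp_ids:
        raise ValueError(f"region SNP {tas_region.top_snp!r} absent from genotypes")
    j = snp_ids.index(tas_region.top_snp)
    phen = _phenotyped(dataset, trait_pair)
    ids = list(phen["id"])
    freqs = estimate_line_frequencies(dataset)
    id_rows = {ind: k for k, ind in enumerate(geno.ids)}
    lam = lambda_coding(dataset, j, freqs)[np.array([id_rows[i] for i in ids])]
    ok = ~np.isnan(lam) & ~phen[list(trait_pair)].isna().any(axis=1).to_numpy()
    phen = phen[ok].reset_index(drop=True)
    lam = lam[ok]
    ids = list(phen["id"])
    basis = SpectralBasis.from_relationship(A, ids)
    F, fnames = build_fixed_design(phen)
    Y = phen[list(trait_pair)].to_numpy(float)
    X = np.column_stack([F, lam])
    t1, t2 = trait_pair
    null = fit_multitrait(Y, [F, F], basis)
    warm = null.varcomp.get("theta")
    pleio = fit_multitrait(
        Y, [X, X], basis,
        names=[f"{t}:{nm}" for t in trait_pair for nm in fnames + ["g_snp"]],
        x0=warm,
    )
    only1 = fit_multitrait(Y, [X, F], basis, x0=warm)
    only2 = fit_multitrait(Y, [F, X], basis, x0=warm)
    call = QTLCall(chromosome=tas_region.chromosome, traits=tuple(trait_pair),
                   classification="none")
    call.tests["pleio_vs_null"] = lr_test(pleio, null, df=2)
    call.tests["pleio_vs_trait1_only"] = lr_test(pleio, only1, df=1)
    call.tests["pleio_vs_trait2_only"] = lr_test(pleio, only2, df=1)
    call.effects = {
        t1: pleio.effect(f"{t1}:g_snp"),
        t2: pleio.effect(f"{t2}:g_snp"),
    }
    call.positions["snp"] = tas_region.top_snp
    if call.tests["pleio_vs_trait1_only"].p < alpha and \
       call.tests["pleio_vs_trait2_only"].p < alpha:
        call.classification = "pleiotropic"
    elif call.tests["pleio_vs_trait1_only"].p >= alpha and \
            call.tests["pleio_vs_trait2_only"].p >= alpha:
        call.classification = (
            "trait1-specific" if only1.loglik >= only2.loglik else "trait2-specific"
        )
    elif call.tests["pleio_vs_trait1_only"].p >= alpha:
        call.classification = "trait1-specific"
    else:
        call.classification = "trait2-specific"
    return call


def multitrait_refine(
    dataset: Dataset,
    traits: Sequence[str],
    chromosome: str,
    lop: LineOriginProbs,
    A: RelationshipMatrix,
    max_traits: int = 5,
) -> Tuple[ScanResult, Optional[ConfidenceInterval]]:
    """k-trait shared-position scan (df = k vs no-QTL) to refine a peak."""
    traits = list(traits)
    k = len(traits)
    if k < 2:
        raise ValueError("need at least two traits")
    if k > max_traits:
        raise ValueError(f"more than {max_traits} traits not supported")
    phen = _phenotyped(dataset, traits)
    ids = list(phen["id"])
    basis = SpectralBasis.from_relationship(A, ids)
    F, fnames = build_fixed_design(phen)
    Y = phen[traits].to_numpy(float)
    null = fit_multitrait(Y, [F] * k, basis)
    row_idx = [lop.ids.index(i) for i in ids]
    pa = lop.p_a[row_idx]
    warm = null.varcomp.get("theta")
    rows = []
    for j, pos in enumerate(lop.positions):
        col = pa[:, j]
        if np.ptp(col) < 1e-12:
            rows.append((chromosome, pos, np.nan, k, np.nan))
            continue
        X = np.column_stack([F, col])
        full = fit_multitrait(Y, [X] * k, basis, x0=warm)
        warm = full.varcomp.get("theta")
        t = lr_test(full, null, df=k)
        rows.append((chromosome, pos, t.lr, k, t.p))
    table = pd.DataFrame(rows, columns=["chrom", "pos_cm", "lr", "df", "p"])
    ok = table["p"].notna()
    table["q"] = np.nan
    table.loc[ok, "q"] = storey_qvalues(table.loc[ok, "p"].to_numpy())
    scan = ScanResult("linkage", tuple(traits), k, table)
    if not ok.any():
        return scan, None
    peak = float(table.loc[table.loc[ok, "lr"].idxmax(), "pos_cm"])
    return scan, mangin_ci(scan, peak, df=k)
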