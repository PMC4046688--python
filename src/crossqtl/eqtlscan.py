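"""Targeted genetical-genomics stage.

Probe expression is treated as the response of the same animal model
used for the fat-composition traits, but the scans are restricted to
windows derived from the pleiotropy stage: cM windows from linkage QTL
confidence intervals, SNP sets from pleiotropic TAS regions.  The
multiplicity of these window scans is counted at the *effective* number
of independent tests (eigenvalue-variance formula applied to the probe
and SNP correlation matrices) and the discovery threshold is controlled
by the Benjamini-Yekutieli step-up at FDR 0.20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Dataset, ExpressionMatrix
from .lineorigin import LineOriginProbs, estimate_line_frequencies
from .mixedlm import SpectralBasis, build_fixed_design, chisq_pvalue, fit_single_trait_many
from .pedkin import RelationshipMatrix
from .qtlscan import ScanResult, lambda_coding, mangin_ci


@dataclass
class ProbeFilterReport:
    status: pd.Series  # probe -> kept / fail-foldchange / collapsed-duplicate
    fold: float
    fraction: float

    @property
    def counts(self) -> pd.Series:
        return self.status.value_counts()


@dataclass
class EffectiveTests:
    m: int
    meff: float
    eigenvalues: np.ndarray


def filter_probes(
    expr: ExpressionMatrix, fold: float = 1.5, fraction: float = 0.20
) -> Tuple[ExpressionMatrix, ProbeFilterReport]:
    """Minimum fold-change filter plus duplicate-probe collapse.

    A sample deviates when its value exceeds ``fold`` times the probe
    median or falls below median/fold; on log2-scale data this is
    |value - median| > log2(fold).  A probe is kept iff strictly more
    than ``fraction`` of samples deviate.  Duplicate probes of one gene
    collapse to the probe with the highest mean expression.
    """
    V = expr.values
    if expr.scale == "log2":
        dev = (V.sub(V.median(axis=1), axis=0)).abs() > np.log2(fold)
    else:
        med = V.median(axis=1)
        if (med <= 0).any():
            bad = list(med[med <= 0].index)
            warnings.warn(f"nonpositive median, probes excluded: {bad}")
        up = V.gt(fold * med, axis=0)
        down = V.lt(med / fold, axis=0)
        dev = up | down
        dev.loc[med <= 0] = False
    frac = dev.mean(axis=1)
    keep_fold = frac > fraction

    status = pd.Series(
        np.where(keep_fold, "kept", "fail-foldchange"), index=V.index
    )
    ann = expr.annotation.set_index("probe")
    keep_final = []
    for gene, grp in ann.loc[status[status == "kept"].index].groupby("gene", sort=False):
        probes = list(grp.index)
        if len(probes) == 1:
            keep_final.append(probes[0])
            continue
        means = V.loc[probes].mean(axis=1)
        best = means.idxmax()
        keep_final.append(best)
        for p in probes:
            if p != best:
                status[p] = "collapsed-duplicate"
    out = ExpressionMatrix(
        V.loc[keep_final],
        expr.annotation[expr.annotation["probe"].isin(keep_final)].reset_index(drop=True),
        tissue=expr.tissue,
        scale=expr.scale,
    )
    return out, ProbeFilterReport(status, fold, fraction)


def effective_tests(values: np.ndarray) -> EffectiveTests:
    """Effective number of independent tests among correlated items.

    ``values`` is items x samples.  Meff = 1 + (M - 1)(1 - Var(lambda)/M)
    with lambda the eigenvalues of the item-item Pearson correlation
    matrix and Var the sample variance (denominator M - 1); clamped to
    [1, M].  Constant items are excluded with a warning.
    """
    V = np.asarray(values, float)
    sd = V.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant items excluded from Meff")
        V = V[sd > 0]
    M = V.shape[0]
    if M < 2:
        return EffectiveTests(M, float(M), np.ones(M))
    C = np.corrcoef(V)
    lam = np.linalg.eigvalsh(C)
    meff = 1.0 + (M - 1.0) * (1.0 - lam.var(ddof=1) / M)
    return EffectiveTests(M, float(np.clip(meff, 1.0, M)), lam)


def by_fdr(pvalues: np.ndarray, m_effective: float, q: float = 0.20) -> np.ndarray:
    """Benjamini-Yekutieli step-up at effective multiplicity.

    Thresholds are k q / (m_effective c) with c the harmonic sum to
    ceil(m_effective); every p at or below the largest passing ranked p
    is a discovery."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    c = float(np.sum(1.0 / np.arange(1, int(np.ceil(m_effective)) + 1)))
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, p.size + 1) * q / (m_effective * c)
    passing = p[order] <= thresholds
    if not passing.any():
        return np.zeros(p.size, dtype=bool)
    k_star = int(np.flatnonzero(passing).max())
    cut = p[order][k_star]
    return p <= cut


def _cm_to_mb(map_table: pd.DataFrame, chrom: str, cm: float) -> float:
    """Map-table lookup (piecewise linear between flanking SNPs)."""
    sub = map_table[map_table["chrom"] == chrom].sort_values("cm")
    return float(np.interp(cm, sub["cm"], sub["mb"]))


def bracket_classify(
    interval_chrom: str,
    interval_lo: float,
    interval_hi: float,
    gene_chrom: str,
    gene_pos: float,
) -> bool:
    """True iff the gene lies on the interval's chromosome within its
    closed bounds (boundary positions count as inside)."""
    if str(interval_chrom) != str(gene_chrom):
        return False
    return interval_lo <= gene_pos <= interval_hi


def targeted_eqtl_scan(
    dataset: Dataset,
    expr: ExpressionMatrix,
    windows: Sequence[dict],
    A: RelationshipMatrix,
    mode: str = "linkage",
    lop_by_chrom: Optional[Dict[str, LineOriginProbs]] = None,
    fdr: float = 0.20,
    neff_probes: Optional[float] = None,
) -> pd.DataFrame:
    """Window-restricted eQTL (linkage) or eTAS (association) scans.

    ``windows``: dicts with keys chrom, lo, hi -- in cM for linkage
    (positions from pleiotropic QTL confidence intervals), in Mb for
    association (pleiotropic TAS regions).  Per window, every probe is
    scanned and its best test retained; discoveries are flagged by
    Benjamini-Yekutieli at ``fdr`` with multiplicity Neff(probes) times
    the number of positions (linkage) or Meff(SNPs) (association).
    Linkage discoveries also receive a Mangin confidence interval and a
    brackets-gene flag.
    """
    if mode not in ("linkage", "association"):
        raise ValueError("mode must be 'linkage' or 'association'")
    samples = [s for s in expr.samples]
    phen = dataset.phenotypes.table.set_index("id").loc[samples].reset_index()
    basis = SpectralBasis.from_relationship(A, samples)
    F, _ = build_fixed_design(phen)
    Y = expr.values[samples].to_numpy(float).T  # samples x probes
    n, m = Y.shape
    if neff_probes is None:
        neff_probes = effective_tests(expr.values.to_numpy()).meff
    ann = expr.annotation.set_index("probe")
    null = fit_single_trait_many(Y, F, basis)

    results: List[dict] = []
    for win in windows:
        chrom = str(win["chrom"])
        lo, hi = float(win["lo"]), float(win["hi"])
        if mode == "linkage":
            lop = lop_by_chrom[chrom]
            sel = (lop.positions >= lo) & (lop.positions <= hi)
            positions = lop.positions[sel]
            if positions.size == 0:
                continue
            row_idx = [lop.ids.index(s) for s in samples]
            pa = lop.p_a[np.ix_(row_idx, np.flatnonzero(sel))]
            lr_mat = np.full((m, positions.size), np.nan)
            eff_mat = np.full((m, positions.size), np.nan)
            se_mat = np.full((m, positions.size), np.nan)
            for j in range(positions.size):
                col = pa[:, j]
                if np.ptp(col) < 1e-12:
                    continue
                X = np.column_stack([F, col])
                fit = fit_single_trait_many(Y, X, basis)
                lr_mat[:, j] = np.maximum(
                    2.0 * (fit["loglik"] - null["loglik"]), 0.0
                )
                eff_mat[:, j] = fit["beta"][:, -1]
                se_mat[:, j] = fit["se"][:, -1]
            best_j = np.nanargmax(lr_mat, axis=1)
            # positions on a cM grid are strongly correlated tests; count
            # them at their effective number exactly as SNPs are counted
            # in association mode
            meff_pos = effective_tests(pa.T).meff
            multiplicity = neff_probes * meff_pos
            labels = positions
            mb_of = None
        else:
            geno = dataset.genotypes
            in_win = (
                (geno.snps["chrom"].astype(str) == chrom)
                & (geno.snps["mb"] >= lo)
                & (geno.snps["mb"] <= hi)
            ).to_numpy()
            snp_idx = np.flatnonzero(in_win)
            if snp_idx.size == 0:
                continue
            freqs = estimate_line_frequencies(dataset)
            id_rows = {ind: k for k, ind in enumerate(geno.ids)}
            rows_geno = np.array([id_rows[s] for s in samples])
            lr_mat = np.full((m, snp_idx.size), np.nan)
            eff_mat = np.full((m, snp_idx.size), np.nan)
            se_mat = np.full((m, snp_idx.size), np.nan)
            lam_cols = []
            for jj, j in enumerate(snp_idx):
                lam = lambda_coding(dataset, j, freqs)[rows_geno]
                okv = ~np.isnan(lam)
                lam_cols.append(np.where(okv, lam, 0.0))
                if okv.sum() < 3 or np.ptp(lam[okv]) < 1e-12:
                    continue
                if okv.all():
                    b, nl = basis, null
                    Xf = np.column_stack([F, lam])
                    Yv = Y
                else:
                    sub = [s for s, k in zip(samples, okv) if k]
                    b = SpectralBasis.from_relationship(A, sub)
                    Yv = Y[okv]
                    nl = fit_single_trait_many(Yv, F[okv], b)
                    Xf = np.column_stack([F[okv], lam[okv]])
                fit = fit_single_trait_many(Yv, Xf, b)
                lr_mat[:, jj] = np.maximum(2.0 * (fit["loglik"] - nl["loglik"]), 0.0)
                eff_mat[:, jj] = fit["beta"][:, -1]
                se_mat[:, jj] = fit["se"][:, -1]
            with np.errstate(all="ignore"):
                best_j = np.nanargmax(np.nan_to_num(lr_mat, nan=-1.0), axis=1)
            meff_snps = effective_tests(np.array(lam_cols)).meff
            multiplicity = neff_probes * meff_snps
            labels = geno.snps["snp"].to_numpy()[snp_idx]
            mb_of = geno.snps["mb"].to_numpy()[snp_idx]

        best_lr = lr_mat[np.arange(m), best_j]
        pvals = np.array(
            [chisq_pvalue(v, 1) if np.isfinite(v) else 1.0 for v in best_lr]
        )
        discovered = by_fdr(pvals, multiplicity, q=fdr)
        for i, probe in enumerate(expr.probes):
            row = {
                "probe": probe,
                "gene": ann.loc[probe, "gene"],
                "gene_chrom": ann.loc[probe, "chrom"],
                "gene_mb": float(ann.loc[probe, "mb"]),
                "window_chrom": chrom,
                "window_lo": lo,
                "window_hi": hi,
                "mode": mode,
                "lr": float(best_lr[i]) if np.isfinite(best_lr[i]) else np.nan,
                "df": 1,
                "p": float(pvals[i]),
                "effect": float(eff_mat[i, best_j[i]]),
                "se": float(se_mat[i, best_j[i]]),
                "discovered": bool(discovered[i]),
                "multiplicity": float(multiplicity),
            }
            if mode == "linkage":
                row["best_pos_cm"] = float(labels[best_j[i]])
                profile = pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos_cm": labels,
                        "lr": lr_mat[i],
                        "df": 1,
                        "p": np.nan,
                    }
                )
                if discovered[i] and np.isfinite(lr_mat[i]).any():
                    ci = mangin_ci(
                        ScanResult("linkage", (probe,), 1, profile),
                        row["best_pos_cm"], df=1,
                    )
                    row["ci_lo_cm"], row["ci_hi_cm"] = ci.lower_cm, ci.upper_cm
                    mb_lo = _cm_to_mb(dataset.map_table, chrom, ci.lower_cm)
                    mb_hi = _cm_to_mb(dataset.map_table, chrom, ci.upper_cm)
                    row["brackets_gene"] = bracket_classify(
                        chrom, mb_lo, mb_hi, row["gene_chrom"], row["gene_mb"]
                    )
                else:
                    row["ci_lo_cm"] = row["ci_hi_cm"] = np.nan
                    row["brackets_gene"] = False
            else:
                row["best_snp"] = labels[best_j[i]]
                row["best_mb"] = float(mb_of[best_j[i]])
                row["brackets_gene"] = bracket_classify(
                    chrom, lo, hi, row["gene_chrom"], row["gene_mb"]
                )
            results.append(row)
    return pd.DataFrame(results)


def cross_tissue_correlation(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    probes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-probe Pearson correlation of expression across paired samples.

    Significance from the t transform with n - 2 degrees of freedom."""
    paired = [s for s in expr_a.samples if s in set(expr_b.samples)]
    if len(paired) < 3:
        raise ValueError("need at least three paired samples")
    if probes is None:
        probes = [p for p in expr_a.probes if p in set(expr_b.probes)]
    rows = []
    for probe in probes:
        a = expr_a.values.loc[probe, paired].to_numpy(float)
        b = expr_b.values.loc[probe, paired].to_numpy(float)
        if a.std() == 0 or b.std() == 0:
            warnings.warn(f"zero variance for probe {probe}; correlation undefined")
            rows.append((probe, np.nan, np.nan, len(paired)))
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        dfree = len(paired) - 2
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(dfree / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), dfree))
        rows.append((probe, r, p, len(paired)))
    return pd.DataFrame(rows, columns=["probe", "r", "p", "n"])
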