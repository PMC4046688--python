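"""SNP quality control, zero-cM map pruning and LD summaries.

Filters mirror the reference study's pipeline: call rate >= 0.85, MAF >=
0.15 (computed on the BC cohort, the analyzed animals), no Mendelian
inconsistencies, and a mapped autosomal position.  Within each run of
contiguous SNPs at an identical cM position a single representative is
retained.  LD is the squared Pearson correlation of unphased genotype
dosages (composite r2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .containers import Dataset, GenotypeMatrix

STATUS_ORDER = (
    "fail-callrate",
    "fail-maf",
    "fail-mendel",
    "fail-unmapped",
    "pruned-zero-cM",
    "kept",
)


@dataclass
class QcReport:
    status: pd.Series  # snp id -> status
    thresholds: dict = field(default_factory=dict)

    @property
    def counts(self) -> pd.Series:
        return self.status.value_counts().reindex(STATUS_ORDER, fill_value=0)

    def to_tsv(self, path) -> None:
        df = self.status.rename("status").rename_axis("snp").reset_index()
        df.to_csv(path, sep="\t", index=False)


def _mendel_violations(dataset: Dataset, trios: bool = False) -> np.ndarray:
    """Per-SNP flag for any parent-offspring pair with opposing homozygotes
    (and, optionally, trios with an impossible joint configuration)."""
    geno = dataset.genotypes
    idx = {ind: k for k, ind in enumerate(geno.ids)}
    calls = geno.calls
    bad = np.zeros(geno.n_snps, dtype=bool)
    for row in dataset.pedigree.table.itertuples(index=False):
        if row.id not in idx:
            continue
        o = calls[idx[row.id]]
        for parent in (row.sire, row.dam):
            if parent and parent in idx:
                p = calls[idx[parent]]
                both = (o >= 0) & (p >= 0)
                bad |= both & (((o == 0) & (p == 2)) | ((o == 2) & (p == 0)))
        if trios and row.sire in idx and row.dam in idx:
            s, d = calls[idx[row.sire]], calls[idx[row.dam]]
            ok = (o >= 0) & (s >= 0) & (d >= 0)
            # het offspring impossible when both parents are the same homozygote
            bad |= ok & (o == 1) & (s != 1) & (d != 1) & (s == d)
    return bad


def filter_snps(
    dataset: Dataset,
    call_rate_min: float = 0.85,
    maf_min: float = 0.15,
    trios: bool = False,
) -> Tuple[GenotypeMatrix, QcReport]:
    """Apply the QC rules; statuses use the fixed reporting priority
    callrate -> maf -> mendel -> unmapped, but the kept set is the same
    whichever order the rules are evaluated in."""
    geno = dataset.genotypes
    bc = [i for i, ind in enumerate(geno.ids) if ind in set(dataset.pedigree.bc_ids)]
    cohort = geno.calls[bc] if bc else geno.calls

    observed = cohort >= 0
    call_rate = observed.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(
            observed.sum(axis=0) > 0,
            np.where(cohort < 0, 0, cohort).sum(axis=0) / (2.0 * observed.sum(axis=0).clip(min=1)),
            np.nan,
        )
    maf = np.minimum(freq, 1.0 - freq)

    fail_call = call_rate < call_rate_min
    fail_maf = ~fail_call & (np.isnan(maf) | (maf < maf_min))
    mendel = _mendel_violations(dataset, trios=trios)
    fail_mendel = ~fail_call & ~fail_maf & mendel
    unmapped = (
        geno.snps["cm"].isna().to_numpy()
        | geno.snps["chrom"].astype(str).str.upper().isin(["X", "Y", ""]).to_numpy()
    )
    fail_unmapped = ~fail_call & ~fail_maf & ~fail_mendel & unmapped

    status = np.full(geno.n_snps, "kept", dtype=object)
    status[fail_unmapped] = "fail-unmapped"
    status[fail_mendel] = "fail-mendel"
    status[fail_maf] = "fail-maf"
    status[fail_call] = "fail-callrate"
    # the kept set itself is order independent: a SNP is kept iff it
    # passes every rule
    keep = ~(fail_call | (np.isnan(maf) | (maf < maf_min)) | mendel | unmapped)
    status[~keep & (status == "kept")] = "fail-maf"

    report = QcReport(
        pd.Series(status, index=geno.snps["snp"].to_numpy()),
        thresholds={"call_rate_min": call_rate_min, "maf_min": maf_min},
    )
    return geno.subset_snps(keep), report


def prune_zero_cm(
    genotypes: GenotypeMatrix,
) -> Tuple[GenotypeMatrix, QcReport]:
    """Keep one representative per run of contiguous SNPs at the same cM.

    The member with the highest call rate wins; ties break to the lowest
    Mb position.  Idempotent.
    """
    snps = genotypes.snps
    call_rate = (genotypes.calls >= 0).mean(axis=0)
    keep = np.zeros(len(snps), dtype=bool)
    for _, grp in snps.groupby("chrom", sort=False):
        order = np.argsort(grp["cm"].to_numpy(), kind="stable")
        idx = grp.index.to_numpy()[order]
        cm = snps["cm"].to_numpy()[idx]
        start = 0
        for j in range(1, len(idx) + 1):
            if j == len(idx) or cm[j] != cm[start]:
                run = idx[start:j]
                best = max(
                    run,
                    key=lambda i: (call_rate[i], -snps["mb"].iloc[i]),
                )
                keep[best] = True
                start = j
    status = np.where(keep, "kept", "pruned-zero-cM")
    report = QcReport(pd.Series(status, index=snps["snp"].to_numpy()))
    return genotypes.subset_snps(keep), report


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < 2:
        raise ValueError("need at least two complete pairs")
    a, b = g1[ok], g2[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        warnings.warn("zero dosage variance; r2 undefined")
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_decay(
    genotypes: GenotypeMatrix,
    distance_bins_mb: Tuple[float, ...] = (0.5, 1.0, 5.0, 10.0),
    bin_halfwidth: float = 0.25,
    max_pairs_per_bin: int = 20000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Mean r2 between within-chromosome SNP pairs by physical distance.

    The 'adjacent' bin holds consecutive kept SNPs on the map; each
    numeric bin d collects pairs with |mb_i - mb_j - d| < halfwidth.
    """
    snps = genotypes.snps
    D = genotypes.dosages()
    rows = []
    pairs_by_bin: dict = {"adjacent": []}
    for d in distance_bins_mb:
        pairs_by_bin[d] = []
    for _, grp in snps.groupby("chrom", sort=False):
        order = grp.sort_values(["mb", "snp"], kind="stable").index.to_numpy()
        mb = snps["mb"].to_numpy()
        for a, b in zip(order[:-1], order[1:]):
            pairs_by_bin["adjacent"].append((a, b))
        for d in distance_bins_mb:
            for i_pos, a in enumerate(order):
                lo = np.searchsorted(mb[order], mb[a] + d - bin_halfwidth, side="left")
                hi = np.searchsorted(mb[order], mb[a] + d + bin_halfwidth, side="right")
                for b in order[max(lo, i_pos + 1):hi]:
                    pairs_by_bin[d].append((a, b))
    for name, pairs in pairs_by_bin.items():
        if rng is not None and len(pairs) > max_pairs_per_bin:
            sel = rng.choice(len(pairs), max_pairs_per_bin, replace=False)
            pairs = [pairs[i] for i in sel]
        vals = []
        for a, b in pairs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    v = ld_r2(D[:, a], D[:, b])
                except ValueError:
                    continue
            if np.isfinite(v):
                vals.append(v)
        rows.append((name, len(vals), np.mean(vals) if vals else np.nan))
    return pd.DataFrame(rows, columns=["bin", "n_pairs", "mean_r2"])
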