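"""Synthetic backcross generator.

Gamete dropping with crossovers placed as a Poisson process of intensity
1 per Morgan and no interference (Haldane-consistent, matching the map
function used by the analysis side).  Phenotypes realize exactly the
analysis model: fixed effects + QTL line-origin contribution + polygenic
term with covariance A (x) G0 + bivariate residual.  Expression traits
add a configurable cis-regulatory genetic effect shared across tissues.

Randomness: every stage derives its own substream from ``config.seed``
via ``numpy`` SeedSequence spawning with fixed stage keys (pedigree=0,
genomes=1, phenotypes=2, expression=3), so each stage is reproducible
independently of call order.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig
from .containers import (
    Dataset,
    ExpressionMatrix,
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
    TruthRecord,
)
from . import pedkin

_STAGE = {"pedigree": 0, "genomes": 1, "phenotypes": 2, "expression": 3}


def _stage_rng(config: SimConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STAGE[stage],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# pedigree

def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Three-generation pedigree with the backcross mating structure.

    F1 boars descend from Iberian F0 sires x Landrace F0 dams (round-robin
    assignment); BC animals have an F1 sire and a Landrace F0 dam drawn
    from a separate pool of ``n_f1_dams`` sows.  Sex alternates within the
    BC so both levels are represented.  Deterministic given the config.
    """
    rows = []
    f0_sires = [f"IB{i + 1}" for i in range(config.n_f0_sires)]
    f0_dams = [f"LW{i + 1}" for i in range(config.n_f0_dams)]
    bc_dams = [f"LWD{i + 1}" for i in range(config.n_f1_dams)]
    for s in f0_sires:
        rows.append((s, "", "", "F0", "Iberian", "M"))
    for d in f0_dams:
        rows.append((d, "", "", "F0", "Landrace", "F"))
    for d in bc_dams:
        rows.append((d, "", "", "F0", "Landrace", "F"))
    f1_sires = []
    for i in range(config.n_f1_sires):
        fid = f"F1_{i + 1}"
        rows.append(
            (fid, f0_sires[i % len(f0_sires)], f0_dams[i % len(f0_dams)], "F1", "", "M")
        )
        f1_sires.append(fid)
    for i in range(config.n_bc):
        rows.append(
            (
                f"BC{i + 1:03d}",
                f1_sires[i % len(f1_sires)],
                bc_dams[i % len(bc_dams)],
                "BC",
                "",
                "M" if i % 2 == 0 else "F",
            )
        )
    ped = Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "line", "sex"])
    )
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# genomes

class _Haplotype:
    """Alleles per SNP plus line-origin segments per chromosome."""

    __slots__ = ("alleles", "origins")

    def __init__(self, alleles: np.ndarray, origins: Dict[str, tuple]):
        self.alleles = alleles  # uint8, 1 = carries allele A
        self.origins = origins  # chrom -> (breaks, origins list)


def _constant_origin(chrom_info, line: str) -> Dict[str, tuple]:
    return {
        name: (np.array([0.0, length]), [line]) for name, length, _ in chrom_info
    }


def _meiose(
    h0: _Haplotype,
    h1: _Haplotype,
    chrom_info: Sequence[tuple],
    snp_slices: Dict[str, slice],
    snp_pos: Dict[str, np.ndarray],
    rng: np.random.Generator,
) -> Tuple[_Haplotype, int]:
    """One meiosis: crossovers ~ Poisson(length/100), uniform placement."""
    alleles = np.empty_like(h0.alleles)
    origins: Dict[str, tuple] = {}
    n_co = 0
    for name, length, _ in chrom_info:
        k = int(rng.poisson(length / 100.0))
        n_co += k
        breaks = np.sort(rng.uniform(0.0, length, size=k))
        start = int(rng.integers(2))
        sl = snp_slices[name]
        pos = snp_pos[name]
        # active parental strand for each SNP
        strand = (start + np.searchsorted(breaks, pos, side="right")) % 2
        alleles[sl] = np.where(strand == 0, h0.alleles[sl], h1.alleles[sl])
        # child origin segments: intersect crossover intervals with the
        # active strand's own origin segments
        edges = np.concatenate(([0.0], breaks, [length]))
        out_breaks = [0.0]
        out_orig = []
        for j in range(len(edges) - 1):
            src = h0 if (start + j) % 2 == 0 else h1
            sb, so = src.origins[name]
            lo, hi = edges[j], edges[j + 1]
            if hi <= lo:
                continue
            i0 = int(np.searchsorted(sb, lo, side="right") - 1)
            i1 = int(np.searchsorted(sb, hi, side="left"))
            for i in range(i0, i1):
                seg_hi = min(sb[i + 1], hi)
                if seg_hi > out_breaks[-1]:
                    out_breaks.append(seg_hi)
                    out_orig.append(so[i])
        origins[name] = (np.asarray(out_breaks), out_orig)
    return _Haplotype(alleles, origins), n_co


def _founder_freq_table(config: SimConfig, snps: pd.DataFrame, rng) -> np.ndarray:
    m = len(snps)
    if config.founder_freqs is not None:
        freqs = np.asarray(config.founder_freqs, dtype=float)
        if freqs.shape != (m, 2) or np.isnan(freqs).any():
            raise ConfigurationError("founder_freqs must be (n_snps, 2) with no gaps")
        if ((freqs < 0) | (freqs > 1)).any():
            raise ConfigurationError("founder frequencies outside [0, 1]")
        return freqs
    a_i, b_i = config.freq_beta_iberian
    a_l, b_l = config.freq_beta_landrace
    return np.column_stack([rng.beta(a_i, b_i, m), rng.beta(a_l, b_l, m)])


def simulate_genomes(
    pedigree: Pedigree, config: SimConfig
) -> Tuple[GenotypeMatrix, TruthRecord]:
    """Drop gametes through the pedigree; record BC line-origin truth.

    Founder haplotypes are drawn from line-specific allele frequencies.
    Missingness and Mendelian errors are injected *after* the truth record
    is taken, so recovery tests can condition on clean origins.
    """
    rng = _stage_rng(config, "genomes")
    chrom_info = list(config.chromosomes)
    snp_rows = []
    snp_slices: Dict[str, slice] = {}
    snp_pos: Dict[str, np.ndarray] = {}
    offset = 0
    for name, length, m in chrom_info:
        pos = np.linspace(0.0, length, m)
        snp_pos[name] = pos
        snp_slices[name] = slice(offset, offset + m)
        for j, p in enumerate(pos):
            snp_rows.append(
                (f"c{name}_s{j + 1}", name, p, p * config.mb_per_cm, "A", "B")
            )
        offset += m
    snps = pd.DataFrame(
        snp_rows, columns=["snp", "chrom", "cm", "mb", "allele_a", "allele_b"]
    )
    freqs = _founder_freq_table(config, snps, rng)

    line_col = dict(zip(pedigree.table["id"], pedigree.table["line"]))
    haplos: Dict[str, Tuple[_Haplotype, _Haplotype]] = {}
    segments: Dict[str, Dict[str, tuple]] = {}
    crossovers: Dict[str, int] = {}
    n_total = offset

    def founder_hap(line: str) -> _Haplotype:
        p = freqs[:, 0] if line == "Iberian" else freqs[:, 1]
        alleles = (rng.random(n_total) < p).astype(np.uint8)
        return _Haplotype(alleles, _constant_origin(chrom_info, line))

    for row in pedigree.table.itertuples(index=False):
        if row.generation == "F0":
            haplos[row.id] = (founder_hap(row.line), founder_hap(row.line))
        else:
            sire_h = haplos[row.sire]
            dam_h = haplos[row.dam]
            pat, n_co = _meiose(sire_h[0], sire_h[1], chrom_info, snp_slices, snp_pos, rng)
            mat, _ = _meiose(dam_h[0], dam_h[1], chrom_info, snp_slices, snp_pos, rng)
            haplos[row.id] = (pat, mat)
            if row.generation == "BC":
                segments[row.id] = pat.origins
                crossovers[row.id] = n_co

    ids = pedigree.ids
    calls = np.empty((len(ids), n_total), dtype=np.int8)
    for i, ind in enumerate(ids):
        pat, mat = haplos[ind]
        calls[i] = pat.alleles.astype(np.int8) + mat.alleles.astype(np.int8)

    truth = TruthRecord(
        segments=segments,
        crossovers=crossovers,
        founder_freqs=pd.DataFrame(
            {"snp": snps["snp"], "freq_iberian": freqs[:, 0], "freq_landrace": freqs[:, 1]}
        ),
    )

    if config.mendel_error_rate > 0:
        flip = rng.random(calls.shape) < config.mendel_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = -1

    return GenotypeMatrix(snps, ids, calls), truth


# ---------------------------------------------------------------------------
# phenotypes

def _trait_cov(scales: np.ndarray, corr: float) -> np.ndarray:
    s = np.asarray(scales, dtype=float)
    out = np.diag(s**2).astype(float)
    out[0, 1] = out[1, 0] = corr * s[0] * s[1]
    return out


def simulate_phenotypes(
    pedigree: Pedigree, truth: TruthRecord, config: SimConfig
) -> PhenotypeTable:
    """Bivariate phenotypes for BC animals with the configured partition.

    Base phenotypic variance is 1 per trait (sigma2_u = h2, sigma2_e =
    1 - h2); QTL effects are added on top in those SD units via the true
    line-origin coefficient (0 het / -1 Landrace homozygote).
    """
    rng = _stage_rng(config, "phenotypes")
    h2 = np.asarray(config.h2, dtype=float)
    if ((h2 < 0) | (h2 > 1)).any():
        raise ConfigurationError("h2 outside [0, 1]")
    bc = pedigree.rows_of("BC")
    n = len(bc)
    ids = list(bc["id"])

    G0 = _trait_cov(np.sqrt(h2), config.genetic_corr)
    R0 = _trait_cov(np.sqrt(1.0 - h2), config.residual_corr)

    if (h2 > 0).any():
        A = pedkin.numerator_relationship(pedigree)
        L = np.linalg.cholesky(A.matrix + 1e-10 * np.eye(A.matrix.shape[0]))
        z = rng.standard_normal((A.matrix.shape[0], 2))
        u_all = L @ z @ np.linalg.cholesky(G0).T
        idx = [A.ids.index(i) for i in ids]
        u = u_all[idx]
    else:
        u = np.zeros((n, 2))

    e = rng.standard_normal((n, 2)) @ np.linalg.cholesky(R0).T

    sex = (bc["sex"] == "M").to_numpy().astype(float)
    batch = np.arange(n) % 3
    cw = rng.standard_normal(n)

    y = u + e
    for t in range(2):
        y[:, t] += config.sex_effect[t] * sex
        y[:, t] += np.asarray(config.batch_effects[t])[batch]
        y[:, t] += config.carcass_weight_slope[t] * cw

    qtl_rows = []
    for q in config.qtl_architecture:
        pa = np.array([truth.pa_true(i, q.chromosome, q.position_cm) for i in ids])
        y[:, 0] += q.effect_trait1 * pa
        y[:, 1] += q.effect_trait2 * pa
        qtl_rows.append(
            pd.DataFrame(
                {"id": ids, "chrom": q.chromosome, "pos_cm": q.position_cm, "pa_true": pa}
            )
        )

    truth.qtl_coefficients = (
        pd.concat(qtl_rows, ignore_index=True) if qtl_rows else pd.DataFrame()
    )
    truth.breeding_values = pd.DataFrame({"id": ids, "u1": u[:, 0], "u2": u[:, 1]})
    truth.fixed_design = pd.DataFrame(
        {"id": ids, "sex": sex, "batch": batch, "carcass_wt": cw}
    )

    table = pd.DataFrame(
        {
            "id": ids,
            "sex": bc["sex"].to_numpy(),
            "batch": [f"b{b + 1}" for b in batch],
            "carcass_wt": cw,
            "bf": y[:, 0],
            "imf": y[:, 1],
        }
    )
    return PhenotypeTable(table, trait_names=("bf", "imf"))


# ---------------------------------------------------------------------------
# expression

def default_probe_plan(
    n_null: int = 10,
    regulated: Sequence[dict] = (),
    chrom: str = "1",
    length_cm: float = 100.0,
    mb_per_cm: float = 0.67,
) -> pd.DataFrame:
    """Convenience probe plan: ``n_null`` unregulated probes spread along
    ``chrom`` plus explicitly specified regulated probes (dicts with keys
    probe, gene_chrom, gene_mb, reg_chrom, reg_cm, effect, sharing)."""
    rows = []
    for i in range(n_null):
        pos_cm = (i + 0.5) * length_cm / max(n_null, 1)
        rows.append(
            {
                "probe": f"null_{i + 1}",
                "gene": f"GENE_N{i + 1}",
                "gene_chrom": chrom,
                "gene_mb": pos_cm * mb_per_cm,
                "reg_chrom": None,
                "reg_cm": np.nan,
                "effect": 0.0,
                "sharing": 1.0,
                "noise_sd": 1.0,
                "baseline": 8.0,
            }
        )
    for spec in regulated:
        row = {
            "gene": spec.get("gene", spec["probe"].upper()),
            "noise_sd": 1.0,
            "baseline": 8.0,
            "sharing": 1.0,
        }
        row.update(spec)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_expression(
    pedigree: Pedigree,
    truth: TruthRecord,
    config: SimConfig,
    probe_plan: pd.DataFrame,
) -> Dict[str, ExpressionMatrix]:
    """Two-tissue expression with shared cis-regulatory genetic effects.

    value = baseline + effect_tissue * P_a(reg locus) + N(0, noise_sd^2),
    with effect in tissue 2 scaled by the probe's ``sharing`` coefficient.
    Tissue 1 covers ``n_expr_samples[0]`` BC animals, tissue 2 a subset.
    """
    rng = _stage_rng(config, "expression")
    bc_ids = pedigree.bc_ids
    n1, n2 = config.n_expr_samples
    n1 = min(n1, len(bc_ids))
    n2 = min(n2, n1)
    samples1 = bc_ids[:n1]
    samples2 = samples1[:n2]

    chrom_len = {c[0]: c[1] for c in config.chromosomes}
    values = {"muscle": {}, "fat": {}}
    ann_rows = []
    # per-sample co-expression factor, independent between tissues
    rho = config.expr_common_rho
    factor = {
        "muscle": rng.standard_normal(n1),
        "fat": rng.standard_normal(n2),
    }
    for p in probe_plan.itertuples(index=False):
        effect = float(p.effect)
        if effect != 0.0 and (p.reg_chrom is None or (isinstance(p.reg_cm, float) and np.isnan(p.reg_cm))):
            raise ConfigurationError(f"probe {p.probe}: effect without regulating locus")
        if p.reg_chrom is not None and not (
            isinstance(p.reg_cm, float) and np.isnan(p.reg_cm)
        ):
            if p.reg_chrom not in chrom_len:
                raise ConfigurationError(f"probe {p.probe}: regulating locus off-map")
            if not 0.0 <= p.reg_cm <= chrom_len[p.reg_chrom]:
                raise ConfigurationError(f"probe {p.probe}: regulating locus off-map")
            pa = np.array([truth.pa_true(i, p.reg_chrom, p.reg_cm) for i in samples1])
        else:
            pa = np.zeros(n1)
        noise_sd = float(getattr(p, "noise_sd", 1.0))
        baseline = float(getattr(p, "baseline", 8.0))
        sharing = float(getattr(p, "sharing", 1.0))
        sd_shared = np.sqrt(rho) * noise_sd
        sd_own = np.sqrt(1.0 - rho) * noise_sd
        v1 = (
            baseline + effect * pa
            + sd_shared * factor["muscle"] + sd_own * rng.standard_normal(n1)
        )
        v2 = (
            baseline + sharing * effect * pa[:n2]
            + sd_shared * factor["fat"] + sd_own * rng.standard_normal(n2)
        )
        values["muscle"][p.probe] = v1
        values["fat"][p.probe] = v2
        ann_rows.append((p.probe, p.gene, p.gene_chrom, p.gene_mb))

    annotation = pd.DataFrame(ann_rows, columns=["probe", "gene", "chrom", "mb"])
    out = {}
    for tissue, cols, samp in (
        ("muscle", values["muscle"], samples1),
        ("fat", values["fat"], samples2),
    ):
        df = pd.DataFrame(cols, index=samp).T
        out[tissue] = ExpressionMatrix(df, annotation.copy(), tissue=tissue)
    return out


# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimConfig, probe_plan: Optional[pd.DataFrame] = None
) -> Dataset:
    """Run every stage and return a validated Dataset."""
    ped = simulate_pedigree(config)
    geno, truth = simulate_genomes(ped, config)
    phen = simulate_phenotypes(ped, truth, config)
    expr = (
        simulate_expression(ped, truth, config, probe_plan)
        if probe_plan is not None
        else None
    )
    ds = Dataset(
        genotypes=geno,
        pedigree=ped,
        phenotypes=phen,
        expression=expr,
        probe_annotation=expr["muscle"].annotation if expr else None,
        truth=truth,
    )
    ds.validate()
    return ds
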