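"""Posterior founder-line origin along the genome and the P_a coefficient.

For a backcross animal the maternal gamete is Landrace by construction,
so the only hidden process is the line origin of the F1-transmitted
(paternal) gamete: a two-state chain {Iberian, Landrace} along each
chromosome, with transition probabilities given by the Haldane map
function and emissions from line-specific allele frequencies estimated
from the F0 genotypes (fixation between lines is not assumed).  A small
emission slack guards against genotyping errors.

P_a = Pr(QQ) - Pr(qq) with Q the Iberian-origin allele; for BC animals
Pr(QQ) = 0 and P_a = -Pr(paternal gamete Landrace), hence P_a in [-1, 0].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import Dataset


def haldane_r(d_cm) -> np.ndarray:
    """Haldane recombination fraction r = (1 - exp(-2d/100)) / 2."""
    d = np.asarray(d_cm, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be nonnegative")
    out = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return out if out.ndim else float(out)


@dataclass
class LineOriginProbs:
    """Per-individual, per-position origin posteriors on one chromosome.

    ``probs`` has shape (n_individuals, n_positions, 3) holding
    (Pr(QQ), Pr(Qq), Pr(qq)); each triple sums to one.
    """

    ids: list
    chromosome: str
    positions: np.ndarray
    probs: np.ndarray

    @property
    def p_a(self) -> np.ndarray:
        """(n_individuals, n_positions) additive coefficient Pr(QQ)-Pr(qq)."""
        return self.probs[:, :, 0] - self.probs[:, :, 2]

    def pa_column(self, position: float, ids: Optional[Sequence] = None) -> np.ndarray:
        j = int(np.argmin(np.abs(self.positions - position)))
        col = self.p_a[:, j]
        if ids is None:
            return col
        idx = [self.ids.index(i) for i in ids]
        return col[idx]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.p_a, index=self.ids, columns=[f"{p:g}" for p in self.positions])
        df.index.name = "id"
        df.to_csv(path, sep="\t")


def estimate_line_frequencies(dataset: Dataset) -> pd.DataFrame:
    """Per-SNP allele-A frequency in each founder line (ML allele counts
    over F0 genotypes); a line with no calls at a SNP gets 0.5."""
    ped = dataset.pedigree.table
    f0 = ped[ped["generation"] == "F0"]
    geno = dataset.genotypes
    id_pos = {ind: k for k, ind in enumerate(geno.ids)}
    out = {}
    for line in ("Iberian", "Landrace"):
        members = [id_pos[i] for i in f0[f0["line"] == line]["id"] if i in id_pos]
        calls = geno.calls[members].astype(float)
        calls[calls < 0] = np.nan
        with np.errstate(invalid="ignore"):
            freq = np.nansum(calls, axis=0) / (2.0 * np.sum(~np.isnan(calls), axis=0))
        freq[~np.isfinite(freq)] = 0.5
        out[line] = freq
    return pd.DataFrame(
        {
            "snp": geno.snps["snp"],
            "freq_iberian": out["Iberian"],
            "freq_landrace": out["Landrace"],
        }
    )


def _emissions(dosage: np.ndarray, p_states: np.ndarray, p_land: np.ndarray,
               slack: float) -> np.ndarray:
    """(n_ind, n_mark, 2) emission likelihoods of the observed BC genotype
    given the paternal-gamete state (0 = Iberian, 1 = Landrace)."""
    n, m = dosage.shape
    e = np.ones((n, m, 2))
    for s in range(2):
        ps = p_states[s]
        e2 = ps * p_land
        e1 = ps * (1.0 - p_land) + (1.0 - ps) * p_land
        e0 = (1.0 - ps) * (1.0 - p_land)
        table = np.stack([e0, e1, e2])  # (3, m)
        obs = dosage.copy()
        known = ~np.isnan(obs)
        idx = obs[known].astype(int)
        cols = np.broadcast_to(np.arange(m), (n, m))[known]
        vals = np.ones((n, m))
        vals[known] = table[idx, cols]
        e[:, :, s] = vals
    return (1.0 - slack) * e + slack / 3.0


def line_origin_posteriors(
    dataset: Dataset,
    chromosome: str,
    grid_step: float = 1.0,
    emission_slack: float = 1e-3,
    individuals: Optional[Sequence] = None,
    positions: Optional[np.ndarray] = None,
) -> LineOriginProbs:
    """Forward-backward smoother for the paternal-gamete line origin.

    Posteriors are returned on the integer cM grid (``grid_step``
    spacing) unless explicit ``positions`` are given.  Missing genotypes
    emit uniformly; SNPs monomorphic in both lines simply carry no
    information.
    """
    geno = dataset.genotypes
    mask = (geno.snps["chrom"] == chromosome).to_numpy()
    if individuals is None:
        individuals = dataset.pedigree.bc_ids
    individuals = list(individuals)
    if not mask.any():
        pos = np.empty(0) if positions is None else np.asarray(positions, float)
        return LineOriginProbs(individuals, chromosome, pos,
                               np.empty((len(individuals), len(pos), 3)))

    order = np.argsort(geno.snps.loc[mask, "cm"].to_numpy(), kind="stable")
    snp_idx = np.flatnonzero(mask)[order]
    cm = geno.snps["cm"].to_numpy()[snp_idx]
    freqs = estimate_line_frequencies(dataset)
    p_ib = freqs["freq_iberian"].to_numpy()[snp_idx]
    p_ld = freqs["freq_landrace"].to_numpy()[snp_idx]

    id_pos = {ind: k for k, ind in enumerate(geno.ids)}
    rows = [id_pos[i] for i in individuals]
    dosage = geno.calls[np.ix_(rows, snp_idx)].astype(float)
    dosage[dosage < 0] = np.nan

    e = _emissions(dosage, (p_ib, p_ld), p_ld, emission_slack)
    n, m, _ = e.shape
    r = haldane_r(np.diff(cm))
    r = np.atleast_1d(r)

    # scaled forward/backward messages at marker loci
    alpha = np.empty((n, m, 2))
    beta = np.empty((n, m, 2))
    a = 0.5 * e[:, 0, :]
    alpha[:, 0] = a / a.sum(axis=1, keepdims=True)
    for l in range(1, m):
        rr = r[l - 1]
        prev = alpha[:, l - 1]
        trans = np.stack(
            [prev[:, 0] * (1 - rr) + prev[:, 1] * rr,
             prev[:, 0] * rr + prev[:, 1] * (1 - rr)], axis=1
        )
        a = trans * e[:, l]
        alpha[:, l] = a / a.sum(axis=1, keepdims=True)
    beta[:, m - 1] = 1.0
    for l in range(m - 2, -1, -1):
        rr = r[l]
        nxt = beta[:, l + 1] * e[:, l + 1]
        b = np.stack(
            [nxt[:, 0] * (1 - rr) + nxt[:, 1] * rr,
             nxt[:, 0] * rr + nxt[:, 1] * (1 - rr)], axis=1
        )
        beta[:, l] = b / b.sum(axis=1, keepdims=True)

    if positions is None:
        positions = np.arange(0.0, cm[-1] + grid_step / 2, grid_step)
    positions = np.asarray(positions, dtype=float)

    pr_ib = np.empty((n, len(positions)))
    for j, pos in enumerate(positions):
        right = int(np.searchsorted(cm, pos, side="left"))
        left = right - 1
        if left >= 0 and np.isclose(cm[min(right, m - 1)], pos):
            l = min(right, m - 1)
            post = alpha[:, l] * beta[:, l]
        elif right == 0:
            rr = haldane_r(cm[0] - pos)
            nxt = beta[:, 0] * e[:, 0]
            msg = np.stack(
                [nxt[:, 0] * (1 - rr) + nxt[:, 1] * rr,
                 nxt[:, 0] * rr + nxt[:, 1] * (1 - rr)], axis=1
            )
            post = 0.5 * msg
        elif right == m:
            rr = haldane_r(pos - cm[-1])
            prev = alpha[:, m - 1]
            post = np.stack(
                [prev[:, 0] * (1 - rr) + prev[:, 1] * rr,
                 prev[:, 0] * rr + prev[:, 1] * (1 - rr)], axis=1
            )
        else:
            r1 = haldane_r(pos - cm[left])
            r2 = haldane_r(cm[right] - pos)
            prev = alpha[:, left]
            fwd = np.stack(
                [prev[:, 0] * (1 - r1) + prev[:, 1] * r1,
                 prev[:, 0] * r1 + prev[:, 1] * (1 - r1)], axis=1
            )
            nxt = beta[:, right] * e[:, right]
            bwd = np.stack(
                [nxt[:, 0] * (1 - r2) + nxt[:, 1] * r2,
                 nxt[:, 0] * r2 + nxt[:, 1] * (1 - r2)], axis=1
            )
            post = fwd * bwd
        post = post / post.sum(axis=1, keepdims=True)
        pr_ib[:, j] = post[:, 0]

    probs = np.zeros((n, len(positions), 3))
    probs[:, :, 1] = pr_ib
    probs[:, :, 2] = 1.0 - pr_ib
    return LineOriginProbs(individuals, chromosome, positions, probs)
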