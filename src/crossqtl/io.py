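"""Readers and writers for the on-disk formats.

PED dialect: columns family, id, sire, dam, sex (1=M/2=F), phenotype
placeholder, then two allele columns per SNP with "0" meaning missing.
MAP: chromosome, snp id, cM, bp.  All other tables are TSV with a single
header line and '#'-prefixed comments.  Both cM and bp are 1-based with
closed intervals; the two coordinate systems are interconverted only by
map-table lookup, never by regression.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .containers import (
    Dataset,
    ExpressionMatrix,
    GenotypeMatrix,
    IntegrityError,
    Pedigree,
    PhenotypeTable,
    TruthRecord,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# writers

def write_dataset(dataset: Dataset, out_dir, prefix: str = "data") -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / f"{prefix}.ped",
        "map": out / f"{prefix}.map",
        "pedigree": out / f"{prefix}.pedigree.tsv",
        "phenotypes": out / f"{prefix}.phenotypes.tsv",
    }
    geno = dataset.genotypes
    snps = geno.snps
    with open(paths["map"], "w") as fh:
        for row in snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t{row.cm:.6g}\t{int(round(row.mb * 1e6))}\n")
    sex_code = dict(zip(dataset.pedigree.table["id"], dataset.pedigree.table["sex"]))
    parents = dataset.pedigree.table.set_index("id")
    aa = snps["allele_a"].to_numpy()
    ab = snps["allele_b"].to_numpy()
    with open(paths["ped"], "w") as fh:
        for i, ind in enumerate(geno.ids):
            sire = parents.loc[ind, "sire"] or "0"
            dam = parents.loc[ind, "dam"] or "0"
            sx = "1" if sex_code.get(ind) == "M" else "2"
            fields = ["FAM", ind, sire, dam, sx, "-9"]
            calls = geno.calls[i]
            for j, c in enumerate(calls):
                if c < 0:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [ab[j], ab[j]]
                elif c == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [aa[j], aa[j]]
            fh.write(" ".join(fields) + "\n")
    dataset.pedigree.table.to_csv(paths["pedigree"], sep="\t", index=False)
    dataset.phenotypes.table.to_csv(paths["phenotypes"], sep="\t", index=False)
    if dataset.expression:
        for tissue, em in dataset.expression.items():
            p = out / f"{prefix}.expression.{tissue}.tsv"
            em.values.rename_axis("probe").to_csv(p, sep="\t")
            paths[f"expression.{tissue}"] = p
        pa = out / f"{prefix}.probes.tsv"
        next(iter(dataset.expression.values())).annotation.to_csv(pa, sep="\t", index=False)
        paths["probes"] = pa
    if dataset.truth is not None:
        paths["truth"] = out / f"{prefix}.truth.json"
        payload = {
            "segments": {
                ind: {
                    ch: {"breaks": list(map(float, b)), "origins": list(o)}
                    for ch, (b, o) in per.items()
                }
                for ind, per in dataset.truth.segments.items()
            },
            "crossovers": dataset.truth.crossovers,
        }
        with open(paths["truth"], "w") as fh:
            json.dump(payload, fh)
    return paths


def write_results(tables: Dict[str, pd.DataFrame], out_dir) -> Dict[str, Path]:
    """Deterministic TSV export: stable column order, sorted rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        p = out / f"{name}.tsv"
        df = table.copy()
        for key in (["chrom", "pos_cm"], ["chrom", "cm", "snp"], ["probe"]):
            if all(k in df.columns for k in key):
                df = df.sort_values(key, kind="stable")
                break
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# readers

def _read_map(path):
    """Returns (snps sorted per chromosome, snps in file order)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 MAP columns, got {len(parts)}")
            chrom, snp, cm, bp = parts
            rows.append((snp, chrom, float(cm), int(bp) / 1e6))
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "cm", "mb"])
    sorted_snps = snps.sort_values(["chrom", "cm", "snp"], kind="stable").reset_index(drop=True)
    per_chrom_sorted = all(
        grp["cm"].is_monotonic_increasing for _, grp in snps.groupby("chrom", sort=False)
    )
    if not per_chrom_sorted:
        warnings.warn(f"{path}: map positions not sorted; re-sorting (snp-id tiebreak)")
        return sorted_snps, snps
    return snps.reset_index(drop=True), snps


def read_dataset(paths: Dict[str, str]) -> Dataset:
    """Load PED/MAP + TSV tables; cross-references are validated.

    ``paths`` keys: ped, map, pedigree, phenotypes; optional
    expression.<tissue>, probes.
    """
    snps, original = _read_map(paths["map"])
    order = {s: k for k, s in enumerate(original["snp"])}
    perm = np.array([order[s] for s in snps["snp"]])
    m = len(snps)

    ped_tab = pd.read_csv(paths["pedigree"], sep="\t", comment="#", dtype=str).fillna("")
    pedigree = Pedigree(ped_tab)
    pedigree.validate()

    ids, raw = [], []
    known_ids = set(ped_tab["id"])
    with open(paths["ped"]) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{paths['ped']}:{ln}: expected {6 + 2 * m} fields "
                    f"(2 alleles for each of {m} SNPs), got {len(parts)}"
                )
            _, ind, sire, dam, _, _ = parts[:6]
            for parent in (sire, dam):
                if parent != "0" and parent not in known_ids:
                    raise IntegrityError(
                        f"{paths['ped']}:{ln}: unknown parent {parent!r} of {ind!r}"
                    )
            ids.append(ind)
            raw.append(parts[6:])
    # allele labelling convention: the lexicographically smaller observed
    # allele is allele A and dosages count its copies
    observed = [set() for _ in range(m)]
    for alleles in raw:
        for jj in range(m):
            j = perm[jj]
            for a in (alleles[2 * j], alleles[2 * j + 1]):
                if a != "0":
                    observed[jj].add(a)
    allele_a = [min(obs) if obs else "A" for obs in observed]
    allele_b = [
        max(obs) if len(obs) > 1 else ("B" if aa == "A" else "?")
        for obs, aa in zip(observed, allele_a)
    ]
    rows = []
    for alleles in raw:
        calls = np.empty(m, dtype=np.int8)
        for jj in range(m):
            j = perm[jj]
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            if a1 == "0" or a2 == "0":
                calls[jj] = -1
            else:
                calls[jj] = (a1 == allele_a[jj]) + (a2 == allele_a[jj])
        rows.append(calls)
    snps = snps.assign(allele_a=allele_a, allele_b=allele_b)
    geno = GenotypeMatrix(snps, ids, np.vstack(rows) if rows else np.empty((0, m), np.int8))

    phen = pd.read_csv(paths["phenotypes"], sep="\t", comment="#")
    phen["id"] = phen["id"].astype(str)
    phenotypes = PhenotypeTable(phen)

    expression = None
    for key in paths:
        if key.startswith("expression."):
            expression = expression or {}
            tissue = key.split(".", 1)[1]
            vals = pd.read_csv(paths[key], sep="\t", index_col=0)
            ann = (
                pd.read_csv(paths["probes"], sep="\t")
                if "probes" in paths
                else pd.DataFrame(
                    {"probe": vals.index, "gene": vals.index, "chrom": "", "mb": np.nan}
                )
            )
            expression[tissue] = ExpressionMatrix(vals, ann, tissue=tissue)

    ds = Dataset(
        genotypes=geno, pedigree=pedigree, phenotypes=phenotypes, expression=expression
    )
    ds.validate()
    return ds


def read_truth(path) -> TruthRecord:
    with open(path) as fh:
        payload = json.load(fh)
    segments = {
        ind: {
            ch: (np.asarray(rec["breaks"], float), list(rec["origins"]))
            for ch, rec in per.items()
        }
        for ind, per in payload["segments"].items()
    }
    return TruthRecord(segments=segments, crossovers=payload.get("crossovers", {}))
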