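"""In-memory containers shared across the pipeline stages.

Genotype calls are stored as the dosage of the per-SNP A allele
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing); PED round-tripping
preserves the allele labels.  All coordinates are carried twice per SNP,
in cM (linkage analyses) and Mb (association/TAS reporting); the two are
never interconverted by regression, only by map-table lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

MISSING = -1

GENERATIONS = ("F0", "F1", "BC")
LINES = ("Iberian", "Landrace")


class IntegrityError(ValueError):
    """Raised when cross-references between tables are inconsistent."""


@dataclass
class Pedigree:
    """Ordered three-generation pedigree (parents precede offspring).

    ``table`` columns: id, sire, dam, generation, line, sex.  ``sire``/``dam``
    are empty strings for founders; ``line`` is set for F0 only.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "generation", "line", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise IntegrityError(f"pedigree missing columns {sorted(missing)}")

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    def rows_of(self, generation: str) -> pd.DataFrame:
        return self.table[self.table["generation"] == generation]

    @property
    def bc_ids(self) -> list:
        return list(self.rows_of("BC")["id"])

    def validate(self) -> None:
        seen: set = set()
        line_of = dict(zip(self.table["id"], self.table["line"]))
        gen_of = dict(zip(self.table["id"], self.table["generation"]))
        for row in self.table.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent and parent not in seen:
                    raise IntegrityError(
                        f"parent {parent!r} of {row.id!r} does not precede it"
                    )
            if row.id in seen:
                raise IntegrityError(f"duplicate id {row.id!r}")
            seen.add(row.id)
            if row.generation == "F1":
                lines = {line_of[row.sire], line_of[row.dam]}
                if lines != {"Iberian", "Landrace"}:
                    raise IntegrityError(f"F1 {row.id!r} parents not Iberian x Landrace")
            elif row.generation == "BC":
                if gen_of[row.sire] != "F1":
                    raise IntegrityError(f"BC {row.id!r} sire is not F1")
                if line_of[row.dam] != "Landrace":
                    raise IntegrityError(f"BC {row.id!r} dam is not Landrace")


@dataclass
class GenotypeMatrix:
    """SNP metadata plus an individuals x SNPs dosage matrix."""

    #: columns: snp, chrom, cm, mb, allele_a, allele_b
    snps: pd.DataFrame
    ids: list
    #: int8 (n_individuals, n_snps); dosage of allele_a; -1 missing
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.ids), len(self.snps)):
            raise IntegrityError("calls shape does not match ids x snps")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise IntegrityError("genotype calls outside the four call states")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def dosage(self, snp_index: int) -> np.ndarray:
        """Dosage column as float with NaN for missing calls."""
        col = self.calls[:, snp_index].astype(float)
        col[col == MISSING] = np.nan
        return col

    def dosages(self) -> np.ndarray:
        out = self.calls.astype(float)
        out[out == MISSING] = np.nan
        return out

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            self.snps.iloc[idx].reset_index(drop=True), list(self.ids), self.calls[:, idx]
        )

    def subset_individuals(self, keep_ids) -> "GenotypeMatrix":
        pos = [self.ids.index(i) for i in keep_ids]
        return GenotypeMatrix(self.snps.copy(), list(keep_ids), self.calls[pos])


@dataclass
class TruthRecord:
    """Ground truth retained by the simulator for recovery tests.

    ``segments[ind][chrom]`` is ``(breaks, origins)`` for the F1-transmitted
    (paternal) gamete of a BC animal: ``breaks`` is an increasing array
    starting at 0 and ending at the chromosome length, ``origins`` holds one
    line label per interval.  Segments tile each chromosome exactly once.
    """

    segments: Dict[str, Dict[str, tuple]]
    crossovers: Dict[str, int] = field(default_factory=dict)
    founder_freqs: Optional[pd.DataFrame] = None
    qtl_coefficients: Optional[pd.DataFrame] = None
    breeding_values: Optional[pd.DataFrame] = None
    fixed_design: Optional[pd.DataFrame] = None

    def origin_at(self, ind: str, chrom: str, pos_cm: float) -> str:
        breaks, origins = self.segments[ind][chrom]
        k = int(np.searchsorted(breaks, pos_cm, side="right") - 1)
        k = min(max(k, 0), len(origins) - 1)
        return origins[k]

    def pa_true(self, ind: str, chrom: str, pos_cm: float) -> float:
        """True additive line-origin coefficient: 0 if the paternal gamete
        is Iberian at the position (heterozygous animal), -1 if Landrace."""
        return 0.0 if self.origin_at(ind, chrom, pos_cm) == "Iberian" else -1.0


@dataclass
class PhenotypeTable:
    """One record per BC animal: two tissue traits plus nuisance terms."""

    table: pd.DataFrame
    trait_names: tuple = ("bf", "imf")

    def __post_init__(self) -> None:
        required = {"id", "sex", "batch", "carcass_wt", *self.trait_names}
        missing = required - set(self.table.columns)
        if missing:
            raise IntegrityError(f"phenotypes missing columns {sorted(missing)}")


@dataclass
class ExpressionMatrix:
    """Normalized (log2-scale) expression values, probes x samples."""

    values: pd.DataFrame
    #: columns: probe, gene, chrom, mb
    annotation: pd.DataFrame
    tissue: str = "muscle"
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise IntegrityError("expression values contain missing entries")

    @property
    def probes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)


@dataclass
class Dataset:
    """Validated bundle of everything a pipeline stage may need."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    phenotypes: PhenotypeTable
    expression: Optional[Dict[str, ExpressionMatrix]] = None
    probe_annotation: Optional[pd.DataFrame] = None
    truth: Optional[TruthRecord] = None

    def validate(self) -> None:
        self.pedigree.validate()
        ped_ids = set(self.pedigree.ids)
        for ind in self.genotypes.ids:
            if ind not in ped_ids:
                raise IntegrityError(f"genotyped individual {ind!r} not in pedigree")
        for ind in self.phenotypes.table["id"]:
            if ind not in ped_ids:
                raise IntegrityError(f"phenotyped individual {ind!r} not in pedigree")
        if self.expression:
            for em in self.expression.values():
                for s in em.samples:
                    if s not in ped_ids:
                        raise IntegrityError(f"expression sample {s!r} not in pedigree")

    @property
    def map_table(self) -> pd.DataFrame:
        return self.genotypes.snps[["snp", "chrom", "cm", "mb"]]
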