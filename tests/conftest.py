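import numpy as np
import pandas as pd
import pytest

import crossqtl as cq
from crossqtl.config import QtlSpec, SimConfig
from crossqtl.containers import Dataset, GenotypeMatrix, Pedigree, PhenotypeTable


@pytest.fixture(scope="session")
def clean_config():
    """Moderate error-free backcross with one pleiotropic QTL."""
    return SimConfig(
        n_bc=120,
        chromosomes=[("1", 100.0, 101)],
        qtl_architecture=[QtlSpec("1", 45.0, 0.7, 0.7, "pleiotropic")],
        h2=(0.3, 0.3),
        missing_rate=0.0,
        mendel_error_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return cq.simulate_dataset(clean_config)


@pytest.fixture(scope="session")
def clean_A(clean_dataset):
    return cq.numerator_relationship(clean_dataset.pedigree)


@pytest.fixture(scope="session")
def fixed_line_dataset():
    """Fully informative markers: allele A fixed in Iberian, absent in
    Landrace, error-free calls."""
    m = 11
    config = SimConfig(
        n_bc=60,
        chromosomes=[("1", 100.0, m)],
        founder_freqs=np.tile([1.0, 0.0], (m, 1)),
        missing_rate=0.0,
        mendel_error_rate=0.0,
        seed=7,
    )
    return cq.simulate_dataset(config), config


def toy_pedigree(rows):
    """rows: (id, sire, dam, generation, line, sex)."""
    return Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "line", "sex"])
    )


@pytest.fixture
def manual_dataset_factory():
    """Build a Dataset from explicit call matrices for QC/LD tests."""

    def build(calls, cm=None, mb=None, chrom="1", f0_iberian=("S1",), f0_landrace=("D1",)):
        calls = np.asarray(calls, dtype=np.int8)
        n_ind, m = calls.shape
        n_bc = n_ind - len(f0_iberian) - len(f0_landrace) - 1
        rows = [(s, "", "", "F0", "Iberian", "M") for s in f0_iberian]
        rows += [(d, "", "", "F0", "Landrace", "F") for d in f0_landrace]
        rows += [("F1_1", f0_iberian[0], f0_landrace[0], "F1", "", "M")]
        rows += [
            (f"BC{i + 1}", "F1_1", f0_landrace[0], "BC", "", "M")
            for i in range(n_bc)
        ]
        ped = toy_pedigree(rows)
        ids = [r[0] for r in rows]
        snps = pd.DataFrame(
            {
                "snp": [f"s{j + 1}" for j in range(m)],
                "chrom": chrom,
                "cm": cm if cm is not None else np.arange(m, dtype=float),
                "mb": mb if mb is not None else np.arange(m, dtype=float) * 0.67,
                "allele_a": "A",
                "allele_b": "B",
            }
        )
        geno = GenotypeMatrix(snps, ids, calls)
        bc_ids = [r[0] for r in rows if r[3] == "BC"]
        phen = PhenotypeTable(
            pd.DataFrame(
                {
                    "id": bc_ids,
                    "sex": ["M"] * len(bc_ids),
                    "batch": ["b1"] * len(bc_ids),
                    "carcass_wt": 0.0,
                    "bf": 0.0,
                    "imf": 0.0,
                }
            )
        )
        return Dataset(genotypes=geno, pedigree=ped, phenotypes=phen)

    return build
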