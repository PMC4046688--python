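"""Configuration objects for the simulator and the analysis pipeline.

The default :class:`SimConfig` mirrors the experimental design the package
is built around: an (Iberian x Landrace) x Landrace backcross founded by 3
Iberian boars and 30 Landrace sows, with 5 F1 boars mated to 25 Landrace
sows to produce 157 backcross (BC) animals carrying one guaranteed Landrace
gamete.  :class:`RunConfig` collects the analysis-stage thresholds (QC
cut-offs, scan grid step, FDR levels, TAS-region rules, probe filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is infeasible or out of range."""


@dataclass(frozen=True)
class QtlSpec:
    """A simulated QTL: chromosome, cM position and per-trait additive effects.

    Effects are expressed in phenotypic-SD units of the base (no-QTL) trait
    distribution.  ``kind`` must be consistent with which effects are
    nonzero: ``pleiotropic`` needs both, ``trait1-only``/``trait2-only``
    exactly one.
    """

    chromosome: str
    position_cm: float
    effect_trait1: float = 0.0
    effect_trait2: float = 0.0
    kind: str = "pleiotropic"

    def __post_init__(self) -> None:
        valid = {"pleiotropic", "trait1-only", "trait2-only"}
        if self.kind not in valid:
            raise ConfigurationError(f"unknown QTL kind {self.kind!r}")
        e1, e2 = self.effect_trait1 != 0.0, self.effect_trait2 != 0.0
        ok = {
            "pleiotropic": e1 and e2,
            "trait1-only": e1 and not e2,
            "trait2-only": e2 and not e1,
        }[self.kind]
        if not ok:
            raise ConfigurationError(
                f"QTL kind {self.kind!r} inconsistent with effects "
                f"({self.effect_trait1}, {self.effect_trait2})"
            )


@dataclass
class SimConfig:
    """Parameters of the synthetic backcross population.

    Counts default to the reference design (3 F0 sires, 30 F0 dams, 5 F1
    sires, 25 BC dams, 157 BC animals).  Founder allele frequencies are,
    by default, drawn per SNP from divergent Beta distributions (mean 0.8
    in the Iberian line, 0.2 in the Landrace line), a modelling choice for
    a cross between lines with mostly, but not completely, divergent
    alleles; supply ``founder_freqs`` explicitly to override.
    """

    n_f0_sires: int = 3
    n_f0_dams: int = 30
    n_f1_sires: int = 5
    n_f1_dams: int = 25
    n_bc: int = 157
    #: list of (name, length in cM, number of SNPs)
    chromosomes: Sequence[tuple] = field(
        default_factory=lambda: [("1", 100.0, 101)]
    )
    #: optional explicit (n_snps, 2) array-like of per-SNP allele-A
    #: frequencies (Iberian, Landrace); None -> Beta-distributed defaults
    founder_freqs: Optional[object] = None
    #: Beta parameters for the default divergent frequency draw
    freq_beta_iberian: tuple = (4.0, 1.0)
    freq_beta_landrace: tuple = (1.0, 4.0)
    qtl_architecture: Sequence[QtlSpec] = field(default_factory=list)
    #: per-trait polygenic heritability
    h2: tuple = (0.3, 0.3)
    genetic_corr: float = 0.0
    residual_corr: float = 0.3
    sex_effect: tuple = (0.3, 0.3)
    batch_effects: tuple = ((-0.2, 0.0, 0.2), (-0.2, 0.0, 0.2))
    carcass_weight_slope: tuple = (0.2, 0.2)
    missing_rate: float = 0.01
    mendel_error_rate: float = 0.002
    #: cM -> Mb scale used to lay physical positions on the synthetic map
    mb_per_cm: float = 0.67
    n_expr_samples: tuple = (102, 40)
    #: variance share of a per-sample co-expression factor common to all
    #: probes of a tissue; emulates the dominant principal component of
    #: normalized arrays, which drives the probe-set effective-test
    #: number well below the probe count
    expr_common_rho: float = 0.75
    seed: int = 20130845

    def __post_init__(self) -> None:
        for name in ("n_f0_sires", "n_f0_dams", "n_f1_sires", "n_f1_dams", "n_bc"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_f1_dams > self.n_f0_dams + self.n_f1_dams:
            raise ConfigurationError("infeasible dam counts")
        for name, L, m in self.chromosomes:
            if L <= 0 or m <= 0:
                raise ConfigurationError(f"chromosome {name}: nonpositive length or SNP count")
        for h in self.h2:
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError("h2 must lie in [0, 1]")
        if not -1.0 < self.residual_corr < 1.0:
            raise ConfigurationError("residual_corr must lie in (-1, 1)")
        if not -1.0 <= self.genetic_corr <= 1.0:
            raise ConfigurationError("genetic_corr must lie in [-1, 1]")
        for name in ("missing_rate", "mendel_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.expr_common_rho < 1.0:
            raise ConfigurationError("expr_common_rho must lie in [0, 1)")
        chrom_len = {c[0]: c[1] for c in self.chromosomes}
        for q in self.qtl_architecture:
            if q.chromosome not in chrom_len:
                raise ConfigurationError(f"QTL on unknown chromosome {q.chromosome!r}")
            if not 0.0 <= q.position_cm <= chrom_len[q.chromosome]:
                raise ConfigurationError(
                    f"QTL position {q.position_cm} outside chromosome {q.chromosome}"
                )


@dataclass
class RunConfig:
    """Analysis-stage parameters; defaults are the pipeline's reference values."""

    call_rate_min: float = 0.85
    maf_min: float = 0.15
    grid_step_cm: float = 1.0
    fdr_scan: float = 0.05
    fdr_eqtl: float = 0.20
    tas_gap_cm: float = 1.5
    tas_min_snps: int = 3
    probe_fold: float = 1.5
    probe_fraction: float = 0.20
    emission_slack: float = 1e-3
    seed: int = 1

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("call_rate_min", 0.0, 1.0),
            ("maf_min", 0.0, 0.5),
            ("fdr_scan", 0.0, 1.0),
            ("fdr_eqtl", 0.0, 1.0),
            ("probe_fraction", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.grid_step_cm <= 0 or self.tas_gap_cm <= 0:
            raise ConfigurationError("grid step and TAS gap must be positive")
        if self.probe_fold <= 1.0:
            raise ConfigurationError("probe_fold must exceed 1")


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a YAML key-value file (flat or under 'run')."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw = raw.get("run", raw)
    return RunConfig(**raw)


def load_sim_config(path) -> SimConfig:
    """Load a SimConfig from YAML; 'qtl_architecture' entries are mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw = raw.get("simulate", raw)
    if "qtl_architecture" in raw:
        raw["qtl_architecture"] = [QtlSpec(**q) for q in raw["qtl_architecture"]]
    if "chromosomes" in raw:
        raw["chromosomes"] = [tuple(c) for c in raw["chromosomes"]]
    return SimConfig(**raw)


def dump_sim_config(config: SimConfig, path) -> None:
    raw = asdict(config)
    raw["chromosomes"] = [list(c) for c in config.chromosomes]
    raw["qtl_architecture"] = [asdict(q) for q in config.qtl_architecture]
    with open(path, "w") as fh:
        yaml.safe_dump({"simulate": raw}, fh, sort_keys=False)
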