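"""Configuration objects for the synthetic-data generator and the pipeline.

All tunable parameters of the simulation are surfaced here rather than
hard-coded in the generators; the seed fully determines every artifact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


def _default_phenotype_measures() -> dict:
    """Two-group longitudinal measures emulating perinatal phenotyping.

    Each entry: baseline per timepoint, residual sd, additive shift applied to
    the mutant (HET) group, and optional latency bounds (seconds).
    """
    return {
        "body_weight_g": {
            "timepoints": ["PND4", "PND6", "PND8", "PND10", "PND12"],
            "baseline": [2.8, 3.6, 4.5, 5.5, 6.5],
            "sd": 0.35,
            "het_shift": -0.55,
            "min_value": None,
            "cutoff": None,
        },
        "usv_calls": {
            "timepoints": ["PND3", "PND5", "PND7", "PND9", "PND11"],
            "baseline": [30.0, 55.0, 80.0, 60.0, 35.0],
            "sd": 12.0,
            "het_shift": -25.0,
            "min_value": 0.0,
            "cutoff": None,
        },
        "righting_latency_s": {
            "timepoints": ["PND4", "PND6", "PND8", "PND10", "PND12"],
            "baseline": [18.0, 12.0, 8.0, 5.0, 3.0],
            "sd": 6.0,
            "het_shift": 4.0,
            "min_value": 0.0,
            "cutoff": 30.0,
        },
    }


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic single-cell / phenotype study.

    Counts are negative-binomial with gene-level means and dispersions drawn
    log-uniformly, thinned by a logistic mean-dependent dropout.  A designated
    "vulnerable" population carries an elevated fraction of planted genotype
    effects, biased toward downregulation.
    """

    seed: int = 0
    region: str = "hippocampus"

    # cells and genes
    n_cell_types: int = 6
    cells_per_type_per_genotype: int = 350
    n_genes: int = 1500
    n_mito_genes: int = 10
    baseline_mean_range: tuple = (0.2, 8.0)
    dispersion_range: tuple = (0.5, 4.0)
    dropout_midpoint: float = -1.0
    dropout_slope: float = 1.0
    cell_size_sd: float = 0.15
    sex_ratio: float = 0.5
    mito_fraction_range: tuple = (0.01, 0.10)

    # planted genotype effects
    vulnerable_type: str = "pop01"
    frac_de_vulnerable: float = 0.08
    frac_de_other: float = 0.01
    lfc_mean: float = 0.8
    lfc_sd: float = 0.3
    down_bias: float = 0.73

    # gene annotation
    frac_excluded_class: float = 0.10
    frac_has_homolog: float = 0.90
    gene_length_log_mean: float = 7.6
    gene_length_log_sd: float = 0.8
    disease_set_names: tuple = ("DD", "epilepsy", "SFARI")
    disease_set_size: int = 60
    disease_set_enrichment: float = 4.0

    # compound reference library
    n_compounds: int = 200
    n_planted_reversers: int = 5
    n_planted_mimics: int = 5
    signature_noise_sd: float = 0.25

    # CLIP sites
    clip_lambda: float = 2.0
    clip_enrichment: float = 50.0
    clip_enriched_floor: float = 5.0
    clip_enriched_gene: Optional[str] = None
    clip_site_width: int = 30

    # phenotypes
    n_subjects_per_genotype: int = 16
    phenotype_measures: dict = field(default_factory=_default_phenotype_measures)

    def cell_type_labels(self) -> list[str]:
        return [f"pop{i:02d}" for i in range(1, self.n_cell_types + 1)]

    def validate(self) -> "SimConfig":
        if int(self.n_genes) <= 0:
            raise ConfigError("n_genes must be a positive integer")
        for name in ("n_cell_types", "cells_per_type_per_genotype", "n_mito_genes",
                     "n_compounds", "n_subjects_per_genotype"):
            v = getattr(self, name)
            if not float(v).is_integer() or int(v) <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("frac_de_vulnerable", "frac_de_other", "down_bias", "sex_ratio",
                     "frac_excluded_class", "frac_has_homolog"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if self.n_mito_genes >= self.n_genes:
            raise ConfigError("n_mito_genes must be smaller than n_genes")
        if self.vulnerable_type not in self.cell_type_labels():
            raise ConfigError(
                f"vulnerable_type {self.vulnerable_type!r} is not one of the "
                f"generated cell-type labels {self.cell_type_labels()}")
        if self.n_planted_reversers + self.n_planted_mimics > self.n_compounds:
            raise ConfigError("planted reversers + mimics exceed n_compounds")
        if self.clip_lambda < 0:
            raise ConfigError("clip_lambda must be nonnegative")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        for key in ("baseline_mean_range", "dispersion_range", "mito_fraction_range",
                    "disease_set_names"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    Every threshold defaults to the standard analysis values: genes kept when
    detected in >= 4 cells; cells kept with 1000-5000 genes detected and
    mitochondrial percentage <= 8 (cortex) / 15 (hippocampus); DE significance
    |log2FC| >= 0.14 with FDR < 0.05 (relaxed: 0.0704 / 0.1); 300 cells per
    genotype for the burden analysis; top-150 down genes per signature; and a
    connectivity-score candidate cutoff of tau < -90.
    """

    sim: SimConfig = field(default_factory=SimConfig)

    min_cells_per_gene: int = 4
    min_genes_per_cell: int = 1000
    max_genes_per_cell: int = 5000
    max_mito_pct: Optional[float] = None  # None -> region default (8 / 15)

    lfc_min: float = 0.14
    fdr_max: float = 0.05
    lfc_min_relaxed: float = 0.0704
    fdr_max_relaxed: float = 0.1
    min_cells_detected: int = 3
    sex_covariate: bool = True

    burden_n_cells: int = 300
    burden_seed: int = 0

    signature_k: int = 150
    candidate_tau: float = -90.0
    top_k_overlap: int = 20

    pheno_n_perm: int = 10000

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            for key in ("baseline_mean_range", "dispersion_range",
                        "mito_fraction_range", "disease_set_names"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            cfg.sim = SimConfig(**sim).validate()
        return cfg
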