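"""Simulation configuration.

The simulator emulates the data regime of a freshwater MAG survey: species
clusters of at least nine partial genomes, within-species nucleotide
divergence below 5%, a tunable secreted-vs-cytoplasmic divergence ratio,
tunable coding density, KO-level gene duplication, completeness between 40
and 100% and contamination between 0 and 5%.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

__all__ = ["SimulationConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid or infeasible."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population-genome generator.

    Rates are per-site, per-lineage probabilities; fractions are in [0, 1];
    completeness/contamination ranges are percentages, matching the retention
    regime of the study design (completeness 40-100%, contamination 0-5%).
    """

    seed: int = 0
    n_species: int = 3
    members_per_species: int = 9
    n_genes: int = 40
    mean_gene_len: int = 90  # amino acids, mature+signal
    sp_fraction: float = 0.3
    coding_density_target: float = 0.9
    mu_cp: float = 0.01  # per-site nucleotide substitution prob., CP genes
    sp_rate_multiplier: float = 1.0  # mu_sp / mu_cp
    recomb_events_per_genome: int = 2
    import_length_mean: int = 400  # bp
    donor_divergence: float = 0.15
    ko_pool_size: int = 500
    duplication_rate: float = 0.2
    completeness_range: tuple[float, float] = (40.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 5.0)
    gc_target: float = 0.5
    # contig fragmentation: fixed length + jitter, with a floor on contig
    # count so partial-completeness MAGs remain representable
    contig_len_mean: int = 30_000
    contig_len_jitter: int = 10_000
    min_contigs: int = 20

    def __post_init__(self) -> None:
        fracs = {
            "sp_fraction": self.sp_fraction,
            "coding_density_target": self.coding_density_target,
            "mu_cp": self.mu_cp,
            "donor_divergence": self.donor_divergence,
            "duplication_rate": self.duplication_rate,
            "gc_target": self.gc_target,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")
        if self.coding_density_target <= 0.0:
            raise ConfigurationError("coding_density_target must be > 0")
        if self.members_per_species < 2:
            raise ConfigurationError("members_per_species must be >= 2")
        if self.n_species < 1 or self.n_genes < 1:
            raise ConfigurationError("n_species and n_genes must be >= 1")
        if self.mean_gene_len < 30:
            raise ConfigurationError("mean_gene_len must be >= 30 aa")
        if self.sp_rate_multiplier < 0:
            raise ConfigurationError("sp_rate_multiplier must be >= 0")
        if self.ko_pool_size < self.n_genes:
            raise ConfigurationError("ko_pool_size must be >= n_genes")
        for name in ("completeness_range", "contamination_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 100.0):
                raise ConfigurationError(f"{name} must satisfy 0 <= lo <= hi <= 100")
            setattr(self, name, (float(lo), float(hi)))
        if self.completeness_range[1] <= 0:
            raise ConfigurationError("completeness upper bound must be > 0")
        if self.n_species == 1 and self.contamination_range[1] > 0:
            raise ConfigurationError(
                "contamination requires a second species as contaminant source"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("completeness_range", "contamination_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["completeness_range"] = list(self.completeness_range)
        data["contamination_range"] = list(self.contamination_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
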