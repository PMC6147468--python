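"""Configuration objects and validation for the simulator and pipeline.

All genomic coordinates held internally are 0-based half-open; conversions
to 1-based (VCF/GFF3/HGVS) happen only at format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    The defaults mirror the design of a recessive-disease mapping study in a
    closed dog breed, scaled to desk size: a multi-generation pedigree with a
    single shared carrier ancestor, two affected homozygotes with
    obligate-carrier parents, a ~10k-marker SNP array carrying an implanted
    autozygous region around the causal locus, an exome variant table in which
    exactly 1 + n_decoy_recessive variants segregate recessively, read pileups
    for genotype calling, and a toy transcriptome whose designated gene can
    undergo cryptic-donor activation.
    """

    seed: int = 0
    n_founders: int = 6
    n_generations: int = 3
    n_markers: int = 10_000
    marker_spacing_bp: int = 1_000
    founder_allele_freq: float = 0.3
    causal_region: tuple[str, int, int] = ("2", 1_000_000, 1_350_000)
    n_exome_variants: int = 500
    n_decoy_recessive: int = 15
    pileup_depth_mean: float = 36.0
    base_error_rate: float = 0.01
    # secondary knobs
    missing_rate: float = 0.002
    recomb_rate: float = 0.1          # per adjacent-marker interval
    litter_size: int = 6
    n_controls: int = 3
    n_chromosomes: int = 4
    n_genes: int = 24
    n_region_genes: int = 6
    cryptic_offset: int = 50          # nt upstream of the designated donor

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> None:
            raise ConfigError(f"SimConfig.{name}: {why}")

        if not isinstance(self.seed, int) or self.seed < 0:
            bad("seed", "must be a non-negative integer")
        if self.n_founders < 2:
            bad("n_founders", "must be >= 2")
        if self.n_generations < 0:
            bad("n_generations", "must be >= 0")
        if self.n_markers < 1:
            bad("n_markers", "must be >= 1")
        if self.marker_spacing_bp < 1:
            bad("marker_spacing_bp", "must be >= 1")
        if not 0.0 < self.founder_allele_freq < 1.0:
            bad("founder_allele_freq", "must lie in the open interval (0, 1)")
        if not 0.0 < self.base_error_rate < 0.5:
            bad("base_error_rate", "must lie in the open interval (0, 0.5)")
        if self.pileup_depth_mean <= 0:
            bad("pileup_depth_mean", "must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            bad("missing_rate", "must lie in [0, 1)")
        if not 0.0 <= self.recomb_rate <= 0.5:
            bad("recomb_rate", "must lie in [0, 0.5]")
        if self.n_exome_variants < self.n_decoy_recessive + 1:
            bad("n_exome_variants", "must exceed n_decoy_recessive")
        if self.n_decoy_recessive < 0:
            bad("n_decoy_recessive", "must be >= 0")
        if self.n_chromosomes < 1:
            bad("n_chromosomes", "must be >= 1")
        if self.n_region_genes < 1 or self.n_genes < self.n_region_genes:
            bad("n_genes", "must be >= n_region_genes >= 1")
        if self.cryptic_offset < 1:
            bad("cryptic_offset", "must be >= 1")
        chrom, start, end = self.causal_region
        if end <= start or start < 0:
            bad("causal_region", "end must exceed start and start must be >= 0")
        if chrom not in self.chromosome_names():
            bad("causal_region", f"chromosome {chrom!r} is not simulated")
        if end > self.chromosome_length():
            bad("causal_region", "region extends beyond the simulated marker span")

    # -- derived geometry -------------------------------------------------

    def chromosome_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def markers_per_chromosome(self) -> int:
        return self.n_markers // self.n_chromosomes

    def chromosome_length(self) -> int:
        """Simulated chromosome length in bp (equal across chromosomes)."""
        return (self.markers_per_chromosome() + 1) * self.marker_spacing_bp


_ROH_DEFAULT_MIN_SNPS = 200
_ROH_DEFAULT_MIN_PRIORITY = 0.15


@dataclass(frozen=True)
class ROHParams:
    """Thresholds of the region priority filter.

    Both thresholds are strict (">"): a region qualifies only with more than
    ``min_consecutive_snps`` candidate loci and a priority value larger than
    ``min_priority``.
    """

    min_consecutive_snps: int = _ROH_DEFAULT_MIN_SNPS
    min_priority: float = _ROH_DEFAULT_MIN_PRIORITY

    def __post_init__(self) -> None:
        if self.min_consecutive_snps <= 0:
            raise ConfigError("ROHParams.min_consecutive_snps: must be positive")
        if self.min_priority <= 0:
            raise ConfigError("ROHParams.min_priority: must be positive")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> call -> map -> filter).

    Loaded from a flat key-value YAML file; unknown keys are rejected and the
    seed is mandatory. All paths are resolved to absolute at load time.
    """

    seed: int
    out_dir: Path
    sim: SimConfig = field(default_factory=SimConfig)
    roh: ROHParams = field(default_factory=ROHParams)
    min_call_rate: float = 0.2
    min_maf: float = 0.05
    min_reads: int = 2
    error_rate: float = 0.01
    donor_scan_window: int = 60
    log_level: str = "INFO"

    _SCALARS = {
        "seed": int,
        "out_dir": str,
        "min_call_rate": float,
        "min_maf": float,
        "min_reads": int,
        "error_rate": float,
        "donor_scan_window": int,
        "log_level": str,
    }

    @classmethod
    def from_mapping(cls, data: dict, base_dir: Optional[Path] = None) -> "RunConfig":
        data = dict(data)
        if "seed" not in data:
            raise ConfigError("RunConfig.seed: missing (seed is mandatory)")
        if "out_dir" not in data:
            raise ConfigError("RunConfig.out_dir: missing")
        sim_fields = {f.name: f for f in fields(SimConfig)}
        known = set(cls._SCALARS) | {f"sim.{k}" for k in sim_fields} | {
            "roh.min_consecutive_snps",
            "roh.min_priority",
        }
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"RunConfig: unknown keys {unknown}")

        sim_kwargs = {}
        for key, value in list(data.items()):
            if key.startswith("sim."):
                name = key[4:]
                if name == "causal_region":
                    chrom, start, end = str(value).split(":")
                    value = (chrom, int(start), int(end))
                sim_kwargs[name] = value
                del data[key]
        sim_kwargs.setdefault("seed", int(data["seed"]))
        roh_kwargs = {}
        for key in ("roh.min_consecutive_snps", "roh.min_priority"):
            if key in data:
                roh_kwargs[key.split(".", 1)[1]] = data.pop(key)

        out_dir = Path(data.pop("out_dir"))
        if base_dir is not None and not out_dir.is_absolute():
            out_dir = base_dir / out_dir
        kwargs = {k: cls._SCALARS[k](v) for k, v in data.items()}
        kwargs.pop("out_dir", None)
        return cls(
            out_dir=out_dir.resolve(),
            sim=SimConfig(**sim_kwargs),
            roh=ROHParams(**roh_kwargs),
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"RunConfig: {path} does not hold a key-value mapping")
        return cls.from_mapping(data, base_dir=path.parent)

    def to_mapping(self) -> dict:
        out = {k: getattr(self, k) for k in self._SCALARS}
        out["out_dir"] = str(self.out_dir)
        for k, v in asdict(self.sim).items():
            if k == "causal_region":
                v = ":".join(str(x) for x in v)
            out[f"sim.{k}"] = v
        out["roh.min_consecutive_snps"] = self.roh.min_consecutive_snps
        out["roh.min_priority"] = self.roh.min_priority
        return out
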