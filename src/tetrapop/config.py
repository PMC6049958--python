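"""Run configuration shared by the CLI subcommands.

The defaults encode the filtering and thresholding rules used throughout
the pipeline: 25-SNP windows, a per-individual depth floor of 4 reads, a
minimum of 5 genotyped individuals per population and site, gene-level
introgression calls requiring f_d > 3 x genome-wide f_hom in every
quartet, and empirical 5% outlier tails.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    window_size_snps: int = 25
    min_depth: int = 4
    min_individuals: int = 5
    fd_multiplier: float = 3.0
    min_informative_snps_per_gene: int = 25
    outlier_quantiles: dict = field(
        default_factory=lambda: {"gst": 0.05, "h": 0.05, "tajd": 0.05}
    )
    permutations: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window_size_snps",
            "min_depth",
            "min_individuals",
            "min_informative_snps_per_gene",
            "permutations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fd_multiplier <= 0:
            raise ValueError("fd_multiplier must be positive")
        for key, q in self.outlier_quantiles.items():
            if not 0 < q <= 0.5:
                raise ValueError(f"outlier quantile {key}={q} outside (0, 0.5]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, logged with every run."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
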