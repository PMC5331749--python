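"""Configuration for the synthetic flock generator.

The defaults describe a single-drop Merino flock of ~2600 group-mated progeny
from 45 sires (33 of which are available for individual genotyping), scored
1-5 for dag (breech soiling) with heritability 0.35 on the liability scale,
and pooled within sex x dag score with two replicate pools per cell.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import yaml

from .errors import ConfigError

#: Liability cutpoints (standard-normal quantiles) giving category occupancy
#: of roughly 30/27/22/15/6 percent, so the top score holds ~78 of 1300
#: animals per sex -- comparable to the 66-80 animals per cell the pooling
#: design expects.
DEFAULT_THRESHOLDS: tuple[float, ...] = (-0.524, 0.176, 0.806, 1.555)


@dataclass(frozen=True)
class FlockConfig:
    """Parameters of the simulated flock and pooling design.

    Attributes
    ----------
    n_sires
        Sires that produced the progeny drop.
    n_genotyped_sires
        Sires still available for individual genotyping (first
        ``n_genotyped_sires`` of the ``n_sires``).
    n_progeny
        Progeny of unknown pedigree available for phenotyping.
    n_loci
        Biallelic SNP loci (independent; no linkage).
    maf_low, maf_high
        Bounds of the uniform per-locus allele-frequency distribution,
        in (0, 0.5].
    heritability
        Narrow-sense heritability of the liability underlying the dag
        score, in [0, 1].
    category_thresholds
        Four strictly increasing liability cutpoints defining scores 1-5.
    sex_effect
        Additive shift of male liability (females are baseline); default 0.
    max_per_cell
        Animals retained per sex x score cell (the race-sampling cap).
    n_replicates
        Replicate pools each retained cell is split into.
    retention
        ``"first_come"`` keeps the first ``max_per_cell`` animals through
        the race; ``"random"`` samples the cell at random.
    contribution_concentration
        Symmetric-Dirichlet concentration of per-animal DNA contributions
        within a pool; ``inf`` means exactly equal contributions.  Smaller
        values mean noisier pooling (lower "effective n").
    seed
        Single seed; every stochastic draw flows from one generator.
    """

    n_sires: int = 45
    n_genotyped_sires: int = 33
    n_progeny: int = 2600
    n_loci: int = 10_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    heritability: float = 0.35
    category_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    sex_effect: float = 0.0
    max_per_cell: int = 80
    n_replicates: int = 2
    retention: str = "first_come"
    contribution_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires < 1 or self.n_progeny < 1 or self.n_loci < 1:
            raise ConfigError("n_sires, n_progeny and n_loci must be >= 1")
        if not 0 < self.n_genotyped_sires <= self.n_sires:
            raise ConfigError(
                f"n_genotyped_sires={self.n_genotyped_sires} must be in "
                f"[1, n_sires={self.n_sires}]"
            )
        if not (0 <= self.maf_low <= self.maf_high <= 0.5):
            raise ConfigError(
                f"require 0 <= maf_low <= maf_high <= 0.5, got "
                f"({self.maf_low}, {self.maf_high})"
            )
        if not 0.0 <= self.heritability <= 1.0:
            raise ConfigError(f"heritability={self.heritability} outside [0, 1]")
        thr = tuple(float(t) for t in self.category_thresholds)
        object.__setattr__(self, "category_thresholds", thr)
        if len(thr) != 4 or any(b <= a for a, b in zip(thr, thr[1:])):
            raise ConfigError(
                "category_thresholds must be 4 strictly increasing cutpoints"
            )
        if self.max_per_cell < 1 or self.n_replicates < 1:
            raise ConfigError("max_per_cell and n_replicates must be >= 1")
        if self.retention not in ("first_come", "random"):
            raise ConfigError(f"unknown retention mode {self.retention!r}")
        if not self.contribution_concentration > 0:
            raise ConfigError("contribution_concentration must be positive")

    @classmethod
    def from_yaml(cls, path) -> "FlockConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
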