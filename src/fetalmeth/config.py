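"""Configuration dataclasses for the synthetic-data generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd


class ConfigurationError(ValueError):
    """A configuration field is missing or outside its valid range."""


TISSUES = ("amnion", "muscle", "adrenal", "pancreas")
WEEKS = (9, 18, 22)

PLANTED_KINDS = ("tissue_hypo", "gom", "lom", "neutral")


@dataclass
class PlantedSignal:
    """One planted block of CpGs sharing an effect.

    kind
        ``tissue_hypo``: the target tissue sits at ``mean_trajectory`` at every
        week while all other tissues sit at ``background_mean``.
        ``gom``/``lom``: the target tissue follows ``mean_trajectory`` across
        weeks (gain or loss), other tissues stay at ``background_mean``.
        ``neutral``: every tissue and week at ``background_mean``.
    mean_trajectory
        One mean beta per gestational week, in week order.
    """

    kind: str
    target_tissue: str | None
    n_cpgs_in_block: int
    mean_trajectory: tuple[float, ...]
    background_mean: float = 0.5

    def validate(self, tissues, weeks) -> None:
        if self.kind not in PLANTED_KINDS:
            raise ConfigurationError(f"PlantedSignal.kind: unknown kind {self.kind!r}")
        if self.n_cpgs_in_block < 1:
            raise ConfigurationError("PlantedSignal.n_cpgs_in_block: must be >= 1")
        if self.kind != "neutral":
            if self.target_tissue not in tissues:
                raise ConfigurationError(
                    f"PlantedSignal.target_tissue: {self.target_tissue!r} "
                    f"not in tissues {tuple(tissues)}")
            if len(self.mean_trajectory) != len(weeks):
                raise ConfigurationError(
                    "PlantedSignal.mean_trajectory: needs one value per week")
        for m in list(self.mean_trajectory) + [self.background_mean]:
            if not 0.0 <= m <= 1.0:
                raise ConfigurationError(
                    f"PlantedSignal.mean_trajectory/background_mean: {m} not in [0,1]")
        if self.kind == "tissue_hypo":
            if any(self.background_mean - m < 0 for m in self.mean_trajectory):
                raise ConfigurationError(
                    "PlantedSignal: tissue_hypo trajectory must not exceed background_mean")


@dataclass
class SimulationConfig:
    """Study design and noise model for the synthetic 450k-style dataset.

    The default design mirrors the study conditions: 4 tissues x 3 gestational
    weeks x 3 replicates, replicate noise Beta-distributed with concentration
    ``noise_concentration`` (kappa = 200 gives SD ~0.035 at mean 0.5).
    """

    n_chromosomes: int = 4
    n_cpgs: int = 20_000
    n_genes: int = 300
    n_cgis: int = 120
    tissues: tuple[str, ...] = TISSUES
    weeks: tuple[int, ...] = WEEKS
    replicates_per_cell: int = 3
    noise_concentration: float = 200.0
    background_mean: float = 0.5
    planted: list[PlantedSignal] = field(default_factory=list)
    seed: int = 0
    # expression model
    expression_base_mean: float = 200.0
    expression_dispersion: float = 0.1
    expression_fold_change: float = 2.0
    # peak geometry
    peak_width: int = 600

    def validate(self) -> None:
        for name in ("n_chromosomes", "n_cpgs", "n_genes", "n_cgis",
                     "replicates_per_cell"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"SimulationConfig.{name}: must be >= 1")
        if len(self.tissues) < 1 or len(self.weeks) < 1:
            raise ConfigurationError("SimulationConfig.tissues/weeks: must be nonempty")
        if list(self.weeks) != sorted(set(self.weeks)):
            raise ConfigurationError(
                "SimulationConfig.weeks: must be strictly increasing")
        if not self.noise_concentration > 0:
            raise ConfigurationError(
                "SimulationConfig.noise_concentration: must be > 0")
        if not 0.0 <= self.background_mean <= 1.0:
            raise ConfigurationError(
                "SimulationConfig.background_mean: must be in [0,1]")
        if self.expression_dispersion < 0:
            raise ConfigurationError(
                "SimulationConfig.expression_dispersion: must be >= 0")
        n_planted = sum(s.n_cpgs_in_block for s in self.planted)
        if n_planted > self.n_cpgs:
            raise ConfigurationError(
                f"SimulationConfig.planted: {n_planted} planted CpGs exceed "
                f"n_cpgs={self.n_cpgs}")
        for sig in self.planted:
            sig.validate(self.tissues, self.weeks)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Machine-readable record of what was planted where.

    probes: probe_id, kind, target_tissue, block_id (one row per probe).
    blocks: block_id, kind, target_tissue, chrom, start, end — 1-based
    inclusive span of the block's probes; intervals pairwise disjoint.
    """

    probes: pd.DataFrame
    blocks: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def planted_probe_ids(self, kind: str, tissue: str | None = None) -> pd.Index:
        sel = self.probes["kind"] == kind
        if tissue is not None:
            sel &= self.probes["target_tissue"] == tissue
        return pd.Index(self.probes.loc[sel, "probe_id"])

    def write(self, probes_path, blocks_path) -> None:
        self.probes.to_csv(probes_path, sep="\t", index=False)
        self.blocks.to_csv(blocks_path, sep="\t", index=False)


def default_planted(tissues=TISSUES, n_hypo_blocks: int = 34, n_gom_blocks: int = 33,
                    n_lom_blocks: int = 33, block_size: int = 5,
                    effect: float = 0.30, background: float = 0.5,
                    ) -> list[PlantedSignal]:
    """Planted-signal list for the default study conditions.

    Per tissue: hypomethylated blocks at background-effect flat across weeks,
    GOM blocks rising by ``effect`` from first to last week, LOM blocks
    falling by ``effect``.  Defaults give 100 blocks x 5 CpGs per tissue
    (2,000 planted CpGs over four tissues).
    """
    low = background - effect
    mid = background - effect / 2
    signals: list[PlantedSignal] = []
    for tissue in tissues:
        for _ in range(n_hypo_blocks):
            signals.append(PlantedSignal("tissue_hypo", tissue, block_size,
                                         (low, low, low), background))
        for _ in range(n_gom_blocks):
            signals.append(PlantedSignal("gom", tissue, block_size,
                                         (low, mid, background), background))
        for _ in range(n_lom_blocks):
            signals.append(PlantedSignal("lom", tissue, block_size,
                                         (background, mid, low), background))
    return signals


def default_config(seed: int = 0, **kwargs) -> SimulationConfig:
    """The default synthetic study: 20,000 CpGs, 2,000 planted, 4x3x3 design."""
    cfg = SimulationConfig(planted=default_planted(), seed=seed, **kwargs)
    cfg.validate()
    return cfg
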