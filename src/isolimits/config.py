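"""Configuration dataclasses, the dataset-emulation preset, and YAML I/O.

The default (``neural_emulation``) preset emulates the scale of a published
neural PacBio transcriptome: 7000 genes, 45% of them multi-isoform, roughly
13,000 transcripts in total, and ~14% of MIGs switching dominant isoform
between the two simulated cell types (neural-stem-cell-like vs
oligodendrocyte-like).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field, replace

import yaml

from .exceptions import ConfigurationError

__all__ = [
    "TranscriptomeConfig",
    "DominanceParams",
    "RunConfig",
    "neural_emulation",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class TranscriptomeConfig:
    """Parameters of the synthetic genome/transcriptome generator.

    ``isoform_geom_p`` parameterises the truncated-geometric count of *extra*
    isoforms per MIG (support 1..max_isoforms-1, P(k) ∝ (1-p)^(k-1)); the
    default is tuned so the expected transcript total matches the emulated
    dataset (~13,000 at 7000 genes / 45% MIGs, i.e. ~2.9 isoforms per MIG).
    """

    n_genes: int = 7000
    mig_fraction: float = 0.45
    isoform_geom_p: float = 0.525
    max_isoforms: int = 10
    exon_count_mean_extra: float = 4.0  # exons per gene = 2 + Poisson(this)
    exon_len_log_mean: float = math.log(180.0)
    exon_len_log_sd: float = 0.75
    min_exon_len: int = 30
    max_exon_len: int = 3000
    intron_len_log_mean: float = math.log(300.0)
    intron_len_log_sd: float = 0.8
    min_intron_len: int = 60
    max_intron_len: int = 5000
    event_probs: dict = field(
        default_factory=lambda: {
            "exon_skip": 0.30,
            "intron_retention": 0.15,
            "alt5ss": 0.125,
            "alt3ss": 0.125,
            "altTSS": 0.15,
            "altTTS": 0.15,
        }
    )
    min_utr: int = 20
    min_shift: int = 10
    intergene_gap: int = 500
    chrom_name: str = "chrS"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not 0.0 <= self.mig_fraction <= 1.0:
            raise ConfigurationError("mig_fraction must be in [0, 1]")
        if not 0.0 < self.isoform_geom_p < 1.0:
            raise ConfigurationError("isoform_geom_p must be in (0, 1)")
        if self.max_isoforms < 2:
            raise ConfigurationError("max_isoforms must be >= 2")
        if not self.event_probs or any(p < 0 for p in self.event_probs.values()):
            raise ConfigurationError("event_probs must be non-negative")
        if abs(sum(self.event_probs.values()) - 1.0) > 1e-6:
            raise ConfigurationError("event_probs must sum to 1")
        unknown = set(self.event_probs) - {
            "exon_skip", "intron_retention", "alt5ss", "alt3ss", "altTSS", "altTTS"
        }
        if unknown:
            raise ConfigurationError(f"unknown event types: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DominanceParams:
    """Expression model: gene abundance and within-gene dominance structure.

    Gene-level abundance is log-normal; the default log-sd puts ~10% of genes
    below one expected read at a one-million-read depth, emulating the long
    low-expression tail that drives drop-outs.  Within a MIG, isoform
    proportions are a symmetric Dirichlet draw whose largest share is assigned
    to the designated dominant isoform; ``switch_fraction`` of MIGs (sampled
    without replacement, count = round) have the dominant and one alternative
    isoform's proportions swapped in the second cell type.
    """

    gene_log_mean: float = 0.0
    gene_log_sd: float = 2.1
    dirichlet_alpha: float = 0.8
    switch_fraction: float = 0.14
    cell_types: tuple[str, str] = ("NSC", "oligodendrocyte")

    def validate(self) -> None:
        if not 0.0 <= self.switch_fraction <= 1.0:
            raise ConfigurationError("switch_fraction must be in [0, 1]")
        if self.dirichlet_alpha <= 0:
            raise ConfigurationError("dirichlet_alpha must be > 0")
        if self.gene_log_sd <= 0:
            raise ConfigurationError("gene_log_sd must be > 0")
        if len(self.cell_types) != 2 or self.cell_types[0] == self.cell_types[1]:
            raise ConfigurationError("cell_types must be two distinct labels")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    transcriptome: TranscriptomeConfig = field(default_factory=TranscriptomeConfig)
    expression: DominanceParams = field(default_factory=DominanceParams)
    windows: tuple[int, ...] = (100, 200, 300, 500, 1000)
    total_reads: int = 1_000_000
    cell_counts: tuple[int, ...] = (2, 6, 10, 16, 20)
    detection_threshold: float = 1.0
    downsample_mode: str = "multinomial"
    longread_replicates: int = 1
    fragment_mean: int = 350
    fragment_sd: int = 35

    def validate(self) -> None:
        self.transcriptome.validate()
        self.expression.validate()
        if self.total_reads < 1:
            raise ConfigurationError("total_reads must be >= 1")
        if any(w < 1 for w in self.windows):
            raise ConfigurationError("windows must be positive")
        if any(n < 2 or n % 2 for n in self.cell_counts):
            raise ConfigurationError("cell counts must be even and >= 2")
        if self.downsample_mode not in ("multinomial", "proportional"):
            raise ConfigurationError("downsample_mode must be multinomial|proportional")
        if self.detection_threshold < 0:
            raise ConfigurationError("detection_threshold must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def neural_emulation(**overrides) -> RunConfig:
    """The dataset-emulation preset (see module docstring)."""
    cfg = RunConfig()
    return replace(cfg, **overrides) if overrides else cfg


def _tupleize(cfg: RunConfig) -> RunConfig:
    return replace(
        cfg,
        windows=tuple(cfg.windows),
        cell_counts=tuple(cfg.cell_counts),
        expression=replace(cfg.expression, cell_types=tuple(cfg.expression.cell_types)),
    )


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; missing keys fall back to the preset."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        tx = TranscriptomeConfig(**raw.pop("transcriptome", {}))
        expr = DominanceParams(**raw.pop("expression", {}))
        cfg = RunConfig(transcriptome=tx, expression=expr, **raw)
        cfg = _tupleize(cfg)
        cfg.validate()
    except (TypeError, ConfigurationError) as err:
        raise ConfigurationError(f"invalid configuration {path}: {err}") from err
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
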