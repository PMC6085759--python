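"""Shared fixtures: a hand-built toy transcriptome with known structure and a
small generated transcriptome for property-style tests."""

from __future__ import annotations

import numpy as np
import pytest

from isolimits import (
    DominanceParams,
    Exon,
    Gene,
    Isoform,
    RunConfig,
    TranscriptomeConfig,
    Transcriptome,
    generate_expression,
    generate_transcriptome,
    neural_emulation,
)


def _rand_genome(length: int, seed: int = 0) -> bytes:
    rng = np.random.default_rng(seed)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, size=length)
    ].tobytes()


@pytest.fixture(scope="session")
def toy_tx() -> Transcriptome:
    """Two genes with fully known structure.

    GA (+ strand): reference I01 with exons [100,200), [300,400), [500,600)
    (transcript 300 nt); I02 skips the middle exon (200 nt); I03 trims 50 nt
    off the TSS (first exon [150,200)).
    GB (- strand): reference I01 with exons [700,800), [900,1000); I02 retains
    the intron (one exon [700,1000)).
    """
    ga_ref = Isoform(
        "GA.I01", "GA",
        (Exon("chrT", 100, 200, "+"), Exon("chrT", 300, 400, "+"),
         Exon("chrT", 500, 600, "+")),
    )
    ga_skip = Isoform(
        "GA.I02", "GA",
        (Exon("chrT", 100, 200, "+"), Exon("chrT", 500, 600, "+")),
        frozenset({"exon_skip"}),
    )
    ga_tss = Isoform(
        "GA.I03", "GA",
        (Exon("chrT", 150, 200, "+"), Exon("chrT", 300, 400, "+"),
         Exon("chrT", 500, 600, "+")),
        frozenset({"altTSS"}),
    )
    gb_ref = Isoform(
        "GB.I01", "GB",
        (Exon("chrT", 700, 800, "-"), Exon("chrT", 900, 1000, "-")),
    )
    gb_ir = Isoform(
        "GB.I02", "GB",
        (Exon("chrT", 700, 1000, "-"),),
        frozenset({"intron_retention"}),
    )
    return Transcriptome(
        (Gene("GA", (ga_ref, ga_skip, ga_tss)), Gene("GB", (gb_ref, gb_ir))),
        {"chrT": _rand_genome(1200, seed=3)},
        {"source": "toy"},
    )


@pytest.fixture(scope="session")
def small_cfg() -> RunConfig:
    return neural_emulation(
        transcriptome=TranscriptomeConfig(n_genes=60, mig_fraction=0.5),
        total_reads=30_000,
    )


@pytest.fixture(scope="session")
def small_tx(small_cfg) -> Transcriptome:
    return generate_transcriptome(small_cfg.transcriptome, seed=11)


@pytest.fixture(scope="session")
def small_profiles(small_tx, small_cfg):
    return generate_expression(small_tx, small_cfg.expression, seed=12)
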