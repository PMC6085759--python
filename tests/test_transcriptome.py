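"""Structural correctness of the event generator and transcriptome synthesis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isolimits import (
    Exon,
    Isoform,
    TranscriptomeConfig,
    derive_alternative_isoform,
    generate_transcriptome,
    validate_transcriptome,
)
from isolimits.exceptions import ConfigurationError, EventNotApplicable
from isolimits.transcriptome import AS_EVENTS


def _ref(n_exons: int, strand: str = "+", exon_len: int = 100, intron_len: int = 150):
    exons, pos = [], 1000
    for _ in range(n_exons):
        exons.append(Exon("chr1", pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    return Isoform("G.I01", "G", tuple(exons))


class TestDeriveEvents:
    def test_exon_skip_removes_one_internal_exon(self):
        ref = _ref(5)
        iso = derive_alternative_isoform(ref, "exon_skip", np.random.default_rng(0))
        assert len(iso.exons) == 4
        assert iso.exons[0] == ref.exons[0] and iso.exons[-1] == ref.exons[-1]
        missing = set(ref.exons) - set(iso.exons)
        assert len(missing) == 1 and missing.pop() in ref.exons[1:-1]

    def test_alt_tss_trims_first_exon_start_plus_strand(self):
        ref = _ref(3, exon_len=400)
        iso = derive_alternative_isoform(
            ref, "altTSS", np.random.default_rng(0), shift=200
        )
        assert iso.exons[0].start == ref.exons[0].start + 200
        assert iso.exons[1:] == ref.exons[1:]

    def test_exon_skip_not_applicable_for_two_exons(self):
        with pytest.raises(EventNotApplicable):
            derive_alternative_isoform(_ref(2), "exon_skip", np.random.default_rng(0))

    def test_unknown_event_is_config_error(self):
        with pytest.raises(ConfigurationError):
            derive_alternative_isoform(_ref(3), "mystery", np.random.default_rng(0))

    @pytest.mark.parametrize("strand", "+-")
    @pytest.mark.parametrize("event", AS_EVENTS)
    def test_derived_isoform_is_valid_and_distinct(self, event, strand):
        ref = _ref(4, strand=strand, exon_len=120)
        rng = np.random.default_rng(7)
        iso = derive_alternative_isoform(ref, event, rng)
        assert iso.event_labels == frozenset({event})
        assert iso.chain_key() != ref.chain_key()
        for a, b in zip(iso.exons, iso.exons[1:]):
            assert a.end <= b.start
        # shares genomic sequence with the reference
        assert any(
            max(a.start, b.start) < min(a.end, b.end)
            for a in iso.exons for b in ref.exons
        )

    @pytest.mark.parametrize("event", ["altTSS", "altTTS"])
    @pytest.mark.parametrize("strand", "+-")
    def test_terminal_trims_strictly_shorten_transcript(self, event, strand):
        ref = _ref(3, strand=strand)
        iso = derive_alternative_isoform(ref, event, np.random.default_rng(1))
        assert iso.length < ref.length
        assert len(iso.exons) == len(ref.exons)

    def test_exon_skip_and_intron_events_length_consistency(self):
        ref = _ref(4)
        skip = derive_alternative_isoform(ref, "exon_skip", np.random.default_rng(2))
        assert skip.length < ref.length
        assert skip.span[1] - skip.span[0] <= ref.span[1] - ref.span[0]
        ir = derive_alternative_isoform(
            ref, "intron_retention", np.random.default_rng(2)
        )
        assert ir.length > ref.length  # the intron is retained in the transcript
        assert ir.span == ref.span  # genomic span unchanged

    def test_alt_splice_sites_move_exactly_one_boundary(self):
        ref = _ref(3)
        for event in ("alt5ss", "alt3ss"):
            iso = derive_alternative_isoform(
                ref, event, np.random.default_rng(3), index=0, shift=25
            )
            diffs = [
                (a.start != b.start) + (a.end != b.end)
                for a, b in zip(ref.exons, iso.exons)
            ]
            assert sum(diffs) == 1


class TestGenerator:
    def test_mig_count_is_exact(self):
        cfg = TranscriptomeConfig(n_genes=41, mig_fraction=0.37)
        tx = generate_transcriptome(cfg, seed=5)
        assert tx.n_genes == 41
        assert len(tx.migs) == round(41 * 0.37)

    def test_single_gene_single_isoform(self):
        cfg = TranscriptomeConfig(n_genes=1, mig_fraction=0.0)
        tx = generate_transcriptome(cfg, seed=0)
        assert tx.n_genes == 1
        gene = tx.genes[0]
        assert not gene.is_mig and len(gene.isoforms) == 1

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_transcriptome(
                TranscriptomeConfig(n_genes=5, mig_fraction=1.5), seed=0
            )

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), mig=st.floats(0.0, 1.0))
    def test_every_generated_structure_validates(self, seed, mig):
        cfg = TranscriptomeConfig(n_genes=12, mig_fraction=mig)
        tx = generate_transcriptome(cfg, seed=seed)
        validate_transcriptome(tx)
        assert len(tx.migs) == round(12 * mig)

    def test_same_seed_reproduces_identical_structures(self, small_cfg):
        a = generate_transcriptome(small_cfg.transcriptome, seed=11)
        b = generate_transcriptome(small_cfg.transcriptome, seed=11)
        assert [i.chain_key() for i in a.isoforms()] == [
            i.chain_key() for i in b.isoforms()
        ]
        assert a.genome == b.genome
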