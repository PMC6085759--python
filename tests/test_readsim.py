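"""Read simulation and the splice-aware compatibility oracle.

The oracle is cross-checked against an independent formulation: a read is
compatible with a candidate iff its 5'→3' sequence of genomic positions is a
contiguous subsequence of the candidate's.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from isolimits import (
    Exon,
    Gene,
    Isoform,
    SimulatedRead,
    Transcriptome,
    build_equivalence_classes,
    compatible,
    expected_counts,
    simulate_equivalence_classes,
    simulate_reads,
    smart,
    umi3,
)
from isolimits.readsim import _start_masks, projection_index


# -- independent oracle ------------------------------------------------------

def _genomic_positions(iso: Isoform) -> list[int]:
    pos: list[int] = []
    for e in iso.exons:
        pos.extend(range(e.start, e.end))
    return pos[::-1] if iso.strand == "-" else pos


def _naive_compatible(read: SimulatedRead, origin: Isoform, cand: Isoform) -> bool:
    po, pc = _genomic_positions(origin), _genomic_positions(cand)
    for a, b in read.mates:
        seg = po[a:b]
        n = len(seg)
        if not any(pc[u:u + n] == seg for u in range(len(pc) - n + 1)):
            return False
    return True


# -- depth allocation --------------------------------------------------------

class TestExpectedCounts:
    def test_counts_conserve_total(self, small_profiles):
        rng = np.random.default_rng(0)
        counts = expected_counts(small_profiles[0], 1234, rng)
        assert counts.sum() == 1234
        assert (counts >= 0).all()

    def test_single_isoform_gets_everything(self, small_profiles):
        profile = small_profiles[0]
        one = profile.__class__(
            "x", (profile.isoform_ids[0],), (profile.gene_ids[0],), np.array([1e6])
        )
        assert expected_counts(one, 10**6, np.random.default_rng(0))[0] == 10**6

    def test_multinomial_mean_matches_binomial_expectation(self):
        """Monte-Carlo check of E[count] = tpm * total / 1e6 within 3 SE."""
        from isolimits.expression import ExpressionProfile

        p = ExpressionProfile("x", ("a", "b"), ("g", "g"), np.array([3e5, 7e5]))
        rng = np.random.default_rng(42)
        total, n_rep = 50, 1000
        draws = np.array([expected_counts(p, total, rng) for _ in range(n_rep)])
        for j, prob in enumerate((0.3, 0.7)):
            mean = draws[:, j].mean()
            se = np.sqrt(total * prob * (1 - prob) / n_rep)
            assert abs(mean - total * prob) < 3 * se


# -- read placement ----------------------------------------------------------

class TestSimulateReads:
    def test_uniform_start_distribution(self):
        proto = umi3(100)
        rng = np.random.default_rng(5)
        reads = simulate_reads({"i": (1400, 1500)}, {"i": 10_000}, proto, rng)
        starts = np.array([r.mates[0][0] for r in reads])
        assert starts.min() >= 1400 and starts.max() <= 1475
        obs = np.bincount(starts - 1400, minlength=76)
        assert stats.chisquare(obs).pvalue > 0.01

    def test_template_shorter_than_read_is_clipped(self):
        proto = umi3(100)  # 25 nt reads
        reads = simulate_reads(
            {"i": (0, 20)}, {"i": 5}, proto, np.random.default_rng(0)
        )
        assert all(r.mates == ((0, 20),) for r in reads)

    def test_paired_mates_sit_at_fragment_ends(self):
        proto = smart()
        reads = simulate_reads(
            {"i": (0, 1500)}, {"i": 200}, proto, np.random.default_rng(1)
        )
        for r in reads:
            (a1, b1), (a2, b2) = r.mates
            assert b1 - a1 == 250 and b2 - a2 == 250
            assert a1 <= a2 and b2 - a1 <= 1500
            assert b2 - a1 >= 250  # fragment at least one read long


# -- compatibility -----------------------------------------------------------

class TestCompatibility:
    def test_junction_read_incompatible_with_skipping_isoform(self, toy_tx):
        read = SimulatedRead("r", "GA.I01", ((90, 110),))  # spans exon1-exon2 junction
        assert compatible(read, toy_tx.isoform("GA.I01"), toy_tx)
        assert not compatible(read, toy_tx.isoform("GA.I02"), toy_tx)

    def test_shared_exon_read_compatible_with_both(self, toy_tx):
        read = SimulatedRead("r", "GA.I01", ((60, 85),))  # inside exon 1
        assert compatible(read, toy_tx.isoform("GA.I01"), toy_tx)
        assert compatible(read, toy_tx.isoform("GA.I02"), toy_tx)

    def test_read_in_tss_trimmed_region_incompatible_with_short_isoform(self, toy_tx):
        read = SimulatedRead("r", "GA.I01", ((10, 35),))  # genomic [110,135)
        assert not compatible(read, toy_tx.isoform("GA.I03"), toy_tx)

    def test_mates_may_straddle_candidate_internal_gap(self, toy_tx):
        read = SimulatedRead("r", "GA.I01", ((10, 35), (210, 235)))
        assert compatible(read, toy_tx.isoform("GA.I02"), toy_tx)

    def test_projection_round_trip_is_identity(self, toy_tx):
        for iso in toy_tx.isoforms():
            f = projection_index(iso, iso)
            np.testing.assert_array_equal(f, np.arange(iso.length))

    @pytest.mark.parametrize("gene_id", ["GA", "GB"])
    def test_oracle_matches_naive_enumeration(self, toy_tx, gene_id):
        """Exhaustively compare package vs independent oracle on every
        (origin, candidate, start) triple for 25 nt reads, and against the
        vectorised start-mask path."""
        gene = next(g for g in toy_tx.genes if g.gene_id == gene_id)
        R = 25
        masks = _start_masks(gene, R)
        for origin in gene.isoforms:
            mat = masks[origin.isoform_id]
            for ci, cand in enumerate(gene.isoforms):
                for s in range(origin.length - R + 1):
                    read = SimulatedRead("r", origin.isoform_id, ((s, s + R),))
                    got = compatible(read, cand, toy_tx)
                    assert got == _naive_compatible(read, origin, cand)
                    assert got == bool(mat[ci, s])


# -- equivalence classes -----------------------------------------------------

class TestEquivalenceClasses:
    def test_reads_always_compatible_with_origin_and_counts_conserve(
        self, small_tx
    ):
        proto = umi3(100)
        templates = {
            i.isoform_id: (max(0, i.length - 100), i.length)
            for i in small_tx.isoforms()
        }
        counts = {i: 7 for i in list(templates)[:40]}
        reads = simulate_reads(templates, counts, proto, np.random.default_rng(3))
        table = build_equivalence_classes(reads, small_tx)
        assert table.total_reads == sum(counts.values())
        for members in table.classes:
            assert list(members) == sorted(members)

    def test_identical_isoforms_collapse_into_one_class(self):
        ex = Exon("c", 0, 300, "+")
        a = Isoform("G.A", "G", (ex,))
        b = Isoform("G.B", "G", (ex,), frozenset({"altTSS"}))
        tx = Transcriptome((Gene("G", (a, b)),), {"c": b"A" * 300}, {})
        reads = simulate_reads(
            {"G.A": (0, 300)}, {"G.A": 50}, umi3(100), np.random.default_rng(0)
        )
        table = build_equivalence_classes(reads, tx)
        assert table.classes == {("G.A", "G.B"): 50}

    @pytest.mark.parametrize("proto", [umi3(100), umi3(300), smart()],
                             ids=["umi3_100", "umi3_300", "smart"])
    def test_fast_path_conserves_reads_and_matches_per_read_semantics(
        self, small_tx, proto
    ):
        ids = small_tx.isoform_ids()
        rng = np.random.default_rng(9)
        counts = dict(zip(ids, rng.integers(0, 30, size=len(ids)).tolist()))
        tables = simulate_equivalence_classes(
            small_tx, counts, proto, np.random.default_rng(10)
        )
        total = sum(t.total_reads for t in tables.values())
        assert total == sum(counts.values())
        # per-gene class members all belong to that gene and include >= 1 read
        for gid, table in tables.items():
            for members, count in table.classes.items():
                assert count >= 1
                assert all(small_tx.gene_of(m).gene_id == gid for m in members)


def test_debug_exports_round_readably(toy_tx, tmp_path):
    from isolimits.readsim import write_classes_tsv, write_reads_tsv
    import pandas as pd

    proto = umi3(100)
    reads = simulate_reads(
        {"GA.I01": (200, 300)}, {"GA.I01": 5}, proto, np.random.default_rng(0)
    )
    rp = tmp_path / "reads.tsv"
    write_reads_tsv(reads, rp)
    df = pd.read_csv(rp, sep="\t")
    assert len(df) == 5 and (df["end"] - df["start"] == 25).all()

    table = build_equivalence_classes(reads, toy_tx)
    cp = tmp_path / "classes.tsv"
    write_classes_tsv(table, cp)
    dfc = pd.read_csv(cp, sep="\t")
    assert dfc["count"].sum() == 5
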