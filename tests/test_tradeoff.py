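"""Long-read downsampling: allocation, detection, switches, flow-cells."""

from __future__ import annotations

import numpy as np
import pytest

from isolimits import (
    count_switches,
    dominant_isoform,
    downsample_cells,
    flowcells_needed,
    migs_detected,
    run_tradeoff,
)
from isolimits.exceptions import ConfigurationError
from isolimits.tradeoff import CellCounts, reference_migs, switching_genes


class TestDownsampling:
    @pytest.mark.parametrize("n_cells,per_cell", [(2, 500_000), (20, 50_000)])
    def test_equal_split(self, small_profiles, n_cells, per_cell):
        cells = downsample_cells(
            small_profiles, n_cells, 1_000_000, np.random.default_rng(0)
        )
        assert len(cells) == n_cells
        assert all(c.counts.sum() == per_cell for c in cells)
        types = [c.cell_type for c in cells]
        assert types.count(small_profiles[0].cell_type) == n_cells // 2

    def test_read_conservation_with_remainder(self, small_profiles):
        cells = downsample_cells(
            small_profiles, 6, 1_000_003, np.random.default_rng(1)
        )
        totals = [int(c.counts.sum()) for c in cells]
        assert sum(totals) == 1_000_003
        assert max(totals) - min(totals) <= 1  # remainder to the first cells

    def test_odd_cell_count_rejected(self, small_profiles):
        with pytest.raises(ConfigurationError):
            downsample_cells(small_profiles, 5, 1000, np.random.default_rng(0))

    def test_proportional_mode_is_deterministic(self, small_profiles):
        a = downsample_cells(small_profiles, 2, 10_000,
                             np.random.default_rng(0), mode="proportional")
        b = downsample_cells(small_profiles, 2, 10_000,
                             np.random.default_rng(99), mode="proportional")
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.counts, cb.counts)

    def test_rare_isoform_detection_matches_binomial_tail(self, small_profiles):
        """An isoform at ~1 TPM in a 50k-read cell has detection probability
        1-(1-1e-6)^50000 ≈ 4.9%; the observed per-cell detection rate over
        replicates must agree within 3 SE."""
        profile = small_profiles[0]
        target = int(np.argmin(np.abs(profile.tpm - 1.0)))
        tpm = profile.tpm[target]
        p_read = tpm / 1e6
        n_reads = 50_000
        p_detect = 1.0 - (1.0 - p_read) ** n_reads
        rng = np.random.default_rng(7)
        n_cells, hits = 0, 0
        for _ in range(100):
            cells = downsample_cells(profile_pair(profile), 20, 1_000_000, rng)
            for c in cells:
                n_cells += 1
                hits += int(c.counts[target] >= 1)
        rate = hits / n_cells
        se = np.sqrt(p_detect * (1 - p_detect) / n_cells)
        assert abs(rate - p_detect) < 3 * se


def profile_pair(profile):
    return (profile, profile)


class TestDetectionOps:
    def _cell(self, tx, overrides):
        ids = tuple(tx.isoform_ids())
        counts = np.zeros(len(ids), dtype=np.int64)
        for iso, n in overrides.items():
            counts[ids.index(iso)] = n
        return CellCounts("c0", "A", ids, counts)

    def test_mig_needs_two_detected_isoforms(self, toy_tx):
        assert migs_detected(self._cell(toy_tx, {"GA.I01": 3, "GA.I02": 1}), toy_tx) == 1
        assert migs_detected(self._cell(toy_tx, {"GA.I01": 3}), toy_tx) == 0

    def test_dominant_argmax_and_tie_break(self):
        assert dominant_isoform({"i1": 10, "i2": 3}) == "i1"
        assert dominant_isoform({"i2": 5, "i1": 5}) == "i1"  # lexicographic tie
        assert dominant_isoform({"i1": 0, "i2": 0}) is None

    def test_count_switches_examples(self, toy_tx):
        same = self._cell(toy_tx, {"GA.I01": 5, "GB.I01": 2})
        mean, pairs = count_switches([same], [same], toy_tx)
        assert mean == 0.0
        flipped = self._cell(toy_tx, {"GA.I02": 5, "GB.I01": 2})
        mean, pairs = count_switches([same], [flipped], toy_tx)
        assert mean == 1.0 and pairs.shape == (1, 1)

    def test_undefined_dominance_is_skipped(self, toy_tx):
        a = self._cell(toy_tx, {"GA.I01": 5})
        b = self._cell(toy_tx, {"GB.I01": 2})  # GA all-zero: no switch scored
        mean, _ = count_switches([a], [b], toy_tx)
        assert mean == 0.0

    def test_vectorised_dominants_agree_with_scalar_op(self, small_tx, small_profiles):
        cells = downsample_cells(
            small_profiles, 4, 20_000, np.random.default_rng(3)
        )
        from isolimits.tradeoff import _dominant_matrix, _mig_layout

        idx, valid, gene_ids = _mig_layout(small_tx)
        dom = _dominant_matrix(cells, idx, valid)
        all_ids = small_tx.isoform_ids()
        for ci, cell in enumerate(cells):
            for mi, gid in enumerate(gene_ids):
                expected = dominant_isoform(cell.gene_counts(small_tx, gid))
                got = None if dom[ci, mi] < 0 else all_ids[dom[ci, mi]]
                assert got == expected


class TestFlowcells:
    @pytest.mark.parametrize("n,cap,expected", [(100, 4, 25), (4, 4, 1), (5, 4, 2)])
    def test_ceiling(self, n, cap, expected):
        assert flowcells_needed(n, cap) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            flowcells_needed(0, 4)


class TestTradeoffRun:
    def test_report_invariants(self, small_tx, small_profiles):
        rep = run_tradeoff(
            small_tx, small_profiles, (2, 6, 10), 30_000,
            np.random.default_rng(0),
        )
        t = rep.table
        assert list(t["n_cells"]) == [2, 6, 10]
        assert rep.ref_switches == len(switching_genes(small_profiles, small_tx))
        assert rep.ref_migs == reference_migs(small_profiles, small_tx)
        assert (t["mean_switches"] <= rep.ref_switches).all()
        assert (t["mean_migs_per_cell"] <= rep.ref_migs).all()
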