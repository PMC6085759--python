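"""Long-read depth-per-cell vs cell-number trade-off.

A fixed budget of full-length long reads (default one million, emulating one
flow-cell run) is split evenly over an increasing number of cells, half per
cell type.  One long read = one full-length transcript, so per-cell counts are
directly isoform counts — no EM step.  Measured per scenario: the mean number
of MIGs with >= 2 detected isoforms per cell, and the mean number of
dominant-isoform switches over all (cell-type-A, cell-type-B) cell pairs,
against the noiseless references from the undownsampled profiles.  Long reads
are simulated error-free and full-length, so results are upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .expression import ExpressionProfile
from .transcriptome import Transcriptome

__all__ = [
    "CellCounts",
    "downsample_cells",
    "migs_detected",
    "dominant_isoform",
    "count_switches",
    "reference_switches",
    "reference_migs",
    "flowcells_needed",
    "run_tradeoff",
    "TradeoffReport",
]


@dataclass(frozen=True)
class CellCounts:
    """Per-cell isoform read counts, aligned with the transcriptome order."""

    cell_id: str
    cell_type: str
    isoform_ids: tuple[str, ...]
    counts: np.ndarray

    def gene_counts(self, tx: Transcriptome, gene_id: str) -> dict[str, int]:
        gene = next(g for g in tx.genes if g.gene_id == gene_id)
        lookup = dict(zip(self.isoform_ids, self.counts.tolist()))
        return {i.isoform_id: int(lookup[i.isoform_id]) for i in gene.isoforms}


def _allocate(total_reads: int, n_cells: int) -> list[int]:
    base, rem = divmod(int(total_reads), int(n_cells))
    return [base + 1 if i < rem else base for i in range(n_cells)]


def _proportional_counts(p: np.ndarray, n: int) -> np.ndarray:
    """Deterministic largest-remainder rounding of n*p to integers summing n."""
    raw = p * n
    out = np.floor(raw).astype(np.int64)
    short = n - int(out.sum())
    if short > 0:
        order = np.argsort(-(raw - out))
        out[order[:short]] += 1
    return out


def downsample_cells(
    profiles: tuple[ExpressionProfile, ExpressionProfile],
    n_cells: int,
    total_reads: int,
    rng: np.random.Generator,
    mode: str = "multinomial",
) -> list[CellCounts]:
    """Split ``total_reads`` long reads evenly over ``n_cells`` cells.

    ``n_cells`` must be even (half per cell type); the integer-division
    remainder goes to the first cells.  Each cell's reads are drawn
    multinomially from its cell type's TPM/1e6 probabilities (or allocated by
    deterministic proportional rounding with ``mode="proportional"``).
    """
    if n_cells < 2 or n_cells % 2:
        raise ConfigurationError("n_cells must be even and >= 2")
    if total_reads < n_cells:
        raise ConfigurationError("total_reads must be >= n_cells")
    if mode not in ("multinomial", "proportional"):
        raise ConfigurationError(f"unknown downsample mode {mode!r}")
    per_cell = _allocate(total_reads, n_cells)
    half = n_cells // 2
    cells = []
    for i in range(n_cells):
        profile = profiles[0] if i < half else profiles[1]
        p = profile.tpm / profile.tpm.sum()
        if mode == "multinomial":
            counts = rng.multinomial(per_cell[i], p)
        else:
            counts = _proportional_counts(p, per_cell[i])
        cells.append(
            CellCounts(
                cell_id=f"{profile.cell_type}_{i}",
                cell_type=profile.cell_type,
                isoform_ids=profile.isoform_ids,
                counts=counts,
            )
        )
    return cells


def migs_detected(
    cell: CellCounts, tx: Transcriptome, threshold: int = 1
) -> int:
    """Number of genes with >= 2 isoforms at >= ``threshold`` reads in the cell."""
    lookup = dict(zip(cell.isoform_ids, cell.counts.tolist()))
    n = 0
    for gene in tx.migs:
        hits = sum(lookup[i.isoform_id] >= threshold for i in gene.isoforms)
        if hits >= 2:
            n += 1
    return n


def dominant_isoform(gene_counts: Mapping[str, float]) -> str | None:
    """Argmax-count isoform id; ties break to the lexicographically smallest.

    Returns None when every count is zero (dominance undefined; the gene is
    skipped in switch counting).
    """
    best = max(sorted(gene_counts), key=lambda i: gene_counts[i])
    return best if gene_counts[best] > 0 else None


def _mig_layout(tx: Transcriptome) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Padded global-isoform-index matrix (n_mig x kmax) and validity mask."""
    order = {iso_id: k for k, iso_id in enumerate(tx.isoform_ids())}
    migs = tx.migs
    kmax = max((len(g.isoforms) for g in migs), default=0)
    idx = np.zeros((len(migs), kmax), dtype=np.int64)
    valid = np.zeros((len(migs), kmax), dtype=bool)
    for r, gene in enumerate(migs):
        for c, iso in enumerate(gene.isoforms):  # id-sorted within gene
            idx[r, c] = order[iso.isoform_id]
            valid[r, c] = True
    return idx, valid, [g.gene_id for g in migs]


def _dominant_matrix(
    cells: Sequence[CellCounts], idx: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Per cell x MIG: global index of the dominant isoform, or -1 if undefined.

    Columns are id-sorted within each gene, so argmax's first-maximum rule
    implements the lexicographic tie-break.
    """
    counts = np.stack([c.counts for c in cells])  # cells x isoforms
    vals = counts[:, idx].astype(np.int64)  # cells x migs x kmax
    vals[:, ~valid] = -1
    rel = np.argmax(vals, axis=2)
    dom = np.take_along_axis(idx[None, :, :].repeat(len(cells), 0), rel[:, :, None], 2)
    dom = dom[:, :, 0]
    defined = np.max(vals, axis=2) > 0
    return np.where(defined, dom, -1)


def count_switches(
    cells_a: Sequence[CellCounts],
    cells_b: Sequence[CellCounts],
    tx: Transcriptome,
    restrict_genes: set[str] | None = None,
) -> tuple[float, np.ndarray]:
    """Mean dominant-isoform switch count over all (cell A, cell B) pairs.

    A switch is a MIG whose dominant isoform is defined (>= 1 read) in both
    cells and differs in identity.  With ``restrict_genes`` the count is
    limited to those MIGs (the trade-off report restricts to the MIGs that
    truly switch between the noiseless profiles, so that sampling noise in
    weakly dominant genes is not scored as a detected switch and detected
    counts stay below the reference).  Returns the mean and the per-pair
    matrix.
    """
    if not cells_a or not cells_b:
        raise ConfigurationError("both cell groups must be non-empty")
    idx, valid, gene_ids = _mig_layout(tx)
    da = _dominant_matrix(cells_a, idx, valid)  # nA x n_mig
    db = _dominant_matrix(cells_b, idx, valid)
    diff = (da[:, None, :] != db[None, :, :]) & (da[:, None, :] >= 0) & (db[None, :, :] >= 0)
    if restrict_genes is not None:
        keep = np.array([g in restrict_genes for g in gene_ids], dtype=bool)
        diff = diff[:, :, keep]
    per_pair = diff.sum(axis=2)
    return float(per_pair.mean()), per_pair


def switching_genes(
    profiles: tuple[ExpressionProfile, ExpressionProfile], tx: Transcriptome
) -> set[str]:
    """MIG ids whose dominant isoform differs between the noiseless profiles."""
    a, b = profiles
    by_gene: dict[str, list[int]] = {}
    for k, gid in enumerate(a.gene_ids):
        by_gene.setdefault(gid, []).append(k)
    out: set[str] = set()
    for gene in tx.migs:
        ks = by_gene[gene.gene_id]
        ids = [a.isoform_ids[k] for k in ks]
        dom_a = dominant_isoform(dict(zip(ids, a.tpm[ks])))
        dom_b = dominant_isoform(dict(zip(ids, b.tpm[ks])))
        if dom_a is not None and dom_b is not None and dom_a != dom_b:
            out.add(gene.gene_id)
    return out


def reference_switches(
    profiles: tuple[ExpressionProfile, ExpressionProfile], tx: Transcriptome
) -> int:
    """Number of MIGs whose dominant isoform differs between the noiseless
    profiles (the dashed reference line of the switch-detection curve)."""
    return len(switching_genes(profiles, tx))


def reference_migs(
    profiles: tuple[ExpressionProfile, ExpressionProfile], tx: Transcriptome
) -> int:
    """MIGs with >= 2 isoforms expressed (TPM > 0) in the first profile —
    the upper bound (dashed reference line) for per-cell MIG detection."""
    a = profiles[0]
    by_gene: dict[str, int] = {}
    for gid, t in zip(a.gene_ids, a.tpm):
        if t > 0:
            by_gene[gid] = by_gene.get(gid, 0) + 1
    mig_ids = {g.gene_id for g in tx.migs}
    return sum(1 for gid, k in by_gene.items() if gid in mig_ids and k >= 2)


def flowcells_needed(n_cells: int, cells_per_flowcell: int = 4) -> int:
    """Flow-cells needed to sequence ``n_cells`` at the instrument's capacity."""
    if n_cells < 1 or cells_per_flowcell < 1:
        raise ConfigurationError("inputs must be >= 1")
    return ceil(n_cells / cells_per_flowcell)


@dataclass
class TradeoffReport:
    """Per-scenario detection curves plus the noiseless references."""

    table: pd.DataFrame  # n_cells, mean_migs_per_cell, mean_switches, ...
    ref_migs: int
    ref_switches: int


def run_tradeoff(
    tx: Transcriptome,
    profiles: tuple[ExpressionProfile, ExpressionProfile],
    cell_counts: Sequence[int],
    total_reads: int,
    rng: np.random.Generator,
    mode: str = "multinomial",
    threshold: int = 1,
) -> TradeoffReport:
    """Run every downsampling scenario once and assemble the report table."""
    idx, valid, _ = _mig_layout(tx)
    ref_m = reference_migs(profiles, tx)
    true_switchers = switching_genes(profiles, tx)
    ref_s = len(true_switchers)
    rows = []
    for n_cells in cell_counts:
        cells = downsample_cells(profiles, n_cells, total_reads, rng, mode=mode)
        half = n_cells // 2
        counts = np.stack([c.counts for c in cells])
        vals = counts[:, idx]
        vals[:, ~valid] = 0
        mig_per_cell = ((vals >= threshold).sum(axis=2) >= 2).sum(axis=1)
        mean_sw, _ = count_switches(
            cells[:half], cells[half:], tx, restrict_genes=true_switchers
        )
        rows.append(
            {
                "n_cells": n_cells,
                "reads_per_cell": total_reads // n_cells,
                "mean_migs_per_cell": float(mig_per_cell.mean()),
                "mean_switches": mean_sw,
                "flowcells": flowcells_needed(n_cells),
            }
        )
    return TradeoffReport(pd.DataFrame(rows), ref_m, ref_s)
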