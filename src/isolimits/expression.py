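"""Two-cell-type expression profiles with dominant-isoform structure.

Each gene's abundance is drawn once and shared by both cell types (gene-level
differential expression is out of scope); within each MIG one isoform is
dominant.  A configured fraction of MIGs swap the dominant and one alternative
isoform's proportions between the two cell types, producing isoform switches
while leaving gene-level output unchanged.  Profiles are normalised to
1e6 TPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DominanceParams
from .transcriptome import Transcriptome

__all__ = ["ExpressionProfile", "generate_expression", "write_expression",
           "read_expression"]

TPM_TOTAL = 1_000_000.0


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-isoform abundance (TPM) for one cell type.

    ``tpm`` is aligned with ``isoform_ids`` (transcriptome order: grouped by
    gene, id-sorted within gene).
    """

    cell_type: str
    isoform_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    tpm: np.ndarray

    def __post_init__(self) -> None:
        if len(self.isoform_ids) != len(self.tpm):
            raise ValueError("tpm and isoform_ids length mismatch")

    def tpm_of(self, isoform_id: str) -> float:
        try:
            idx = self._index[isoform_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {i: k for k, i in enumerate(self.isoform_ids)}
            )
            idx = self._index[isoform_id]
        return float(self.tpm[idx])

    def as_series(self) -> pd.Series:
        return pd.Series(self.tpm, index=list(self.isoform_ids), name=self.cell_type)


def _dirichlet_with_dominant(
    rng: np.random.Generator, k: int, alpha: float, dominant: int
) -> np.ndarray:
    """Symmetric Dirichlet shares with the strictly-largest share at ``dominant``."""
    while True:
        shares = rng.dirichlet(np.full(k, alpha))
        order = np.argsort(shares)
        if shares[order[-1]] > shares[order[-2]]:  # strict dominance (ties redrawn)
            break
    top = int(np.argmax(shares))
    shares[top], shares[dominant] = shares[dominant], shares[top]
    return shares


def generate_expression(
    tx: Transcriptome, params: DominanceParams, seed: int
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Generate the two cell-type profiles over ``tx``.

    Exactly ``round(n_MIG * switch_fraction)`` MIGs (sampled without
    replacement) differ in dominant-isoform identity between the two profiles.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    iso_ids: list[str] = []
    gene_ids: list[str] = []
    weights_a: list[np.ndarray] = []

    migs = [g for g in tx.genes if g.is_mig]
    n_switch = round(len(migs) * params.switch_fraction)
    switch_set = set(
        rng.choice(len(migs), size=n_switch, replace=False).tolist()
    ) if migs else set()

    mig_no = 0
    switch_edits: list[tuple[int, int, int]] = []  # (offset, dominant_idx, alt_idx)
    offset = 0
    for gene in tx.genes:
        k = len(gene.isoforms)
        gene_w = float(rng.lognormal(params.gene_log_mean, params.gene_log_sd))
        if k == 1:
            shares = np.ones(1)
        else:
            dominant = int(rng.integers(0, k))
            shares = _dirichlet_with_dominant(rng, k, params.dirichlet_alpha, dominant)
            if mig_no in switch_set:
                alts = [i for i in range(k) if i != dominant]
                alt = alts[int(rng.integers(0, len(alts)))]
                switch_edits.append((offset, dominant, alt))
            mig_no += 1
        iso_ids.extend(i.isoform_id for i in gene.isoforms)
        gene_ids.extend([gene.gene_id] * k)
        weights_a.append(gene_w * shares)
        offset += k

    wa = np.concatenate(weights_a) if weights_a else np.zeros(0)
    wb = wa.copy()
    for off, dom, alt in switch_edits:
        wb[off + dom], wb[off + alt] = wb[off + alt], wb[off + dom]

    norm = TPM_TOTAL / wa.sum()  # per-gene sums are swap-invariant: same norm
    a, b = params.cell_types
    return (
        ExpressionProfile(a, tuple(iso_ids), tuple(gene_ids), wa * norm),
        ExpressionProfile(b, tuple(iso_ids), tuple(gene_ids), wb * norm),
    )


def write_expression(
    profiles: tuple[ExpressionProfile, ExpressionProfile], path
) -> None:
    """TSV with columns isoform_id, gene_id, tpm_<A>, tpm_<B>."""
    a, b = profiles
    if a.isoform_ids != b.isoform_ids:
        raise ValueError("profiles must share the same isoform universe")
    df = pd.DataFrame(
        {
            "isoform_id": list(a.isoform_ids),
            "gene_id": list(a.gene_ids),
            f"tpm_{a.cell_type}": a.tpm,
            f"tpm_{b.cell_type}": b.tpm,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_expression(path) -> tuple[ExpressionProfile, ExpressionProfile]:
    df = pd.read_csv(path, sep="\t")
    tpm_cols = [c for c in df.columns if c.startswith("tpm_")]
    if len(tpm_cols) != 2:
        raise ValueError(f"expected two tpm_<celltype> columns, got {tpm_cols}")
    ids = tuple(df["isoform_id"])
    genes = tuple(df["gene_id"])
    return tuple(
        ExpressionProfile(c[len("tpm_"):], ids, genes, df[c].to_numpy(float))
        for c in tpm_cols
    )
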