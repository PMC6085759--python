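"""Per-MIG resolution percentages and the 4-bin summary.

Resolution of a MIG under a protocol is 100 x (isoforms detected) / (isoforms
in the reference set), capped at 100.  For UMI protocols the reference is the
isoform count detected in the matched Smart-seq run; for Smart-seq it is the
annotated isoform count.  MIGs with a zero reference (nothing Smart-detected)
have an undefined ratio: they are excluded from the percentages and reported
as a separate count.

Bins partition [0, 100] as [0,25], (25,50], (50,75], (75,100]; the top bin is
the "near fully resolved" (>75%) class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["BIN_LABELS", "ResolutionReport", "mig_resolution", "bin_resolution"]

BIN_LABELS = ("0-25", "25-50", "50-75", "75-100")
_BIN_UPPER = (25.0, 50.0, 75.0, 100.0)


@dataclass
class ResolutionReport:
    """Per-MIG resolution rows plus the zero-reference exclusion count."""

    rows: pd.DataFrame  # gene_id, n_reference, n_detected, pct_resolved
    n_excluded: int

    @property
    def mean_pct(self) -> float:
        return float(self.rows["pct_resolved"].mean())

    def bin_fractions(self) -> dict[str, float]:
        return bin_resolution(self.rows["pct_resolved"].to_numpy())


def mig_resolution(
    n_detected: Mapping[str, int], n_reference: Mapping[str, int]
) -> ResolutionReport:
    """Resolution percentages for the MIGs in ``n_reference``.

    ``n_detected`` maps gene_id → isoforms detected under the protocol;
    ``n_reference`` maps gene_id → reference isoform count.  Percentages above
    100 (possible when EM splits reads over more isoforms than the Smart
    reference detected) are capped at 100.
    """
    recs = []
    n_excluded = 0
    for gene_id, ref in n_reference.items():
        if ref <= 0:
            n_excluded += 1
            continue
        det = int(n_detected.get(gene_id, 0))
        pct = min(100.0, 100.0 * det / ref)
        recs.append((gene_id, int(ref), det, pct))
    rows = pd.DataFrame(
        recs, columns=["gene_id", "n_reference", "n_detected", "pct_resolved"]
    )
    return ResolutionReport(rows=rows, n_excluded=n_excluded)


def bin_resolution(pcts: Sequence[float]) -> dict[str, float]:
    """Fractions of MIGs per resolution bin; fractions sum to 1.

    Bin closure: [0,25], (25,50], (50,75], (75,100] — a MIG at exactly 75%
    falls in the 50-75 bin, so the top bin equals the strict >75% class.
    """
    p = np.asarray(pcts, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 100):
        raise ValueError("percentages must lie in [0, 100]")
    if p.size == 0:
        return {label: 0.0 for label in BIN_LABELS}
    idx = np.searchsorted(_BIN_UPPER, p, side="left")  # [0,25]->0, (25,50]->1...
    frac = np.bincount(idx, minlength=4) / p.size
    return dict(zip(BIN_LABELS, frac.tolist()))
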