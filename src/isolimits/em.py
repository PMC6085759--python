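"""Maximum-likelihood EM over equivalence classes, per gene.

The model: a read arises from isoform i with probability theta_i (read
fraction) and lands uniformly on one of eff_len_i fragment start positions.
A class with compatibility set c therefore has likelihood proportional to
sum_{i in c} theta_i / eff_len_i.  The E-step distributes each class count
over its members proportional to theta_i / eff_len_i; the M-step sets theta
proportional to the assigned counts.  Plain ML (no sparse prior), uniform
initialisation; boundary optima are reached through EM's deterministic
trajectory, making results reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .readsim import EquivalenceClassTable

__all__ = ["AbundanceEstimate", "em_quantify", "log_likelihood", "call_detected"]


@dataclass
class AbundanceEstimate:
    """Per-isoform estimates for one gene."""

    est_count: dict[str, float]
    theta: dict[str, float]
    eff_len: dict[str, int]
    n_iter: int
    converged: bool

    @property
    def total(self) -> float:
        return sum(self.est_count.values())


def log_likelihood(
    classes: Mapping[tuple[str, ...], int],
    theta: Mapping[str, float],
    eff_len: Mapping[str, int],
) -> float:
    """Class-multinomial log-likelihood of ``theta`` (up to the fixed
    combinatorial constant)."""
    ll = 0.0
    for members, count in classes.items():
        p = sum(theta[i] / eff_len[i] for i in members)
        if p <= 0.0:
            return -math.inf
        ll += count * math.log(p)
    return ll


def em_quantify(
    classes: EquivalenceClassTable | Mapping[tuple[str, ...], int],
    eff_len: Mapping[str, int],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AbundanceEstimate:
    """EM estimation of read fractions from one gene's equivalence classes.

    ``eff_len`` defines the isoform universe (isoforms absent from every
    class converge to zero).  Iterates until ``max |Δtheta| < tol`` or
    ``max_iter``.  An empty class table yields an all-zero, converged
    estimate.  Conservation (Σ est_count = Σ class counts) holds at every
    iteration by construction.
    """
    if isinstance(classes, EquivalenceClassTable):
        classes = classes.classes
    ids = sorted(eff_len)
    idx = {i: k for k, i in enumerate(ids)}
    n_iso = len(ids)
    ell = np.array([float(eff_len[i]) for i in ids])
    if np.any(ell < 1):
        raise ValueError("effective lengths must be >= 1")

    members = []
    counts = []
    for mem, cnt in classes.items():
        unknown = [i for i in mem if i not in idx]
        if unknown:
            raise KeyError(f"classes reference unknown isoforms {unknown}")
        members.append(np.array([idx[i] for i in mem], dtype=int))
        counts.append(float(cnt))
    total = float(sum(counts))

    if not members or total == 0.0:
        zero = {i: 0.0 for i in ids}
        return AbundanceEstimate(dict(zero), dict(zero),
                                 {i: int(eff_len[i]) for i in ids}, 0, True)

    # membership matrix (n_class x n_iso)
    M = np.zeros((len(members), n_iso), dtype=float)
    for ci, mem in enumerate(members):
        M[ci, mem] = 1.0
    n_c = np.array(counts)

    theta = np.full(n_iso, 1.0 / n_iso)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = theta / ell
        denom = M @ w  # class-level weight sums; >0 since theta>0 initially
        assigned = w * (M.T @ (n_c / denom))  # E-step counts per isoform
        new_theta = assigned / total  # M-step
        delta = np.max(np.abs(new_theta - theta))
        theta = new_theta
        if delta < tol:
            converged = True
            break

    est = theta * total
    return AbundanceEstimate(
        est_count={i: float(est[k]) for k, i in enumerate(ids)},
        theta={i: float(theta[k]) for k, i in enumerate(ids)},
        eff_len={i: int(eff_len[i]) for i in ids},
        n_iter=n_iter,
        converged=converged,
    )


def call_detected(estimate: AbundanceEstimate, threshold_reads: float = 1.0) -> set[str]:
    """Isoforms whose estimated read count reaches the threshold (inclusive)."""
    if threshold_reads > 0:
        return {i for i, c in estimate.est_count.items() if c >= threshold_reads}
    return {i for i, c in estimate.est_count.items() if c > 0}


def estimates_to_frame(estimates, tx) -> "pd.DataFrame":
    """Per-isoform estimate table (isoform_id, gene_id, est_count, theta)
    from a mapping gene_id → :class:`AbundanceEstimate`."""
    import pandas as pd

    rows = []
    for gene_id, est in estimates.items():
        for iso_id in sorted(est.est_count):
            rows.append(
                (iso_id, gene_id, est.est_count[iso_id], est.theta[iso_id])
            )
    return pd.DataFrame(rows, columns=["isoform_id", "gene_id", "est_count", "theta"])
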