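"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

import numpy as np


def grid_loglik(classes, eff_len, resolution=1e-3):
    """Maximum class log-likelihood over a simplex grid (independent oracle)."""
    ids = sorted(eff_len)
    ell = np.array([eff_len[i] for i in ids], dtype=float)
    members = [np.array([ids.index(m) for m in mem]) for mem in classes]
    counts = np.array([classes[mem] for mem in classes], dtype=float)
    steps = int(round(1.0 / resolution))
    best = -np.inf
    if len(ids) == 1:
        return float(counts.sum() * np.log(1.0 / ell[0]))
    if len(ids) == 2:
        t0 = np.arange(steps + 1) / steps
        thetas = np.stack([t0, 1.0 - t0], axis=1)
    elif len(ids) == 3:
        grids = []
        for i in range(steps + 1):
            j = np.arange(steps + 1 - i)
            grids.append(np.stack(
                [np.full(len(j), i / steps), j / steps, 1.0 - i / steps - j / steps],
                axis=1,
            ))
        thetas = np.concatenate(grids)
    else:
        raise ValueError("grid oracle supports <= 3 isoforms")
    w = thetas / ell  # (n_grid, n_iso)
    ll = np.zeros(len(thetas))
    for mem, cnt in zip(members, counts):
        p = w[:, mem].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll += cnt * np.log(p)
    return float(np.nanmax(ll))
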