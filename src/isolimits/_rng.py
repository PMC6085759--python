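"""Deterministic derivation of per-stage random substreams.

Every stage of a pipeline draws from its own ``numpy`` generator whose seed is
a stable hash of the root seed and a tuple of string labels (stage name,
protocol name, cell index, ...).  Adding a protocol or scenario therefore never
perturbs the random stream of any other stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "substream"]


def child_seed(root_seed: int, *labels: object) -> int:
    """Derive a deterministic 31-bit seed from a root seed and labels."""
    key = "/".join([str(int(root_seed))] + [str(x) for x in labels])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(root_seed: int, *labels: object) -> np.random.Generator:
    """A ``numpy`` generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(root_seed, *labels))
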