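"""Deterministic per-operation random substreams.

Every generator in the package derives its own independent stream from a
single user-supplied integer seed and a string label, so adding a new
generator (or calling one more than once) never perturbs the draws of any
other.  The label is folded into the stream with an FNV-1a hash rather than
Python's builtin ``hash``, which is salted per process.
"""

from __future__ import annotations

import numpy as np

_FNV_OFFSET = 2166136261
_FNV_PRIME = 16777619
_MASK32 = 0xFFFFFFFF


def _fnv1a(label: str) -> int:
    h = _FNV_OFFSET
    for byte in label.encode("utf-8"):
        h = ((h ^ byte) * _FNV_PRIME) & _MASK32
    return h


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return an RNG keyed by (seed, labels); identical inputs give an
    identical stream."""
    key = _fnv1a("/".join(str(x) for x in labels))
    return np.random.default_rng([int(seed) & _MASK32, key])
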