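"""Deterministic seed derivation.

All randomness in the package flows from one root seed. Each consumer
derives an independent stream from (root, labels...), so adding replicates
or reordering subcommands never perturbs earlier streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(root: int, *labels) -> int:
    """A stable 31-bit seed derived from a root seed and string labels."""
    key = [int(root) & 0x7FFFFFFF]
    key.extend(zlib.crc32(str(lab).encode()) & 0xFFFFFFFF for lab in labels)
    return int(np.random.SeedSequence(key).generate_state(1)[0] & 0x7FFFFFFF)


def derive_rng(root: int, *labels) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root, *labels))
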