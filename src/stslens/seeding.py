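"""Deterministic seed derivation.

One root integer seed drives every stage of the pipeline.  Stage and
item-level seeds are derived with a counter-based scheme built on
``numpy.random.SeedSequence``: each label (a stage name, a pair index, a
planting index, ...) is hashed into the entropy stream, so any module can
be re-run in isolation and still draw exactly the bits it would have
drawn inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np


def _label_entropy(label) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def seed_sequence(root_seed: int, *labels) -> np.random.SeedSequence:
    """SeedSequence for (root_seed, labels...); stable across runs."""
    entropy = [int(root_seed) & 0xFFFFFFFF] + [_label_entropy(l) for l in labels]
    return np.random.SeedSequence(entropy)


def rng_for(root_seed: int, *labels) -> np.random.Generator:
    """A fresh Generator keyed by the root seed and a label path."""
    return np.random.default_rng(seed_sequence(root_seed, *labels))


def child_seed(root_seed: int, *labels) -> int:
    """A derived integer seed below 2**31 for APIs that want an int."""
    return int(seed_sequence(root_seed, *labels).generate_state(1)[0] % (2**31))
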