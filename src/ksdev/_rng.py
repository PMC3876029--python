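"""Seed-splitting scheme shared by all generators.

All randomness flows from one top-level integer seed. Independent streams
for named sub-tasks are derived with ``numpy.random.SeedSequence`` spawned
keys so that adding a new consumer never perturbs existing ones: each
consumer asks for a stream by a stable string label, hashed to a child
spawn key.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, label: str) -> np.random.Generator:
    """A Generator unique to (seed, label), stable across runs."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
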