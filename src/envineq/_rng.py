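"""Deterministic random-stream derivation.

A single master seed drives every stochastic component.  Each component
derives its own independent stream from ``(master_seed, crc32(label))`` so
that adding, removing or reordering components never perturbs the draws of
the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]

_MASK = 0x7FFFFFFF  # keep derived integers below 2**31


def subseed(master_seed: int, label: str) -> int:
    """A stable 31-bit integer seed for the component named ``label``."""
    return (int(master_seed) ^ zlib.crc32(label.encode("utf8"))) & _MASK


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Independent generator for the component named ``label``."""
    ss = np.random.SeedSequence([int(master_seed) & _MASK, zlib.crc32(label.encode("utf8"))])
    return np.random.default_rng(ss)
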