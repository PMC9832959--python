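"""Seeded random-number substreams.

All randomness in the package flows from one top-level integer seed.  Each
component (layout, counts, images, qpcr, ...) derives its own independent
stream from ``(seed, crc32(name))`` so that, e.g., regenerating images does
not perturb the well-count stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent, reproducible generator for a named component.

    Parameters
    ----------
    seed
        Top-level run seed.
    name
        Component name, e.g. ``"layout"`` or ``"counts/P1/male"``.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
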