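"""Seed fan-out and small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_seed", "rng_for", "time_sort_key"]


def spawn_seed(master: int, *labels: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and a label path.

    The derivation is label-keyed, so toggling one analysis stage or
    re-ordering inputs never shifts another stage's random stream.
    """
    crcs = [zlib.crc32(str(lab).encode("utf-8")) for lab in labels]
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *crcs])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def rng_for(master: int, *labels: object) -> np.random.Generator:
    return np.random.default_rng(spawn_seed(master, *labels))


def time_sort_key(label: object):
    """Order time labels numerically when they parse as numbers, else lexically.

    Returns a tuple so numeric and non-numeric labels never compare directly.
    """
    s = str(label)
    try:
        return (0, float(s), "")
    except ValueError:
        return (1, 0.0, s)
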