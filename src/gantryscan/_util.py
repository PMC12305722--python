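"""Shared plumbing: error types and stable seed derivation."""

from __future__ import annotations

import hashlib


class GantryScanError(Exception):
    """Base class for all package errors."""


class ValidationError(GantryScanError):
    """A configuration or input value violates an invariant."""


def stable_seed(global_seed: int, *keys) -> int:
    """Derive a reproducible sub-seed from a global seed and a key tuple.

    The derivation is independent of visit order and of Python's per-process
    hash randomization, so any pose (or stage) gets the same stream no matter
    when it is rendered.  The result fits in a signed 32-bit integer.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(repr((int(global_seed),) + tuple(keys)).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


def pose_key(x: float, pitch: float, roll: float) -> tuple:
    """Lattice key for a pose, quantized so float noise cannot split cache
    entries for the same physical pose."""
    return (round(float(x), 6), round(float(pitch), 6), round(float(roll), 6))
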