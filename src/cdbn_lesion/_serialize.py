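"""Exact round-trip encoding of float arrays inside JSON containers.

Arrays are stored as base64 of their raw little-endian bytes plus dtype and
shape, so serialization never loses precision to decimal formatting.
"""

from __future__ import annotations

import base64

import numpy as np


def encode_array(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a)
    return {
        "dtype": a.dtype.str,
        "shape": list(a.shape),
        "data": base64.b64encode(a.tobytes()).decode("ascii"),
    }


def decode_array(d: dict) -> np.ndarray:
    raw = base64.b64decode(d["data"])
    return np.frombuffer(raw, dtype=np.dtype(d["dtype"])).reshape(d["shape"]).copy()
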