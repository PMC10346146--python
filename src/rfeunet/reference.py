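"""Naive per-element reference implementation of the RFE layer.

Used as an independent oracle in the test suite: everything is computed with
scalar index arithmetic and Python loops — no array slicing, reshaping or
vectorized algebra — so agreement with :func:`rfeunet.rfe.rfe_layer_forward`
checks the block/strip bookkeeping of the fast path, not a shared code path.
"""

from __future__ import annotations

import math

import numpy as np

from .rfe import RFEParams

_BLOCK_ORDER = (("A", 0, 0), ("B", 0, 1), ("C", 1, 0), ("D", 1, 1))


def _gelu_scalar(x: float) -> float:
    return 0.5 * x * (1.0 + math.erf(x / math.sqrt(2.0)))


def rfe_layer_reference(x: np.ndarray, params: RFEParams) -> np.ndarray:
    """Scalar-indexing forward pass of one RFE layer on a (C, H, W) array."""
    x = np.asarray(x, dtype=np.float64)
    n_ch, height, width = x.shape
    if height % 2 or width % 2:
        raise ValueError("reference layer needs even spatial dimensions")
    h, w = height // 2, width // 2
    np_params = params.to_numpy()
    n_el = h * w
    out = np.zeros_like(x)

    for bid, bi, bj in _BLOCK_ORDER:
        r0, c0 = bi * h, bj * w
        w_by_dir = {
            "row": np_params.correlation[(bid, "row")].tolist(),
            "col": np_params.correlation[(bid, "col")].tolist(),
        }
        w1, b1, w2, b2 = (a.tolist() for a in np_params.mlp[bid])
        hidden = len(b1)
        n_variants = h + w

        for ch in range(n_ch):
            agg = [0.0] * n_el
            for direction, count in (("row", h), ("col", w)):
                wmat = w_by_dir[direction]
                for k in range(count):
                    # assembly: base block row-major, then index-k strips of
                    # the remote blocks in A->B->C->D order (base omitted)
                    vec = []
                    for i in range(h):
                        for j in range(w):
                            vec.append(float(x[ch, r0 + i, c0 + j]))
                    for obid, oi, oj in _BLOCK_ORDER:
                        if obid == bid:
                            continue
                        if direction == "row":
                            for j in range(w):
                                vec.append(float(x[ch, oi * h + k, oj * w + j]))
                        else:
                            for i in range(h):
                                vec.append(float(x[ch, oi * h + i, oj * w + k]))
                    for e in range(n_el):
                        s = 0.0
                        for t in range(len(vec)):
                            s += vec[t] * wmat[t][e]
                        agg[e] += s
            for e in range(n_el):
                agg[e] /= n_variants
            hid = []
            for m in range(hidden):
                s = b1[m]
                for e in range(n_el):
                    s += agg[e] * w1[e][m]
                hid.append(_gelu_scalar(s))
            for e in range(n_el):
                s = b2[e]
                for m in range(hidden):
                    s += hid[m] * w2[m][e]
                i, j = e // w, e % w
                out[ch, r0 + i, c0 + j] = s + float(x[ch, r0 + i, c0 + j])
    return out
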