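"""Remote feature exploration (RFE): strip-assisted spatial mixing.

The layer partitions a feature map into the four spatial quadrants A, B, C,
D, extracts single-row / single-column strips from each quadrant, and lets
the strips of the three *remote* quadrants assist the regeneration of each
*base* quadrant: the base block and one index-matched strip per remote block
are flattened and pushed through a fully connected correlation map.  One
such variant exists per row index and per column index of the block
(2 + 2 = 4 variants for 2x2 blocks, h + w in general).  The variants are
averaged, passed through a small MLP, and added residually to the base
block, after which the four transformed quadrants are reassembled into a
feature map of the original size.

All functions below are written against a minimal array protocol (shape,
slicing, ``reshape``, ``@``, ``+``) and therefore run both on plain NumPy
arrays and on autodiff :class:`~rfeunet.nn.Tensor` objects; the trainable
:class:`RFELayer` wraps them for use inside the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .nn import Module, Tensor
from .nn import cat as tensor_cat
from .nn.tensor import gelu_np

__all__ = [
    "BLOCK_IDS",
    "BLOCK_POSITIONS",
    "PartitionError",
    "BlockGrid",
    "StripSet",
    "FusionAssembly",
    "RFEParams",
    "partition_blocks",
    "reassemble_blocks",
    "extract_strips",
    "assemble_fusion_input",
    "correlate",
    "rfe_block_transform",
    "rfe_layer_forward",
    "init_rfe_params",
    "RFELayer",
]

#: quadrant labels in fixed order: top-left, top-right, bottom-left, bottom-right
BLOCK_IDS: Tuple[str, ...] = ("A", "B", "C", "D")
BLOCK_POSITIONS: Dict[str, Tuple[int, int]] = {"A": (0, 0), "B": (0, 1), "C": (1, 0), "D": (1, 1)}


class PartitionError(ValueError):
    """Raised when a feature map cannot be cut into four equal quadrants."""


def _cat(parts, axis):
    if isinstance(parts[0], Tensor):
        return tensor_cat(parts, axis=axis)
    return np.concatenate(parts, axis=axis)


def _gelu(x):
    return x.gelu() if isinstance(x, Tensor) else gelu_np(x)


@dataclass
class BlockGrid:
    """The 2x2 quadrant decomposition of a (C, H, W) feature map."""

    blocks: Dict[str, object]
    h: int  # block height (= H / 2)
    w: int  # block width  (= W / 2)

    def block(self, block_id: str):
        return self.blocks[block_id]


@dataclass
class StripSet:
    """All row strips (C x 1 x w) and column strips (C x h x 1) of one block."""

    rows: list
    cols: list


@dataclass
class FusionAssembly:
    """Base block plus one index-matched strip from each remote block, flattened.

    ``flat`` has shape (C, h*w + 3*s) per channel: the base block in
    row-major order followed by the index-``k`` strips of the three remote
    blocks in fixed A->B->C->D order (base omitted).
    """

    flat: object
    base_id: str
    direction: str  # "row" | "col"
    k: int
    h: int
    w: int
    strip_len: int

    @property
    def stacked_shape(self) -> Tuple[int, int]:
        """Spatial shape of the assembly before flattening (e.g. T1: 5 x 2).

        For the row direction the base block's h rows and the three remote
        strips stack vertically into (h + 3) rows of width w; for the column
        direction, symmetrically, (w + 3) columns of height h.
        """
        n_strips = (self.flat.shape[-1] - self.h * self.w) // self.strip_len
        if self.direction == "row":
            return (self.h + n_strips, self.w)
        return (self.h, self.w + n_strips)


def partition_blocks(fmap) -> BlockGrid:
    """Cut a (C, H, W) feature map into quadrants A (top-left), B (top-right),
    C (bottom-left), D (bottom-right)."""
    if len(fmap.shape) != 3:
        raise PartitionError(f"expected a rank-3 (C, H, W) feature map, got shape {fmap.shape}")
    _, height, width = fmap.shape
    if height % 2 != 0:
        raise PartitionError(f"height {height} is odd; quadrant partition needs even H")
    if width % 2 != 0:
        raise PartitionError(f"width {width} is odd; quadrant partition needs even W")
    h, w = height // 2, width // 2
    blocks = {
        bid: fmap[:, bi * h : (bi + 1) * h, bj * w : (bj + 1) * w]
        for bid, (bi, bj) in BLOCK_POSITIONS.items()
    }
    return BlockGrid(blocks=blocks, h=h, w=w)


def reassemble_blocks(blocks: Dict[str, object]):
    """Inverse of :func:`partition_blocks`: tile four quadrants back together."""
    top = _cat([blocks["A"], blocks["B"]], axis=2)
    bottom = _cat([blocks["C"], blocks["D"]], axis=2)
    return _cat([top, bottom], axis=1)


def extract_strips(block) -> StripSet:
    """Decompose one block into its h row strips and w column strips."""
    _, h, w = block.shape
    rows = [block[:, k : k + 1, :] for k in range(h)]
    cols = [block[:, :, k : k + 1] for k in range(w)]
    return StripSet(rows=rows, cols=cols)


def assemble_fusion_input(grid: BlockGrid, base_id: str, direction: str, k: int) -> FusionAssembly:
    """Flatten a base block together with the k-th strip of each remote block.

    Remote strips are appended in A->B->C->D order with the base omitted, so
    for base A, row direction, k = 0 the result lists the base elements
    row-major followed by the first rows of B, C and D — the operand order of
    the correlation sum.
    """
    if base_id not in BLOCK_IDS:
        raise ValueError(f"unknown block id {base_id!r}; expected one of {BLOCK_IDS}")
    if direction not in ("row", "col"):
        raise ValueError(f"direction must be 'row' or 'col', got {direction!r}")
    h, w = grid.h, grid.w
    limit = h if direction == "row" else w
    if not 0 <= k < limit:
        raise IndexError(f"strip index {k} out of range for direction {direction!r} (limit {limit})")
    base = grid.blocks[base_id]
    c = base.shape[0]
    parts = [base.reshape(c, h * w)]
    for bid in BLOCK_IDS:
        if bid == base_id:
            continue
        blk = grid.blocks[bid]
        strip = blk[:, k, :] if direction == "row" else blk[:, :, k]
        parts.append(strip)
    flat = _cat(parts, axis=1)
    return FusionAssembly(
        flat=flat, base_id=base_id, direction=direction, k=k, h=h, w=w,
        strip_len=(w if direction == "row" else h),
    )


def correlate(assembly: FusionAssembly, weights):
    """Fully connected correlation map: each output element M(i, j) is the
    weighted sum of *all* assembly entries (no bias), shared across channels.

    ``weights`` has shape (h*w + 3*s, h*w); column j holds the coefficients
    w(., j) of output element j (row-major over the block).
    """
    length = assembly.flat.shape[-1]
    expected = (length, assembly.h * assembly.w)
    if tuple(weights.shape) != expected:
        raise ValueError(
            f"correlation weights shape {tuple(weights.shape)} does not match "
            f"assembly: expected {expected}"
        )
    c = assembly.flat.shape[0]
    out = assembly.flat @ weights
    return out.reshape(c, assembly.h, assembly.w)


@dataclass
class RFEParams:
    """Parameters of one RFE layer.

    ``correlation[(block_id, direction)]`` is the (h*w + 3*s) x (h*w)
    correlation matrix for that base block and strip direction;
    ``mlp[block_id]`` holds (w1, b1, w2, b2) of the per-block two-layer MLP
    applied to the aggregated block.  Spatial weights are shared across
    channels; each base block and direction has its own matrix.
    """

    h: int
    w: int
    correlation: Dict[Tuple[str, str], object] = field(default_factory=dict)
    mlp: Dict[str, tuple] = field(default_factory=dict)
    share_channels: bool = True
    share_blocks: bool = False

    def to_numpy(self) -> "RFEParams":
        """Return a copy with all parameters as float64 ndarrays."""

        def conv(a):
            return np.asarray(a.data if isinstance(a, Tensor) else a, dtype=np.float64)

        return RFEParams(
            h=self.h,
            w=self.w,
            correlation={k: conv(v) for k, v in self.correlation.items()},
            mlp={k: tuple(conv(a) for a in v) for k, v in self.mlp.items()},
            share_channels=self.share_channels,
            share_blocks=self.share_blocks,
        )


def init_rfe_params(
    h: int,
    w: int,
    rng=None,
    weight_sigma: float = 0.02,
    hidden_mult: int = 4,
    dtype=np.float64,
    trainable: bool = False,
) -> RFEParams:
    """Small-normal initialization: the layer starts near the identity, since
    the residual path dominates when correlation and MLP weights are ~0."""
    rng = rng if rng is not None else np.random.default_rng()
    n_el = h * w
    hidden = hidden_mult * n_el

    def mk(shape):
        arr = rng.normal(0.0, weight_sigma, shape).astype(dtype)
        return Tensor(arr, requires_grad=True) if trainable else arr

    def zeros(shape):
        arr = np.zeros(shape, dtype=dtype)
        return Tensor(arr, requires_grad=True) if trainable else arr

    params = RFEParams(h=h, w=w)
    for bid in BLOCK_IDS:
        params.correlation[(bid, "row")] = mk((n_el + 3 * w, n_el))
        params.correlation[(bid, "col")] = mk((n_el + 3 * h, n_el))
        params.mlp[bid] = (mk((n_el, hidden)), zeros(hidden), mk((hidden, n_el)), zeros(n_el))
    return params


def rfe_block_transform(grid: BlockGrid, base_id: str, params: RFEParams):
    """Transform one base block: all h row variants and w column variants are
    generated, averaged element-wise, passed through the block's MLP, and
    added residually to the base block."""
    h, w = grid.h, grid.w
    variants = []
    for direction, count in (("row", h), ("col", w)):
        weights = params.correlation[(base_id, direction)]
        for k in range(count):
            variants.append(correlate(assemble_fusion_input(grid, base_id, direction, k), weights))
    agg = variants[0]
    for v in variants[1:]:
        agg = agg + v
    agg = agg * (1.0 / len(variants))

    w1, b1, w2, b2 = params.mlp[base_id]
    c = agg.shape[0]
    flat = agg.reshape(c, h * w)
    hid = _gelu(flat @ w1 + b1)
    out = (hid @ w2 + b2).reshape(c, h, w)
    return out + grid.blocks[base_id]


def rfe_layer_forward(fmap, params: RFEParams):
    """Full layer: transform each quadrant with itself as base, then place
    At, Bt, Ct, Dt back in their quadrant positions (output shape == input)."""
    grid = partition_blocks(fmap)
    if (grid.h, grid.w) != (params.h, params.w):
        raise ValueError(
            f"parameters built for {params.h}x{params.w} blocks, "
            f"feature map gives {grid.h}x{grid.w}"
        )
    transformed = {bid: rfe_block_transform(grid, bid, params) for bid in BLOCK_IDS}
    return reassemble_blocks(transformed)


class RFELayer(Module):
    """Trainable RFE layer operating on (N, C, H, W) tensors.

    Spatial weights are shared across channels, so the batch axis is folded
    into the channel axis before the functional core is applied.
    """

    def __init__(self, block_h: int, block_w: int, rng=None, weight_sigma: float = 0.02,
                 hidden_mult: int = 4, dtype=np.float32):
        super().__init__()
        self.block_h = block_h
        self.block_w = block_w
        self.params = init_rfe_params(
            block_h, block_w, rng=rng, weight_sigma=weight_sigma,
            hidden_mult=hidden_mult, dtype=dtype, trainable=True,
        )
        # expose parameter dicts for Module traversal
        self.correlation = self.params.correlation
        self.mlp = self.params.mlp

    def forward(self, x: Tensor) -> Tensor:
        n, c, height, width = x.shape
        folded = x.reshape(n * c, height, width)
        out = rfe_layer_forward(folded, self.params)
        return out.reshape(n, c, height, width)
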