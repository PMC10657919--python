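"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with the computation-graph
edges needed for backpropagation.  The graph is built dynamically on every
forward pass and discarded afterwards; trainable parameters are long-lived
tensors with ``requires_grad=True`` whose ``.grad`` is read by the optimiser.

Only the operations required by the U-Net / CNN architectures in this
package are implemented (see :mod:`wsunet.nn.ops`).  Everything is plain
numpy, so the whole stack is deterministic on a single thread.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "Parameter", "backward", "no_grad", "grad_enabled"]

_GRAD_ENABLED = [True]


def grad_enabled() -> bool:
    return _GRAD_ENABLED[0]


class no_grad:
    """Context manager: tensors created inside carry no graph edges.

    Inference through large convolutional stacks would otherwise retain
    every layer's im2col patch matrix in backward closures.
    """

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data
        The numpy value of this node.
    parents
        Input tensors this node was computed from.
    vjp
        Vector-Jacobian product: maps the gradient at this node to a tuple
        of gradients aligned with ``parents`` (entries may be ``None``).
    requires_grad
        Whether gradients should flow into this node.  Propagates to any
        node computed from it.
    """

    __slots__ = ("data", "parents", "vjp", "requires_grad", "grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        vjp: Optional[Callable[[np.ndarray], Tuple[Optional[np.ndarray], ...]]] = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data)
        if _GRAD_ENABLED[0]:
            self.parents = tuple(parents)
            self.vjp = vjp
            self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        else:
            self.parents = ()
            self.vjp = None
            self.requires_grad = False
        self.grad: Optional[np.ndarray] = None

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def backward(self, seed: Optional[np.ndarray] = None) -> None:
        backward(self, seed)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data), requires_grad=True)


def _toposort(root: Tensor) -> list:
    order: list = []
    seen: set = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    return order


def backward(root: Tensor, seed: Optional[np.ndarray] = None) -> None:
    """Accumulate gradients of ``root`` into every reachable tensor.

    ``root.grad`` is seeded with ``seed`` (default: ones), then gradients
    are pushed through the graph in reverse topological order.  Existing
    ``.grad`` values on interior nodes are overwritten; call-sites that
    reuse parameters across steps must clear ``.grad`` themselves.
    """
    order = _toposort(root)
    for node in order:
        node.grad = None
    root.grad = np.ones_like(root.data) if seed is None else np.asarray(seed)
    for node in reversed(order):
        if node.vjp is None or node.grad is None:
            continue
        grads = node.vjp(node.grad)
        for parent, g in zip(node.parents, grads):
            if g is None or not parent.requires_grad:
                continue
            if parent.grad is None:
                parent.grad = g
            else:
                parent.grad = parent.grad + g
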