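"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps a numpy
array, records the operation that produced it, and ``backward()`` walks the
graph in reverse topological order accumulating gradients.  Only the
operations needed by the 3D segmentation/outcome networks and the survival
losses are provided (elementwise arithmetic, matmul, reductions, reshaping,
3D convolution / transposed convolution / pooling via im2col).

Dtypes are preserved: networks run in float32, the survival losses accept
float64 inputs and then match their closed-form oracles to machine
precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "conv_transpose3d",
    "max_pool3d",
    "avg_pool3d",
]


def _as_array(value, dtype=None):
    arr = np.asarray(value)
    if dtype is not None:
        arr = arr.astype(dtype, copy=False)
    elif arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float64)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, dtype=None):
        self.value = _as_array(value, dtype)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other, like: "Tensor") -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=like.value.dtype))

    @staticmethod
    def _node(value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    @property
    def dtype(self):
        return self.value.dtype

    def item(self) -> float:
        return float(self.value)

    def __float__(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, dtype={self.value.dtype}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other, self)

        def backward(grad, out):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor._node(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, out):
            return (-grad,)

        return Tensor._node(-self.value, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other, self))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = Tensor._lift(other, self)

        def backward(grad, out):
            return (
                _unbroadcast(grad * other.value, self.shape),
                _unbroadcast(grad * self.value, other.shape),
            )

        return Tensor._node(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other, self)

        def backward(grad, out):
            return (
                _unbroadcast(grad / other.value, self.shape),
                _unbroadcast(-grad * self.value / other.value**2, other.shape),
            )

        return Tensor._node(self.value / other.value, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other, self) / self

    def __pow__(self, exponent: float):
        def backward(grad, out):
            return (grad * exponent * self.value ** (exponent - 1),)

        return Tensor._node(self.value**exponent, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other, self)

        def backward(grad, out):
            a, b = self.value, other.value
            ga = grad @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ grad
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._node(self.value @ other.value, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_val = np.exp(self.value)

        def backward(grad, out):
            return (grad * out.value,)

        return Tensor._node(out_val, (self,), backward)

    def log(self):
        def backward(grad, out):
            return (grad / self.value,)

        return Tensor._node(np.log(self.value), (self,), backward)

    def sqrt(self):
        out_val = np.sqrt(self.value)

        def backward(grad, out):
            return (grad * 0.5 / out.value,)

        return Tensor._node(out_val, (self,), backward)

    def tanh(self):
        out_val = np.tanh(self.value)

        def backward(grad, out):
            return (grad * (1.0 - out.value**2),)

        return Tensor._node(out_val, (self,), backward)

    def sigmoid(self):
        out_val = np.empty_like(self.value)
        pos = self.value >= 0
        out_val[pos] = 1.0 / (1.0 + np.exp(-self.value[pos]))
        ex = np.exp(self.value[~pos])
        out_val[~pos] = ex / (1.0 + ex)

        def backward(grad, out):
            return (grad * out.value * (1.0 - out.value),)

        return Tensor._node(out_val, (self,), backward)

    def relu(self):
        mask = self.value > 0

        def backward(grad, out):
            return (grad * mask,)

        return Tensor._node(np.where(mask, self.value, 0.0), (self,), backward)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.value > 0

        def backward(grad, out):
            return (grad * np.where(mask, 1.0, slope),)

        return Tensor._node(np.where(mask, self.value, slope * self.value), (self,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient is zero outside the active range."""
        inside = (self.value >= lo) & (self.value <= hi)

        def backward(grad, out):
            return (grad * inside,)

        return Tensor._node(np.clip(self.value, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad, out):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis=axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._node(self.value.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.value.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(grad, out):
            return (grad.reshape(self.shape),)

        return Tensor._node(self.value.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(grad, out):
            return (grad.transpose(inv),)

        return Tensor._node(self.value.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(grad, out):
            g = np.zeros_like(self.value)
            np.add.at(g, idx, grad)
            return (g,)

        return Tensor._node(self.value[idx], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen = set()

        def visit(node: Tensor):
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                current, parents = stack[-1]
                advanced = False
                for p in parents:
                    if p.requires_grad and id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(current)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.value.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf (parameter or input)
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g, node)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, out):
        grads = []
        slicer = [slice(None)] * grad.ndim
        for i in range(len(tensors)):
            slicer[axis] = slice(offsets[i], offsets[i + 1])
            grads.append(grad[tuple(slicer)])
        return tuple(grads)

    value = np.concatenate([t.value for t in tensors], axis=axis)
    return Tensor._node(value, tensors, backward)


# -- 3D convolution machinery (im2col) ----------------------------------------


def _pad5(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    """(N,C,D,H,W) -> columns (N, C*k^3, L) plus the output spatial shape."""
    xp = _pad5(x, p)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]  # (N,C,Do,Ho,Wo,k,k,k)
    n, c, do, ho, wo = win.shape[:5]
    cols = win.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(n, c * k**3, do * ho * wo)
    return np.ascontiguousarray(cols), (do, ho, wo)

def _col2im(cols: np.ndarray, x_shape, k: int, s: int, p: int) -> np.ndarray:
    """Scatter-add columns back to the (padded, then cropped) input shape."""
    n, c, d, h, w = x_shape
    do = (d + 2 * p - k) // s + 1
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    xp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, k, do, ho, wo)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                xp[:, :, dz : dz + s * do : s, dy : dy + s * ho : s, dx : dx + s * wo : s] += cols6[
                    :, :, dz, dy, dx
                ]
    if p == 0:
        return xp
    return xp[:, :, p : p + d, p : p + h, p : p + w]


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation. `w` has shape (Cout, Cin, k, k, k)."""
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    cols, (do, ho, wo) = _im2col(x.value, k, stride, padding)
    n = x.shape[0]
    wflat = w.value.reshape(cout, -1)
    y = np.matmul(wflat, cols).reshape(n, cout, do, ho, wo)
    if b is not None:
        y = y + b.value.reshape(1, cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad, out):
        gy = np.ascontiguousarray(grad.reshape(n, cout, -1))
        gw = np.matmul(gy, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        gcols = np.matmul(wflat.T, gy)
        gx = _col2im(gcols, x.value.shape, k, stride, padding)
        if b is None:
            return (gx, gw)
        return (gx, gw, grad.sum(axis=(0, 2, 3, 4)))

    return Tensor._node(y, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2) -> Tensor:
    """Transposed 3D convolution; `w` has shape (Cin, Cout, k, k, k).

    Output spatial size is (in - 1) * stride + k (no output padding), the
    adjoint of `conv3d` with the same kernel/stride and zero padding.
    """
    cin, cout, k = w.shape[0], w.shape[1], w.shape[2]
    n, _, d, h, wd = x.value.shape
    out_shape = (n, cout, (d - 1) * stride + k, (h - 1) * stride + k, (wd - 1) * stride + k)
    wflat = w.value.reshape(cin, -1)  # (Cin, Cout*k^3)
    xflat = np.ascontiguousarray(x.value.reshape(n, cin, -1))
    cols = np.matmul(wflat.T, xflat)
    y = _col2im(cols, out_shape, k, stride, 0)
    if b is not None:
        y = y + b.value.reshape(1, cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad, out):
        gcols, _ = _im2col(grad, k, stride, 0)
        gx = np.matmul(wflat, gcols).reshape(x.value.shape)
        gw = np.matmul(xflat, gcols.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        if b is None:
            return (gx, gw)
        return (gx, gw, grad.sum(axis=(0, 2, 3, 4)))

    return Tensor._node(y, parents, backward)


def max_pool3d(x: Tensor, kernel: int = 2, stride: int | None = None, padding: int = 0) -> Tensor:
    s = stride or kernel
    n, c = x.shape[:2]
    if padding:  # pad with -inf so padded voxels never win over negative activations
        xp = np.pad(x.value, ((0, 0), (0, 0)) + ((padding, padding),) * 3, constant_values=-np.inf)
    else:
        xp = x.value
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel,) * 3, axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]
    do, ho, wo = win.shape[2:5]
    flat = win.reshape(n, c, do, ho, wo, kernel**3)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(grad, out):
        k3 = kernel**3
        gcols = np.zeros((n, c, do, ho, wo, k3), dtype=grad.dtype)
        np.put_along_axis(gcols, arg[..., None], grad[..., None], axis=-1)
        # (n, c, k,k,k, do,ho,wo) layout expected by _col2im
        gcols = gcols.reshape(n, c, do, ho, wo, kernel, kernel, kernel)
        gcols = gcols.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(n, c * k3, do * ho * wo)
        return (_col2im(gcols, x.value.shape, kernel, s, padding),)

    return Tensor._node(y, (x,), backward)


def avg_pool3d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    s = stride or kernel
    n, c, d, h, w = x.shape
    if s == kernel and d % kernel == 0 and h % kernel == 0 and w % kernel == 0:
        do, ho, wo = d // kernel, h // kernel, w // kernel
        y = x.value.reshape(n, c, do, kernel, ho, kernel, wo, kernel).mean(axis=(3, 5, 7))

        def backward(grad, out):
            g = grad / kernel**3
            g = np.repeat(np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3), kernel, axis=4)
            return (g,)

        return Tensor._node(y, (x,), backward)
    win = np.lib.stride_tricks.sliding_window_view(x.value, (kernel,) * 3, axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]
    do, ho, wo = win.shape[2:5]
    y = win.reshape(n, c, do, ho, wo, -1).mean(axis=-1)

    def backward(grad, out):
        k3 = kernel**3
        gcols = np.broadcast_to((grad / k3)[..., None], (n, c, do, ho, wo, k3)).astype(grad.dtype)
        gcols = gcols.reshape(n, c, do, ho, wo, kernel, kernel, kernel)
        gcols = gcols.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(n, c * k3, -1)
        return (_col2im(gcols, x.value.shape, kernel, s, 0),)

    return Tensor._node(y, (x,), backward)
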