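"""Minimal reverse-mode automatic differentiation on numpy arrays.

The posterior of the life-cycle model is a smooth function of a few hundred
unconstrained parameters, and the NUTS sampler needs its gradient at every
leapfrog step.  This module provides exactly the operator set that the traced
model requires -- arithmetic with numpy broadcasting, exp/log/expm1/log1p,
sums, cumulative sums, constant-index gathers, concatenation, stacking and
reshaping -- recorded on a flat tape with vector-Jacobian products for the
reverse pass.  It is deliberately small: no higher-order derivatives, no
in-place mutation, arrays up to 2-D.

Gradients are exact to machine precision; the test-suite checks every
operator against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tape", "Var", "exp", "log", "log1p", "expm1", "expit", "vsum",
           "cumsum", "concat", "stack", "take", "reshape", "grad"]


class Tape:
    """Records operations; one tape per forward evaluation."""

    __slots__ = ("parents", "vjps", "n")

    def __init__(self) -> None:
        self.parents: list[tuple[int, ...]] = []
        self.vjps: list[tuple[Callable, ...]] = []
        self.n = 0

    def leaf(self, value) -> "Var":
        return self._push(np.asarray(value, dtype=float), (), ())

    def _push(self, value, parents, vjps) -> "Var":
        i = self.n
        self.parents.append(parents)
        self.vjps.append(vjps)
        self.n += 1
        return Var(value, self, i)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    if g.shape == shape:
        return g
    nd = len(shape)
    while g.ndim > nd:
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Var:
    """A node on the tape wrapping an ndarray (or scalar) value."""

    __slots__ = ("v", "t", "i")
    __array_ufunc__ = None  # make ndarray <op> Var defer to our reflected ops

    def __init__(self, value, tape: Tape, idx: int) -> None:
        self.v = value
        self.t = tape
        self.i = idx

    @property
    def shape(self):
        return np.shape(self.v)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, o):
        if isinstance(o, Var):
            a, b = self.v, o.v
            return self.t._push(a + b, (self.i, o.i),
                                (lambda g, s=np.shape(a): _unbroadcast(g, s),
                                 lambda g, s=np.shape(b): _unbroadcast(g, s)))
        return self.t._push(self.v + o, (self.i,),
                            (lambda g, s=np.shape(self.v): _unbroadcast(g, s),))

    __radd__ = __add__

    def __neg__(self):
        return self.t._push(-self.v, (self.i,), (lambda g: -g,))

    def __sub__(self, o):
        if isinstance(o, Var):
            a, b = self.v, o.v
            return self.t._push(a - b, (self.i, o.i),
                                (lambda g, s=np.shape(a): _unbroadcast(g, s),
                                 lambda g, s=np.shape(b): -_unbroadcast(g, s)))
        return self.t._push(self.v - o, (self.i,),
                            (lambda g, s=np.shape(self.v): _unbroadcast(g, s),))

    def __rsub__(self, o):
        return self.t._push(o - self.v, (self.i,),
                            (lambda g, s=np.shape(self.v): -_unbroadcast(g, s),))

    def __mul__(self, o):
        if isinstance(o, Var):
            a, b = self.v, o.v
            return self.t._push(a * b, (self.i, o.i),
                                (lambda g, b=b, s=np.shape(a): _unbroadcast(g * b, s),
                                 lambda g, a=a, s=np.shape(b): _unbroadcast(g * a, s)))
        return self.t._push(self.v * o, (self.i,),
                            (lambda g, o=o, s=np.shape(self.v):
                             _unbroadcast(g * o, s),))

    __rmul__ = __mul__

    def __truediv__(self, o):
        if isinstance(o, Var):
            a, b = self.v, o.v
            out = a / b
            return self.t._push(out, (self.i, o.i),
                                (lambda g, b=b, s=np.shape(a): _unbroadcast(g / b, s),
                                 lambda g, out=out, b=b, s=np.shape(b):
                                 _unbroadcast(-g * out / b, s)))
        return self.t._push(self.v / o, (self.i,),
                            (lambda g, o=o, s=np.shape(self.v):
                             _unbroadcast(g / o, s),))

    def __rtruediv__(self, o):
        a = self.v
        out = o / a
        return self.t._push(out, (self.i,),
                            (lambda g, out=out, a=a, s=np.shape(a):
                             _unbroadcast(-g * out / a, s),))

    def __pow__(self, p):
        a = self.v
        return self.t._push(a ** p, (self.i,),
                            (lambda g, a=a, p=p: g * p * a ** (p - 1),))

    def __getitem__(self, key):
        a = self.v
        out = a[key]

        def vjp(g, key=key, shape=np.shape(a)):
            full = np.zeros(shape)
            np.add.at(full, key, g)
            return full

        return self.t._push(out, (self.i,), (vjp,))


def _as_value(x):
    return x.v if isinstance(x, Var) else np.asarray(x, dtype=float)


def exp(x: Var) -> Var:
    out = np.exp(x.v)
    return x.t._push(out, (x.i,), (lambda g, out=out: g * out,))


def log(x: Var) -> Var:
    a = x.v
    return x.t._push(np.log(a), (x.i,), (lambda g, a=a: g / a,))


def log1p(x: Var) -> Var:
    a = x.v
    return x.t._push(np.log1p(a), (x.i,), (lambda g, a=a: g / (1.0 + a),))


def expm1(x: Var) -> Var:
    out = np.expm1(x.v)
    return x.t._push(out, (x.i,), (lambda g, out=out: g * (out + 1.0),))


def expit(x: Var) -> Var:
    out = 1.0 / (1.0 + np.exp(-x.v))
    return x.t._push(out, (x.i,),
                     (lambda g, out=out: g * out * (1.0 - out),))


def vsum(x: Var, axis=None) -> Var:
    a = x.v
    out = np.sum(a, axis=axis)

    def vjp(g, axis=axis, shape=np.shape(a)):
        if axis is None:
            return np.broadcast_to(g, shape).copy()
        return np.broadcast_to(np.expand_dims(g, axis), shape).copy()

    return x.t._push(out, (x.i,), (vjp,))


def cumsum(x: Var, axis: int = 0) -> Var:
    """Cumulative sum along an axis (reverse-cumsum backward)."""
    out = np.cumsum(x.v, axis=axis)

    def vjp(g, axis=axis):
        return np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)

    return x.t._push(out, (x.i,), (vjp,))


def concat(parts: Sequence) -> Var:
    """Concatenate 1-D Vars and constant arrays."""
    tape = next(p.t for p in parts if isinstance(p, Var))
    values = [np.atleast_1d(_as_value(p)) for p in parts]
    out = np.concatenate(values)
    offsets = np.cumsum([0] + [v.size for v in values])
    parents, vjps = [], []
    for k, p in enumerate(parts):
        if isinstance(p, Var):
            parents.append(p.i)
            sl = slice(offsets[k], offsets[k + 1])
            scalar = np.shape(p.v) == ()
            vjps.append(lambda g, sl=sl, scalar=scalar:
                        g[sl][0] if scalar else g[sl])
    return tape._push(out, tuple(parents), tuple(vjps))


def stack(rows: Sequence[Var]) -> Var:
    """Stack equal-length 1-D Vars into a 2-D array (rows)."""
    tape = rows[0].t
    out = np.stack([r.v for r in rows])
    parents = tuple(r.i for r in rows)
    vjps = tuple((lambda g, k=k: g[k]) for k in range(len(rows)))
    return tape._push(out, parents, vjps)


def take(x: Var, idx: np.ndarray) -> Var:
    """Gather with a constant integer index array (flat, on the raveled value)."""
    a = np.ravel(x.v)
    out = a[idx]

    def vjp(g, idx=idx, shape=np.shape(x.v)):
        full = np.zeros(a.size)
        np.add.at(full, idx, np.ravel(g))
        return full.reshape(shape)

    return x.t._push(out, (x.i,), (vjp,))


def reshape(x: Var, shape) -> Var:
    old = np.shape(x.v)
    return x.t._push(np.reshape(x.v, shape), (x.i,),
                     (lambda g, old=old: np.reshape(g, old),))


def grad(out: Var, wrt: Sequence[Var]) -> list[np.ndarray]:
    """Gradients of a scalar output with respect to leaf variables."""
    tape = out.t
    if np.shape(out.v) != ():
        raise ValueError("grad target must be scalar")
    adj: list = [None] * tape.n
    adj[out.i] = np.asarray(1.0)
    parents, vjps = tape.parents, tape.vjps
    for i in range(out.i, -1, -1):
        g = adj[i]
        if g is None:
            continue
        for pi, vjp in zip(parents[i], vjps[i]):
            contrib = vjp(g)
            if adj[pi] is None:
                adj[pi] = np.array(contrib, dtype=float, copy=True)
            else:
                adj[pi] = adj[pi] + contrib
    results = []
    for w in wrt:
        g = adj[w.i]
        if g is None:
            g = np.zeros(np.shape(w.v))
        results.append(np.asarray(g, dtype=float))
    return results
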