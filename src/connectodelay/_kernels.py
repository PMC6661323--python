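"""Compiled inner loops for the delay-coupled Euler–Maruyama integrator.

Each kernel advances one chunk of steps for one model family.  Delayed states
are read from a ring-buffer history ``H`` of length L (the maximum link lag in
steps plus one); the invariant is that at the top of every step ``H[pos]``
holds the current state, so a link with lag 0 reads the present value.  Noise
increments are drawn outside (by a seeded numpy Generator, in chunks) so the
compiled and pure-numpy paths consume the identical stream.

Storage: the caller records the state every ``stride`` steps; a kernel writes
sample ``g // stride`` whenever the global step counter ``g`` is a multiple
of ``stride``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def rossler_chunk(Hx, pos, x, y, z, src, dst, lag, kw, ksum,
                  a, b, cpar, w0, dt, sigma, noise,
                  out_x, out_y, out_z, g0, stride):
    L = Hx.shape[0]
    N = x.shape[0]
    nlinks = src.shape[0]
    chunk = noise.shape[0]
    c = np.empty(N)
    for s in range(chunk):
        for i in range(N):
            c[i] = -ksum[i] * x[i]
        for l in range(nlinks):
            c[dst[l]] += kw[l] * Hx[(pos - lag[l]) % L, src[l]]
        for i in range(N):
            dx = -w0 * y[i] - z[i] + c[i]
            dy = w0 * x[i] + a * y[i]
            dz = b + z[i] * (x[i] - cpar)
            x[i] = x[i] + dt * dx + sigma * noise[s, i]
            y[i] = y[i] + dt * dy
            z[i] = z[i] + dt * dz
        pos = (pos + 1) % L
        for i in range(N):
            Hx[pos, i] = x[i]
        g = g0 + s + 1
        if g % stride == 0:
            k = g // stride
            for i in range(N):
                out_x[k, i] = x[i]
                out_y[k, i] = y[i]
                out_z[k, i] = z[i]
    return pos


@njit(cache=False)
def vdp_chunk(Hx, pos, x, y, src, dst, lag, kw, ksum,
              m, beta, w0, literal, dt, sigma, noise,
              out_x, out_y, g0, stride):
    L = Hx.shape[0]
    N = x.shape[0]
    nlinks = src.shape[0]
    chunk = noise.shape[0]
    c = np.empty(N)
    for s in range(chunk):
        for i in range(N):
            c[i] = -ksum[i] * x[i]
        for l in range(nlinks):
            c[dst[l]] += kw[l] * Hx[(pos - lag[l]) % L, src[l]]
        for i in range(N):
            restore = x[i] if literal else y[i]
            dx = 2.0 * m * (1.0 - beta * y[i] * y[i]) * x[i] - w0 * w0 * restore + c[i]
            dy = x[i]
            x[i] = x[i] + dt * dx + sigma * noise[s, i]
            y[i] = y[i] + dt * dy
        pos = (pos + 1) % L
        for i in range(N):
            Hx[pos, i] = x[i]
        g = g0 + s + 1
        if g % stride == 0:
            k = g // stride
            for i in range(N):
                out_x[k, i] = x[i]
                out_y[k, i] = y[i]
    return pos


@njit(cache=False)
def ls_chunk(Hx, Hy, pos, x, y, src, dst, lag, kw, ksum,
             q, w0, dt, sigma, noise,
             out_x, out_y, g0, stride):
    L = Hx.shape[0]
    N = x.shape[0]
    nlinks = src.shape[0]
    chunk = noise.shape[0]
    cx = np.empty(N)
    cy = np.empty(N)
    for s in range(chunk):
        for i in range(N):
            cx[i] = -ksum[i] * x[i]
            cy[i] = -ksum[i] * y[i]
        for l in range(nlinks):
            p = (pos - lag[l]) % L
            cx[dst[l]] += kw[l] * Hx[p, src[l]]
            cy[dst[l]] += kw[l] * Hy[p, src[l]]
        for i in range(N):
            r2 = x[i] * x[i] + y[i] * y[i]
            dx = x[i] * (1.0 - r2) - y[i] * (w0 - q * r2) + cx[i]
            dy = y[i] * (1.0 - r2) + x[i] * (w0 - q * r2) + cy[i]
            x[i] = x[i] + dt * dx + sigma * noise[s, i, 0]
            y[i] = y[i] + dt * dy + sigma * noise[s, i, 1]
        pos = (pos + 1) % L
        for i in range(N):
            Hx[pos, i] = x[i]
            Hy[pos, i] = y[i]
        g = g0 + s + 1
        if g % stride == 0:
            k = g // stride
            for i in range(N):
                out_x[k, i] = x[i]
                out_y[k, i] = y[i]
    return pos
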