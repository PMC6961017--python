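"""Numba kernels: forward and backward passes of one GMM convolution layer.

The layer computes, for output channel m and node s,

    pre[s, m] = b[m] + sum_n sum_{edges e with src=s} w[e, m, n] * f[dst_e, n]
    w[e, m, n] = sum_j g[m,n,j] * exp(-1/2 sum_d (v[e,d]-mu[m,n,j,d])^2 / var[m,n,j,d])

where v is the (possibly linearly transformed) pseudo-coordinate of edge e.
The backward kernel reuses the cached per-Gaussian exponentials from the
forward pass, so no exponential is re-evaluated.  Edges are processed in
their stored (sorted) order, making floating-point accumulation
reproducible run to run.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def layer_forward(src, dst, v, f, g, mu, var, b, relu):
    """Return (h, pre, ecache) for one layer.

    ecache[e, m, n, j] holds the Gaussian exponential of edge e under
    component j of filter (n, m); it is consumed by ``layer_backward``.
    """
    E = src.shape[0]
    M, N, J = g.shape
    K = f.shape[0]
    pre = np.empty((K, M))
    for s in range(K):
        for m in range(M):
            pre[s, m] = b[m]
    ecache = np.empty((E, M, N, J))
    for e in range(E):
        s = src[e]
        t = dst[e]
        vx = v[e, 0]
        vy = v[e, 1]
        for m in range(M):
            acc = 0.0
            for n in range(N):
                w = 0.0
                for j in range(J):
                    dx = vx - mu[m, n, j, 0]
                    dy = vy - mu[m, n, j, 1]
                    q = dx * dx / var[m, n, j, 0] + dy * dy / var[m, n, j, 1]
                    ex = np.exp(-0.5 * q)
                    ecache[e, m, n, j] = ex
                    w += g[m, n, j] * ex
                acc += w * f[t, n]
            pre[s, m] += acc
    if relu:
        h = np.maximum(pre, 0.0)
    else:
        h = pre.copy()
    return h, pre, ecache


@njit(cache=True)
def layer_backward(src, dst, v, f, g, mu, var, pre, ecache, grad_h, relu):
    """Gradients of a scalar loss w.r.t. all layer parameters and inputs.

    Returns (grad_g, grad_mu, grad_var, grad_b, grad_f).  ``grad_var`` is
    w.r.t. the variance itself; the caller applies the log-variance chain
    rule.
    """
    E = src.shape[0]
    M, N, J = g.shape
    K = f.shape[0]
    gpre = np.empty((K, M))
    for s in range(K):
        for m in range(M):
            gp = grad_h[s, m]
            if relu and pre[s, m] <= 0.0:
                gp = 0.0
            gpre[s, m] = gp
    grad_g = np.zeros((M, N, J))
    grad_mu = np.zeros((M, N, J, 2))
    grad_var = np.zeros((M, N, J, 2))
    grad_b = np.zeros(M)
    grad_f = np.zeros((K, N))
    for s in range(K):
        for m in range(M):
            grad_b[m] += gpre[s, m]
    for e in range(E):
        s = src[e]
        t = dst[e]
        vx = v[e, 0]
        vy = v[e, 1]
        for m in range(M):
            gp = gpre[s, m]
            if gp == 0.0:
                continue
            for n in range(N):
                fn = f[t, n]
                dw = gp * fn
                w = 0.0
                for j in range(J):
                    ex = ecache[e, m, n, j]
                    gj = g[m, n, j]
                    w += gj * ex
                    grad_g[m, n, j] += dw * ex
                    qcom = dw * gj * ex
                    dx = vx - mu[m, n, j, 0]
                    dy = vy - mu[m, n, j, 1]
                    grad_mu[m, n, j, 0] += qcom * dx / var[m, n, j, 0]
                    grad_mu[m, n, j, 1] += qcom * dy / var[m, n, j, 1]
                    grad_var[m, n, j, 0] += qcom * 0.5 * dx * dx / (var[m, n, j, 0] ** 2)
                    grad_var[m, n, j, 1] += qcom * 0.5 * dy * dy / (var[m, n, j, 1] ** 2)
                grad_f[t, n] += gp * w
    return grad_g, grad_mu, grad_var, grad_b, grad_f
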