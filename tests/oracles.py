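"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's FFT-based code paths: the wavelet
transform is a direct time-domain convolution, the smoothing operators are
explicit Python loops, and the beta-regression oracle maximizes the exact
likelihood through scipy alone.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats


def cwt_direct(x: np.ndarray, fs_hz: float, scales: np.ndarray, omega0: float = 6.0):
    """Direct-convolution Morlet CWT of a zero-extended series.

    W[s, t] = sqrt(dt/s) * sum_k x[k] * conj(psi((k - t) * dt / s))
    with psi(eta) = pi^{-1/4} exp(i*omega0*eta) exp(-eta^2/2).
    """
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    dt = 1.0 / fs_hz
    W = np.zeros((len(scales), n), complex)
    k = np.arange(n)
    for si, s in enumerate(scales):
        for t in range(n):
            eta = (k - t) * dt / s
            psi = (np.pi**-0.25) * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
            W[si, t] = np.sqrt(dt / s) * np.sum(x * np.conj(psi))
    return W


def smooth_loops(Z, scales, dt, dj, scale_smooth_octaves=0.6):
    """Explicit-loop version of the WTC smoothing operator."""
    S, n = Z.shape
    out_t = np.zeros_like(Z)
    for si, s in enumerate(scales):
        sig = s / dt
        r = max(1, int(4.0 * sig + 0.5))
        kk = np.arange(-r, r + 1)
        g = np.exp(-0.5 * (kk / sig) ** 2)
        g /= g.sum()
        for t in range(n):
            acc = 0.0j if np.iscomplexobj(Z) else 0.0
            for j, w in zip(kk, g):
                u = t + j
                if 0 <= u < n:
                    acc += w * Z[si, u]
            out_t[si, t] = acc
    # fractional boxcar across scales, edge-renormalized
    wbins = max(1.0, scale_smooth_octaves / dj)
    m = int(np.ceil((wbins - 1) / 2))
    kernel = np.ones(2 * m + 1)
    if m > 0:
        kernel[0] = kernel[-1] = (wbins - (2 * m - 1)) / 2
    kernel /= kernel.sum()
    out = np.zeros_like(out_t)
    for si in range(S):
        acc = np.zeros(n, dtype=out_t.dtype)
        wsum = 0.0
        for j, w in enumerate(kernel):
            u = si + j - m
            if 0 <= u < S:
                acc += w * out_t[u]
                wsum += w
        out[si] = acc / wsum
    return out


def wtc_brute(x, y, fs_hz, scales, dj, omega0=6.0):
    """Brute-force wavelet coherence on a given scale grid."""
    dt = 1.0 / fs_hz
    Wx = cwt_direct(x, fs_hz, scales, omega0)
    Wy = cwt_direct(y, fs_hz, scales, omega0)
    inv_s = 1.0 / scales[:, None]
    Sxx = smooth_loops(np.abs(Wx) ** 2 * inv_s, scales, dt, dj)
    Syy = smooth_loops(np.abs(Wy) ** 2 * inv_s, scales, dt, dj)
    Sxy = smooth_loops(Wx * np.conj(Wy) * inv_s, scales, dt, dj)
    return np.clip(np.abs(Sxy) ** 2 / (Sxx.real * Syy.real), 0, 1)


def beta_regression_ml(y, X):
    """Exact fixed-effects beta-regression ML via scipy only.

    Returns (beta_hat, phi_hat, loglik).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)

    def nll(theta):
        beta, logphi = theta[:-1], theta[-1]
        mu = special.expit(X @ beta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        phi = np.exp(logphi)
        return -np.sum(stats.beta.logpdf(y, mu * phi, (1 - mu) * phi))

    eta0 = np.log(y / (1 - y))
    b0, *_ = np.linalg.lstsq(X, eta0, rcond=None)
    res = optimize.minimize(
        nll, np.concatenate([b0, [np.log(10.0)]]), method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
    )
    return res.x[:-1], float(np.exp(res.x[-1])), -res.fun
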