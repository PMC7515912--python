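"""Independent numerical oracles shared across tests.

The lineshape oracle deliberately avoids the eigendecomposition route used
by the package: it step-propagates the two-site FID with a matrix
exponential, Fourier-transforms it, and peak-picks the real spectrum.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from nmrbind.exchange import ExchangeParams


def oracle_lineshape_peak(params: ExchangeParams, p_bound: float) -> tuple[float, float]:
    """Position (ppm) and decay rate (s⁻¹) of the tallest peak of the
    numerically synthesized two-site spectrum."""
    p_f, p_b = 1.0 - p_bound, p_bound
    k_on = params.k_off * p_b / p_f
    k_ex = k_on + params.k_off
    wf, wb = params.omega(params.shift_free), params.omega(params.shift_bound)
    wc = 0.5 * (wf + wb)  # demodulate at the midpoint
    a = np.array(
        [[1j * (wf - wc) - params.r2_free - k_on, params.k_off],
         [k_on, 1j * (wb - wc) - params.r2_bound - params.k_off]]
    )
    span_hz = abs(wb - wf) / (2 * np.pi)
    sw = 24.0 * (span_hz + (params.r2_free + params.r2_bound) / np.pi + 1.0)
    if abs(wb - wf) > 0 and k_ex < 10.0 * abs(wb - wf):
        sw += 24.0 * k_ex / np.pi  # broad component is spectrally relevant
    t_max = 40.0 / min(params.r2_free, params.r2_bound)
    n = int(2 ** np.ceil(np.log2(max(sw * t_max, 4096))))
    n = min(n, 1 << 18)
    dt = 1.0 / sw
    prop = expm(a * dt)
    v = np.array([p_f, p_b], complex)
    fid = np.empty(n, complex)
    for i in range(n):
        fid[i] = v.sum()
        v = prop @ v
    fid[0] *= 0.5
    nfft = 4 * n
    spec = np.fft.fftshift(np.fft.fft(fid, nfft)).real
    freq = np.fft.fftshift(np.fft.fftfreq(nfft, dt))
    i = int(np.argmax(spec))
    y0, y1, y2 = spec[i - 1], spec[i], spec[i + 1]
    di = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)  # parabolic refinement
    pos_hz = freq[i] + di * (freq[1] - freq[0])
    half = y1 / 2.0
    j = i
    while spec[j] > half:
        j += 1
    right = freq[j - 1] + (freq[j] - freq[j - 1]) * (spec[j - 1] - half) / (spec[j - 1] - spec[j])
    j = i
    while spec[j] > half:
        j -= 1
    left = freq[j + 1] - (freq[j + 1] - freq[j]) * (spec[j + 1] - half) / (spec[j + 1] - spec[j])
    pos_ppm = (pos_hz + wc / (2 * np.pi)) / params.larmor_mhz
    return pos_ppm, np.pi * (right - left)


def oracle_fraction_bound(p_total: float, l_total: float, kd: float,
                          tol: float = 1e-12) -> float:
    """Brute-force bisection on the 1:1 mass balance, independent of the
    closed-form quadratic root."""
    lo, hi = 0.0, 1.0

    def residual(fb: float) -> float:
        bound = fb * p_total
        free_p, free_l = p_total - bound, l_total - bound
        return free_p * free_l - kd * bound

    if residual(1.0) >= 0:  # stoichiometric limit with kd ~ 0
        return min(l_total / p_total, 1.0)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_c50_bisect(p_total: float, kd: float, tol: float = 1e-10) -> float:
    """Ligand concentration at 50% bound, by bisection on the mass balance."""
    lo, hi = 0.0, 1e9
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if oracle_fraction_bound(p_total, mid, kd, tol=1e-13) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
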