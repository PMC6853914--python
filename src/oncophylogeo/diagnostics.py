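"""Posterior-trace summaries: HPD intervals, ESS, Geweke z-scores."""

from __future__ import annotations

import numpy as np

__all__ = ["hpd_interval", "effective_sample_size", "geweke_z", "trace_diagnostics"]


def hpd_interval(samples, mass: float = 0.95):
    """Shortest interval containing ``ceil(mass * n)`` of the samples.

    Parameters
    ----------
    samples : array-like
        Posterior draws (1-D).
    mass : float
        Posterior mass to cover, in (0, 1).
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an HPD interval")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def effective_sample_size(samples) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n].real / (var * n)
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(min(n, n / (1 + 2 * s)))


def geweke_z(samples, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    a = x[: max(2, int(first * n))]
    b = x[-max(2, int(last * n)):]
    va = a.var(ddof=1) / effective_sample_size(a)
    vb = b.var(ddof=1) / effective_sample_size(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def trace_diagnostics(trace_df, burn_in: float = 0.0) -> dict:
    """Per-parameter ESS and Geweke z for a trace DataFrame."""
    out = {}
    n = len(trace_df)
    start = int(burn_in * n)
    for col in trace_df.columns:
        x = np.asarray(trace_df[col], dtype=float)[start:]
        if np.all(~np.isfinite(x)) or np.std(x) == 0:
            out[col] = {"ess": float(len(x)), "geweke_z": 0.0}
        else:
            out[col] = {
                "ess": effective_sample_size(x),
                "geweke_z": geweke_z(x),
            }
    return out
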