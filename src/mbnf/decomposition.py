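"""Empirical mode decomposition of BOLD signals into frequency bands.

Resting-state BOLD fluctuations mix slow (< 0.06 Hz) and faster
(0.06-0.15 Hz) oscillatory components whose connectivity structure can
differ.  Instead of a fixed band-pass filter bank, the decomposition here
is adaptive: plain EMD extracts intrinsic mode functions (IMFs) by
iterative sifting with cubic-spline envelopes, and EEMD stabilises the
decomposition against mode mixing by averaging EMD results over an
ensemble of white-noise-perturbed copies of the signal.

The first IMF of a band-passed BOLD series concentrates in roughly
0.06-0.16 Hz and is used as the high-frequency band; the remaining IMFs
are summed into the low-frequency band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

logger = logging.getLogger(__name__)

__all__ = [
    "ImfSet",
    "EemdParams",
    "BandSignals",
    "emd",
    "eemd",
    "average_frequency",
    "split_bands",
]


@dataclass
class ImfSet:
    """Ordered intrinsic mode functions plus residual for one signal.

    ``imfs[0]`` is the highest-frequency component; average frequencies
    are non-increasing with index.  For plain EMD the decomposition is
    exact: ``sum(imfs) + residual == x`` to floating tolerance.
    """

    imfs: list[np.ndarray] = field(default_factory=list)
    residual: np.ndarray = None
    source_length: int = 0

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


@dataclass
class EemdParams:
    """Ensemble EMD settings.

    ensemble_size : number of noise-perturbed decompositions averaged.
    noise_amplitude : white-noise standard deviation as a fraction of
        the input signal's standard deviation.
    """

    ensemble_size: int = 100
    noise_amplitude: float = 0.2
    max_sift_iterations: int = 50
    sift_sd_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.max_sift_iterations <= 0 or self.sift_sd_threshold <= 0:
            raise ValueError("sift limits must be positive")


@dataclass
class BandSignals:
    """High/low frequency band matrices (P ROIs x T time points)."""

    high: np.ndarray
    low: np.ndarray
    residuals: np.ndarray = None


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima.

    Plateaus are collapsed by carrying the last nonzero slope sign, so a
    flat top counts as a single extremum at its left edge.
    """
    d = np.sign(np.diff(x))
    # replace zeros (flat segments) with the preceding nonzero sign
    nz = d != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nz, np.arange(len(d)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, d[np.clip(idx, 0, None)], d[nz.argmax()])
    turn = np.diff(filled)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int,
                   n_mirror: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to ``n_mirror`` extrema about each end of the support."""
    k = min(n_mirror, len(idx))
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    return (np.concatenate([left_i, idx, right_i]),
            np.concatenate([left_v, val, right_v]))


def _envelope(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    t = np.arange(n)
    ei, ev = _mirror_extend(idx, val, n)
    # drop accidental duplicate abscissae from mirroring a boundary extremum
    ei, keep = np.unique(ei, return_index=True)
    ev = ev[keep]
    if len(ei) >= 4:
        return CubicSpline(ei, ev)(t)
    if len(ei) >= 2:
        return np.interp(t, ei, ev)
    return np.full(n, ev[0])


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def emd(x: np.ndarray, max_sift: int = 50,
        sift_sd_threshold: float = 0.2) -> ImfSet:
    """Decompose a series into IMFs by envelope sifting.

    Sifting subtracts the mean of the cubic-spline upper/lower envelopes
    (through maxima/minima, mirror-extended at the boundaries) until the
    Cauchy criterion ``SD = sum((h_prev - h)^2) / sum(h_prev^2)`` drops
    below ``sift_sd_threshold`` or ``max_sift`` passes are reached.
    Extraction stops when the residual is monotone or has fewer than two
    interior extrema.  ``sum(imfs) + residual`` reconstructs ``x``
    exactly to floating tolerance.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D series")
    if x.size < 8:
        raise ValueError("series too short to decompose (T >= 8 required)")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant input cannot be decomposed")

    result = ImfSet(source_length=x.size)
    residual = x.copy()
    max_imfs = int(np.log2(x.size)) + 1  # extrema count at least halves per IMF
    while len(result.imfs) < max_imfs:
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 2 or _is_monotone(residual):
            break
        h = residual
        for _ in range(max_sift):
            mx, mn = _local_extrema(h)
            if len(mx) < 1 or len(mn) < 1:
                break
            upper = _envelope(mx, h[mx], h.size)
            lower = _envelope(mn, h[mn], h.size)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sift_sd_threshold:
                break
        if np.sum(np.diff(np.signbit(h))) < 2:
            break  # no full oscillation left: this belongs to the residual
        result.imfs.append(h)
        residual = residual - h
    result.residual = residual
    return result


def eemd(x: np.ndarray, params: EemdParams | None = None) -> ImfSet:
    """Ensemble EMD: average EMD over white-noise-perturbed copies.

    For each of ``ensemble_size`` trials, white noise with standard
    deviation ``noise_amplitude * std(x)`` is added and the perturbed
    copy decomposed by :func:`emd`.  The f-th output IMF is the mean of
    the trials' f-th IMFs; trials producing fewer components contribute
    zeros for the missing high indices.  The residual is whatever of
    ``x`` the averaged IMFs do not explain, so ``sum(imfs) + residual``
    still reconstructs ``x`` exactly.

    Only components produced by at least half the trials are kept: a
    mode appearing in a small minority of noise realisations is a
    vestige of that noise (its zero-padded average has negligible
    energy and an arbitrary spectrum), so it is folded into the
    residual instead.
    """
    if params is None:
        params = EemdParams()
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(params.seed)
    scale = params.noise_amplitude * float(np.std(x))
    trials: list[list[np.ndarray]] = []
    for _ in range(params.ensemble_size):
        noise = scale * rng.standard_normal(x.size) if scale > 0 else 0.0
        dec = emd(x + noise, params.max_sift_iterations,
                  params.sift_sd_threshold)
        trials.append(dec.imfs)
    counts = np.bincount([len(t) for t in trials],
                         minlength=max(len(t) for t in trials) + 1)
    produced = np.cumsum(counts[::-1])[::-1]  # trials with >= f imfs
    majority = (params.ensemble_size + 1) // 2
    n_imfs = max(int(np.sum(produced[1:] >= majority)), 1)
    out = ImfSet(source_length=x.size)
    for f in range(n_imfs):
        acc = np.zeros(x.size)
        for t in trials:
            if f < len(t):
                acc += t[f]
        out.imfs.append(acc / params.ensemble_size)
    residual = x.copy()
    for c in out.imfs:  # subtract in extraction order: bit-matches emd
        residual = residual - c
    out.residual = residual
    return out


def average_frequency(imf: np.ndarray, TR: float,
                      method: str = "centroid") -> float:
    """Average frequency of a component in Hz.

    Default is the spectral centroid of the one-sided periodogram over
    (0, Nyquist]; ``method='zero_crossings'`` instead counts sign
    changes (rate = crossings / (2 * duration)).
    """
    imf = np.asarray(imf, dtype=float)
    if not np.any(imf):
        raise ValueError("average frequency undefined for all-zero series")
    if method == "zero_crossings":
        crossings = int(np.sum(np.diff(np.signbit(imf))))
        return crossings / (2.0 * imf.size * TR)
    if method != "centroid":
        raise ValueError(f"unknown method {method!r}")
    f, p = periodogram(imf, fs=1.0 / TR)
    f, p = f[1:], p[1:]  # drop DC
    total = float(np.sum(p))
    if total == 0:
        raise ValueError("zero spectral mass")
    return float(np.sum(f * p) / total)


def split_bands(imfsets: list[ImfSet]) -> BandSignals:
    """Split per-ROI decompositions into high/low frequency matrices.

    High band = IMF1 per ROI; low band = sum of the remaining IMFs
    (the monotone residual trend is excluded).  An ROI with a single IMF
    yields an all-zero low-band row and a logged warning.
    """
    if not imfsets:
        raise ValueError("no decompositions given")
    T = imfsets[0].source_length
    high = np.zeros((len(imfsets), T))
    low = np.zeros((len(imfsets), T))
    residuals = np.zeros((len(imfsets), T))
    for i, dec in enumerate(imfsets):
        if dec.n_imfs == 0:
            raise ValueError(f"ROI {i}: empty decomposition")
        high[i] = dec.imfs[0]
        if dec.n_imfs == 1:
            logger.warning(
                "ROI %d has a single IMF; low-frequency band is zero", i)
        else:
            low[i] = np.sum(dec.imfs[1:], axis=0)
        residuals[i] = dec.residual
    return BandSignals(high=high, low=low, residuals=residuals)
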