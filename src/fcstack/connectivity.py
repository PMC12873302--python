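"""Twelve pairwise functional-connectivity metrics on band-limited epochs.

Each metric maps one epoch (channels x samples) to a symmetric channels x
channels matrix, which is then projected onto the SPD cone with
:func:`fcstack.spd.nearest_spd` (eigenvalue clipping at ``eps``).

The metrics span four domains:

- time: ``Cov`` (biased sample covariance), ``Corr`` (Pearson), ``XCov``
  (circular cross-covariance at the lag maximizing its absolute value over
  all lags, biased normalization), ``XCorr`` (XCov normalized by
  sqrt(Var X * Var Y));
- frequency: ``CSD`` (band-mean cross-spectral magnitude) and ``Coh``
  (band-mean magnitude-squared coherence), both estimated by Welch's method
  with 1-s Hann segments at 50% overlap and averaged over the frequency bins
  inside the band;
- information: ``MI`` (plug-in histogram mutual information, bits, with
  Freedman-Diaconis binning) and ``ECC`` (MI normalized by the geometric mean
  of the marginal entropies);
- analytic signal: ``AECov``/``AECorr`` (covariance/correlation of Hilbert
  amplitude envelopes), ``PLV`` (circular mean length of the phase
  difference), ``wPLV`` (amplitude-weighted PLV).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .bands import BandDefinition, bandpass_epochs, get_band
from .spd import nearest_spd

#: The twelve metric identifiers, in canonical order.
METRIC_IDS = (
    "Cov",
    "Corr",
    "XCov",
    "XCorr",
    "CSD",
    "Coh",
    "MI",
    "ECC",
    "AECov",
    "AECorr",
    "PLV",
    "wPLV",
)

NORMALIZED_METRICS = frozenset(
    {"Corr", "XCorr", "Coh", "ECC", "AECorr", "PLV", "wPLV"}
)

DEFAULT_EPS = 1e-10


def _check_epoch(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError(f"epoch must be (channels >= 2, samples), got {data.shape}")
    if data.shape[1] < 16:
        raise ValueError(f"epoch too short: {data.shape[1]} samples")
    if not np.all(np.isfinite(data)):
        raise ValueError("epoch contains non-finite values")
    return data


def _check_variance(var: np.ndarray, what: str) -> None:
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValueError(f"zero-variance channel(s) {bad.tolist()} in {what}")


# ---------------------------------------------------------------- time domain


def covariance(data: np.ndarray) -> np.ndarray:
    """Biased sample covariance matrix E[(X-EX)(Y-EY)]."""
    data = _check_epoch(data)
    return np.cov(data, bias=True)


def correlation(data: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix."""
    data = _check_epoch(data)
    var = data.var(axis=1)
    _check_variance(var, "correlation")
    c = np.corrcoef(data)
    np.fill_diagonal(c, 1.0)
    return c


def _full_cross_covariance(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circular cross-covariance of all channel pairs at every lag.

    Returns ``(xc, lags)`` where ``xc[i, j, k]`` is the biased (divide by N)
    circular estimate of ``E[(X_i(t) - m_i)(X_j(t - lags[k]) - m_j)]``; lags
    run over ``-floor((N-1)/2) .. ceil((N-1)/2)`` (periodogram convention).
    The circular estimator keeps every lag an average of N products, so a
    time-shifted copy of a channel is recovered with coefficient 1 at the
    true lag.
    """
    n_ch, n = data.shape
    d = data - data.mean(axis=1, keepdims=True)
    F = np.fft.rfft(d, n, axis=1)
    # r[i,j,k] = sum_t d_i[t] d_j[t-k (mod n)]
    R = np.fft.irfft(F[:, None, :] * np.conj(F[None, :, :]), n, axis=-1)
    lags = np.arange(n)
    lags[lags > n // 2] -= n
    return R / n, lags


def cross_covariance(
    data: np.ndarray, return_lags: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Cross-covariance at the lag maximizing its absolute value (signed).

    The search covers every circular lag with biased (divide by N)
    normalization; the diagonal is the lag-0 variance.
    """
    data = _check_epoch(data)
    xc, lags = _full_cross_covariance(data)
    idx = np.argmax(np.abs(xc), axis=-1)
    out = np.take_along_axis(xc, idx[..., None], axis=-1)[..., 0]
    out = 0.5 * (out + out.T)  # symmetric up to fp rounding already
    if return_lags:
        return out, lags[idx]
    return out


def cross_correlation(data: np.ndarray) -> np.ndarray:
    """Cross-covariance at the maximizing lag, normalized by sqrt(VarX VarY)."""
    data = _check_epoch(data)
    var = data.var(axis=1)
    _check_variance(var, "cross-correlation")
    xcov = cross_covariance(data)
    return xcov / np.sqrt(np.outer(var, var))


# ----------------------------------------------------------- frequency domain


def _welch_cross_spectra(
    data: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Welch cross-spectral densities (1-s Hann segments, 50% overlap)."""
    n = data.shape[1]
    nperseg = min(int(round(fs)), n)
    f, S = signal.csd(
        data[:, None, :],
        data[None, :, :],
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        axis=-1,
    )
    return f, S


def _band_bins(f: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (f >= band.f_lo) & (f <= band.f_hi)
    if not np.any(mask):
        raise ValueError(
            f"no Welch frequency bin falls inside band {band.name!r} "
            f"({band.f_lo}-{band.f_hi} Hz)"
        )
    return mask


def csd_magnitude(
    data: np.ndarray, fs: float, band: str | BandDefinition
) -> np.ndarray:
    """Band-mean cross-spectral density magnitude |S_XY|."""
    data = _check_epoch(data)
    band = get_band(band)
    f, S = _welch_cross_spectra(data, fs)
    mask = _band_bins(f, band)
    return np.abs(S[..., mask]).mean(axis=-1)


def coherence(
    data: np.ndarray, fs: float, band: str | BandDefinition
) -> np.ndarray:
    """Band-mean magnitude-squared coherence |S_XY|^2 / (S_XX S_YY)."""
    data = _check_epoch(data)
    band = get_band(band)
    f, S = _welch_cross_spectra(data, fs)
    mask = _band_bins(f, band)
    S = S[..., mask]
    auto = np.real(np.einsum("iif->if", S))
    _check_variance(auto.min(axis=1), "coherence")
    coh = (np.abs(S) ** 2 / (auto[:, None, :] * auto[None, :, :])).mean(axis=-1)
    np.fill_diagonal(coh, 1.0)
    return coh


# --------------------------------------------------------- information domain


def freedman_diaconis_edges(
    samples: np.ndarray, max_bins: int = 512
) -> np.ndarray:
    """Histogram bin edges by the Freedman-Diaconis rule for one channel.

    Falls back to Sturges' rule (with a warning) when the interquartile range
    is zero.  ``samples`` may pool several epochs of the same subject.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("constant channel: histogram undefined")
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        warnings.warn(
            "Freedman-Diaconis IQR is zero; falling back to Sturges' rule",
            RuntimeWarning,
            stacklevel=2,
        )
        n_bins = int(np.ceil(np.log2(n))) + 1
    else:
        width = 2.0 * iqr * n ** (-1.0 / 3.0)
        n_bins = int(np.ceil((hi - lo) / width))
    n_bins = int(np.clip(n_bins, 2, max_bins))
    return np.linspace(lo, hi, n_bins + 1)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    data: np.ndarray,
    bin_edges: list[np.ndarray] | None = None,
    normalized: bool = False,
) -> np.ndarray:
    """Histogram mutual information (bits) for all channel pairs.

    ``bin_edges`` gives one edge array per channel (typically computed from
    the subject's pooled samples with :func:`freedman_diaconis_edges` and
    shared across that subject's epochs); if omitted, edges are derived from
    this epoch alone.  The diagonal holds the marginal entropy H(X) (MI of a
    channel with itself); for the normalized variant (``ECC``, mutual
    information over the geometric mean of marginal entropies) the diagonal
    is 1.  The joint histogram is computed once per unordered pair, so the
    matrix is exactly symmetric.
    """
    data = _check_epoch(data)
    n_ch, n = data.shape
    if bin_edges is None:
        bin_edges = [freedman_diaconis_edges(data[i]) for i in range(n_ch)]
    if len(bin_edges) != n_ch:
        raise ValueError("need one bin-edge array per channel")

    # per-channel marginal entropies from the shared edges
    H = np.empty(n_ch)
    for i in range(n_ch):
        counts, _ = np.histogram(data[i], bins=bin_edges[i])
        H[i] = _entropy_bits(counts / n)
    if normalized:
        _check_variance(H, "entropy correlation (zero-entropy channel)")

    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            joint, _, _ = np.histogram2d(
                data[i], data[j], bins=[bin_edges[i], bin_edges[j]]
            )
            p = joint / n
            hx = _entropy_bits(p.sum(axis=1))
            hy = _entropy_bits(p.sum(axis=0))
            mi = max(hx + hy - _entropy_bits(p.ravel()), 0.0)
            out[i, j] = out[j, i] = mi
    if normalized:
        out = out / np.sqrt(np.outer(H, H))
        np.fill_diagonal(out, 1.0)
    else:
        np.fill_diagonal(out, H)
    return out


# ------------------------------------------------------------ analytic domain


def _analytic(data: np.ndarray) -> np.ndarray:
    data = _check_epoch(data)
    A = signal.hilbert(data, axis=-1)
    env = np.abs(A)
    bad = np.flatnonzero(env.max(axis=1) == 0)
    if bad.size:
        raise ValueError(f"all-zero channel(s) {bad.tolist()} in analytic transform")
    return A


def amplitude_envelope_cov(data: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Covariance (or Pearson correlation) of Hilbert amplitude envelopes."""
    env = np.abs(_analytic(data))
    if normalized:
        _check_variance(env.var(axis=1), "amplitude-envelope correlation")
        c = np.corrcoef(env)
        np.fill_diagonal(c, 1.0)
        return c
    return np.cov(env, bias=True)


def phase_locking_value(data: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Phase-locking value |E[exp(i dphi)]|, optionally amplitude-weighted.

    The weighted variant divides |E[|X||Y| exp(i dphi)]| by E[|X||Y|], which
    down-weights phase estimates taken where power is low.  Both variants
    have unit diagonal and entries in [0, 1].
    """
    A = _analytic(data)
    n = A.shape[1]
    env = np.abs(A)
    if weighted:
        num = np.abs(A @ A.conj().T) / n  # |E[|X||Y| e^{i dphi}]|
        den = (env @ env.T) / n
        out = num / den
    else:
        U = A / env
        out = np.abs(U @ U.conj().T) / n
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return np.clip(out, 0.0, 1.0)


# -------------------------------------------------------------- dispatch


def fc_matrix(
    data: np.ndarray,
    metric: str,
    fs: float | None = None,
    band: str | BandDefinition | None = None,
    bin_edges: list[np.ndarray] | None = None,
    project: bool = True,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Compute one connectivity matrix for a (band-limited) epoch.

    ``fs`` and ``band`` are required for the spectral metrics; ``bin_edges``
    is an optional shared binning for the information metrics.  With
    ``project=True`` (default) the result is clipped onto the SPD cone.
    """
    if metric == "Cov":
        M = covariance(data)
    elif metric == "Corr":
        M = correlation(data)
    elif metric == "XCov":
        M = cross_covariance(data)
    elif metric == "XCorr":
        M = cross_correlation(data)
    elif metric in ("CSD", "Coh"):
        if fs is None or band is None:
            raise ValueError(f"{metric} requires fs and band")
        M = csd_magnitude(data, fs, band) if metric == "CSD" else coherence(data, fs, band)
    elif metric in ("MI", "ECC"):
        M = mutual_information(data, bin_edges, normalized=(metric == "ECC"))
    elif metric in ("AECov", "AECorr"):
        M = amplitude_envelope_cov(data, normalized=(metric == "AECorr"))
    elif metric in ("PLV", "wPLV"):
        M = phase_locking_value(data, weighted=(metric == "wPLV"))
    else:
        raise ValueError(f"unknown FC metric {metric!r}; choose from {METRIC_IDS}")
    if project:
        M = nearest_spd(M, eps=eps)
    return M


class FCTransformer:
    """sklearn-style transformer: raw epochs -> SPD connectivity matrices.

    Band-pass filters each epoch into ``band`` and applies the chosen metric,
    projecting the result onto the SPD cone.

    Parameters
    ----------
    band : str
        One of the five canonical bands (or a BandDefinition).
    metric : str
        One of :data:`METRIC_IDS`.
    fs : float
        Sampling rate of the input epochs.
    eps : float
        SPD eigenvalue floor.
    """

    def __init__(self, band="alpha", metric="Cov", fs=500.0, eps=DEFAULT_EPS):
        self.band = band
        self.metric = metric
        self.fs = fs
        self.eps = eps

    def get_params(self, deep=True):
        return {"band": self.band, "metric": self.metric, "fs": self.fs, "eps": self.eps}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X, bin_edges=None) -> np.ndarray:
        """Transform epochs (n_epochs, n_channels, n_samples) -> (n, c, c)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        filt = bandpass_epochs(X, self.fs, self.band)
        return np.stack(
            [
                fc_matrix(
                    ep,
                    self.metric,
                    fs=self.fs,
                    band=self.band,
                    bin_edges=bin_edges,
                    eps=self.eps,
                )
                for ep in filt
            ]
        )

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y).transform(X, **kw)
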