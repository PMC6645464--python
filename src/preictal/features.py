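"""Multiscale features on sliding 4-s windows (2-s steps).

Four feature groups per window:

* ``lfp_power`` -- multitaper power spectrum of each LFP channel averaged
  within ten frequency bands (0.3-500 Hz);
* ``lfp_coherence`` -- per band: leading eigenvalue and eigenvector
  (eigenvector centrality) of the pairwise magnitude-squared coherence
  matrix (diagonal zeroed), plus the mean and variance of its off-diagonal
  entries;
* ``mua_count`` -- total threshold-crossing count per channel;
* ``mua_correlation`` -- leading eigenvalue/eigenvector of the pairwise
  lagged-correlation-extremum matrices for the fine count series (0.5 ms
  bins), the coarse count series (100 ms bins) and the MUA envelope, with
  lags up to +/-50 ms.

Multitaper estimates use DPSS tapers with a 2 Hz half-bandwidth on the 4-s
window (time-half-bandwidth product NW = 8, K = 2*NW - 1 = 15 tapers).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy.signal.windows import dpss

from .bands import BANDS
from .dataset import STEP_S, WINDOW_S
from .preprocess import DerivedStreams

__all__ = [
    "GROUPS",
    "WindowGrid",
    "window_grid",
    "multitaper_psd",
    "multitaper_band_power",
    "band_coherence_matrices",
    "eigen_centrality",
    "window_total_counts",
    "lagged_correlation_extrema",
    "extract_features",
    "combine_groups",
    "parse_feature_name",
    "feature_dim",
]

GROUPS = ("lfp_power", "lfp_coherence", "mua_count", "mua_correlation")
HALF_BW_HZ = 2.0
CORR_SOURCES = ("count", "coarse", "env")
MAX_LAG_S = 0.05
COARSE_BIN_S = 0.1


@dataclass(frozen=True)
class WindowGrid:
    starts: np.ndarray
    window_s: float = WINDOW_S
    step_s: float = STEP_S

    @property
    def n_windows(self) -> int:
        return self.starts.size


def window_grid(duration: float, t0: float = 0.0) -> WindowGrid:
    """All 4-s windows on the 2-s grid fully inside [t0, t0 + duration]."""
    n = int(np.floor((duration - WINDOW_S) / STEP_S)) + 1
    return WindowGrid(t0 + STEP_S * np.arange(max(n, 0)))


@lru_cache(maxsize=4)
def _tapers(n: int, nw: float = 8.0) -> np.ndarray:
    k = int(2 * nw - 1)
    w = dpss(n, nw, Kmax=k)
    return w / np.sqrt((w**2).sum(axis=1, keepdims=True))  # unit energy


def _tapered_fft(x: np.ndarray, fs: float, fmax: float = 500.0):
    """Tapered FFTs X[ch, taper, freq] restricted to (0, fmax]."""
    x = np.atleast_2d(x)
    n = x.shape[-1]
    w = _tapers(n)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    sel = (f > 0) & (f <= fmax)
    X = sfft.rfft(x[:, None, :] * w[None, :, :], axis=-1)[:, :, sel]
    return f[sel], X


def multitaper_psd(x: np.ndarray, fs: float):
    """One-sided multitaper PSD (signal-units^2 per Hz) per channel."""
    f, X = _tapered_fft(x, fs)
    psd = (2.0 / fs) * np.mean(np.abs(X) ** 2, axis=1)
    return f, psd


def _band_slices(f: np.ndarray, bands) -> list[np.ndarray]:
    out = []
    for i, (lo, hi) in enumerate(bands):
        if i == len(bands) - 1:
            out.append((f >= lo) & (f <= hi))
        else:
            out.append((f >= lo) & (f < hi))
    return out


def multitaper_band_power(x: np.ndarray, fs: float, bands=BANDS) -> np.ndarray:
    """Mean PSD within each band -> (channels, n_bands)."""
    f, psd = multitaper_psd(x, fs)
    return np.stack([psd[:, m].mean(axis=1) for m in _band_slices(f, bands)], axis=1)


def band_coherence_matrices(x: np.ndarray, fs: float, bands=BANDS) -> np.ndarray:
    """Pairwise magnitude-squared coherence averaged per band.

    Returns (n_bands, ch, ch); symmetric, entries in [0, 1], diagonal zeroed.
    Zero-variance channels get zero rows/columns.
    """
    x = np.atleast_2d(x)
    f, X = _tapered_fft(x, fs)
    S = np.einsum("atf,btf->abf", X, X.conj())  # cross-spectra summed over tapers
    P = np.real(np.einsum("aaf->af", S))
    ok = x.std(axis=1) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = (np.abs(S) ** 2) / (P[:, None, :] * P[None, :, :])
    msc = np.nan_to_num(msc, nan=0.0, posinf=0.0)
    out = np.empty((len(bands), x.shape[0], x.shape[0]))
    for i, m in enumerate(_band_slices(f, bands)):
        M = msc[:, :, m].mean(axis=2) if m.any() else np.zeros(out.shape[1:])
        M[~ok, :] = 0.0
        M[:, ~ok] = 0.0
        np.fill_diagonal(M, 0.0)
        out[i] = np.clip(M, 0.0, 1.0)
    return out


def eigen_centrality(M: np.ndarray, tol: float = 1e-8) -> tuple[float, np.ndarray]:
    """Leading eigenvalue and unit-norm leading eigenvector of a symmetric matrix.

    Sign fixed so the largest-magnitude entry is positive (for a nonnegative
    matrix this is the Perron vector: the eigenvector centrality). The
    eigenvector of the *algebraically* largest eigenvalue is returned, so
    correlation matrices with negative entries are handled as-is.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(M - M.T)) > tol:
        raise ValueError("matrix is not symmetric within tolerance")
    n = M.shape[0]
    if not M.any():
        v = np.zeros(n)
        v[0] = 1.0
        return 0.0, v
    w, V = np.linalg.eigh((M + M.T) / 2)
    lam = float(w[-1])
    v = V[:, -1]
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return lam, v


def window_total_counts(counts: np.ndarray, bin_s: float, grid: WindowGrid, t0: float = 0.0) -> np.ndarray:
    """Exact per-channel event totals per window -> (n_windows, channels)."""
    per_win = int(round(grid.window_s / bin_s))
    out = np.empty((grid.n_windows, counts.shape[0]), dtype=np.int64)
    for w, ts in enumerate(grid.starts):
        i0 = int(round((ts - t0) / bin_s))
        out[w] = counts[:, i0 : i0 + per_win].sum(axis=1)
    return out


def lagged_correlation_extrema(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Signed extremum over lags in [-L, L] of the pairwise Pearson correlation.

    At each lag the two series are truncated to their common support and the
    correlation uses that support's means and SDs. Returns a symmetric matrix
    with zero diagonal; pairs involving a zero-variance channel are zero.
    The per-pair extremum is the value of largest absolute magnitude (sign
    preserved); ties resolve to the smallest lag.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    ch, T = x.shape
    L = int(max_lag)
    if L >= T:
        raise ValueError("max lag must be smaller than the window length")
    ok = x.std(axis=1) > 0
    iu, ju = np.triu_indices(ch, k=1)
    out = np.zeros((ch, ch))
    if iu.size == 0:
        return out
    # raw lagged cross-sums for every pair at once, via FFT
    nfft = sfft.next_fast_len(T + L)
    F = sfft.rfft(x, nfft)
    cc = sfft.irfft(F[iu] * F[ju].conj(), nfft)  # cc[p, l] = sum_t a[t+l] b[t]
    lags = np.concatenate([np.arange(0, L + 1), np.arange(-L, 0)])  # order by |lag|-friendly scan below
    cross = np.concatenate([cc[:, : L + 1], cc[:, nfft - L :]], axis=1)  # lags 0..L, -L..-1
    lag_order = np.argsort(np.abs(lags), kind="stable")  # 0, 1, -1?, ... ties -> earlier entry
    # prefix sums for truncated means / SDs
    c1 = np.concatenate([np.zeros((ch, 1)), np.cumsum(x, axis=1)], axis=1)
    c2 = np.concatenate([np.zeros((ch, 1)), np.cumsum(x**2, axis=1)], axis=1)
    r = np.zeros((iu.size, lags.size))
    for k, l in enumerate(lags):
        if l >= 0:  # a[l:], b[:T-l]
            na = T - l
            sa = c1[iu, T] - c1[iu, l]
            qa = c2[iu, T] - c2[iu, l]
            sb = c1[ju, na]
            qb = c2[ju, na]
        else:  # a[:T+l], b[-l:]
            na = T + l
            sa = c1[iu, na]
            qa = c2[iu, na]
            sb = c1[ju, T] - c1[ju, -l]
            qb = c2[ju, T] - c2[ju, -l]
        va = qa - sa**2 / na
        vb = qb - sb**2 / na
        denom = np.sqrt(np.maximum(va, 0.0) * np.maximum(vb, 0.0))
        num = cross[:, k] - sa * sb / na
        with np.errstate(divide="ignore", invalid="ignore"):
            r[:, k] = np.where(denom > 1e-12, num / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    best = lag_order[np.argmax(np.abs(r[:, lag_order]), axis=1)]
    vals = r[np.arange(iu.size), best]
    bad = ~ok[iu] | ~ok[ju]
    vals[bad] = 0.0
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


# ---------------------------------------------------------------------------
# feature-vector assembly


def _names_lfp_power(ch: int) -> list[str]:
    return [f"pow|b{b}|c{c}" for b in range(len(BANDS)) for c in range(ch)]


def _names_lfp_coherence(ch: int) -> list[str]:
    names = []
    for b in range(len(BANDS)):
        names.append(f"coh|b{b}|lam")
        names += [f"coh|b{b}|ev|c{c}" for c in range(ch)]
        names += [f"coh|b{b}|mean", f"coh|b{b}|var"]
    return names


def _names_mua_count(ch: int) -> list[str]:
    return [f"cnt|c{c}" for c in range(ch)]


def _names_mua_correlation(ch: int) -> list[str]:
    names = []
    for src in CORR_SOURCES:
        names.append(f"mcorr|{src}|lam")
        names += [f"mcorr|{src}|ev|c{c}" for c in range(ch)]
    return names


def feature_dim(group: str, n_channels: int) -> int:
    """Length of one window's feature vector for a group."""
    return len(
        {
            "lfp_power": _names_lfp_power,
            "lfp_coherence": _names_lfp_coherence,
            "mua_count": _names_mua_count,
            "mua_correlation": _names_mua_correlation,
        }[group](n_channels)
    )


def parse_feature_name(name: str) -> dict:
    """Decode a column name into (group, band, channel, source, kind) tags."""
    parts = name.split("|")
    tag = {"group": None, "band": None, "channel": None, "source": None, "kind": None}
    head = parts[0]
    if head == "pow":
        tag.update(group="lfp_power", band=int(parts[1][1:]), channel=int(parts[2][1:]), kind="power")
    elif head == "coh":
        tag.update(group="lfp_coherence", band=int(parts[1][1:]), kind=parts[2])
        if parts[2] == "ev":
            tag["channel"] = int(parts[3][1:])
    elif head == "cnt":
        tag.update(group="mua_count", channel=int(parts[1][1:]), kind="count")
    elif head == "mcorr":
        tag.update(group="mua_correlation", source=parts[1], kind=parts[2])
        if parts[2] == "ev":
            tag["channel"] = int(parts[3][1:])
    else:
        raise ValueError(f"untagged feature name: {name}")
    return tag


def _coherence_features(C: np.ndarray) -> np.ndarray:
    """Per band: lambda1, centrality vector, mean and variance of the upper triangle."""
    n_bands, ch, _ = C.shape
    iu, ju = np.triu_indices(ch, k=1)
    out = np.empty(n_bands * (ch + 3))
    pos = 0
    for b in range(n_bands):
        lam, v = eigen_centrality(C[b])
        tri = C[b][iu, ju]
        out[pos] = lam
        out[pos + 1 : pos + 1 + ch] = v
        out[pos + 1 + ch] = tri.mean()
        out[pos + 2 + ch] = tri.var()
        pos += ch + 3
    return out


def _correlation_features(mats: dict[str, np.ndarray]) -> np.ndarray:
    ch = next(iter(mats.values())).shape[0]
    out = np.empty(len(CORR_SOURCES) * (ch + 1))
    pos = 0
    for src in CORR_SOURCES:
        lam, v = eigen_centrality(mats[src])
        out[pos] = lam
        out[pos + 1 : pos + 1 + ch] = v
        pos += ch + 1
    return out


def extract_features(
    streams: DerivedStreams,
    bands=BANDS,
    max_lag_s: float = MAX_LAG_S,
    groups=GROUPS,
) -> dict[str, pd.DataFrame]:
    """Compute the selected feature groups for every 4-s window.

    Windows overlapping a flagged artifact interval are dropped. Returns one
    window-indexed DataFrame per group.
    """
    lfp = streams.lfp
    counts = streams.counts
    env = streams.envelope
    ch = lfp.signal.shape[0]
    duration = lfp.signal.shape[1] / lfp.fs
    grid = window_grid(duration, lfp.t0)
    keep = np.ones(grid.n_windows, dtype=bool)
    for a, b in streams.artifact_intervals:
        keep &= (grid.starts + WINDOW_S <= a) | (grid.starts >= b)

    from .preprocess import coarse_counts as _coarse

    coarse = _coarse(counts, COARSE_BIN_S)
    lag_fine = int(round(max_lag_s / counts.bin_s))
    lag_coarse = int(max_lag_s // coarse.bin_s)  # sub-bin lag budget -> 0 (zero-lag Pearson)
    lag_env = int(round(max_lag_s * env.fs))

    rows = {g: [] for g in groups}
    times = []
    n_lfp = int(round(WINDOW_S * lfp.fs))
    n_cnt = int(round(WINDOW_S / counts.bin_s))
    n_crs = int(round(WINDOW_S / coarse.bin_s))
    n_env = int(round(WINDOW_S * env.fs))
    for w, ts in enumerate(grid.starts):
        if not keep[w]:
            continue
        i_lfp = int(round((ts - lfp.t0) * lfp.fs))
        lfp_w = lfp.signal[:, i_lfp : i_lfp + n_lfp]
        i_cnt = int(round((ts - counts.t0) / counts.bin_s))
        cnt_w = counts.counts[:, i_cnt : i_cnt + n_cnt]
        i_crs = int(round((ts - coarse.t0) / coarse.bin_s))
        crs_w = coarse.counts[:, i_crs : i_crs + n_crs]
        i_env = int(round((ts - env.t0) * env.fs))
        env_w = env.envelope[:, i_env : i_env + n_env]
        times.append(ts)
        if "lfp_power" in groups:
            rows["lfp_power"].append(multitaper_band_power(lfp_w, lfp.fs, bands).T.ravel())
        if "lfp_coherence" in groups:
            C = band_coherence_matrices(lfp_w, lfp.fs, bands)
            rows["lfp_coherence"].append(_coherence_features(C))
        if "mua_count" in groups:
            rows["mua_count"].append(cnt_w.sum(axis=1).astype(float))
        if "mua_correlation" in groups:
            mats = {
                "count": lagged_correlation_extrema(cnt_w, lag_fine),
                "coarse": lagged_correlation_extrema(crs_w, lag_coarse),
                "env": lagged_correlation_extrema(env_w, lag_env),
            }
            rows["mua_correlation"].append(_correlation_features(mats))

    idx = pd.Index(times, name="t")
    namers = {
        "lfp_power": _names_lfp_power,
        "lfp_coherence": _names_lfp_coherence,
        "mua_count": _names_mua_count,
        "mua_correlation": _names_mua_correlation,
    }
    return {
        g: pd.DataFrame(np.asarray(rows[g]).reshape(len(times), -1), index=idx, columns=namers[g](ch))
        for g in groups
    }


def combine_groups(frames: dict[str, pd.DataFrame], groups=GROUPS) -> pd.DataFrame:
    """Concatenate per-group feature tables column-wise (shared window index)."""
    return pd.concat([frames[g] for g in groups], axis=1)
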