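"""Synthetic multichannel broadband recordings with planted preictal effects.

The generator emulates the statistical structure the downstream analysis
assumes, with exact ground truth:

* a pink (1/f power) Gaussian background per channel, band-limited below the
  MUA detection band;
* shared narrowband latent sources per frequency band, mixed into every
  channel, producing controllable inter-channel coherence;
* extracellular action potentials: a fixed biphasic ~1 ms template inserted
  at Poisson times (2 ms refractory), negative-leading so the -3 SD crossing
  rule fires exactly once per event;
* a two-state (interictal/preictal) modulation of spike rate, band power and
  coherence via configurable multipliers.

The MUA band (>250 Hz) noise floor is amplitude-bounded: it is a three-sine
mixture whose peak stays below 2.5x its own SD, with any Gaussian content in
that band kept at least an order of magnitude smaller. A -3 SD threshold is
therefore never reached by noise, and detected threshold crossings correspond
one-to-one to the inserted spikes -- the planted Poisson counts are exact
ground truth for the detection stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .bands import BANDS, validate_bands
from .dataset import INTERICTAL, PREICTAL, STEP_S, WindowTimeline
from .preprocess import BroadbandRecording

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_recording",
    "simulate_feature_timeline",
    "band_noise_power",
    "expected_band_coherence",
]

MAX_BAND_EDGE = 500.0  # highest synthesized LFP band edge, Hz


@dataclass
class SynthConfig:
    """Study conditions for one synthetic recording.

    Effect multipliers are applied during preictal state only; all-ones
    multipliers make the two states statistically exchangeable. Default
    effect sizes (spike rate x2.0, band power x1.5 in two bands, coherence
    mixing x1.5) are the package's strong-effect conditions; they are free
    parameters of the generator, not estimates of real preictal physiology.
    """

    n_channels: int = 16
    fs: float = 10_000.0
    duration: float | None = None  # derived from seizure layout when None
    file_length: float = 2_400.0  # native 40-minute acquisition files
    # background
    bg_sigma: float = 1.0
    bg_band: tuple[float, float] = (0.3, 200.0)
    bg_slope: float = -1.0  # PSD ~ f**slope (pink)
    hf_noise_sigma: float = 0.032  # flat Gaussian floor 200-500 Hz
    sine_floor_sigma: float = 0.3  # bounded MUA-band noise floor
    sine_floor_band: tuple[float, float] = (600.0, 3_800.0)
    # spikes
    spike_rate: float = 5.0  # events/s per channel, interictal
    spike_amp: float = 6.0  # peak amplitude in multiples of bg_sigma
    spike_refractory: float = 2e-3
    rate_corr_depth: float = 0.3  # shared slow rate co-fluctuation depth
    # shared narrowband sources: band index -> per-channel shared power
    band_mixing: dict[int, float] | None = None
    power_bands: tuple[int, ...] = (6, 7)  # 50-80, 80-150 Hz
    coh_bands: tuple[int, ...] = (2, 4)  # 8-12, 18-25 Hz
    # preictal / interictal effect ratios
    rate_mult: float = 2.0
    power_mult: float = 1.5
    coh_mult: float = 1.5
    rate_corr_mult: float = 1.5
    # seizure layout: preictal state occupies [onset - preictal_state_span, onset)
    seizure_times: tuple[float, ...] | None = None
    preictal_state_span: float = 130.0
    duration_per_state: float = 300.0  # alternating layout when no seizures given
    keep_latents: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        validate_bands(BANDS)
        if self.fs <= 2 * MAX_BAND_EDGE:
            raise ValueError("fs must exceed twice the highest synthesized band edge (500 Hz)")
        for name in ("bg_sigma", "spike_rate", "hf_noise_sigma", "sine_floor_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.spike_rate > 0 and self.spike_amp <= 3:
            raise ValueError("spike_amp must exceed 3 to guarantee detectability at -3 SD")
        if self.band_mixing is None:
            mix = {}
            for b in self.power_bands:
                mix[b] = 1.0 * band_noise_power(self, b)
            for b in self.coh_bands:
                mix[b] = mix.get(b, 0.0) + 0.4 * band_noise_power(self, b)
            self.band_mixing = mix
        if self.seizure_times is not None:
            ext = self.extent
            for o in self.seizure_times:
                if not (0 < o <= ext):
                    raise ValueError("seizure_times must lie within the recording extent")

    @property
    def extent(self) -> float:
        if self.duration is not None:
            return float(self.duration)
        if self.seizure_times:
            return float(max(self.seizure_times) + 2 * self.duration_per_state)
        return 2 * self.duration_per_state

    def state_intervals(self) -> list[tuple[float, float, int]]:
        """(t0, t1, state) tiles covering the recording without overlap."""
        ext = self.extent
        if self.seizure_times:
            marks = []
            for o in sorted(self.seizure_times):
                marks.append((max(0.0, o - self.preictal_state_span), min(o, ext)))
            out = []
            cur = 0.0
            for a, b in marks:
                a = max(a, cur)
                if a > cur:
                    out.append((cur, a, INTERICTAL))
                if b > a:
                    out.append((a, b, PREICTAL))
                cur = max(cur, b)
            if cur < ext:
                out.append((cur, ext, INTERICTAL))
            return out
        out = []
        t, state = 0.0, INTERICTAL
        while t < ext - 1e-9:
            t1 = min(t + self.duration_per_state, ext)
            out.append((t, t1, state))
            t, state = t1, 1 - state
        return out


@dataclass
class GroundTruth:
    spike_times: list[np.ndarray]  # per channel, seconds
    state_intervals: list[tuple[float, float, int]]
    effect_params: dict
    latent_sources: dict[int, np.ndarray] | None = None

    def spike_count(self, channel: int, t0: float, t1: float) -> int:
        st = self.spike_times[channel]
        return int(np.count_nonzero((st >= t0) & (st < t1)))


def band_noise_power(cfg: SynthConfig, band: int | tuple[float, float]) -> float:
    """Analytic channel-independent noise power inside an LFP band.

    Integrates the generator's background PSD (pink piece plus the flat
    high-frequency Gaussian floor) over the band; the bounded sine floor lies
    above 500 Hz and does not contribute.
    """
    lo, hi = BANDS[band] if isinstance(band, int) else band
    g0, g1 = cfg.bg_band
    p = 0.0
    if cfg.bg_sigma > 0 and hi > g0 and lo < g1:
        a, b = max(lo, g0), min(hi, g1)
        if cfg.bg_slope == -1.0:
            frac = math.log(b / a) / math.log(g1 / g0)
        else:
            s = cfg.bg_slope + 1
            frac = (b**s - a**s) / (g1**s - g0**s)
        p += cfg.bg_sigma**2 * frac
    h0, h1 = cfg.bg_band[1], MAX_BAND_EDGE
    if cfg.hf_noise_sigma > 0 and hi > h0 and lo < h1:
        p += cfg.hf_noise_sigma**2 * (min(hi, h1) - max(lo, h0)) / (h1 - h0)
    return p


def expected_band_coherence(cfg: SynthConfig, band: int, state: int = INTERICTAL) -> float:
    """Closed-form magnitude-squared coherence of the one-factor band model.

    With shared in-band power s = alpha^2 v per channel and independent
    in-band noise power n, the MSC between two channels is s^2 / (s + n)^2.
    """
    s = (cfg.band_mixing or {}).get(band, 0.0)
    if state == PREICTAL:
        if band in cfg.power_bands:
            s = s * cfg.power_mult
        if band in cfg.coh_bands:
            s = s * cfg.coh_mult**2
    n = band_noise_power(cfg, band)
    if s <= 0:
        return 0.0
    return s**2 / (s + n) ** 2


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float,
                variance: float, slope: float = 0.0) -> np.ndarray:
    """Gaussian noise with PSD ~ f**slope confined to [lo, hi] Hz (FFT synthesis)."""
    if variance <= 0:
        return np.zeros(n)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros(f.size)
    sel = (f >= lo) & (f <= hi) & (f > 0)
    amp[sel] = f[sel] ** (slope / 2.0)
    coef = amp * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    x = sfft.irfft(coef, n)
    sd = x.std()
    if sd > 0:
        x *= math.sqrt(variance) / sd
    return x


def _spike_template(fs: float, amp: float) -> np.ndarray:
    """Biphasic waveform: 0.4 ms negative lobe (peak -amp), 0.6 ms positive lobe."""
    n_neg = max(2, int(round(0.4e-3 * fs)))
    n_pos = max(2, int(round(0.6e-3 * fs)))
    neg = -amp * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = 0.4 * amp * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return np.concatenate([neg, pos])


def _poisson_times(rng, rate_of_t, r_peak: float, duration: float, refractory: float) -> np.ndarray:
    """Inhomogeneous Poisson via thinning, then a refractory sweep."""
    if r_peak <= 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(r_peak * duration)
    t = np.sort(rng.uniform(0, duration, n))
    keep = rng.uniform(0, 1, n) < rate_of_t(t) / r_peak
    t = t[keep]
    if t.size == 0:
        return t
    out = [t[0]]
    for ti in t[1:]:
        if ti - out[-1] >= refractory:
            out.append(ti)
    return np.asarray(out)


def simulate_recording(cfg: SynthConfig) -> tuple[BroadbandRecording, GroundTruth]:
    """Synthesize a broadband recording and its exact ground truth."""
    fs = cfg.fs
    ext = cfg.extent
    n = int(round(ext * fs))
    states = cfg.state_intervals()
    pre_mask = np.zeros(n, dtype=bool)
    for a, b, s in states:
        if s == PREICTAL:
            pre_mask[int(round(a * fs)) : int(round(b * fs))] = True

    ss = np.random.SeedSequence(cfg.seed)
    shared_rng = np.random.default_rng(ss.spawn(1)[0])
    chan_rngs = [np.random.default_rng(c) for c in np.random.SeedSequence((cfg.seed, 1)).spawn(cfg.n_channels)]

    # shared narrowband latent sources (unit variance) + their state envelopes
    latents: dict[int, np.ndarray] = {}
    envelopes: dict[int, np.ndarray] = {}
    for b, s_pow in sorted((cfg.band_mixing or {}).items()):
        if s_pow <= 0:
            continue
        lo, hi = BANDS[b]
        latents[b] = _band_noise(shared_rng, n, fs, lo, hi, 1.0)
        g = np.ones(n)
        mult = 1.0
        if b in cfg.power_bands:
            mult *= math.sqrt(cfg.power_mult)
        if b in cfg.coh_bands:
            mult *= cfg.coh_mult
        if mult != 1.0:
            g[pre_mask] = mult
        envelopes[b] = g

    # shared slow signal driving correlated spike-rate fluctuations
    slow = _band_noise(shared_rng, n, fs, 0.2, 1.0, 1.0) if cfg.rate_corr_depth > 0 else None

    nyq_sine_hi = min(cfg.sine_floor_band[1], 0.45 * fs)
    template = _spike_template(fs, cfg.spike_amp * cfg.bg_sigma)

    sig = np.empty((cfg.n_channels, n), dtype=np.float64)
    spike_times: list[np.ndarray] = []
    tgrid = None
    for c in range(cfg.n_channels):
        rng = chan_rngs[c]
        x = _band_noise(rng, n, fs, cfg.bg_band[0], cfg.bg_band[1], cfg.bg_sigma**2, cfg.bg_slope)
        x += _band_noise(rng, n, fs, cfg.bg_band[1], MAX_BAND_EDGE, cfg.hf_noise_sigma**2)
        if cfg.sine_floor_sigma > 0:
            freqs = rng.uniform(cfg.sine_floor_band[0], nyq_sine_hi, 3)
            phases = rng.uniform(0, 2 * np.pi, 3)
            a = cfg.sine_floor_sigma * math.sqrt(2.0 / 3.0)
            if tgrid is None:
                tgrid = np.arange(n) / fs
            for fq, ph in zip(freqs, phases):
                x += a * np.sin(2 * np.pi * fq * tgrid + ph)
        for b, z in latents.items():
            alpha = math.sqrt(cfg.band_mixing[b])
            x += alpha * envelopes[b] * z
        # spikes
        if cfg.spike_rate > 0:
            depth_i = cfg.rate_corr_depth
            depth_p = cfg.rate_corr_depth * cfg.rate_corr_mult

            def rate_of_t(t):
                idx = np.minimum((t * fs).astype(np.int64), n - 1)
                base = np.where(pre_mask[idx], cfg.spike_rate * cfg.rate_mult, cfg.spike_rate)
                if slow is None:
                    return base
                depth = np.where(pre_mask[idx], depth_p, depth_i)
                return base * (1.0 + depth * np.tanh(slow[idx]))

            r_peak = cfg.spike_rate * max(cfg.rate_mult, 1.0) * (1.0 + max(depth_i, depth_p))
            st = _poisson_times(rng, rate_of_t, r_peak, ext, cfg.spike_refractory)
            st = st[(st * fs).astype(np.int64) + template.size < n]
            for ti in st:
                i0 = int(ti * fs)
                x[i0 : i0 + template.size] += template
            spike_times.append(st)
        else:
            spike_times.append(np.empty(0))
        sig[c] = x

    file_bounds = [int(round(k * cfg.file_length * fs)) for k in range(1, int(math.ceil(ext / cfg.file_length)))]
    rec = BroadbandRecording(sig, fs, file_bounds=[b for b in file_bounds if 0 < b < n])
    gt = GroundTruth(
        spike_times=spike_times,
        state_intervals=states,
        effect_params={
            "rate_mult": cfg.rate_mult,
            "power_mult": cfg.power_mult,
            "coh_mult": cfg.coh_mult,
            "rate_corr_mult": cfg.rate_corr_mult,
            "power_bands": cfg.power_bands,
            "coh_bands": cfg.coh_bands,
        },
        latent_sources=latents if cfg.keep_latents else None,
    )
    return rec, gt


def simulate_feature_timeline(
    n_windows: int,
    n_features: int,
    effect,
    seed: int,
    interictal_block: int = 900,
    preictal_block: int = 300,
) -> WindowTimeline:
    """Fast path: Gaussian per-window feature vectors with class-dependent means.

    Labels alternate interictal/preictal blocks on the 2-s window grid
    (default 900/300 windows = 30-min baseline / 10-min preictal stretches,
    an imbalanced cadence compatible with 10-minute permutation blocks);
    each preictal block belongs to one synthetic seizure. ``effect`` is the
    preictal mean shift in SD units, scalar or per-feature.
    """
    if n_windows < 2 or n_features < 1:
        raise ValueError("need n_windows >= 2 and n_features >= 1")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_windows, n_features))
    label = np.empty(n_windows, dtype=np.int8)
    seizure = np.full(n_windows, -1, dtype=np.int32)
    i, sid = 0, 0
    while i < n_windows:
        j = min(i + interictal_block, n_windows)
        label[i:j] = INTERICTAL
        i = j
        j = min(i + preictal_block, n_windows)
        if j > i:
            label[i:j] = PREICTAL
            seizure[i:j] = sid
            sid += 1
        i = j
    shift = np.broadcast_to(np.asarray(effect, dtype=float), (n_features,))
    X[label == PREICTAL] += shift
    t = np.arange(n_windows) * STEP_S
    return WindowTimeline(t, X, label, seizure)
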