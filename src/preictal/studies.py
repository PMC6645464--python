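"""Canned synthetic study conditions for end-to-end runs.

These are compact analogs of a multi-day clinical recording: the labeling
rule structure (a fixed preictal interval ending a guard gap before onset,
and baseline kept a margin away from every onset) is preserved, but the
clock is shrunk so that a full signal-level run (synthesis at kS/s rates,
filtering, multitaper features, LOSO training) stays at desk scale. The
preictal interval maps 1 min -> 1 s (65/5 minutes -> 65/5 seconds) and the
interictal margin to 2 minutes; because the synthetic state is planted
exactly, the margin's only job -- keeping baseline windows out of the
modulated state -- is still done with large headroom.

Effect multipliers are never scaled: the strong-effect study plants a 2.0x
preictal spike-rate ratio, a 1.5x band-power ratio in the 50-80 and
80-150 Hz bands, and a 1.5x coherence-mixing ratio in the 8-12 and
18-25 Hz bands; the null study sets every multiplier to one.
"""

from __future__ import annotations

import dataclasses

from .dataset import LabelingConfig
from .synth import SynthConfig

__all__ = ["SCALED_LABELING", "strong_effect_study", "null_effect_study"]

#: scaled labeling rules: preictal [onset-65 s, onset-5 s], baseline >=120 s away
SCALED_LABELING = LabelingConfig(
    preictal_start_s=65.0, preictal_gap_s=5.0, interictal_margin_s=120.0
)

_LEAD_S = 180.0  # baseline before the first onset
_SPACING_S = 320.0  # between consecutive onsets (leaves 80 s of usable baseline)
_TAIL_S = 60.0


def strong_effect_study(
    seed: int, n_seizures: int = 4, n_channels: int = 16, fs: float = 8_000.0
) -> tuple[SynthConfig, LabelingConfig]:
    """Recording with strongly modulated preictal state (defaults of SynthConfig)."""
    onsets = tuple(_LEAD_S + k * _SPACING_S for k in range(n_seizures))
    cfg = SynthConfig(
        n_channels=n_channels,
        fs=fs,
        duration=onsets[-1] + _TAIL_S,
        seizure_times=onsets,
        preictal_state_span=SCALED_LABELING.preictal_start_s,
        seed=seed,
    )
    return cfg, SCALED_LABELING


def null_effect_study(
    seed: int, n_seizures: int = 4, n_channels: int = 16, fs: float = 8_000.0
) -> tuple[SynthConfig, LabelingConfig]:
    """Same layout with all effect multipliers at one: states exchangeable."""
    cfg, labeling = strong_effect_study(seed, n_seizures, n_channels, fs)
    cfg = dataclasses.replace(
        cfg, rate_mult=1.0, power_mult=1.0, coh_mult=1.0, rate_corr_mult=1.0
    )
    return cfg, labeling
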