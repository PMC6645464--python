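"""The ten LFP frequency bands used throughout the package (Hz)."""

from __future__ import annotations

BANDS: tuple[tuple[float, float], ...] = (
    (0.3, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 18.0),
    (18.0, 25.0),
    (25.0, 50.0),
    (50.0, 80.0),
    (80.0, 150.0),
    (150.0, 300.0),
    (300.0, 500.0),
)

N_BANDS = len(BANDS)


def band_label(i: int) -> str:
    lo, hi = BANDS[i]
    return f"{lo:g}-{hi:g}Hz"


def validate_bands(bands) -> None:
    prev_hi = 0.0
    for lo, hi in bands:
        if not (0 < lo < hi):
            raise ValueError("band edges must satisfy 0 < low < high")
        if lo < prev_hi:
            raise ValueError("bands must be ordered and non-overlapping (shared edges allowed)")
        prev_hi = hi
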