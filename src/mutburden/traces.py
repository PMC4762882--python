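"""Chromatogram-trace heuristic for validating candidate heterozygous variants.

A confirmation amplicon around a candidate heterozygous SNV should show a
secondary peak at the variant position.  The ten flanking bases on each side
are assumed homozygous, so their amplitude on the expected alternate channel
estimates the background noise; a centre amplitude more than two standard
deviations above the mean background is called a variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["TraceWindow", "TraceCall", "call_trace_variant"]

CHANNELS = ("A", "C", "G", "T")
N_FLANK = 10                      # bases each side of the variant
WINDOW = 2 * N_FLANK + 1          # positions -10..+10


@dataclass
class TraceWindow:
    """A 21-position, four-channel amplitude window centred on a variant."""

    variant_id: str
    amplitudes: np.ndarray                 # shape (4, 21), channel order ACGT
    primary_base_calls: Optional[tuple] = None   # per-position base call

    def __post_init__(self):
        amp = np.asarray(self.amplitudes, dtype=float)
        if amp.shape != (4, WINDOW):
            raise ValueError(f"amplitudes must be 4 x {WINDOW}, got {amp.shape}")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be non-negative")
        self.amplitudes = amp

    def channel(self, base: str) -> np.ndarray:
        return self.amplitudes[CHANNELS.index(base.upper())]


@dataclass
class TraceCall:
    variant_id: str
    is_variant: bool
    background_mean: float
    background_sd: float
    threshold: float
    center_amplitude: float


def call_trace_variant(
    trace: TraceWindow,
    expected_alt_channel: str,
    n_sd: float = 2.0,
    channel_mode: str = "alt",
) -> TraceCall:
    """Two-standard-deviation background rule for one trace.

    Background is taken from the 20 flanking positions — on the expected
    alternate channel in "alt" mode (flanks are assumed homozygous, so any
    alternate-channel signal there is noise), or pooled over all non-primary
    channels in "pooled" mode (requires per-position primary base calls).
    The variant is called when the centre amplitude on the expected alternate
    channel is strictly greater than mean + n_sd * sd (sd with the n-1
    divisor).
    """
    center = WINDOW // 2
    flank_idx = np.array([i for i in range(WINDOW) if i != center])
    alt = trace.channel(expected_alt_channel)

    if channel_mode == "alt":
        background = alt[flank_idx]
    elif channel_mode == "pooled":
        if trace.primary_base_calls is None:
            raise ValueError("pooled mode requires primary_base_calls")
        vals = []
        for i in flank_idx:
            primary = trace.primary_base_calls[i].upper()
            for ch in CHANNELS:
                if ch != primary:
                    vals.append(trace.amplitudes[CHANNELS.index(ch), i])
        background = np.asarray(vals, dtype=float)
    else:
        raise ValueError("channel_mode must be 'alt' or 'pooled'")

    if background.size < 2 * N_FLANK:
        raise ValueError("need all 20 flanking positions")
    mean = float(background.mean())
    sd = float(background.std(ddof=1))
    threshold = mean + n_sd * sd
    center_amp = float(alt[center])
    return TraceCall(
        variant_id=trace.variant_id,
        is_variant=center_amp > threshold,
        background_mean=mean,
        background_sd=sd,
        threshold=threshold,
        center_amplitude=center_amp,
    )


def traces_from_frame(df: pd.DataFrame) -> list[TraceWindow]:
    """Build trace windows from a long-format table with columns
    variant_id, position (-10..10), A, C, G, T."""
    out = []
    for vid, sub in df.groupby("variant_id", sort=True):
        sub = sub.sort_values("position")
        if list(sub["position"]) != list(range(-N_FLANK, N_FLANK + 1)):
            raise ValueError(f"trace {vid!r} lacks the full -10..10 window")
        amp = np.vstack([sub[ch].to_numpy(dtype=float) for ch in CHANNELS])
        out.append(TraceWindow(variant_id=str(vid), amplitudes=amp))
    return out
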