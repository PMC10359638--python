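"""4C-seq near-cis profile smoothing and region quantification.

Display tracks are smoothed with a centered moving mean spanning
``span / bin_size`` bins (left-biased by one bin when that count is even),
with shrinking windows at chromosome ends.  Quantification always uses the
unsmoothed normalized signal: mean over a target region divided by the mean
over a caller-supplied background region.
"""

from __future__ import annotations

import warnings

import numpy as np

from .genome import GenomicInterval, SignalTrack

__all__ = ["smooth_4c", "quantify_region"]


def smooth_4c(track: SignalTrack, span: int = 5000) -> SignalTrack:
    """Centered moving mean over ``span`` bp (span/bin bins) per chromosome.

    At chromosome ends the window shrinks to the available bins.  A unit
    impulse becomes a plateau of height 1/(span/bin) across the span.
    """
    if span < track.bin_size:
        raise ValueError("span must be at least one bin")
    w = span // track.bin_size
    left = w // 2
    right = w - left  # window = [i - left, i + right), w bins total
    out = {}
    for chrom, v in track.data.items():
        n = len(v)
        csum = np.concatenate([[0.0], np.cumsum(v)])
        lo = np.clip(np.arange(n) - left, 0, n)
        hi = np.clip(np.arange(n) + right, 0, n)
        out[chrom] = (csum[hi] - csum[lo]) / (hi - lo)
    return SignalTrack(track.bin_size, out, normalization=track.normalization)


def quantify_region(
    track: SignalTrack,
    region: GenomicInterval,
    background: GenomicInterval,
) -> float:
    """Region-over-background signal ratio on the unsmoothed track.

    Returns nan (with a warning) when the background mean is zero.
    """
    num = track.region_mean(region.chrom, region.start, region.end)
    den = track.region_mean(background.chrom, background.start, background.end)
    if not np.isfinite(den) or den == 0:
        warnings.warn("background mean is zero; 4C ratio undefined", RuntimeWarning)
        return float("nan")
    return num / den
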