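"""Target-centered pileups (APA, local, rescaled meta-domain) and insulation.

Pileups average O/E submatrices over a list of targets, tracking per-cell
denominators so masked bins never zero-inflate the mean.  The pileup score
is the mean of the central 3x3 cells of the odd-sized (2F+1)^2 grid.
Insulation is the log2 ratio of each bin's w x w cross-boundary diamond mean
to the chromosome-wide mean of those diamond means, which makes it exactly
invariant to global matrix scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, ExpectedProfile, oe_dense
from .genome import PeakSet, SignalTrack

__all__ = [
    "PileupResult",
    "InsulationTrack",
    "apa",
    "local_pileup",
    "pileup_decay_curve",
    "rescaled_domain_pileup",
    "insulation_score",
    "aggregate_insulation_delta",
]


@dataclass
class PileupResult:
    matrix: np.ndarray
    n_windows: int
    enrichment: float
    resolution: int
    n_skipped: int = 0


@dataclass
class InsulationTrack:
    bin_size: int
    window: int
    data: dict  # chrom -> log2 insulation (nan = masked)

    def to_track(self) -> SignalTrack:
        return SignalTrack(self.bin_size, dict(self.data), normalization="insulation")


def _central_score(mat: np.ndarray) -> float:
    """Mean of the central 3x3 cells of an odd-sized square matrix."""
    c = mat.shape[0] // 2
    block = mat[c - 1 : c + 2, c - 1 : c + 2]
    return float(np.nanmean(block))


def _dense_oe_maps(matrices, expected):
    out = {}
    for chrom, m in matrices.items():
        exp = expected.get(chrom) if expected else None
        out[chrom] = oe_dense(m, exp)
    return out


def _stack_windows(oe_maps, targets, flank):
    """Accumulate submatrices centered on (row_bin, col_bin) targets.

    ``targets`` is an iterable of (chrom, bi, bj).  Returns (mean, n, skipped).
    """
    size = 2 * flank + 1
    sums = np.zeros((size, size))
    counts = np.zeros((size, size))
    n_used = 0
    n_skipped = 0
    for chrom, bi, bj in targets:
        oe = oe_maps.get(chrom)
        if oe is None:
            n_skipped += 1
            continue
        n = oe.shape[0]
        if bi - flank < 0 or bj - flank < 0 or bi + flank >= n or bj + flank >= n:
            n_skipped += 1
            continue
        sub = oe[bi - flank : bi + flank + 1, bj - flank : bj + flank + 1]
        fin = np.isfinite(sub)
        sums[fin] += sub[fin]
        counts[fin] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable windows for pileup")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean, n_used, n_skipped


def apa(matrices, loops, expected=None, resolution: int | None = None, flank_bins: int = 10) -> PileupResult:
    """Aggregate peak analysis: mean O/E submatrix centered on loop pixels.

    ``loops`` is a LoopSet (or its DataFrame with chrom/start1/end1/start2/
    end2 columns).  Enrichment is the central 3x3 mean.
    """
    any_m = next(iter(matrices.values()))
    res = resolution or any_m.bin_size
    if res != any_m.bin_size:
        raise ValueError("resolution must match matrix bin_size")
    df = loops.df if hasattr(loops, "df") else loops
    oe_maps = _dense_oe_maps(matrices, expected)
    targets = []
    for row in df.itertuples(index=False):
        b1 = int((row.start1 + row.end1) // 2 // res)
        b2 = int((row.start2 + row.end2) // 2 // res)
        targets.append((row.chrom, min(b1, b2), max(b1, b2)))
    mean, n_used, n_skipped = _stack_windows(oe_maps, targets, flank_bins)
    return PileupResult(mean, n_used, _central_score(mean), res, n_skipped)


def local_pileup(matrices, anchors: PeakSet, expected=None, flank_bins: int = 10) -> PileupResult:
    """Diagonal-centered pileup at anchor bins (local interaction strength)."""
    any_m = next(iter(matrices.values()))
    res = any_m.bin_size
    oe_maps = _dense_oe_maps(matrices, expected)
    centers = anchors.centers() // res
    targets = [(c, int(b), int(b)) for c, b in zip(anchors.chroms, centers)]
    mean, n_used, n_skipped = _stack_windows(oe_maps, targets, flank_bins)
    return PileupResult(mean, n_used, _central_score(mean), res, n_skipped)


def pileup_decay_curve(matrices, anchors: PeakSet, expected=None, max_dist: int | None = None) -> pd.DataFrame:
    """Mean O/E at each distance from anchor bins, pooled over anchors."""
    any_m = next(iter(matrices.values()))
    res = any_m.bin_size
    oe_maps = _dense_oe_maps(matrices, expected)
    max_bins = (max_dist // res) if max_dist else max(m.n_bins for m in matrices.values()) - 1
    sums = np.zeros(max_bins + 1)
    counts = np.zeros(max_bins + 1)
    centers = anchors.centers() // res
    for chrom, b in zip(anchors.chroms, centers):
        oe = oe_maps.get(chrom)
        if oe is None:
            continue
        n = oe.shape[0]
        b = int(b)
        if not (0 <= b < n):
            continue
        row = oe[b]
        for d in range(0, max_bins + 1):
            for pos in ({b + d, b - d} if d else {b}):
                if 0 <= pos < n and np.isfinite(row[pos]):
                    sums[d] += row[pos]
                    counts[d] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"distance_bp": np.arange(max_bins + 1) * res, "mean_oe": mean, "n": counts.astype(int)}
    )


def _block_resample(sub: np.ndarray, out_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Block-average an M x M matrix to out_size x out_size (mass-preserving)."""
    m = sub.shape[0]
    idx = (np.arange(m) * out_size) // m
    sums = np.zeros((out_size, out_size))
    counts = np.zeros((out_size, out_size))
    fin = np.isfinite(sub)
    ii, jj = np.nonzero(fin)
    np.add.at(sums, (idx[ii], idx[jj]), sub[ii, jj])
    np.add.at(counts, (idx[ii], idx[jj]), 1.0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean, counts


def rescaled_domain_pileup(
    matrices,
    domains: PeakSet,
    expected=None,
    out_size: int = 33,
    pad_factor: float = 1.0,
) -> PileupResult:
    """Rescaled meta-domain map: each domain padded by ``pad_factor`` x its own
    length on both sides, the diagonal window block-averaged to a fixed size,
    then averaged across domains."""
    any_m = next(iter(matrices.values()))
    res = any_m.bin_size
    oe_maps = _dense_oe_maps(matrices, expected)
    sums = np.zeros((out_size, out_size))
    counts = np.zeros((out_size, out_size))
    n_used = 0
    n_skipped = 0
    for chrom, start, end in zip(domains.chroms, domains.starts, domains.ends):
        oe = oe_maps.get(chrom)
        if oe is None:
            n_skipped += 1
            continue
        n = oe.shape[0]
        length = end - start
        w0 = int((start - pad_factor * length) // res)
        w1 = -(-int(end + pad_factor * length) // res)
        if w0 < 0 or w1 > n or (w1 - w0) < 3:
            n_skipped += 1
            continue
        sub = oe[w0:w1, w0:w1]
        mean, cnt = _block_resample(sub, out_size)
        fin = np.isfinite(mean)
        sums[fin] += mean[fin]
        counts[fin] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable domains for rescaled pileup")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PileupResult(mean, n_used, _central_score(mean), res, n_skipped)


def insulation_score(matrices, window: int, resolution: int | None = None) -> InsulationTrack:
    """Diamond insulation: log2(diamond mean / chromosome mean of diamond means).

    The diamond at bin i spans rows (i-w .. i-1) x cols (i+1 .. i+w) with
    w = window / resolution; bins where the diamond does not fully fit, or
    whose own bin is masked, are nan.  Structural zeros between unmasked bins
    count in the diamond mean.
    """
    any_m = next(iter(matrices.values()))
    res = resolution or any_m.bin_size
    if res != any_m.bin_size:
        raise ValueError("resolution must match matrix bin_size")
    if window % res != 0:
        raise ValueError("window must be a multiple of the resolution")
    w = window // res
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    data = {}
    for chrom, m in matrices.items():
        if m.state != "balanced":
            raise ValueError("insulation_score requires balanced matrices")
        dense = m.to_dense()  # nan at masked rows/cols
        n = m.n_bins
        raw = np.full(n, np.nan)
        valid = m.valid_bins
        for i in range(w, n - w):
            if not valid[i]:
                continue
            block = dense[i - w : i, i + 1 : i + w + 1]
            if np.isfinite(block).any():
                raw[i] = np.nanmean(block)
        mean = np.nanmean(raw) if np.isfinite(raw).any() else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            ins = np.log2(raw / mean)
        # raw == 0 maps to -inf: a real (structural-zero) insulation minimum;
        # only undefined diamonds stay nan
        data[chrom] = ins
    return InsulationTrack(res, window, data)


def aggregate_insulation_delta(
    before: InsulationTrack,
    after: InsulationTrack,
    features: PeakSet,
    flank: int,
):
    """Mean (after - before) insulation profile aligned on feature centers.

    Returns ``(offsets_bp, profile, per_feature_central_delta)``.
    """
    if before.bin_size != after.bin_size:
        raise ValueError("insulation tracks have different binning")
    res = before.bin_size
    fb = flank // res
    size = 2 * fb + 1
    sums = np.zeros(size)
    counts = np.zeros(size)
    central = np.full(len(features), np.nan)
    centers = features.centers() // res
    for k, (chrom, b) in enumerate(zip(features.chroms, centers)):
        if chrom not in before.data or chrom not in after.data:
            continue
        delta = after.data[chrom] - before.data[chrom]
        n = len(delta)
        b = int(b)
        lo, hi = b - fb, b + fb + 1
        if lo < 0 or hi > n:
            continue
        seg = delta[lo:hi]
        fin = np.isfinite(seg)
        sums[fin] += seg[fin]
        counts[fin] += 1
        if np.isfinite(delta[b]):
            central[k] = delta[b]
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    offsets = (np.arange(size) - fb) * res
    return offsets, profile, central
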