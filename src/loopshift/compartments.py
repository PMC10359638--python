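"""A/B compartment eigenvector, orientation and saddle enrichment.

The compartment signal is the leading eigenvector (E1) of the Pearson
correlation matrix of the dense O/E map.  E1 is sign-ambiguous; it is
oriented so that it correlates positively with an active-chromatin reference
track (H3K27ac-type signal).  Compartmentalization strength is summarized by
the saddle score (AA + BB) / (2 AB): mean O/E within the top-ranked (A-A) and
bottom-ranked (B-B) eigenvector quantile blocks over the mean between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import (
    ContactMatrix,
    ExpectedProfile,
    expected_by_distance,
    ice_balance,
    oe_dense,
    split_counts,
)
from .genome import SignalTrack

__all__ = [
    "CompartmentTrack",
    "SaddleResult",
    "compartment_eigenvector",
    "orient_eigenvector",
    "saddle",
    "cross_validated_saddle",
]


@dataclass
class CompartmentTrack:
    """Per-bin E1 values (nan = masked), one vector per chromosome."""

    bin_size: int
    values: dict = field(default_factory=dict)  # chrom -> ndarray
    oriented: bool = False
    orientation_reference: str | None = None
    flags: dict = field(default_factory=dict)  # chrom -> str notes

    def to_track(self) -> SignalTrack:
        return SignalTrack(self.bin_size, dict(self.values), normalization="eigenvector")


@dataclass
class SaddleResult:
    matrix: np.ndarray           # Q x Q mean O/E by quantile pair
    quantile_edges: np.ndarray   # per-quantile E1 value ranges pooled
    aa: float
    bb: float
    ab: float
    enrichment: float
    n_quantiles: int
    top_frac: float


def compartment_eigenvector(
    matrix: ContactMatrix,
    expected: ExpectedProfile | None = None,
    min_valid_frac: float = 0.5,
    min_bins: int = 20,
) -> tuple[np.ndarray, str | None]:
    """Leading eigenvector of the O/E Pearson-correlation matrix (unsigned).

    Returns ``(e1, flag)`` with e1 of length n_bins (nan at masked bins) and
    a flag string when the chromosome is degenerate or skipped.  The vector
    is scaled to unit norm over its defined entries.
    """
    if matrix.state not in ("oe", "balanced"):
        raise ValueError("compartment_eigenvector requires oe (or balanced+expected)")
    if matrix.state == "balanced" and expected is None:
        raise ValueError("balanced matrix requires an expected profile")
    oe = oe_dense(matrix, expected) if matrix.state == "balanced" else oe_dense(matrix, None)
    n = matrix.n_bins
    e1 = np.full(n, np.nan)
    valid = matrix.valid_bins & (np.isfinite(oe).sum(axis=1) >= min_valid_frac * matrix.valid_bins.sum())
    if valid.sum() < min_bins:
        warnings.warn(f"{matrix.chrom}: too few valid bins for eigenvector", RuntimeWarning)
        return e1, "too_few_bins"
    sub = oe[np.ix_(valid, valid)]
    # fill undefined cells (masked diagonal etc.) with the mean O/E so they
    # are correlation-neutral; zero-filling would couple each pixel's noise
    # negatively into its own bins' correlation and bias downstream saddles
    fin = np.isfinite(sub)
    fill = sub[fin].mean() if fin.any() else 0.0
    sub = np.where(fin, sub, fill)
    sd = sub.std(axis=1)
    nz = sd > 0
    if nz.sum() < min_bins:
        warnings.warn(f"{matrix.chrom}: degenerate (constant) O/E", RuntimeWarning)
        return e1, "degenerate"
    idx = np.flatnonzero(valid)[nz]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub[np.ix_(nz, nz)])
    corr = np.where(np.isfinite(corr), corr, 0.0)
    evals, evecs = np.linalg.eigh(corr)
    vec = evecs[:, -1]
    vec = vec / np.linalg.norm(vec)
    e1[idx] = vec
    return e1, None


def compartment_track(
    matrices: dict,
    expected: dict | None = None,
    min_valid_frac: float = 0.5,
    min_bins: int = 20,
) -> CompartmentTrack:
    """Genome-level unsigned E1 (per-chromosome eigenvectors)."""
    any_m = next(iter(matrices.values()))
    out = CompartmentTrack(bin_size=any_m.bin_size)
    for chrom, m in matrices.items():
        exp = expected.get(chrom) if expected else None
        e1, flag = compartment_eigenvector(m, exp, min_valid_frac, min_bins)
        out.values[chrom] = e1
        if flag:
            out.flags[chrom] = flag
    return out


def orient_eigenvector(track: CompartmentTrack, active: SignalTrack) -> CompartmentTrack:
    """Flip E1 per chromosome so it correlates positively with the active track."""
    if track.bin_size != active.bin_size:
        raise ValueError("binning mismatch between E1 and active track")
    out = CompartmentTrack(
        track.bin_size, {}, oriented=True,
        orientation_reference=active.normalization, flags=dict(track.flags),
    )
    for chrom, e1 in track.values.items():
        e1 = e1.copy()
        if chrom in active.data:
            ref = active.data[chrom]
            k = min(len(ref), len(e1))
            both = np.isfinite(e1[:k]) & np.isfinite(ref[:k])
            if both.sum() >= 2 and e1[:k][both].std() > 0 and ref[:k][both].std() > 0:
                r = np.corrcoef(e1[:k][both], ref[:k][both])[0, 1]
                if r < 0:
                    e1 = -e1
            else:
                out.flags[chrom] = out.flags.get(chrom, "") + ";zero_variance_orientation"
        out.values[chrom] = e1
    return out


def saddle(
    matrices: dict,
    track: CompartmentTrack,
    expected: dict | None = None,
    n_quantiles: int = 50,
    top_frac: float = 0.2,
) -> SaddleResult:
    """Quantile-ordered mean O/E ("saddle") pooled across chromosomes.

    Bins are ranked by E1 into ``n_quantiles`` equal-count quantiles per
    chromosome (ties broken by bin index); cell (p, q) is the mean O/E over
    all pixel pairs whose bins fall in quantiles p and q, pooled genome-wide.
    AA/BB are the mean over the top/bottom ``top_frac`` quantile blocks and
    AB the mean over the rectangle between them; the compartmentalization
    score is (AA + BB) / (2 AB).
    """
    if n_quantiles < 5:
        raise ValueError("n_quantiles must be >= 5")
    q = n_quantiles
    sums = np.zeros((q, q))
    counts = np.zeros((q, q))
    edges_lo = np.full(q, np.inf)
    edges_hi = np.full(q, -np.inf)
    for chrom, m in matrices.items():
        e1 = track.values.get(chrom)
        if e1 is None:
            continue
        exp = expected.get(chrom) if expected else None
        oe = oe_dense(m, exp) if m.state == "balanced" else oe_dense(m, None)
        defined = np.isfinite(e1)
        idx = np.flatnonzero(defined)
        if len(idx) < q:
            continue
        # equal-count quantiles, ascending E1, ties by bin index (stable sort)
        order = idx[np.argsort(e1[idx], kind="stable")]
        qid_of = np.full(len(e1), -1, dtype=np.int64)
        qid_of[order] = (np.arange(len(order)) * q) // len(order)
        for j in range(q):
            vals = e1[order][(np.arange(len(order)) * q) // len(order) == j]
            if len(vals):
                edges_lo[j] = min(edges_lo[j], vals.min())
                edges_hi[j] = max(edges_hi[j], vals.max())
        sub = oe[np.ix_(idx, idx)]
        qi = qid_of[idx]
        finite = np.isfinite(sub)
        # exclude the self-diagonal
        np.fill_diagonal(finite, False)
        ii, jj = np.nonzero(finite)
        np.add.at(sums, (qi[ii], qi[jj]), sub[ii, jj])
        np.add.at(counts, (qi[ii], qi[jj]), 1.0)
    with np.errstate(invalid="ignore"):
        smat = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_top = max(1, int(round(top_frac * q)))
    hi = slice(q - n_top, q)   # high E1 = A
    lo = slice(0, n_top)       # low E1 = B
    aa = float(np.nansum(sums[hi, hi]) / max(np.nansum(counts[hi, hi]), 1e-300))
    bb = float(np.nansum(sums[lo, lo]) / max(np.nansum(counts[lo, lo]), 1e-300))
    nab = np.nansum(counts[lo, hi]) + np.nansum(counts[hi, lo])
    ab = float((np.nansum(sums[lo, hi]) + np.nansum(sums[hi, lo])) / max(nab, 1e-300))
    if ab == 0 or nab == 0:
        warnings.warn("saddle: AB block empty or zero; enrichment undefined", RuntimeWarning)
        enrichment = np.nan
    else:
        enrichment = (aa + bb) / (2.0 * ab)
    edges = np.stack([edges_lo, edges_hi], axis=1)
    return SaddleResult(smat, edges, aa, bb, ab, float(enrichment), q, top_frac)


def cross_validated_saddle(
    raw_matrices: dict,
    seed: int,
    active: SignalTrack | None = None,
    n_quantiles: int = 20,
    top_frac: float = 0.2,
    min_pair_distance: int = 20000,
) -> SaddleResult:
    """Saddle enrichment with split-half cross-validation.

    Raw counts are binomially split into two independent halves; the
    compartment eigenvector is estimated on one half and the saddle averages
    the other.  Because the ranking is then statistically independent of the
    averaged pixels, the score is unbiased: a compartment-free map scores
    1.0 up to Monte-Carlo error, where the naive double-dipping estimator is
    pulled away from 1 by the ranking's alignment with the map's own noise.
    """
    from .contacts import filter_min_distance

    h1, h2 = {}, {}
    for chrom, m in raw_matrices.items():
        a, b = split_counts(filter_min_distance(m, min_pair_distance), [seed, 11])
        h1[chrom] = ice_balance(a)
        h2[chrom] = ice_balance(b)
    exp1 = {c: expected_by_distance(m) for c, m in h1.items()}
    e1 = compartment_track(h1, exp1)
    if active is not None:
        e1 = orient_eigenvector(e1, active)
    exp2 = {c: expected_by_distance(m) for c, m in h2.items()}
    return saddle(h2, e1, exp2, n_quantiles=n_quantiles, top_frac=top_frac)
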