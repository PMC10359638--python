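"""Contact-matrix container, iterative balancing, expected profile and O/E.

Matrices are per-chromosome, intrachromosomal, stored as sparse upper-triangle
pixels (bin_i <= bin_j).  Balancing is iterative correction (ICE) toward equal
unmasked marginals; the observed/expected transform divides each balanced
pixel by the mean balanced contact at its genomic distance, where the mean is
taken over all pairs of unmasked bins at that distance (structural zeros
included, so long-range expectations are unbiased).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "load_contacts",
    "write_contacts",
    "filter_min_distance",
    "downsample_pairs",
    "ice_balance",
    "expected_by_distance",
    "oe_transform",
    "decay_curve",
]


@dataclass
class ContactMatrix:
    """Sparse symmetric contact counts for one chromosome.

    ``state`` is one of ``raw``, ``balanced``, ``oe``.  ``weights`` holds the
    per-bin balancing weights (nan = masked); raw matrices have no weights.
    """

    chrom: str
    bin_size: int
    n_bins: int
    bin1: np.ndarray
    bin2: np.ndarray
    values: np.ndarray
    state: str = "raw"
    weights: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self):
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.bin1 > self.bin2):
            raise ValueError("pixels must be upper-triangle (bin1 <= bin2)")
        if len(self.bin1) and (self.bin2.max() >= self.n_bins or self.bin1.min() < 0):
            raise ValueError("bin index out of range")
        if np.any(self.values < 0):
            raise ValueError("negative contact counts")

    def total(self) -> float:
        return float(self.values.sum())

    @property
    def valid_bins(self) -> np.ndarray:
        """Boolean mask of unmasked bins."""
        if self.weights is None:
            return np.ones(self.n_bins, dtype=bool)
        return np.isfinite(self.weights)

    def to_dense(self) -> np.ndarray:
        """Dense symmetric matrix; masked rows/cols are nan for balanced/oe."""
        m = np.zeros((self.n_bins, self.n_bins))
        m[self.bin1, self.bin2] = self.values
        m[self.bin2, self.bin1] = self.values
        if self.state in ("balanced", "oe") and self.weights is not None:
            bad = ~self.valid_bins
            m[bad, :] = np.nan
            m[:, bad] = np.nan
        return m

    def with_values(self, values, state: str | None = None, **kw) -> "ContactMatrix":
        return ContactMatrix(
            self.chrom, self.bin_size, self.n_bins,
            self.bin1.copy(), self.bin2.copy(), np.asarray(values, dtype=float),
            state=state or self.state,
            weights=None if self.weights is None else self.weights.copy(),
            **kw,
        )


@dataclass
class ExpectedProfile:
    """Mean balanced contact per genomic distance (in bins) for one chromosome."""

    chrom: str
    bin_size: int
    expected: np.ndarray  # indexed by distance in bins; nan where undefined
    n_valid: np.ndarray   # number of unmasked bin pairs per distance

    def at_distance(self, d_bins) -> np.ndarray:
        return self.expected[np.asarray(d_bins, dtype=np.int64)]

    def to_frame(self) -> pd.DataFrame:
        d = np.arange(len(self.expected))
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "distance_bp": d * self.bin_size,
                "expected": self.expected,
                "n_pixels": self.n_valid,
            }
        )


def _fold_upper(bin1, bin2, values, n_bins):
    """Fold pixels into the upper triangle and sum duplicates."""
    bin1 = np.asarray(bin1, dtype=np.int64)
    bin2 = np.asarray(bin2, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    lo = np.minimum(bin1, bin2)
    hi = np.maximum(bin1, bin2)
    key = lo * n_bins + hi
    uniq, inv = np.unique(key, return_inverse=True)
    sums = np.bincount(inv, weights=values, minlength=len(uniq))
    return uniq // n_bins, uniq % n_bins, sums


def load_contacts(path, genome: GenomeModel, bin_size: int) -> dict:
    """Read a COO contact list into per-chromosome matrices.

    Accepted layouts (tab-separated, ``#`` comments ignored):
      * ``chrom  bin_i  bin_j  count``
      * ``chrom1  pos1  chrom2  pos2  count`` (interchromosomal rows dropped,
        logged)

    Duplicate pixels (and transposed duplicates) are summed.
    """
    per_chrom: dict[str, list] = {c: [] for c in genome.chrom_names}
    n_trans = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 4:
                chrom, i, j, c = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            elif len(parts) >= 5:
                c1, p1, c2, p2 = parts[0], int(parts[1]), parts[2], int(parts[3])
                if c1 != c2:
                    n_trans += 1
                    continue
                chrom, i, j, c = c1, p1 // bin_size, p2 // bin_size, float(parts[4])
            else:
                raise ValueError(f"{path}: line {lineno}: expected 4 or 5 columns")
            if chrom not in genome.chrom_sizes:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            if c < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            n = genome.n_bins(chrom, bin_size)
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{path}: line {lineno}: bin out of range")
            per_chrom[chrom].append((i, j, c))
    if n_trans:
        logger.info("dropped %d interchromosomal pixels", n_trans)
    out = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom, bin_size)
        rows = per_chrom[chrom]
        if rows:
            arr = np.asarray(rows, dtype=float)
            b1, b2, v = _fold_upper(arr[:, 0], arr[:, 1], arr[:, 2], n)
        else:
            b1 = b2 = np.empty(0, dtype=np.int64)
            v = np.empty(0)
        out[chrom] = ContactMatrix(chrom, bin_size, n, b1, b2, v)
    return out


def write_contacts(matrices: dict, path) -> None:
    with open(path, "w") as fh:
        any_m = next(iter(matrices.values()))
        fh.write(f"# bin_size={any_m.bin_size}\n")
        for chrom, m in matrices.items():
            for i, j, v in zip(m.bin1, m.bin2, m.values):
                sv = f"{int(v)}" if float(v).is_integer() else repr(float(v))
                fh.write(f"{chrom}\t{i}\t{j}\t{sv}\n")


def filter_min_distance(matrix: ContactMatrix, min_sep: int = 20000) -> ContactMatrix:
    """Drop pixels at genomic separation <= ``min_sep`` (strictly-greater kept)."""
    if min_sep < 0:
        raise ValueError("min_sep must be >= 0")
    sep = (matrix.bin2 - matrix.bin1) * matrix.bin_size
    keep = sep > min_sep
    out = ContactMatrix(
        matrix.chrom, matrix.bin_size, matrix.n_bins,
        matrix.bin1[keep], matrix.bin2[keep], matrix.values[keep],
        state=matrix.state,
        weights=None if matrix.weights is None else matrix.weights.copy(),
    )
    return out


def downsample_pairs(matrix: ContactMatrix, target_n: int, seed) -> ContactMatrix:
    """Multinomial thinning of raw counts to exactly ``target_n`` pairs."""
    if matrix.state != "raw":
        raise ValueError("downsampling applies to raw counts")
    rng = np.random.default_rng(seed)
    total = matrix.values.sum()
    if target_n > total:
        raise ValueError(f"target_n {target_n} exceeds total {total:.0f}")
    if total == 0 or target_n == 0:
        new = np.zeros_like(matrix.values)
    else:
        new = rng.multinomial(int(target_n), matrix.values / total).astype(float)
    keep = new > 0
    return ContactMatrix(
        matrix.chrom, matrix.bin_size, matrix.n_bins,
        matrix.bin1[keep], matrix.bin2[keep], new[keep], state="raw",
    )


def split_counts(matrix: ContactMatrix, seed, frac: float = 0.5):
    """Binomially split raw counts into two independent halves.

    Each pixel's count is thinned Binomial(count, frac); the remainder forms
    the second half.  For Poisson-distributed counts the halves are
    independent Poisson fields with proportionally scaled intensity, which
    makes the split suitable for cross-validated statistics (estimate a
    ranking on one half, average the other).
    """
    if matrix.state != "raw":
        raise ValueError("split_counts applies to raw counts")
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    counts = np.round(matrix.values).astype(np.int64)
    a = rng.binomial(counts, frac).astype(float)
    b = counts - a
    out = []
    for vals in (a, b):
        keep = vals > 0
        out.append(
            ContactMatrix(
                matrix.chrom, matrix.bin_size, matrix.n_bins,
                matrix.bin1[keep], matrix.bin2[keep], vals[keep], state="raw",
            )
        )
    return out[0], out[1]


def ice_balance(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mad_max: float = 5.0,
) -> ContactMatrix:
    """Iterative correction toward equal unmasked marginals.

    Bins whose log marginal lies more than ``mad_max`` median absolute
    deviations below the median (or with zero marginal) are masked before
    correction.  After convergence the weights are rescaled so unmasked
    rowsums equal 1.  Non-convergence within ``max_iter`` is flagged on the
    result (``converged=False``) and warned, never silent.
    """
    if matrix.state != "raw":
        raise ValueError("ice_balance expects a raw matrix")
    n = matrix.n_bins
    dense = np.zeros((n, n))
    dense[matrix.bin1, matrix.bin2] = matrix.values
    dense[matrix.bin2, matrix.bin1] = matrix.values
    marg = dense.sum(axis=1)
    valid = marg > 0
    if mad_max > 0 and valid.any():
        logm = np.log(marg[valid])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        # the cut targets order-of-magnitude coverage dropouts; skip it when
        # marginals are already essentially uniform (e.g. a re-balanced
        # matrix), where the MAD is numerical noise
        if mad > 1e-3:
            cut = med - mad_max * mad
            valid[valid] &= logm >= cut
    if not valid.any():
        raise ValueError("no unmasked bins to balance")
    w = np.zeros(n)
    w[valid] = 1.0
    sub = dense[np.ix_(valid, valid)]
    wv = np.ones(valid.sum())
    converged = False
    for _ in range(max_iter):
        rows = (sub * wv).sum(axis=1) * wv
        mean = rows.mean()
        if mean == 0:
            raise ValueError("zero marginals among unmasked bins")
        dev = np.abs(rows / mean - 1).max()
        if dev < tol:
            converged = True
            break
        wv = wv / np.sqrt(np.where(rows > 0, rows / mean, 1.0))
    rows = (sub * wv).sum(axis=1) * wv
    scale = rows.mean()
    if scale > 0:
        wv = wv / np.sqrt(scale)
    if not converged:
        warnings.warn(
            f"ICE did not converge on {matrix.chrom} within {max_iter} iterations",
            RuntimeWarning,
        )
    weights = np.full(n, np.nan)
    weights[valid] = wv
    keep = valid[matrix.bin1] & valid[matrix.bin2]
    values = matrix.values[keep] * weights[matrix.bin1[keep]] * weights[matrix.bin2[keep]]
    return ContactMatrix(
        matrix.chrom, matrix.bin_size, matrix.n_bins,
        matrix.bin1[keep], matrix.bin2[keep], values,
        state="balanced", weights=weights, converged=converged,
    )


def expected_by_distance(matrix: ContactMatrix) -> ExpectedProfile:
    """Per-distance mean balanced contact over all unmasked bin pairs.

    Structural zeros between unmasked bins enter the denominator.
    """
    if matrix.state != "balanced":
        raise ValueError("expected_by_distance requires a balanced matrix")
    n = matrix.n_bins
    valid = matrix.valid_bins
    # n_valid(d) = number of i with valid[i] and valid[i+d]
    v = valid.astype(float)
    n_valid = np.correlate(v, v, mode="full")[n - 1 :]
    n_valid = np.round(n_valid).astype(np.int64)
    sums = np.bincount(matrix.bin2 - matrix.bin1, weights=matrix.values, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    return ExpectedProfile(matrix.chrom, matrix.bin_size, expected, n_valid)


def oe_transform(matrix: ContactMatrix, expected: ExpectedProfile) -> ContactMatrix:
    """Observed/expected: divide each balanced pixel by expected at its distance."""
    if matrix.state != "balanced":
        raise ValueError("oe_transform requires a balanced matrix")
    if matrix.bin_size != expected.bin_size:
        raise ValueError("bin_size mismatch between matrix and expected profile")
    d = matrix.bin2 - matrix.bin1
    exp = expected.at_distance(d)
    ok = np.isfinite(exp) & (exp > 0)
    values = np.where(ok, matrix.values / np.where(ok, exp, 1.0), np.nan)
    out = matrix.with_values(values[ok], state="oe")
    out.bin1 = matrix.bin1[ok]
    out.bin2 = matrix.bin2[ok]
    out.values = values[ok]
    return out


def oe_dense(matrix: ContactMatrix, expected: ExpectedProfile) -> np.ndarray:
    """Dense O/E matrix with structural zeros filled in (0/expected = 0).

    Masked rows/columns and undefined distances are nan.
    """
    if matrix.state == "balanced":
        dense = matrix.to_dense()
        n = matrix.n_bins
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        exp = expected.expected[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = dense / exp
        oe[~np.isfinite(exp) | (exp <= 0)] = np.nan
        bad = ~matrix.valid_bins
        oe[bad, :] = np.nan
        oe[:, bad] = np.nan
        return oe
    if matrix.state == "oe":
        # stored pixels are ratios; structural zeros between valid bins are 0
        oe = np.zeros((matrix.n_bins, matrix.n_bins))
        oe[matrix.bin1, matrix.bin2] = matrix.values
        oe[matrix.bin2, matrix.bin1] = matrix.values
        bad = ~matrix.valid_bins
        oe[bad, :] = np.nan
        oe[:, bad] = np.nan
        return oe
    raise ValueError("oe_dense requires a balanced or oe matrix")


def decay_curve(
    matrix: ContactMatrix,
    min_sep: int = 0,
    bin_scheme: str = "linear",
    n_dist_bins: int = 50,
) -> pd.DataFrame:
    """Mean contact vs genomic distance, aggregated into distance bins.

    Structural zeros between unmasked bins are included in the means, so the
    curve of a balanced matrix matches its expected profile.
    """
    if matrix.state not in ("balanced", "oe"):
        raise ValueError("decay_curve requires a balanced or oe matrix")
    n = matrix.n_bins
    valid = matrix.valid_bins.astype(float)
    n_valid = np.round(np.correlate(valid, valid, mode="full")[n - 1 :]).astype(np.int64)
    sums = np.bincount(matrix.bin2 - matrix.bin1, weights=matrix.values, minlength=n)
    dist_bp = np.arange(n) * matrix.bin_size
    keep = (dist_bp >= min_sep) & (n_valid > 0)
    if not keep.any():
        warnings.warn("decay_curve: no distances survive filtering", RuntimeWarning)
        return pd.DataFrame(columns=["distance_bp", "mean", "n_pixels"])
    d = dist_bp[keep].astype(float)
    s = sums[keep]
    nv = n_valid[keep]
    if bin_scheme == "linear":
        edges = np.linspace(d.min(), d.max() + 1, n_dist_bins + 1)
    elif bin_scheme == "log":
        lo = max(d.min(), matrix.bin_size)
        edges = np.geomspace(lo, d.max() + 1, n_dist_bins + 1)
        edges[0] = d.min()
    else:
        raise ValueError(f"unknown bin_scheme {bin_scheme!r}")
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_dist_bins - 1)
    agg_sum = np.bincount(idx, weights=s, minlength=n_dist_bins)
    agg_n = np.bincount(idx, weights=nv, minlength=n_dist_bins)
    agg_d = np.bincount(idx, weights=d * nv, minlength=n_dist_bins)
    nz = agg_n > 0
    return pd.DataFrame(
        {
            "distance_bp": agg_d[nz] / agg_n[nz],
            "mean": agg_sum[nz] / agg_n[nz],
            "n_pixels": agg_n[nz].astype(np.int64),
        }
    )
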