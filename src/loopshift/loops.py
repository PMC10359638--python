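"""Loop containers, multi-resolution merging, strength scoring, the
responsive-loop classifier, and the three permutation procedures.

All permutation p-values use the +1 correction, p = (1 + #{null >= obs}) /
(1 + n_perm) for a one-sided greater test, so p is never 0 and is exactly
uniform on its discrete support under exchangeability.  Every randomized
routine takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel, PeakSet, SignalTrack

__all__ = [
    "LoopSet",
    "PermTestResult",
    "read_loops",
    "write_loops",
    "merge_multires_loops",
    "loop_strength",
    "loop_strength_log2fc",
    "length_rank_gsea",
    "anchor_element_enrichment",
    "classify_responsive_loops",
    "gene_category_enrichment",
]


@dataclass
class PermTestResult:
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: int


class LoopSet:
    """Two-anchor intrachromosomal records at a stated resolution.

    Backed by a DataFrame with columns chrom, start1, end1, start2, end2 and
    optional extras (score, strength columns, source resolution).  Anchors
    are normalized so anchor1 is upstream.
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeModel, resolution: int | None = None):
        df = df.copy().reset_index(drop=True)
        for chrom in df["chrom"].unique():
            if chrom not in genome.chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} not in genome")
        swap = df["start1"] > df["start2"]
        if swap.any():
            c1 = df.loc[swap, ["start1", "end1"]].to_numpy()
            df.loc[swap, ["start1", "end1"]] = df.loc[swap, ["start2", "end2"]].to_numpy()
            df.loc[swap, ["start2", "end2"]] = c1
        self.df = df
        self.genome = genome
        self.resolution = resolution

    def __len__(self):
        return len(self.df)

    def lengths(self) -> np.ndarray:
        """Anchor midpoint separation in bp."""
        mid1 = (self.df["start1"] + self.df["end1"]) // 2
        mid2 = (self.df["start2"] + self.df["end2"]) // 2
        return (mid2 - mid1).to_numpy(dtype=np.int64)

    def spans(self):
        """(chrom, span_start, span_end) per loop: anchor1 start to anchor2 end."""
        return (
            self.df["chrom"].to_numpy(),
            self.df["start1"].to_numpy(dtype=np.int64),
            self.df["end2"].to_numpy(dtype=np.int64),
        )

    def subset(self, mask) -> "LoopSet":
        return LoopSet(self.df[np.asarray(mask)], self.genome, self.resolution)

    @classmethod
    def from_bins(cls, genome, chroms, bins1, bins2, resolution, **extra) -> "LoopSet":
        b1 = np.asarray(bins1, dtype=np.int64)
        b2 = np.asarray(bins2, dtype=np.int64)
        data = {
            "chrom": list(chroms),
            "start1": b1 * resolution,
            "end1": (b1 + 1) * resolution,
            "start2": b2 * resolution,
            "end2": (b2 + 1) * resolution,
        }
        data.update(extra)
        return cls(pd.DataFrame(data), genome, resolution)


def read_loops(path, genome: GenomeModel, resolution: int | None = None) -> LoopSet:
    """Read BEDPE-style loops: chrom1 start1 end1 chrom2 start2 end2 [score].

    Interchromosomal rows are rejected.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 6:
                raise ValueError(f"{path}: line {lineno}: fewer than 6 columns")
            if p[0] != p[3]:
                raise ValueError(f"{path}: line {lineno}: interchromosomal loop")
            rec = {
                "chrom": p[0],
                "start1": int(p[1]), "end1": int(p[2]),
                "start2": int(p[4]), "end2": int(p[5]),
            }
            if len(p) >= 7 and p[6] not in (".", ""):
                rec["score"] = float(p[6])
            rows.append(rec)
    return LoopSet(pd.DataFrame(rows), genome, resolution)


def write_loops(loops: LoopSet, path) -> None:
    with open(path, "w") as fh:
        for row in loops.df.itertuples(index=False):
            cols = [row.chrom, str(int(row.start1)), str(int(row.end1)),
                    row.chrom, str(int(row.start2)), str(int(row.end2))]
            if "score" in loops.df.columns:
                cols.append(repr(float(row.score)))
            fh.write("\t".join(cols) + "\n")


def merge_multires_loops(loop_sets, base_resolution: int = 25000) -> LoopSet:
    """Extend loops called at several resolutions to the coarsest resolution
    and deduplicate on the resulting bin pair.

    ``loop_sets`` is a list of LoopSet (each with its ``resolution`` set, used
    only as provenance).  Each anchor maps to the base-resolution bin holding
    its midpoint; loops sharing both bins collapse to one record keeping the
    finest source resolution.
    """
    recs = {}
    genome = None
    for ls in loop_sets:
        genome = genome or ls.genome
        src = ls.resolution or base_resolution
        mid1 = ((ls.df["start1"] + ls.df["end1"]) // 2).to_numpy()
        mid2 = ((ls.df["start2"] + ls.df["end2"]) // 2).to_numpy()
        b1 = mid1 // base_resolution
        b2 = mid2 // base_resolution
        for chrom, x, y in zip(ls.df["chrom"], b1, b2):
            key = (chrom, int(min(x, y)), int(max(x, y)))
            if key not in recs or src < recs[key]:
                recs[key] = src
    keys = sorted(recs, key=lambda k: (genome.chrom_index(k[0]), k[1], k[2]))
    return LoopSet.from_bins(
        genome,
        [k[0] for k in keys],
        [k[1] for k in keys],
        [k[2] for k in keys],
        base_resolution,
        source_resolution=[recs[k] for k in keys],
    )


def loop_strength(matrices, loop_row, expected=None, center_bins: int = 3) -> float:
    """Mean O/E over the center_bins x center_bins block at one loop pixel."""
    from .contacts import oe_dense

    chrom = loop_row["chrom"] if isinstance(loop_row, (dict, pd.Series)) else loop_row.chrom
    get = (lambda k: loop_row[k]) if isinstance(loop_row, (dict, pd.Series)) else (lambda k: getattr(loop_row, k))
    m = matrices[chrom]
    exp = expected.get(chrom) if expected else None
    oe = oe_dense(m, exp)
    res = m.bin_size
    b1 = int((get("start1") + get("end1")) // 2 // res)
    b2 = int((get("start2") + get("end2")) // 2 // res)
    h = center_bins // 2
    n = oe.shape[0]
    if b1 - h < 0 or b2 - h < 0 or b1 + h >= n or b2 + h >= n:
        raise ValueError("loop window out of chromosome bounds")
    block = oe[b1 - h : b1 + h + 1, b2 - h : b2 + h + 1]
    if not np.isfinite(block).any():
        warnings.warn("loop center fully masked; strength undefined", RuntimeWarning)
        return float("nan")
    return float(np.nanmean(block))


def loop_strength_log2fc(matrices_before, matrices_after, loops: LoopSet,
                         expected_before=None, expected_after=None,
                         center_bins: int = 3) -> pd.DataFrame:
    """Per-loop strengths in two conditions and their log2 fold change."""
    s_before = np.full(len(loops), np.nan)
    s_after = np.full(len(loops), np.nan)
    for k, row in enumerate(loops.df.itertuples(index=False)):
        try:
            s_before[k] = loop_strength(matrices_before, row, expected_before, center_bins)
            s_after[k] = loop_strength(matrices_after, row, expected_after, center_bins)
        except ValueError:
            continue
    with np.errstate(invalid="ignore", divide="ignore"):
        lfc = np.log2(s_after / s_before)
    return pd.DataFrame(
        {"strength_before": s_before, "strength_after": s_after, "log2fc": lfc}
    )


def _gsea_es(steps: np.ndarray) -> float:
    """Signed maximum deviation of the running sum."""
    cs = np.cumsum(steps)
    k = np.argmax(np.abs(cs))
    return float(cs[k])


def length_rank_gsea(loops: LoopSet, hit_mask, n_perm: int = 1000, seed: int = 0):
    """Unweighted (classic) GSEA of a hit set along the loop-length ranking.

    Loops are sorted by decreasing length; the running sum steps +1/|hits| at
    hits and -1/(N - |hits|) elsewhere; ES is the signed maximum deviation.
    The null permutes the hit labels.  Returns ``(PermTestResult, curve)``.
    """
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = len(loops)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("hit set must be a proper nonempty subset")
    order = np.argsort(-loops.lengths(), kind="stable")
    ranked_hits = hit_mask[order]
    step_hit = 1.0 / nh
    step_miss = -1.0 / (n - nh)
    steps = np.where(ranked_hits, step_hit, step_miss)
    curve = np.cumsum(steps)
    observed = float(curve[np.argmax(np.abs(curve))])
    rng = np.random.default_rng(seed)
    # vectorized label permutation: shuffle the hit indicator per replicate
    labels = np.tile(ranked_hits, (n_perm, 1))
    labels = rng.permuted(labels, axis=1)
    null_steps = np.where(labels, step_hit, step_miss)
    null_cs = np.cumsum(null_steps, axis=1)
    null_es = np.take_along_axis(
        null_cs, np.argmax(np.abs(null_cs), axis=1)[:, None], axis=1
    )[:, 0]
    p = (1.0 + np.sum(null_es >= observed)) / (1.0 + n_perm)
    result = PermTestResult(
        observed, float(null_es.mean()), float(null_es.std(ddof=1)), float(p),
        n_perm, seed,
    )
    return result, curve


def _count_peaks_in_intervals(peak_mids: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> int:
    """Number of peaks (midpoint rule) inside the union of intervals."""
    if len(starts) == 0 or len(peak_mids) == 0:
        return 0
    order = np.argsort(starts)
    s, e = starts[order], ends[order]
    # merge
    ms, me = [], []
    cur_s, cur_e = s[0], e[0]
    for k in range(1, len(s)):
        if s[k] <= cur_e:
            cur_e = max(cur_e, e[k])
        else:
            ms.append(cur_s)
            me.append(cur_e)
            cur_s, cur_e = s[k], e[k]
    ms.append(cur_s)
    me.append(cur_e)
    ms = np.asarray(ms)
    me = np.asarray(me)
    idx = np.searchsorted(ms, peak_mids, side="right") - 1
    ok = idx >= 0
    return int(np.sum(ok & (peak_mids < me[np.clip(idx, 0, len(me) - 1)])))


def anchor_element_enrichment(
    loops: LoopSet,
    element_peaks: PeakSet,
    genome: GenomeModel,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Enrichment of element peaks at loop anchors over a relocation null.

    Observed = number of element peaks whose midpoint falls in a loop anchor.
    Each permutation relocates every loop uniformly on its own chromosome,
    preserving anchor widths and the anchor separation; loops longer than
    their chromosome are skipped (counted).  Enrichment = observed / null
    mean; p is one-sided greater with the +1 correction.
    """
    rng = np.random.default_rng(seed)
    df = loops.df
    mids = element_peaks.midpoints()
    pk_chrom = element_peaks.chroms
    per_chrom = {}
    for chrom in np.unique(df["chrom"]):
        per_chrom[chrom] = np.sort(mids[pk_chrom == chrom])

    def count(anchor_starts, anchor_ends, chroms):
        total = 0
        for chrom in per_chrom:
            sel = chroms == chrom
            total += _count_peaks_in_intervals(
                per_chrom[chrom], anchor_starts[sel], anchor_ends[sel]
            )
        return total

    chroms = df["chrom"].to_numpy()
    s1 = df["start1"].to_numpy(np.int64)
    e1 = df["end1"].to_numpy(np.int64)
    s2 = df["start2"].to_numpy(np.int64)
    e2 = df["end2"].to_numpy(np.int64)
    spans = e2 - s1
    sizes = np.array([genome.size(c) for c in chroms])
    feasible = spans <= sizes
    n_skipped = int((~feasible).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} loops longer than their chromosome skipped", RuntimeWarning)
    observed = count(np.concatenate([s1, s2]), np.concatenate([e1, e2]),
                     np.concatenate([chroms, chroms]))
    null = np.zeros(n_perm)
    f = feasible
    for p in range(n_perm):
        shift_max = sizes[f] - spans[f]
        new_s1 = (rng.random(f.sum()) * (shift_max + 1)).astype(np.int64)
        off = new_s1 - s1[f]
        null[p] = count(
            np.concatenate([s1[f] + off, s2[f] + off]),
            np.concatenate([e1[f] + off, e2[f] + off]),
            np.concatenate([chroms[f], chroms[f]]),
        )
    null_mean = float(null.mean())
    if observed == 0 and null_mean == 0:
        warnings.warn("no element overlaps observed or expected; enrichment undefined", RuntimeWarning)
        enrichment = float("nan")
    else:
        enrichment = observed / null_mean if null_mean > 0 else float("inf")
    pval = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return enrichment, PermTestResult(
        float(observed), null_mean, float(null.std(ddof=1)), float(pval), n_perm, seed
    )


@dataclass
class ResponsiveLoopResult:
    responsive: np.ndarray       # loop indices (into the input LoopSet)
    less_responsive: np.ndarray
    scores: np.ndarray           # per-loop score (nan for non-candidates)
    candidate_mask: np.ndarray
    has_tf: np.ndarray
    has_down: np.ndarray


def classify_responsive_loops(
    loops: LoopSet,
    tf_peaks: PeakSet,
    down_cohesin_peaks: PeakSet,
    atac_peaks: PeakSet,
    tf_track: SignalTrack,
    cohesin_lfc_per_atac: np.ndarray,
    min_length: int = 500_000,
    top_n: int = 500,
) -> ResponsiveLoopResult:
    """Partition long loops into responsive / less-responsive classes.

    Candidates are loops with length > ``min_length``.  Each candidate is
    scored as the sum over ATAC peaks inside its span (midpoint containment,
    [anchor1.start, anchor2.end]) of the TF track signal at the peak plus the
    absolute cohesin log2FC at the peak.  Responsive = the ``top_n``
    highest-scoring candidates containing >=1 TF peak and >=1 down-regulated
    cohesin peak; less-responsive = the ``top_n`` lowest-scoring candidates
    containing neither.  Ties break by (score, genome chromosome order,
    anchor1 start).
    """
    cohesin_lfc_per_atac = np.asarray(cohesin_lfc_per_atac, dtype=float)
    if len(cohesin_lfc_per_atac) != len(atac_peaks):
        raise ValueError("cohesin_lfc_per_atac must align with atac_peaks")
    n = len(loops)
    chroms, span_s, span_e = loops.spans()
    lengths = loops.lengths()
    candidate = lengths > min_length

    atac_mid = atac_peaks.midpoints()
    atac_chrom = atac_peaks.chroms
    atac_signal = np.array(
        [
            tf_track.region_mean(c, s, e) if c in tf_track.data else 0.0
            for c, s, e in zip(atac_chrom, atac_peaks.starts, atac_peaks.ends)
        ]
    )
    atac_value = np.nan_to_num(atac_signal) + np.abs(cohesin_lfc_per_atac)

    tf_mid, tf_chrom = tf_peaks.midpoints(), tf_peaks.chroms
    down_mid, down_chrom = down_cohesin_peaks.midpoints(), down_cohesin_peaks.chroms

    scores = np.full(n, np.nan)
    has_tf = np.zeros(n, dtype=bool)
    has_down = np.zeros(n, dtype=bool)
    for chrom in np.unique(chroms):
        lsel = np.flatnonzero((chroms == chrom) & candidate)
        if len(lsel) == 0:
            continue
        a_sel = atac_chrom == chrom
        a_mid = atac_mid[a_sel]
        a_val = atac_value[a_sel]
        ordm = np.argsort(a_mid)
        a_mid, a_val = a_mid[ordm], a_val[ordm]
        a_cum = np.concatenate([[0.0], np.cumsum(a_val)])
        t_mid = np.sort(tf_mid[tf_chrom == chrom])
        d_mid = np.sort(down_mid[down_chrom == chrom])
        for i in lsel:
            s, e = span_s[i], span_e[i]  # closed span [start1, end2]
            lo = np.searchsorted(a_mid, s, side="left")
            hi = np.searchsorted(a_mid, e, side="right")
            scores[i] = a_cum[hi] - a_cum[lo]
            has_tf[i] = np.searchsorted(t_mid, e, "right") > np.searchsorted(t_mid, s, "left")
            has_down[i] = np.searchsorted(d_mid, e, "right") > np.searchsorted(d_mid, s, "left")

    chrom_order = np.array([loops.genome.chrom_index(c) for c in chroms])
    start1 = loops.df["start1"].to_numpy(np.int64)

    def ranked(idx, descending):
        sgn = -1.0 if descending else 1.0
        key = np.lexsort((start1[idx], chrom_order[idx], sgn * scores[idx]))
        return idx[key]

    resp_pool = np.flatnonzero(candidate & has_tf & has_down)
    less_pool = np.flatnonzero(candidate & ~has_tf & ~has_down)
    if len(resp_pool) < top_n:
        warnings.warn(f"only {len(resp_pool)} responsive-eligible loops (< {top_n})", RuntimeWarning)
    if len(less_pool) < top_n:
        warnings.warn(f"only {len(less_pool)} less-responsive-eligible loops (< {top_n})", RuntimeWarning)
    responsive = ranked(resp_pool, descending=True)[:top_n]
    less = ranked(less_pool, descending=False)[:top_n]
    return ResponsiveLoopResult(responsive, less, scores, candidate, has_tf, has_down)


def gene_category_enrichment(
    loops: LoopSet,
    gene_tss: np.ndarray,
    gene_chrom: np.ndarray,
    gene_category: np.ndarray,
    genome: GenomeModel,
    n_perm: int = 10000,
    seed: int = 0,
    categories=("down", "unchanged", "up"),
):
    """Observed/expected gene-category ratios inside a loop set vs a
    relocation null.

    A gene belongs to the loop set if its TSS lies within at least one loop
    span.  The observed ratio per category is (fraction of in-loop genes in
    that category) / (genome-wide fraction).  The null relocates every loop
    uniformly on its own chromosome, length preserved, ``n_perm`` times; the
    empirical p per category is two-sided with the +1 correction.

    Returns ``{category: (ratio, PermTestResult)}``.
    """
    rng = np.random.default_rng(seed)
    gene_tss = np.asarray(gene_tss, dtype=np.int64)
    gene_chrom = np.asarray(gene_chrom)
    gene_category = np.asarray(gene_category)
    unknown = set(gene_category) - set(categories)
    if unknown:
        raise ValueError(f"uncategorized genes: {sorted(unknown)}")
    n_genes = len(gene_tss)
    cat_onehot = np.stack([(gene_category == c) for c in categories]).astype(float)
    genome_frac = cat_onehot.sum(axis=1) / n_genes

    chroms, span_s, span_e = loops.spans()
    span_len = span_e - span_s

    # membership matrix over permutations, chunked to bound memory
    member_obs = np.zeros(n_genes, dtype=bool)
    member_null = np.zeros((n_perm, n_genes), dtype=bool)
    for chrom in np.unique(chroms):
        lsel = np.flatnonzero(chroms == chrom)
        gsel = np.flatnonzero(gene_chrom == chrom)
        if len(gsel) == 0:
            continue
        tss = gene_tss[gsel]
        for i in lsel:
            member_obs[gsel] |= (tss >= span_s[i]) & (tss < span_e[i])
        size = genome.size(chrom)
        feas = span_len[lsel] <= size
        L = span_len[lsel][feas]
        if len(L) == 0:
            continue
        chunk = max(1, min(n_perm, int(2e7 // max(1, len(L) * len(gsel)))))
        for p0 in range(0, n_perm, chunk):
            p1 = min(n_perm, p0 + chunk)
            starts = (rng.random((p1 - p0, len(L))) * (size - L + 1)).astype(np.int64)
            inside = (tss[None, None, :] >= starts[:, :, None]) & (
                tss[None, None, :] < (starts + L)[:, :, None]
            )
            member_null[p0:p1, gsel] |= inside.any(axis=1)

    results = {}
    n_in = member_obs.sum()
    in_counts = cat_onehot @ member_obs
    null_n_in = member_null.sum(axis=1)
    null_counts = member_null.astype(float) @ cat_onehot.T  # n_perm x n_cat
    for k, cat in enumerate(categories):
        if genome_frac[k] == 0:
            warnings.warn(f"category {cat!r} absent genome-wide; ratio undefined", RuntimeWarning)
            results[cat] = (float("nan"), None)
            continue
        obs_ratio = (in_counts[k] / n_in / genome_frac[k]) if n_in > 0 else float("nan")
        with np.errstate(invalid="ignore", divide="ignore"):
            null_ratio = null_counts[:, k] / null_n_in / genome_frac[k]
        null_ratio = np.where(null_n_in > 0, null_ratio, np.nan)
        finite = np.isfinite(null_ratio)
        nr = null_ratio[finite]
        n_eff = len(nr)
        if n_eff == 0 or not np.isfinite(obs_ratio):
            results[cat] = (float(obs_ratio), None)
            continue
        p_hi = (1.0 + np.sum(nr >= obs_ratio)) / (1.0 + n_eff)
        p_lo = (1.0 + np.sum(nr <= obs_ratio)) / (1.0 + n_eff)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        results[cat] = (
            float(obs_ratio),
            PermTestResult(float(obs_ratio), float(nr.mean()), float(nr.std(ddof=1)),
                           float(p), n_eff, seed),
        )
    return results
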