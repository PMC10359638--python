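"""ChIP-seq track quantification, normalization scalings, peak annotation,
bound/unbound gene selection, differential-signal clustering, co-occupancy
categories and the ChIP-qPCR percent-input formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .genome import Gene, GenomeModel, PeakSet, SignalTrack, _windowed_means, intersect

__all__ = [
    "FeatureMatrix",
    "rpgc_scale",
    "spike_in_scale",
    "feature_matrix",
    "build_regulatory_elements",
    "annotate_peaks",
    "bound_unbound_genes",
    "zscore_rows",
    "cluster_diff_signal",
    "cooccupancy_categories",
    "percent_input",
    "resource_annotations",
]

PROMOTER_FLANK = 1000  # +-1 kb around the TSS defines a promoter


def rpgc_scale(total_coverage_bp: float, genome_size: int) -> float:
    """1x-coverage (RPGC) scale factor: genome_size / total coverage.

    Applying the factor makes the genome-wide mean per-bp coverage exactly 1.
    """
    if total_coverage_bp <= 0:
        raise ValueError("total coverage must be positive")
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return genome_size / total_coverage_bp


def spike_in_scale(primary_reads: int, spike_reads: int, reference_spike_reads: int) -> float:
    """Exogenous spike-in scale factor: reference spike depth over sample spike depth."""
    if spike_reads <= 0:
        raise ValueError("spike reads must be positive")
    return reference_spike_reads / spike_reads


@dataclass
class FeatureMatrix:
    values: np.ndarray      # n_features x n_columns, nan where off-chromosome
    offsets: np.ndarray     # column center offsets in bp (or scaled units)
    row_keys: list

    def meta_profile(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)


def feature_matrix(
    track: SignalTrack,
    features,
    flank: int,
    bin: int,
    mode: str = "center",
) -> FeatureMatrix:
    """Signal matrix around features (peak centers, TSSs or scaled bodies).

    ``mode='center'``: columns span [-flank, +flank) around the peak center
    (summit when present).  ``mode='tss'``: same around gene TSSs, columns
    reversed for minus-strand genes so upstream is always left.
    ``mode='scale-region'``: the gene body TSS->TES is resampled to the same
    number of columns (strand-aware).  Cells are exact length-weighted means
    of the binned track; off-chromosome windows are nan.
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    ncol = 2 * flank // bin
    offs = np.arange(-flank, flank, bin) + bin // 2

    if mode in ("center", "tss"):
        if mode == "center":
            centers = features.centers()
            chroms = features.chroms
            strands = ["+"] * len(centers)
            keys = list(range(len(centers)))
        else:
            centers = np.array([g.tss for g in features])
            chroms = np.array([g.chrom for g in features])
            strands = [g.strand for g in features]
            keys = [g.id for g in features]
        rows = np.full((len(centers), ncol), np.nan)
        for k, (chrom, c) in enumerate(zip(chroms, centers)):
            if chrom not in track.data:
                continue
            starts = c - flank + np.arange(ncol) * bin
            rows[k] = _windowed_means(track.data[chrom], track.bin_size, starts, starts + bin)
            if strands[k] == "-":
                rows[k] = rows[k][::-1]
        return FeatureMatrix(rows, offs, keys)

    if mode == "scale-region":
        rows = np.full((len(features), ncol), np.nan)
        keys = [g.id for g in features]
        for k, g in enumerate(features):
            if g.chrom not in track.data:
                continue
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
            edges = np.linspace(lo, hi, ncol + 1).astype(np.int64)
            vals = _windowed_means(track.data[g.chrom], track.bin_size, edges[:-1], edges[1:])
            rows[k] = vals[::-1] if g.strand == "-" else vals
        scaled = np.linspace(0, 1, ncol, endpoint=False) + 0.5 / ncol
        return FeatureMatrix(rows, scaled, keys)

    raise ValueError(f"unknown mode {mode!r}")


def build_regulatory_elements(
    genes,
    active_peaks: PeakSet,
    ctcf_peaks: PeakSet,
    genome: GenomeModel,
):
    """Build promoter / enhancer / CTCF-site sets with their exclusions.

    Promoters are TSS +-1 kb; enhancers are active-chromatin peaks not
    overlapping promoters; CTCF sites are CTCF peaks overlapping neither
    promoters nor enhancers.  Gene bodies (TSS to TES) are returned too.
    """
    rows = []
    body_rows = []
    for g in genes:
        size = genome.size(g.chrom)
        s = max(0, g.tss - PROMOTER_FLANK)
        e = min(size, g.tss + PROMOTER_FLANK)
        rows.append({"chrom": g.chrom, "start": s, "end": e, "label": g.id})
        lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
        body_rows.append({"chrom": g.chrom, "start": max(0, lo), "end": min(size, hi), "label": g.id})
    promoters = PeakSet(pd.DataFrame(rows), genome)
    bodies = PeakSet(pd.DataFrame(body_rows), genome)
    enh_hit, _ = intersect(active_peaks, promoters)
    enhancers = active_peaks.subset(~enh_hit)
    ctcf_hit_p, _ = intersect(ctcf_peaks, promoters)
    if len(enhancers):
        ctcf_hit_e, _ = intersect(ctcf_peaks, enhancers)
    else:
        ctcf_hit_e = np.zeros(len(ctcf_peaks), dtype=bool)
    ctcf_sites = ctcf_peaks.subset(~(ctcf_hit_p | ctcf_hit_e))
    return promoters, enhancers, ctcf_sites, bodies


def annotate_peaks(
    peaks: PeakSet,
    promoters: PeakSet,
    enhancers: PeakSet,
    ctcf_sites: PeakSet,
    gene_bodies: PeakSet,
):
    """Assign each peak its first matching category in the fixed priority
    order promoter > enhancer > CTCF site > gene body > other.

    Returns ``(categories, proportions)``; categories are mutually exclusive
    and exhaustive, proportions sum to 1.
    """
    order = [
        ("promoter", promoters),
        ("enhancer", enhancers),
        ("ctcf", ctcf_sites),
        ("gene_body", gene_bodies),
    ]
    cats = np.array(["other"] * len(peaks), dtype=object)
    unassigned = np.ones(len(peaks), dtype=bool)
    for name, elements in order:
        if len(elements) == 0:
            continue
        hit, _ = intersect(peaks, elements)
        take = unassigned & hit
        cats[take] = name
        unassigned &= ~hit
    labels = [name for name, _ in order] + ["other"]
    n = max(len(peaks), 1)
    proportions = {lab: float(np.sum(cats == lab)) / n for lab in labels}
    return cats, proportions


def bound_unbound_genes(
    genes,
    tf_peaks: PeakSet,
    tf_track: SignalTrack,
    genome: GenomeModel,
    top_n: int = 1000,
):
    """Top-N TF-bound genes and bottom-N unbound genes by promoter signal.

    A gene is peak-bearing if >=1 TF peak overlaps its promoter (TSS +-1 kb).
    Bound = top_n peak-bearing genes by mean promoter signal (descending);
    unbound = top_n peak-free genes by mean promoter signal (ascending).
    Ties break by gene id.
    """
    rows = []
    for g in genes:
        size = genome.size(g.chrom)
        rows.append({
            "chrom": g.chrom,
            "start": max(0, g.tss - PROMOTER_FLANK),
            "end": min(size, g.tss + PROMOTER_FLANK),
            "label": g.id,
        })
    promoters = PeakSet(pd.DataFrame(rows), genome)
    hit, _ = intersect(promoters, tf_peaks)
    # map back to the input gene order (PeakSet sorted the promoters)
    by_id = {lab: h for lab, h in zip(promoters.df["label"], hit)}
    signal = {}
    for g in genes:
        if g.chrom in tf_track.data:
            signal[g.id] = tf_track.region_mean(
                g.chrom, max(0, g.tss - PROMOTER_FLANK),
                min(genome.size(g.chrom), g.tss + PROMOTER_FLANK),
            )
        else:
            signal[g.id] = 0.0
    with_peak = [g for g in genes if by_id.get(g.id, False)]
    without = [g for g in genes if not by_id.get(g.id, False)]
    if len(with_peak) < top_n:
        warnings.warn(f"only {len(with_peak)} peak-bearing genes (< {top_n})", RuntimeWarning)
    if len(without) < top_n:
        warnings.warn(f"only {len(without)} peak-free genes (< {top_n})", RuntimeWarning)
    bound = sorted(with_peak, key=lambda g: (-signal[g.id], g.id))[:top_n]
    unbound = sorted(without, key=lambda g: (signal[g.id], g.id))[:top_n]
    return bound, unbound


def zscore_rows(matrix: np.ndarray):
    """Row-wise z-scores, (x - mean) / sample SD (ddof=1).

    Constant rows become all-zero and are flagged.  Returns ``(z, flagged)``.
    """
    m = np.asarray(matrix, dtype=float)
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    flagged = np.flatnonzero(sd[:, 0] == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m - mean) / sd
    z[flagged] = 0.0
    return z, flagged


def cluster_diff_signal(z_matrix: np.ndarray, k_range, seed: int = 0):
    """Ward-linkage hierarchical clustering with an elbow choice of k.

    The dendrogram is cut at each k in ``k_range``; the within-cluster
    dispersion W(k) is the total squared Euclidean distance to cluster
    centroids.  The elbow is the k maximizing the second difference
    W(k-1) - 2 W(k) + W(k+1).  Returns ``(labels, chosen_k, dispersion,
    degenerate_flag)``; labels are for the chosen k, deterministic given
    input order.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.shape[0] < 3:
        raise ValueError("need at least 3 rows to cluster")
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 2 or ks[-1] > z.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n_rows - 1]")
    link = linkage(z, method="ward")

    def dispersion(labels):
        w = 0.0
        for lab in np.unique(labels):
            rows = z[labels == lab]
            w += float(((rows - rows.mean(axis=0)) ** 2).sum())
        return w

    # evaluate one k beyond the range on each side (k=1 is the total
    # dispersion) so the second difference is defined at every requested k
    eval_ks = sorted(set(ks) | {max(1, ks[0] - 1), min(z.shape[0], ks[-1] + 1)})
    disp = {}
    labels_at = {}
    for k in eval_ks:
        lab = fcluster(link, t=k, criterion="maxclust")
        labels_at[k] = lab
        disp[k] = dispersion(lab)
    degenerate = all(v == 0 for v in disp.values())
    if degenerate:
        chosen = ks[0]
    else:
        second_diff = {
            k: disp.get(k - 1, disp[k]) - 2 * disp[k] + disp.get(k + 1, disp[k])
            for k in ks
        }
        chosen = max(second_diff, key=lambda k: (second_diff[k], -k))
    curve = np.array([disp[k] for k in ks])
    return labels_at[chosen], chosen, curve, degenerate


def cooccupancy_categories(peak_sets: dict):
    """Merge all factors' peaks into maximal regions and label each by the
    number of distinct factors present ('1', '2', '3', '4', '4+').

    Returns a DataFrame with chrom/start/end/n_factors/category plus the
    per-category region counts.
    """
    recs = []
    for name, ps in peak_sets.items():
        for chrom, s, e in zip(ps.chroms, ps.starts, ps.ends):
            recs.append((chrom, int(s), int(e), name))
    if not recs:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_factors", "category"]), {}
    any_ps = next(iter(peak_sets.values()))
    genome = any_ps.genome
    recs.sort(key=lambda r: (genome.chrom_index(r[0]), r[1], r[2]))
    regions = []
    cur = None
    members: set = set()
    for chrom, s, e, name in recs:
        if cur is not None and chrom == cur[0] and s <= cur[2]:
            cur = (chrom, cur[1], max(cur[2], e))
            members.add(name)
        else:
            if cur is not None:
                regions.append((*cur, len(members)))
            cur = (chrom, s, e)
            members = {name}
    if cur is not None:
        regions.append((*cur, len(members)))
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_factors"])
    df["category"] = np.where(df["n_factors"] > 4, "4+", df["n_factors"].astype(str))
    counts = df["category"].value_counts().to_dict()
    return df, counts


def percent_input(ct_input: float, ct_sample: float, input_fraction: float = 0.05) -> float:
    """ChIP-qPCR percent input: 100 * input_fraction * 2**(Ct_input - Ct_sample).

    With the default 5% input aliquot, equal Ct values return 5.0 (%).
    """
    if not (np.isfinite(ct_input) and np.isfinite(ct_sample)):
        raise ValueError("Ct values must be finite")
    return 100.0 * input_fraction * 2.0 ** (ct_input - ct_sample)


def resource_annotations(
    tpm: pd.DataFrame,
    crispr: pd.DataFrame,
    tpm_threshold: float = 10.0,
) -> pd.DataFrame:
    """Tissue-expression breadth and CRISPR essentiality per gene.

    ``tpm`` is gene x tissue (already averaged per tissue); the expression
    percentage is the share of tissues strictly above ``tpm_threshold``.
    ``crispr`` needs columns 'score' and 'p'; essential iff score < 0 and
    p < 0.05.  Genes missing from a table are absent from that column.
    """
    pct = (tpm > tpm_threshold).mean(axis=1) * 100.0
    out = pd.DataFrame({"expression_pct": pct})
    ess = (crispr["score"] < 0) & (crispr["p"] < 0.05)
    out = out.join(ess.rename("essential"), how="outer")
    return out
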