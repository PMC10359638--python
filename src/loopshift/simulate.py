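"""Synthetic datasets with planted, recorded truth for every pipeline input.

The contact-map model is a Poisson field over intrachromosomal bin pairs,

    counts_ij ~ Poisson(lambda_ij),
    lambda_ij  ∝  depth * (d + 1)^(-alpha) * B_i B_j
                  * exp(A * e_i e_j) * tau^[same TAD] * bump_l(i, j),

with lognormal bin biases B, a +-1 plaid compartment vector e of amplitude
A, a within-TAD contrast tau, and focal loop bumps.  A planted loop of
strength l multiplies lambda by 1 + c * exp(-(di^2 + dj^2) / 2) around the
loop pixel with c chosen so the mean enhancement over the central 3x3 block
equals l; the planted strength is therefore exactly what an aggregate-peak
central-3x3 score estimates.

ChIP landscapes place factor peaks on a shared site pool (promoters,
enhancers, CTCF sites) with per-factor occupancy probabilities; tracks are
Gaussian peak kernels over background noise.  The perturbation experiment
emulates an acute-depletion design: the cohesin track drops by a fixed
factor at factor-bound promoters only, a planted subset of long loops gains
strength in the treated map, and gene DE categories are enriched inside
those loops.  Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, write_contacts
from .genome import (
    Gene,
    GenomeModel,
    PeakSet,
    SignalTrack,
    write_genes,
    write_intervals,
    write_track,
)
from .loops import LoopSet, write_loops

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_contact_map",
    "simulate_chip_landscape",
    "simulate_perturbation_experiment",
    "simulate_psm_table",
    "simulate_4c",
]

# 3x3 Gaussian kernel mass used to normalize planted loop strength
_KERNEL_3X3 = sum(
    np.exp(-(di * di + dj * dj) / 2.0) for di in (-1, 0, 1) for dj in (-1, 0, 1)
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets (desk-scale defaults)."""

    seed: int = 0
    # genome / contact map
    n_chroms: int = 2
    chrom_size: int = 10_000_000
    bin_size: int = 25_000
    decay_exponent: float = 1.0
    depth: int = 2_000_000
    bias_sd: float = 0.15
    compartment_amplitude: float = 0.3
    compartment_block: int = 20          # bins per homogeneous block
    tad_contrast: float = 1.5
    tad_min_bins: int = 8
    tad_max_bins: int = 20
    loop_strength: float = 2.0
    n_loops: int = 40                    # background loops, whole genome
    loop_min_bins: int = 8
    loop_max_bins: int = 40
    # chip landscape
    n_genes: int = 300
    active_frac: float = 0.6
    n_enhancers: int = 120
    n_ctcf_sites: int = 100
    peak_width: int = 400
    track_bin: int = 100
    peak_amplitude: float = 5.0
    track_noise_sd: float = 0.1
    factor_probs: dict = field(
        default_factory=lambda: {"zf1": 0.5, "zf2": 0.5, "zf3": 0.5, "zf4": 0.5, "zf5": 0.5}
    )
    # perturbation experiment
    cohesin_reduction: float = 0.5
    responsive_gain: float = 1.5
    n_responsive: int = 12
    n_less_responsive: int = 12
    responsive_min_bins: int = 24        # > 500 kb at 25 kb bins
    responsive_max_bins: int = 56
    tf_extra_frac: float = 0.05
    gene_down_rate: float = 0.15
    gene_up_rate: float = 0.15
    responsive_up_enrichment: float = 2.0
    # chip-ms
    n_background_proteins: int = 300
    n_enriched_proteins: int = 30
    psm_mean: float = 10.0
    psm_enrich_ratio: float = 4.0
    n_chip_samples: int = 2
    n_input_samples: int = 2
    isoform_frac: float = 0.3
    # 4c
    fourc_bin: int = 50
    fourc_depth: int = 500_000
    fourc_fold: float = 2.0

    def genome(self) -> GenomeModel:
        sizes = {f"chr{i + 1}": self.chrom_size for i in range(self.n_chroms)}
        return GenomeModel.from_sizes(sizes, self.bin_size)


@dataclass
class TruthRecord:
    """Planted ground truth accompanying each simulated dataset."""

    compartment_labels: dict = field(default_factory=dict)   # chrom -> +-1 ints
    tad_boundaries: dict = field(default_factory=dict)       # chrom -> bin indices
    loops: pd.DataFrame | None = None                        # chrom/bin1/bin2/strength[/after]
    responsive_loops: np.ndarray | None = None               # indices into `loops`
    less_responsive_loops: np.ndarray | None = None
    gene_categories: dict = field(default_factory=dict)      # gene id -> category
    bound_promoter_genes: list = field(default_factory=list)
    factor_membership: dict = field(default_factory=dict)    # factor -> site indices
    enriched_proteins: list = field(default_factory=list)
    fourc_region: tuple | None = None
    fourc_background: tuple | None = None

    def to_json(self, path) -> None:
        obj = {
            "compartment_labels": {c: v.tolist() for c, v in self.compartment_labels.items()},
            "tad_boundaries": {c: list(map(int, v)) for c, v in self.tad_boundaries.items()},
            "loops": None if self.loops is None else self.loops.to_dict(orient="list"),
            "responsive_loops": None if self.responsive_loops is None else [int(i) for i in self.responsive_loops],
            "less_responsive_loops": None if self.less_responsive_loops is None else [int(i) for i in self.less_responsive_loops],
            "gene_categories": self.gene_categories,
            "bound_promoter_genes": self.bound_promoter_genes,
            "factor_membership": {k: list(map(int, v)) for k, v in self.factor_membership.items()},
            "enriched_proteins": self.enriched_proteins,
            "fourc_region": self.fourc_region,
            "fourc_background": self.fourc_background,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


# ---------------------------------------------------------------------------
# contact maps


def _plan_architecture(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw biases, compartments, TADs and loop positions (no counts yet)."""
    genome = cfg.genome()
    arch = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        biases = rng.lognormal(-cfg.bias_sd**2 / 2, cfg.bias_sd, n)
        labels = np.empty(n, dtype=np.int64)
        block = cfg.compartment_block
        sign = 1 if rng.random() < 0.5 else -1
        for b0 in range(0, n, block):
            labels[b0 : b0 + block] = sign
            sign = -sign
        bounds = [0]
        while bounds[-1] < n:
            bounds.append(bounds[-1] + int(rng.integers(cfg.tad_min_bins, cfg.tad_max_bins + 1)))
        bounds[-1] = n
        arch[chrom] = {"biases": biases, "labels": labels, "tad_bounds": np.asarray(bounds)}
    return genome, arch


def _draw_loops(cfg, genome, rng, n, min_bins, max_bins):
    """Random loop bin pairs, deduplicated, flanked away from chromosome ends."""
    recs = []
    seen = set()
    guard = 0
    while len(recs) < n and guard < 50 * n:
        guard += 1
        chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
        nb = genome.n_bins(chrom)
        span = int(rng.integers(min_bins, max_bins + 1))
        b1 = int(rng.integers(2, nb - span - 2))
        key = (chrom, b1, b1 + span)
        if key in seen:
            continue
        seen.add(key)
        recs.append(key)
    return recs


def _lambda_map(cfg, arch_c, n, loops_c):
    """Unnormalized Poisson intensity for one chromosome.

    ``loops_c`` is a list of (b1, b2, strength) for this chromosome.
    """
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    lam = (d + 1.0) ** (-cfg.decay_exponent)
    b = arch_c["biases"]
    lam = lam * np.outer(b, b)
    e = arch_c["labels"].astype(float)
    lam = lam * np.exp(cfg.compartment_amplitude * np.outer(e, e))
    if cfg.tad_contrast != 1.0:
        bounds = arch_c["tad_bounds"]
        tad_id = np.searchsorted(bounds, np.arange(n), side="right")
        same = tad_id[:, None] == tad_id[None, :]
        lam = lam * np.where(same, cfg.tad_contrast, 1.0)
    for b1, b2, strength in loops_c:
        if strength == 1.0:
            continue
        c = 9.0 * (strength - 1.0) / _KERNEL_3X3
        for di in (-2, -1, 0, 1, 2):
            for dj in (-2, -1, 0, 1, 2):
                i, j = b1 + di, b2 + dj
                if 0 <= i < n and 0 <= j < n:
                    w = np.exp(-(di * di + dj * dj) / 2.0)
                    lam[i, j] *= 1.0 + c * w
                    lam[j, i] = lam[i, j]
    return lam


def _draw_counts(cfg, genome, arch, loop_df, strength_col, rng):
    """Poisson contact matrices for all chromosomes at the configured depth."""
    lams = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        sel = loop_df[loop_df["chrom"] == chrom] if loop_df is not None else None
        loops_c = (
            list(zip(sel["bin1"], sel["bin2"], sel[strength_col])) if sel is not None else []
        )
        lams[chrom] = _lambda_map(cfg, arch[chrom], n, loops_c)
    total = sum(np.triu(l).sum() for l in lams.values())
    out = {}
    for chrom, lam in lams.items():
        n = lam.shape[0]
        iu, ju = np.triu_indices(n)
        rates = lam[iu, ju] * (cfg.depth / total)
        counts = rng.poisson(rates)
        keep = counts > 0
        out[chrom] = ContactMatrix(
            chrom, cfg.bin_size, n, iu[keep], ju[keep], counts[keep].astype(float)
        )
    return out


def simulate_contact_map(cfg: SimulationConfig):
    """One raw contact map with planted compartments, TADs and loops.

    Returns ``(matrices, truth)`` where matrices is chrom -> ContactMatrix.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    genome, arch = _plan_architecture(cfg, rng)
    keys = _draw_loops(cfg, genome, rng, cfg.n_loops, cfg.loop_min_bins, cfg.loop_max_bins)
    loop_df = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "bin1": [k[1] for k in keys],
            "bin2": [k[2] for k in keys],
            "strength": cfg.loop_strength,
        }
    )
    matrices = _draw_counts(cfg, genome, arch, loop_df, "strength", rng)
    truth = TruthRecord(
        compartment_labels={c: arch[c]["labels"] for c in genome.chrom_names},
        tad_boundaries={c: arch[c]["tad_bounds"][1:-1] for c in genome.chrom_names},
        loops=loop_df,
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# chip landscape


@dataclass
class ChipLandscape:
    genome: GenomeModel
    genes: list
    active: np.ndarray               # per-gene bool
    sites: PeakSet                   # shared candidate sites (all classes)
    site_class: np.ndarray           # 'promoter' | 'enhancer' | 'ctcf'
    factor_peaks: dict               # factor -> PeakSet
    factor_tracks: dict              # factor -> SignalTrack
    truth: TruthRecord


def _make_genes(cfg, genome, rng):
    genes = []
    active = []
    k = 0
    for chrom in genome.chrom_names:
        size = genome.size(chrom)
        n_c = cfg.n_genes // cfg.n_chroms
        tss = np.sort(rng.choice(np.arange(20_000, size - 60_000, 2_000), n_c, replace=False))
        for t in tss:
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(5_000, 50_000))
            tes = t + length if strand == "+" else max(1000, t - length)
            genes.append(Gene(f"g{k:04d}", chrom, strand, int(t), int(tes)))
            active.append(rng.random() < cfg.active_frac)
            k += 1
    return genes, np.asarray(active)


def _peak_track(cfg, genome, centers_by_chrom, amps_by_chrom, rng):
    """Gaussian peak kernels (sd = peak_width/2) over background noise."""
    data = {}
    sd_bins = max(1.0, cfg.peak_width / 2 / cfg.track_bin)
    half = int(np.ceil(4 * sd_bins))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_bins) ** 2)
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom, cfg.track_bin)
        v = np.abs(rng.normal(0.0, cfg.track_noise_sd, n))
        for c, a in zip(centers_by_chrom.get(chrom, []), amps_by_chrom.get(chrom, [])):
            b = int(c) // cfg.track_bin
            lo, hi = max(0, b - half), min(n, b + half + 1)
            v[lo:hi] += a * kernel[half - (b - lo) : half + (hi - b)]
        data[chrom] = v
    return SignalTrack(cfg.track_bin, data)


def simulate_chip_landscape(cfg: SimulationConfig):
    """Factor peaks and tracks over a shared site pool with co-occupancy.

    Each factor occupies each candidate site independently with its
    configured probability; peak signal amplitudes are lognormal.  Raises if
    any occupancy probability exceeds 1.
    """
    if any(p > 1 or p < 0 for p in cfg.factor_probs.values()):
        raise ValueError("factor occupancy probabilities must lie in [0, 1]")
    rng = np.random.default_rng([cfg.seed, 2])
    genome = cfg.genome()
    genes, active = _make_genes(cfg, genome, rng)

    site_rows = []
    classes = []
    for g, a in zip(genes, active):
        if a:
            site_rows.append((g.chrom, g.tss))
            classes.append("promoter")
    for chrom in genome.chrom_names:
        size = genome.size(chrom)
        for cls, n_sites in (("enhancer", cfg.n_enhancers // cfg.n_chroms),
                             ("ctcf", cfg.n_ctcf_sites // cfg.n_chroms)):
            pos = rng.integers(10_000, size - 10_000, n_sites)
            site_rows.extend((chrom, int(p)) for p in pos)
            classes.extend([cls] * n_sites)
    w = cfg.peak_width
    sites = PeakSet.from_arrays(
        genome,
        [r[0] for r in site_rows],
        [max(0, r[1] - w // 2) for r in site_rows],
        [r[1] + w // 2 for r in site_rows],
    )
    # from_arrays sorts; recover the class per sorted site via position key
    key = {(r[0], max(0, r[1] - w // 2)): c for r, c in zip(site_rows, classes)}
    site_class = np.array([key[(c, int(s))] for c, s in zip(sites.chroms, sites.starts)])

    factor_peaks = {}
    factor_tracks = {}
    membership = {}
    for name, p in cfg.factor_probs.items():
        occupied = rng.random(len(sites)) < p
        amps = rng.lognormal(np.log(cfg.peak_amplitude), 0.3, len(sites))
        idx = np.flatnonzero(occupied)
        membership[name] = idx
        ps = sites.subset(occupied)
        ps.df["score"] = amps[occupied]
        factor_peaks[name] = PeakSet(ps.df, genome)
        centers = {}
        amplitudes = {}
        for chrom in genome.chrom_names:
            sel = ps.chroms == chrom
            centers[chrom] = ps.midpoints()[sel]
            amplitudes[chrom] = ps.df["score"].to_numpy()[sel]
        factor_tracks[name] = _peak_track(cfg, genome, centers, amplitudes, rng)

    truth = TruthRecord(factor_membership=membership)
    return ChipLandscape(genome, genes, active, sites, site_class, factor_peaks, factor_tracks, truth)


# ---------------------------------------------------------------------------
# perturbation experiment


@dataclass
class PerturbationExperiment:
    genome: GenomeModel
    matrices_before: dict
    matrices_after: dict
    loops: LoopSet
    genes: list
    gene_categories: np.ndarray
    tf_peaks: PeakSet
    tf_track: SignalTrack
    cohesin_peaks: PeakSet
    cohesin_before: SignalTrack
    cohesin_after: SignalTrack
    down_cohesin_peaks: PeakSet
    atac_peaks: PeakSet
    cohesin_lfc_per_atac: np.ndarray
    truth: TruthRecord


def simulate_perturbation_experiment(cfg: SimulationConfig) -> PerturbationExperiment:
    """Paired untreated/depleted maps, cohesin tracks and peak labels.

    The treated cohesin track is the untreated one multiplied by
    ``cohesin_reduction`` at factor-bound promoters only; planted responsive
    loops (long, factor-bound, cohesin-down) change strength by
    ``responsive_gain`` in the treated map; DE categories are enriched for
    'up' inside responsive loops.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    genome, arch = _plan_architecture(cfg, rng)
    genes, active = _make_genes(cfg, genome, rng)

    # loops: planted responsive (long), planted less-responsive (long), background
    def overlaps(a, b):
        return a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]

    resp_keys = _draw_loops(cfg, genome, rng, cfg.n_responsive,
                            cfg.responsive_min_bins, cfg.responsive_max_bins)
    # less-responsive spans are rejection-sampled away from responsive spans
    less_keys = []
    guard = 0
    while len(less_keys) < cfg.n_less_responsive and guard < 200 * cfg.n_less_responsive:
        guard += 1
        k = _draw_loops(cfg, genome, rng, 1, cfg.responsive_min_bins, cfg.responsive_max_bins)[0]
        if any(overlaps(k, r) for r in resp_keys + less_keys):
            continue
        less_keys.append(k)
    bg_keys = _draw_loops(cfg, genome, rng, cfg.n_loops, cfg.loop_min_bins, cfg.loop_max_bins)
    bg_keys = [
        k for k in bg_keys
        if not any(overlaps(k, r) for r in resp_keys + less_keys)
    ]
    keys = resp_keys + less_keys + bg_keys
    n_resp, n_less = len(resp_keys), len(less_keys)
    strength_before = np.full(len(keys), cfg.loop_strength)
    strength_after = strength_before.copy()
    strength_after[:n_resp] = 1.0 + (cfg.loop_strength - 1.0) * cfg.responsive_gain
    loop_df = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "bin1": [k[1] for k in keys],
            "bin2": [k[2] for k in keys],
            "strength": strength_before,
            "strength_after": strength_after,
        }
    )
    m_before = _draw_counts(cfg, genome, arch, loop_df, "strength",
                            np.random.default_rng([cfg.seed, 31]))
    m_after = _draw_counts(cfg, genome, arch, loop_df, "strength_after",
                           np.random.default_rng([cfg.seed, 32]))
    loops = LoopSet.from_bins(
        genome, loop_df["chrom"], loop_df["bin1"], loop_df["bin2"], cfg.bin_size
    )

    # factor-bound promoters: genes inside responsive spans + a random extra set
    tss = np.array([g.tss for g in genes])
    gchrom = np.array([g.chrom for g in genes])
    in_resp = np.zeros(len(genes), dtype=bool)
    for chrom, b1, b2 in resp_keys:
        s, e = b1 * cfg.bin_size, (b2 + 1) * cfg.bin_size
        in_resp |= (gchrom == chrom) & (tss >= s) & (tss < e)
    in_less = np.zeros(len(genes), dtype=bool)
    for chrom, b1, b2 in less_keys:
        s, e = b1 * cfg.bin_size, (b2 + 1) * cfg.bin_size
        in_less |= (gchrom == chrom) & (tss >= s) & (tss < e)
    extra = (rng.random(len(genes)) < cfg.tf_extra_frac) & ~in_resp & ~in_less
    tf_bound = (in_resp & ~in_less) | extra

    w = cfg.peak_width
    def promoter_peaks(mask, scores=None):
        sel = np.flatnonzero(mask)
        return PeakSet.from_arrays(
            genome,
            [genes[i].chrom for i in sel],
            [max(0, genes[i].tss - w // 2) for i in sel],
            [genes[i].tss + w // 2 for i in sel],
            score=(scores[sel] if scores is not None else np.ones(len(sel))),
        )

    tf_amp = rng.lognormal(np.log(cfg.peak_amplitude), 0.3, len(genes))
    tf_peaks = promoter_peaks(tf_bound, tf_amp)
    tf_track = _peak_track(
        cfg, genome,
        {c: np.array([g.tss for g, b in zip(genes, tf_bound) if b and g.chrom == c]) for c in genome.chrom_names},
        {c: np.array([a for g, b, a in zip(genes, tf_bound, tf_amp) if b and g.chrom == c]) for c in genome.chrom_names},
        rng,
    )

    # cohesin sits at every promoter; the treated track loses signal at
    # factor-bound promoters only
    coh_amp = rng.lognormal(np.log(cfg.peak_amplitude), 0.3, len(genes))
    cohesin_peaks = promoter_peaks(np.ones(len(genes), dtype=bool), coh_amp)
    centers = {c: np.array([g.tss for g in genes if g.chrom == c]) for c in genome.chrom_names}
    amps = {c: np.array([a for g, a in zip(genes, coh_amp) if g.chrom == c]) for c in genome.chrom_names}
    amps_after = {
        c: np.array([
            a * (cfg.cohesin_reduction if b else 1.0)
            for g, a, b in zip(genes, coh_amp, tf_bound) if g.chrom == c
        ])
        for c in genome.chrom_names
    }
    cohesin_before = _peak_track(cfg, genome, centers, amps, np.random.default_rng([cfg.seed, 33]))
    cohesin_after = _peak_track(cfg, genome, centers, amps_after, np.random.default_rng([cfg.seed, 34]))

    down_cohesin_peaks = promoter_peaks(tf_bound, coh_amp)
    down_cohesin_peaks.df["lfc"] = np.log2(cfg.cohesin_reduction)

    # ATAC peaks at every promoter; measured cohesin log2FC per peak
    atac_peaks = promoter_peaks(np.ones(len(genes), dtype=bool))
    lfc = np.empty(len(atac_peaks))
    for k, (chrom, s, e) in enumerate(zip(atac_peaks.chroms, atac_peaks.starts, atac_peaks.ends)):
        b = cohesin_before.region_mean(chrom, int(s), int(e))
        a = cohesin_after.region_mean(chrom, int(s), int(e))
        lfc[k] = np.log2((a + 0.01) / (b + 0.01))
    # gene categories, enriched for 'up' inside responsive loops
    p_up = np.where(in_resp, min(1.0, cfg.gene_up_rate * cfg.responsive_up_enrichment), cfg.gene_up_rate)
    u = rng.random(len(genes))
    categories = np.where(u < p_up, "up", np.where(u < p_up + cfg.gene_down_rate, "down", "unchanged"))

    truth = TruthRecord(
        compartment_labels={c: arch[c]["labels"] for c in genome.chrom_names},
        tad_boundaries={c: arch[c]["tad_bounds"][1:-1] for c in genome.chrom_names},
        loops=loop_df,
        responsive_loops=np.arange(n_resp),
        less_responsive_loops=np.arange(n_resp, n_resp + n_less),
        gene_categories={g.id: str(c) for g, c in zip(genes, categories)},
        bound_promoter_genes=[g.id for g, b in zip(genes, tf_bound) if b],
    )
    return PerturbationExperiment(
        genome, m_before, m_after, loops, genes, categories,
        tf_peaks, tf_track, cohesin_peaks, cohesin_before, cohesin_after,
        down_cohesin_peaks, atac_peaks, lfc, truth,
    )


# ---------------------------------------------------------------------------
# chip-ms and 4c


def simulate_psm_table(cfg: SimulationConfig):
    """Isoform-level PSM table with a planted enriched-protein set.

    Background proteins have chip ~= input (same Poisson mean); enriched
    proteins have chip counts at ``psm_enrich_ratio`` times the input mean.
    Returns ``(raw_isoform_table, isoform_map, truth)``.
    """
    from .chipms import PsmTable

    rng = np.random.default_rng([cfg.seed, 4])
    n_bg, n_en = cfg.n_background_proteins, cfg.n_enriched_proteins
    proteins = [f"P{k:04d}" for k in range(n_bg + n_en)]
    enriched = proteins[:n_en]
    samples = [f"chip{i + 1}" for i in range(cfg.n_chip_samples)] + [
        f"input{i + 1}" for i in range(cfg.n_input_samples)
    ]
    roles = {s: ("chip" if s.startswith("chip") else "input") for s in samples}
    base = rng.gamma(4.0, cfg.psm_mean / 4.0, n_bg + n_en)  # per-protein abundance
    rows = {}
    for k, pid in enumerate(proteins):
        mu_in = base[k]
        mu_chip = mu_in * (cfg.psm_enrich_ratio if pid in enriched else 1.0)
        rows[pid] = [
            int(rng.poisson(mu_chip)) for _ in range(cfg.n_chip_samples)
        ] + [int(rng.poisson(mu_in)) for _ in range(cfg.n_input_samples)]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)

    # split a fraction of proteins into two isoform rows
    iso_rows = {}
    isoform_map = {}
    for pid in proteins:
        vals = counts.loc[pid].to_numpy()
        if rng.random() < cfg.isoform_frac and vals.sum() > 1:
            split = rng.binomial(vals, 0.5)
            iso_rows[f"{pid}-1"] = split
            iso_rows[f"{pid}-2"] = vals - split
            isoform_map[f"{pid}-1"] = pid
            isoform_map[f"{pid}-2"] = pid
        else:
            iso_rows[pid] = vals
            isoform_map[pid] = pid
    raw = PsmTable(pd.DataFrame.from_dict(iso_rows, orient="index", columns=samples), roles)
    truth = TruthRecord(enriched_proteins=list(enriched))
    return raw, isoform_map, truth


def simulate_4c(cfg: SimulationConfig):
    """Bait-anchored near-cis 4C profile with one planted interacting region.

    Signal decays as 1/(distance + 5 kb) from the bait; a 120 kb region 1 Mb
    downstream is multiplied by ``fourc_fold``; counts are Poisson and the
    track is scaled to mean coverage 1 (RPGC-like).  Returns
    ``(track, truth)``; truth carries the planted region and the matched
    background region mirrored upstream of the bait.
    """
    rng = np.random.default_rng([cfg.seed, 5])
    genome = cfg.genome()
    chrom = genome.chrom_names[0]
    size = genome.size(chrom)
    bs = cfg.fourc_bin
    n = size // bs
    pos = (np.arange(n) + 0.5) * bs
    bait = size // 2
    lam = 1.0 / (np.abs(pos - bait) + 5_000.0)
    region = (chrom, bait + 1_000_000, bait + 1_120_000)
    background = (chrom, bait - 1_120_000, bait - 1_000_000)
    in_region = (pos >= region[1]) & (pos < region[2])
    lam = lam * np.where(in_region, cfg.fourc_fold, 1.0)
    lam = lam * (cfg.fourc_depth / lam.sum())
    counts = rng.poisson(lam).astype(float)
    track = SignalTrack(bs, {chrom: counts})
    track = track.scale(1.0 / max(counts.mean(), 1e-12), normalization="rpgc")
    truth = TruthRecord(fourc_region=region, fourc_background=background)
    return track, truth


# ---------------------------------------------------------------------------
# file emission


def write_perturbation_dataset(exp: PerturbationExperiment, outdir) -> dict:
    """Write every input class as the flat formats the pipeline reads.

    Returns the mapping of artifact name -> path.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = str(out / name)
        return out / name

    write_contacts(exp.matrices_before, p("contacts_untreated.coo.tsv"))
    write_contacts(exp.matrices_after, p("contacts_treated.coo.tsv"))
    write_loops(exp.loops, p("loops.bedpe"))
    write_genes(exp.genes, p("genes.tsv"))
    write_intervals(exp.tf_peaks, p("tf_peaks.bed"))
    write_intervals(exp.cohesin_peaks, p("cohesin_peaks.bed"))
    write_intervals(exp.down_cohesin_peaks, p("down_cohesin_peaks.bed"))
    write_intervals(exp.atac_peaks, p("atac_peaks.bed"))
    write_track(exp.tf_track, p("tf_signal.bedgraph"), exp.genome)
    write_track(exp.cohesin_before, p("cohesin_untreated.bedgraph"), exp.genome)
    write_track(exp.cohesin_after, p("cohesin_treated.bedgraph"), exp.genome)
    np.savetxt(p("cohesin_lfc_per_atac.tsv"), exp.cohesin_lfc_per_atac, fmt="%.6f")
    pd.DataFrame(
        {"id": [g.id for g in exp.genes], "category": exp.gene_categories}
    ).to_csv(p("gene_categories.tsv"), sep="\t", index=False)
    exp.truth.to_json(p("truth.json"))
    return paths
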