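"""Genome coordinate model, interval containers and flat-format I/O.

All coordinates are 0-based, half-open ``[start, end)``.  Inputs in 1-based
conventions must be converted by the caller.  Chromosome order is the order
of :class:`GenomeModel`, never lexicographic, so that sorting is reproducible
across genomes with non-alphabetic chromosome naming.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "PeakSet",
    "Gene",
    "SignalTrack",
    "read_intervals",
    "write_intervals",
    "read_track",
    "write_track",
    "read_genes",
    "write_genes",
    "intersect",
]


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and sizes, optionally with a bin size."""

    chrom_names: tuple
    chrom_sizes: Mapping[str, int]
    bin_size: int | None = None

    def __post_init__(self):
        names = tuple(self.chrom_names)
        object.__setattr__(self, "chrom_names", names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name in names:
            if self.chrom_sizes[name] <= 0:
                raise ValueError(f"non-positive size for chromosome {name}")
        if self.bin_size is not None and self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def size(self, chrom: str) -> int:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return int(self.chrom_sizes[chrom])

    def n_bins(self, chrom: str, bin_size: int | None = None) -> int:
        bs = bin_size if bin_size is not None else self.bin_size
        if bs is None:
            raise ValueError("no bin_size set")
        return -(-self.size(chrom) // bs)

    @classmethod
    def from_sizes(cls, sizes: Mapping[str, int], bin_size: int | None = None):
        return cls(tuple(sizes), dict(sizes), bin_size)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.id}")
        if self.tss == self.tes:
            raise ValueError(f"tss == tes for gene {self.id}")


_PEAK_COLUMNS = ("chrom", "start", "end", "score", "summit", "lfc", "label")


class PeakSet:
    """Scored genomic intervals stored as a DataFrame sorted by genome order.

    Columns: chrom, start, end, score (>=0), plus optional summit (absolute
    bp), lfc and label columns.  Sorting key is (genome chromosome order,
    start, end).
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeModel):
        df = df.copy()
        if "score" not in df:
            df["score"] = 0.0
        for chrom in df["chrom"].unique():
            if chrom not in genome.chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} not in genome")
        sizes = df["chrom"].map(genome.chrom_sizes)
        bad = (df["start"] < 0) | (df["end"] > sizes) | (df["start"] >= df["end"])
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"interval out of bounds: {row['chrom']}:{row['start']}-{row['end']}"
            )
        if (df["score"] < 0).any():
            raise ValueError("negative peak score")
        if "summit" in df:
            s = df["summit"].dropna()
            inside = (s >= df.loc[s.index, "start"]) & (s < df.loc[s.index, "end"])
            if not inside.all():
                raise ValueError("summit outside its interval")
        order = df["chrom"].map(genome.chrom_index)
        df = (
            df.assign(_order=order)
            .sort_values(["_order", "start", "end"], kind="stable")
            .drop(columns="_order")
            .reset_index(drop=True)
        )
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy(dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy(dtype=np.int64)

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def centers(self) -> np.ndarray:
        """Summit when present, midpoint otherwise."""
        mid = self.midpoints()
        if "summit" in self.df:
            s = self.df["summit"].to_numpy(dtype=float)
            return np.where(np.isfinite(s), s, mid).astype(np.int64)
        return mid

    def subset(self, mask) -> "PeakSet":
        return PeakSet(self.df[np.asarray(mask)].reset_index(drop=True), self.genome)

    @classmethod
    def from_arrays(cls, genome, chroms, starts, ends, **extra) -> "PeakSet":
        data = {"chrom": list(chroms), "start": list(starts), "end": list(ends)}
        data.update({k: list(v) for k, v in extra.items()})
        return cls(pd.DataFrame(data), genome)


@dataclass
class SignalTrack:
    """Fixed-bin genome-wide numeric signal (dense per-chromosome vectors)."""

    bin_size: int
    data: dict = field(default_factory=dict)  # chrom -> float ndarray
    normalization: str = "raw"

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.bin_size, {c: v.copy() for c, v in self.data.items()}, self.normalization
        )

    def scale(self, factor: float, normalization: str | None = None) -> "SignalTrack":
        out = self.copy()
        for c in out.data:
            out.data[c] = out.data[c] * factor
        if normalization is not None:
            out.normalization = normalization
        return out

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean of the piecewise-constant signal over [start, end)."""
        v = self.data[chrom]
        return float(
            _windowed_means(v, self.bin_size, np.array([start]), np.array([end]))[0]
        )


def _windowed_means(values: np.ndarray, bin_size: int, starts, ends) -> np.ndarray:
    """Exact length-weighted means of a binned signal over bp windows.

    Windows are clipped to the covered span; fully outside windows give nan.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    n = len(values)
    total = n * bin_size
    s = np.clip(starts, 0, total)
    e = np.clip(ends, 0, total)
    # prefix integral at arbitrary bp x of the piecewise-constant signal
    csum = np.concatenate([[0.0], np.cumsum(values) * bin_size])

    def integral(x):
        b = x // bin_size
        frac = x - b * bin_size
        b = np.minimum(b, n)
        base = csum[b]
        inside = b < n
        add = np.where(inside, frac * np.where(inside, values[np.minimum(b, n - 1)], 0.0), 0.0)
        return base + add

    length = (e - s).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (integral(e) - integral(s)) / length
    out[length <= 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# readers / writers


def read_intervals(path, genome: GenomeModel) -> PeakSet:
    """Read a BED/BED5/narrowPeak file into a :class:`PeakSet`.

    Score is taken from column 5 when present (else 0); a 10-column
    narrowPeak line supplies the summit as an offset from ``start``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = parts[0]
            if chrom not in genome.chrom_sizes:
                raise ValueError(
                    f"{path}: line {lineno}: chromosome {chrom!r} not in genome"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            rec = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 5 and parts[4] not in (".", ""):
                rec["score"] = float(parts[4])
            if len(parts) >= 10 and parts[9] not in (".", "-1", ""):
                rec["summit"] = start + int(parts[9])
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "summit"])
    if df["summit"].isna().all():
        df = df.drop(columns="summit")
    df["score"] = df["score"].fillna(0.0)
    return PeakSet(df, genome)


def write_intervals(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED5 (narrowPeak-style 10 columns when summits exist)."""
    df = peaks.df
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            cols = [row.chrom, str(int(row.start)), str(int(row.end)),
                    f"peak_{i}", _fmt(row.score)]
            if "summit" in df.columns and np.isfinite(getattr(row, "summit", np.nan)):
                cols += [".", "0", "-1", "-1", str(int(row.summit - row.start))]
            fh.write("\t".join(cols) + "\n")


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else repr(float(x))


def read_track(path, genome: GenomeModel, bin_size: int) -> SignalTrack:
    """Read a bedGraph into fixed bins by length-weighted averaging.

    Records must not overlap; uncovered bins are 0.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    recs: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: fewer than 4 columns")
            chrom = parts[0]
            if chrom not in genome.chrom_sizes:
                raise ValueError(
                    f"{path}: line {lineno}: chromosome {chrom!r} not in genome"
                )
            recs.setdefault(chrom, []).append(
                (int(parts[1]), int(parts[2]), float(parts[3]))
            )
    data = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom, bin_size)
        vec_num = np.zeros(n)
        vec_den = np.zeros(n)
        rows = sorted(recs.get(chrom, []))
        prev_end = -1
        for start, end, value in rows:
            if start < prev_end:
                raise ValueError(f"overlapping bedGraph records on {chrom} at {start}")
            prev_end = end
            b0, b1 = start // bin_size, -(-end // bin_size)
            for b in range(b0, min(b1, n)):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                vec_num[b] += value * (hi - lo)
                vec_den[b] += hi - lo
        with np.errstate(invalid="ignore"):
            vec = np.where(vec_den > 0, vec_num / np.maximum(vec_den, 1), 0.0)
        data[chrom] = vec
    return SignalTrack(bin_size, data)


def write_track(track: SignalTrack, path, genome: GenomeModel | None = None) -> None:
    """Write a SignalTrack as bedGraph, merging runs of equal value, skipping 0."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            i = 0
            n = len(values)
            while i < n:
                j = i
                while j + 1 < n and values[j + 1] == values[i]:
                    j += 1
                v = values[i]
                if v != 0 and np.isfinite(v):
                    end = (j + 1) * bs
                    if genome is not None:
                        end = min(end, genome.size(chrom))
                    fh.write(f"{chrom}\t{i * bs}\t{end}\t{_fmt(v)}\n")
                i = j + 1


def read_genes(path, genome: GenomeModel) -> list:
    """Read a tab-separated gene table with header id, chrom, strand, tss, tes."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "chrom", "strand", "tss", "tes"}
    if not required <= set(df.columns):
        raise ValueError(f"gene table missing columns {required - set(df.columns)}")
    genes = []
    for row in df.itertuples(index=False):
        if row.chrom not in genome.chrom_sizes:
            raise ValueError(f"chromosome {row.chrom!r} not in genome")
        genes.append(Gene(str(row.id), row.chrom, row.strand, int(row.tss), int(row.tes)))
    return genes


def write_genes(genes: Sequence[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstrand\ttss\ttes\n")
        for g in genes:
            fh.write(f"{g.id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\n")


# ---------------------------------------------------------------------------
# interval intersection


def intersect(a: PeakSet, b: PeakSet):
    """Overlap test between two sorted interval sets (half-open semantics).

    Returns ``(hit, pairs)`` where ``hit[i]`` is True iff a-interval i shares
    >=1 bp with any b interval, and ``pairs`` is the sorted list of (i, j)
    overlapping index pairs.  Sorted-input sweep, O(n + m + k).
    """
    hit = np.zeros(len(a), dtype=bool)
    pairs: list[tuple[int, int]] = []
    adf, bdf = a.df, b.df
    for chrom in set(adf["chrom"]).intersection(bdf["chrom"]):
        ai = np.flatnonzero((adf["chrom"] == chrom).to_numpy())
        bi = np.flatnonzero((bdf["chrom"] == chrom).to_numpy())
        astart, aend = a.starts[ai], a.ends[ai]
        bstart, bend = b.starts[bi], b.ends[bi]
        # sweep over intervals of both sets ordered by start
        events = []  # (start, source, local index)
        events = sorted(
            [(astart[k], 0, k) for k in range(len(ai))]
            + [(bstart[k], 1, k) for k in range(len(bi))]
        )
        active_a: dict[int, int] = {}
        active_b: dict[int, int] = {}
        for start, src, k in events:
            if src == 0:
                for kb in list(active_b):
                    if bend[kb] <= start:
                        del active_b[kb]
                for kb in active_b:
                    pairs.append((int(ai[k]), int(bi[kb])))
                    hit[ai[k]] = True
                active_a[k] = 1
            else:
                for ka in list(active_a):
                    if aend[ka] <= start:
                        del active_a[ka]
                for ka in active_a:
                    pairs.append((int(ai[ka]), int(bi[k])))
                    hit[ai[ka]] = True
                active_b[k] = 1
    pairs.sort()
    return hit, pairs
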