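"""Domain containers and plain-text genomic I/O.

One internal coordinate convention is used everywhere: 0-based, half-open
intervals (BED-native).  Conversion, where a format needs it, happens only at
the parse/serialize boundary.  All parsers validate coordinates against the
chromosome sizes table and *reject* out-of-range records rather than clamping
them.

Containers
----------
``GenomeAnnotation``
    The gene universe: one TSS per gene with strand and chromosome, plus the
    chromosome sizes table that is the reference frame for every distance
    computation downstream.
``PeakSet``
    A named collection of binding-site intervals, each with an absolute summit
    coordinate and a score.
``CoverageTrack``
    Binned per-chromosome read density with the library size that produced it.
``DETable``
    Per-gene log2 fold changes and BH-adjusted p-values for the two contrasts
    (pre-B and immature B), plus an expression-pattern cluster label.

Formats: BED3/4/6, 10-column narrowPeak, bedGraph, two-column chrom.sizes,
and TSV tables with fixed headers.  Round-trip identity (``read(write(x)) ==
x``) holds for in-range data at matching parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, FormatError, ParseError, ValidationError

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "summit"]
GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss"]
DE_COLUMNS = [
    "gene_id",
    "log2fc_preB",
    "fdr_preB",
    "log2fc_immB",
    "fdr_immB",
    "cluster",
]
CONTRASTS = ("preB", "immB")
CLUSTER_LABELS = ("I", "II", "III", "IV", "V", "VI")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenomeAnnotation:
    genes: pd.DataFrame  # columns: gene_id, chrom, strand, tss
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        g = self.genes
        missing = [c for c in GENE_COLUMNS if c not in g.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        if len(g) == 0:
            raise ValidationError("annotation must contain at least one gene")
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        for chrom, sub in g.groupby("chrom", sort=False):
            if chrom not in self.chrom_sizes:
                raise ValidationError(f"gene chromosome {chrom!r} not in chrom_sizes")
            size = self.chrom_sizes[chrom]
            tss = sub["tss"].to_numpy()
            if (tss < 0).any() or (tss >= size).any():
                raise CoordinateError(f"TSS outside [0, {size}) on {chrom}")

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return (
            self.chrom_sizes == other.chrom_sizes
            and self.genes.reset_index(drop=True).equals(other.genes.reset_index(drop=True))
        )


@dataclass
class PeakSet:
    name: str
    peaks: pd.DataFrame  # columns: chrom, start, end, name, score, summit

    def __post_init__(self) -> None:
        p = self.peaks
        missing = [c for c in PEAK_COLUMNS if c not in p.columns]
        if missing:
            raise ValidationError(f"peak table missing columns {missing}")
        start = p["start"].to_numpy()
        end = p["end"].to_numpy()
        summit = p["summit"].to_numpy()
        if (start < 0).any() or (start >= end).any():
            raise ValidationError("peaks require 0 <= start < end")
        if (summit < start).any() or (summit >= end).any():
            raise ValidationError("peak summit must lie inside [start, end)")

    def __len__(self) -> int:
        return len(self.peaks)

    def validate_bounds(self, chrom_sizes: dict[str, int]) -> None:
        for chrom, sub in self.peaks.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise CoordinateError(f"peak chromosome {chrom!r} not in chrom_sizes")
            if (sub["end"].to_numpy() > chrom_sizes[chrom]).any():
                raise CoordinateError(f"peak interval beyond end of {chrom}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.name == other.name and self.peaks.reset_index(drop=True).equals(
            other.peaks.reset_index(drop=True)
        )


@dataclass
class CoverageTrack:
    name: str
    bin_size: int
    values: dict[str, np.ndarray]  # chrom -> per-bin densities
    libsize: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        if self.libsize < 0:
            raise ValidationError("libsize must be nonnegative")
        for chrom, v in self.values.items():
            arr = np.asarray(v, dtype=float)
            if (arr < 0).any():
                raise ValidationError(f"negative coverage on {chrom}")
            self.values[chrom] = arr
            if chrom in self.chrom_sizes:
                expect = math.ceil(self.chrom_sizes[chrom] / self.bin_size)
                if len(arr) != expect:
                    raise ValidationError(
                        f"{chrom}: expected {expect} bins, got {len(arr)}"
                    )

    def scaled(self, factor: float, name: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            name=name or self.name,
            bin_size=self.bin_size,
            values={c: v * factor for c, v in self.values.items()},
            libsize=self.libsize,
            chrom_sizes=dict(self.chrom_sizes),
        )

    def allclose(self, other: "CoverageTrack", atol: float = 1e-9) -> bool:
        if set(self.values) != set(other.values) or self.bin_size != other.bin_size:
            return False
        return all(
            np.allclose(self.values[c], other.values[c], atol=atol) for c in self.values
        )


@dataclass
class DETable:
    rows: pd.DataFrame  # DE_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"DE table missing columns {missing}")
        for c in ("fdr_preB", "fdr_immB"):
            v = self.rows[c].to_numpy(dtype=float)
            if (v < 0).any() or (v > 1).any():
                raise ValidationError(f"{c} outside [0, 1]")
        bad = ~self.rows["cluster"].isin(CLUSTER_LABELS + ("none",))
        if bad.any():
            raise ValidationError(
                f"unknown cluster label {self.rows.loc[bad, 'cluster'].iloc[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.rows)

    def cluster_genes(self, label: str) -> set[str]:
        return set(self.rows.loc[self.rows["cluster"] == label, "gene_id"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DETable):
            return NotImplemented
        return self.rows.reset_index(drop=True).equals(other.rows.reset_index(drop=True))


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _split_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def _as_int(value: str, what: str, path, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"non-integer {what} {value!r}", path, lineno) from None


def _as_float(value: str, what: str, path, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"non-numeric {what} {value!r}", path, lineno) from None


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, fields in _split_lines(path):
        if len(fields) < 2:
            raise ParseError("chrom.sizes needs two columns", path, lineno)
        size = _as_int(fields[1], "chromosome size", path, lineno)
        if size <= 0:
            raise ParseError(f"non-positive size for {fields[0]}", path, lineno)
        sizes[fields[0]] = size
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# annotation TSV
# ---------------------------------------------------------------------------


def read_annotation(path, chrom_sizes: dict[str, int]) -> GenomeAnnotation:
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ParseError(f"annotation TSV missing columns {missing}", path)
    genes["tss"] = genes["tss"].astype(int)
    return GenomeAnnotation(genes=genes[GENE_COLUMNS], chrom_sizes=dict(chrom_sizes))


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    annotation.genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peaks: BED / narrowPeak
# ---------------------------------------------------------------------------


def read_peaks(path, chrom_sizes: dict[str, int], name: str | None = None) -> PeakSet:
    """Parse BED3/4/6 or 10-column narrowPeak into a validated :class:`PeakSet`.

    The summit is ``start + column-10 offset`` for narrowPeak records (a ``-1``
    offset falls back to the midpoint rule) and the interval midpoint,
    ``floor((start + end) / 2)``, for plain BED.
    """
    records = []
    for lineno, f in _split_lines(path):
        if len(f) < 3:
            raise ParseError("BED needs at least 3 columns", path, lineno)
        chrom = f[0]
        start = _as_int(f[1], "start", path, lineno)
        end = _as_int(f[2], "end", path, lineno)
        if chrom not in chrom_sizes:
            raise CoordinateError(f"unknown chromosome {chrom!r}", path, lineno)
        if start < 0 or start >= end or end > chrom_sizes[chrom]:
            raise CoordinateError(
                f"interval [{start}, {end}) outside [0, {chrom_sizes[chrom]}) on {chrom}",
                path,
                lineno,
            )
        peak_name = f[3] if len(f) >= 4 else f"peak_{lineno}"
        score = _as_float(f[4], "score", path, lineno) if len(f) >= 5 else 0.0
        if len(f) >= 10:  # narrowPeak: col 7 = signalValue, col 10 = summit offset
            score = _as_float(f[6], "signalValue", path, lineno)
            offset = _as_int(f[9], "summit offset", path, lineno)
            summit = start + offset if offset >= 0 else (start + end) // 2
        else:
            summit = (start + end) // 2
        if not start <= summit < end:
            raise CoordinateError(f"summit {summit} outside interval", path, lineno)
        records.append((chrom, start, end, peak_name, score, summit))
    peaks = pd.DataFrame(records, columns=PEAK_COLUMNS)
    if len(peaks) == 0:
        peaks = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=int),
                "end": pd.Series(dtype=int),
                "name": pd.Series(dtype=str),
                "score": pd.Series(dtype=float),
                "summit": pd.Series(dtype=int),
            }
        )
    ps = PeakSet(name=name or str(path), peaks=peaks)
    ps.validate_bounds(chrom_sizes)
    return ps


def write_peaks(peak_set: PeakSet, path) -> None:
    """Write 10-column narrowPeak (summit as column-10 offset from start)."""
    with open(path, "w") as fh:
        for row in peak_set.peaks.itertuples(index=False):
            offset = int(row.summit) - int(row.start)
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.name}\t0\t.\t"
                f"{row.score:.6g}\t-1\t-1\t{offset}\n"
            )


# ---------------------------------------------------------------------------
# coverage: bedGraph
# ---------------------------------------------------------------------------


def n_bins(length: int, bin_size: int) -> int:
    return math.ceil(length / bin_size)


def _bin_spans(length: int, bin_size: int) -> np.ndarray:
    """Actual base span of each bin (the last bin may be truncated)."""
    nb = n_bins(length, bin_size)
    spans = np.full(nb, bin_size, dtype=float)
    rem = length - (nb - 1) * bin_size
    spans[-1] = rem
    return spans


def read_coverage(
    path, chrom_sizes: dict[str, int], bin_size: int = 25, name: str | None = None
) -> CoverageTrack:
    """Parse a bedGraph into a binned track.

    Values are rebinned by length-weighted averaging over each bin's base
    span; uncovered bases contribute zero.  Overlapping records on one
    chromosome are a format error.  An optional leading ``track`` line with a
    ``libsize=`` attribute carries the library size; otherwise libsize is the
    rounded total signal.
    """
    libsize = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("track"):
        for token in first.split():
            if token.startswith("libsize="):
                libsize = int(token.split("=", 1)[1])

    accum = {c: np.zeros(n_bins(s, bin_size)) for c, s in chrom_sizes.items()}
    last_end: dict[str, int] = {}
    intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for lineno, f in _split_lines(path):
        if len(f) < 4:
            raise ParseError("bedGraph needs 4 columns", path, lineno)
        chrom = f[0]
        if chrom not in chrom_sizes:
            raise CoordinateError(f"unknown chromosome {chrom!r}", path, lineno)
        start = _as_int(f[1], "start", path, lineno)
        end = _as_int(f[2], "end", path, lineno)
        value = _as_float(f[3], "value", path, lineno)
        if start < 0 or start >= end or end > chrom_sizes[chrom]:
            raise CoordinateError(f"interval [{start}, {end}) out of bounds", path, lineno)
        if value < 0:
            raise FormatError("negative coverage value", path, lineno)
        intervals[chrom].append((start, end))
        first_bin = start // bin_size
        last_bin = (end - 1) // bin_size
        for b in range(first_bin, last_bin + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            accum[chrom][b] += value * (hi - lo)
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping bedGraph records on {chrom}", path)
    values = {
        c: accum[c] / _bin_spans(chrom_sizes[c], bin_size) for c in chrom_sizes
    }
    if libsize is None:
        libsize = int(round(sum(float(a.sum()) for a in accum.values())))
    return CoverageTrack(
        name=name or str(path),
        bin_size=bin_size,
        values=values,
        libsize=libsize,
        chrom_sizes=dict(chrom_sizes),
    )


def write_coverage(track: CoverageTrack, path) -> None:
    """Write bedGraph with run-length merging of equal adjacent bins."""
    with open(path, "w") as fh:
        fh.write(
            f"track type=bedGraph name={track.name} libsize={track.libsize} "
            f"bin_size={track.bin_size}\n"
        )
        for chrom, vals in track.values.items():
            length = track.chrom_sizes.get(chrom, len(vals) * track.bin_size)
            run_start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[run_start]:
                    v = vals[run_start]
                    if v != 0.0:
                        s = run_start * track.bin_size
                        e = min(i * track.bin_size, length)
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
                    run_start = i


# ---------------------------------------------------------------------------
# DE table TSV
# ---------------------------------------------------------------------------


def read_de_table(path) -> DETable:
    rows = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "cluster" not in rows.columns:
        rows["cluster"] = "none"
    rows["cluster"] = rows["cluster"].fillna("none").astype(str)
    missing = [c for c in DE_COLUMNS if c not in rows.columns]
    if missing:
        raise ParseError(f"DE table missing columns {missing}", path)
    return DETable(rows=rows[DE_COLUMNS])


def write_de_table(de: DETable, path) -> None:
    out = de.rows[DE_COLUMNS].copy()
    for c in ("log2fc_preB", "fdr_preB", "log2fc_immB", "fdr_immB"):
        out[c] = out[c].map(lambda x: f"{x:.10g}")
    out.to_csv(path, sep="\t", index=False)
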