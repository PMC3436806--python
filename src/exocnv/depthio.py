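"""Capture regions, per-base read depth and sample-normalized depth matrices.

Exome capture yields read depth only over the targeted regions, so all
depth summaries here are computed over the capture footprint (the union
of capture regions); it stands in for "genome-wide" depth because
off-target bases are not consistently observed.

Coordinates are BED-style throughout: 0-based, half-open.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CaptureRegion",
    "Sample",
    "RegionDepthMatrix",
    "DepthTable",
    "load_regions",
    "load_manifest",
    "write_manifest",
    "per_base_depth",
    "sample_mean_depth",
    "build_normalized_matrix",
    "region_gc",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


class BedParseError(ValueError):
    """Raised for a malformed BED line; message names the line number."""


@dataclass(frozen=True)
class CaptureRegion:
    """One capture target: ``chrom:[start, end)`` with an identifier.

    ``gc_fraction`` is the G+C fraction of the reference sequence over the
    region, in [0, 1], or ``None`` when unknown.
    """

    chrom: str
    start: int
    end: int
    region_id: str
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.region_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(
                f"region {self.region_id}: gc_fraction {self.gc_fraction} outside [0, 1]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Sample:
    """One cohort member: identifier, 0/1 phenotype and its depth source.

    ``mean_depth`` is the average fold-coverage over the capture footprint,
    filled in by :func:`sample_mean_depth` (or supplied directly).
    """

    sample_id: str
    phenotype: int
    depth_source: str | None = None
    mean_depth: float | None = None

    def __post_init__(self) -> None:
        if self.phenotype not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id}: phenotype must be 0 or 1, got {self.phenotype}"
            )
        if self.mean_depth is not None and not self.mean_depth > 0:
            raise ValueError(f"sample {self.sample_id}: mean_depth must be > 0")


@dataclass
class RegionDepthMatrix:
    """Per-base normalized depth for one region: rows = bases, cols = samples.

    Entry (j, k) is the raw depth at base ``start + j`` in sample k divided
    by that sample's mean capture-footprint depth, so a diploid-typical
    base sits near 1 for every sample regardless of sequencing yield.
    """

    region: CaptureRegion
    values: np.ndarray
    sample_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != self.region.length:
            raise ValueError(
                f"region {self.region.region_id}: {self.values.shape[0]} rows for "
                f"length {self.region.length}"
            )
        if self.sample_order and len(self.sample_order) != self.values.shape[1]:
            raise ValueError("sample_order length does not match column count")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("normalized depths must be finite and non-negative")


def load_regions(
    bed_source, gc_column: int | None = None
) -> list[CaptureRegion]:
    """Parse capture regions from a BED source (path or open text handle).

    Column 4, when present, supplies ``region_id``; otherwise the id is
    ``chrom:start-end``.  ``gc_column`` (0-based) optionally names a numeric
    column holding the per-region GC fraction.
    """
    close = False
    if isinstance(bed_source, (str, os.PathLike)):
        handle = open(bed_source)
        close = True
    else:
        handle = bed_source
    regions: list[CaptureRegion] = []
    seen: set[str] = set()
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates {parts[1]!r}, {parts[2]!r}"
                ) from None
            if start >= end:
                raise BedParseError(f"line {lineno}: start {start} >= end {end}")
            region_id = parts[3] if len(parts) > 3 and parts[3] else f"{parts[0]}:{start}-{end}"
            if region_id in seen:
                raise BedParseError(f"line {lineno}: duplicate region_id {region_id!r}")
            seen.add(region_id)
            gc = None
            if gc_column is not None:
                if gc_column >= len(parts):
                    raise BedParseError(f"line {lineno}: no column {gc_column} for GC")
                try:
                    gc = float(parts[gc_column])
                except ValueError:
                    raise BedParseError(
                        f"line {lineno}: non-numeric GC value {parts[gc_column]!r}"
                    ) from None
            regions.append(CaptureRegion(parts[0], start, end, region_id, gc))
    finally:
        if close:
            handle.close()
    return regions


def load_manifest(path) -> list[Sample]:
    """Read a sample manifest TSV: sample_id, phenotype, depth_source[, mean_depth].

    A relative ``depth_source`` is resolved against the manifest's own
    directory, so a fixture directory stays relocatable.
    """
    base = os.path.dirname(os.fspath(path))
    samples: list[Sample] = []
    seen: set[str] = set()
    with open(path) as handle:
        header = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None and parts[0] == "sample_id":
                header = parts
                continue
            sid = parts[0]
            if sid in seen:
                raise ValueError(f"duplicate sample_id {sid!r} in manifest")
            seen.add(sid)
            mean_depth = None
            if len(parts) > 3 and parts[3] not in ("", "NA"):
                mean_depth = float(parts[3])
            source = parts[2] if len(parts) > 2 and parts[2] else None
            if source and not os.path.isabs(source):
                resolved = os.path.join(base, source)
                if os.path.exists(resolved):
                    source = resolved
            samples.append(Sample(sid, int(parts[1]), source, mean_depth))
    return samples


def write_manifest(samples: Sequence[Sample], path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("sample_id\tphenotype\tdepth_source\tmean_depth\n")
        for s in samples:
            md = "NA" if s.mean_depth is None else repr(float(s.mean_depth))
            out.write(f"{s.sample_id}\t{s.phenotype}\t{s.depth_source or ''}\t{md}\n")


# ---------------------------------------------------------------------------
# depth sources
# ---------------------------------------------------------------------------


class DepthTable:
    """Per-base depth table: header ``chrom pos sample_1 ... sample_N``.

    One row per captured base, positions 0-based, raw integer depths.  A
    single table can carry the whole cohort; per-sample lookup goes through
    the column name.
    """

    def __init__(self, chroms: np.ndarray, pos: np.ndarray, depths: np.ndarray,
                 sample_ids: list[str]):
        self.chroms = np.asarray(chroms)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.depths = np.asarray(depths)
        self.sample_ids = list(sample_ids)
        self._col = {sid: i for i, sid in enumerate(self.sample_ids)}

    @classmethod
    def read(cls, path) -> "DepthTable":
        chroms: list[str] = []
        pos: list[int] = []
        rows: list[list[int]] = []
        with open(path) as handle:
            header = None
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if header is None:
                    if parts[0] != "chrom" or parts[1] != "pos":
                        raise ValueError(
                            f"{path}: depth table must start with 'chrom\\tpos' header"
                        )
                    header = parts
                    continue
                chroms.append(parts[0])
                pos.append(int(parts[1]))
                rows.append([int(v) for v in parts[2:]])
        if header is None:
            raise ValueError(f"{path}: empty depth table")
        depths = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(header) - 2), int)
        return cls(np.array(chroms), np.array(pos, dtype=np.int64), depths, header[2:])

    def write(self, path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as out:
            for line in header_lines:
                out.write(f"# {line}\n")
            out.write("chrom\tpos\t" + "\t".join(self.sample_ids) + "\n")
            for i in range(len(self.pos)):
                row = "\t".join(str(int(v)) for v in self.depths[i])
                out.write(f"{self.chroms[i]}\t{int(self.pos[i])}\t{row}\n")

    def region_depth(self, region: CaptureRegion, sample_id: str) -> np.ndarray:
        if sample_id not in self._col:
            raise KeyError(f"sample {sample_id!r} not in depth table")
        if not np.any(self.chroms == region.chrom):
            raise ValueError(f"chromosome {region.chrom!r} absent from depth table")
        mask = (self.chroms == region.chrom) & (self.pos >= region.start) & (self.pos < region.end)
        out = np.zeros(region.length, dtype=np.int64)
        out[self.pos[mask] - region.start] = self.depths[mask, self._col[sample_id]]
        return out

    def region_matrix(self, region: CaptureRegion) -> np.ndarray:
        """All-sample raw depth for one region, rows = bases, cols = samples."""
        if not np.any(self.chroms == region.chrom):
            raise ValueError(f"chromosome {region.chrom!r} absent from depth table")
        mask = (self.chroms == region.chrom) & (self.pos >= region.start) & (self.pos < region.end)
        out = np.zeros((region.length, len(self.sample_ids)), dtype=np.int64)
        out[self.pos[mask] - region.start] = self.depths[mask]
        return out


def _alignment_depth(path: str, region: CaptureRegion, min_mapq: int) -> np.ndarray:
    """Per-base depth from SAM/BAM/CRAM by counting the aligned reference span.

    A read contributes 1 to every base its reference span covers; no base
    quality filter, duplicates counted, strand ignored.  BAM/CRAM require an
    index; plain SAM is streamed end to end.
    """
    import pysam

    depth = np.zeros(region.length, dtype=np.int64)

    def add(read) -> None:
        if read.is_unmapped or read.mapping_quality < min_mapq:
            return
        s = max(read.reference_start, region.start)
        e = min(read.reference_end or read.reference_start, region.end)
        if s < e:
            depth[s - region.start : e - region.start] += 1

    is_sam = str(path).endswith(".sam")
    mode = "r" if is_sam else "rb"
    with pysam.AlignmentFile(path, mode) as af:
        if region.chrom not in af.references:
            raise ValueError(f"chromosome {region.chrom!r} absent from {path}")
        if is_sam:
            for read in af.fetch(until_eof=True):
                if read.reference_name == region.chrom:
                    add(read)
        else:
            try:
                reads = af.fetch(region.chrom, region.start, region.end)
            except ValueError as exc:
                raise ValueError(f"{path}: alignment file is not indexed") from exc
            for read in reads:
                add(read)
    return depth


def per_base_depth(depth_source, region: CaptureRegion, sample_id: str | None = None,
                   min_mapq: int = 0) -> np.ndarray:
    """Per-base raw read depth over ``region`` for one sample.

    ``depth_source`` is a :class:`DepthTable` (``sample_id`` required), a
    path to a depth-table TSV, or a path to a SAM/BAM alignment.  Bases with
    no coverage are 0, never missing.
    """
    if isinstance(depth_source, DepthTable):
        if sample_id is None:
            raise ValueError("sample_id required with a DepthTable source")
        return depth_source.region_depth(region, sample_id)
    path = str(depth_source)
    if path.endswith((".sam", ".bam", ".cram")):
        return _alignment_depth(path, region, min_mapq)
    return DepthTable.read(path).region_depth(region, sample_id)


def sample_mean_depth(depth_source, regions: Sequence[CaptureRegion],
                      sample_id: str | None = None, min_mapq: int = 0) -> float:
    """Average fold-coverage of one sample over the capture footprint.

    Total covered-base count across all regions divided by the total region
    length.  A sample with zero depth everywhere is unusable and raises.
    """
    total_len = sum(r.length for r in regions)
    if total_len == 0:
        raise ValueError("no capture bases: all regions empty")
    total = 0
    for region in regions:
        total += int(per_base_depth(depth_source, region, sample_id, min_mapq).sum())
    if total == 0:
        raise ValueError(
            f"sample {sample_id or depth_source}: zero depth over the capture footprint"
        )
    return total / total_len


def build_normalized_matrix(region: CaptureRegion, samples: Sequence[Sample],
                            depth_source=None, min_mapq: int = 0) -> RegionDepthMatrix:
    """Assemble the M x N normalized depth matrix r for one region.

    Each sample's raw per-base depth is divided by its ``mean_depth``
    (which must be populated).  ``depth_source`` may be a shared
    :class:`DepthTable`; otherwise each sample's ``depth_source`` path is
    read.
    """
    if region.length == 0:
        raise ValueError(f"region {region.region_id} has length 0")
    cols = []
    for s in samples:
        if s.mean_depth is None:
            raise ValueError(f"sample {s.sample_id}: mean_depth not populated")
        src = depth_source if depth_source is not None else s.depth_source
        raw = per_base_depth(src, region, s.sample_id, min_mapq)
        cols.append(raw / s.mean_depth)
    values = np.column_stack(cols)
    return RegionDepthMatrix(region, values, [s.sample_id for s in samples])


def region_gc(region: CaptureRegion, reference) -> float | None:
    """G+C fraction of the reference sequence over ``region``.

    ``reference`` is a pyfaidx ``Fasta`` or a FASTA path.  Ambiguous bases
    are excluded from the denominator; a region of only ambiguous bases has
    no defined GC and returns ``None``.
    """
    from pyfaidx import Fasta

    fasta = reference if not isinstance(reference, (str, os.PathLike)) else Fasta(str(reference))
    if region.chrom not in fasta:
        raise ValueError(f"chromosome {region.chrom!r} absent from reference")
    seq = str(fasta[region.chrom][region.start : region.end]).upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return gc / acgt


def write_matrix_tsv(matrix: RegionDepthMatrix, path, header_lines: Iterable[str] = ()) -> None:
    """Write a normalized matrix as TSV: header of sample ids, one row per base.

    Values use shortest round-trip float formatting so read-back is exact.
    """
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("\t".join(matrix.sample_order) + "\n")
        for row in matrix.values:
            out.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_tsv(path, region: CaptureRegion) -> RegionDepthMatrix:
    rows: list[list[float]] = []
    with open(path) as handle:
        header = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append([float(v) for v in line.split("\t")])
    if header is None:
        raise ValueError(f"{path}: empty matrix file")
    return RegionDepthMatrix(region, np.array(rows, dtype=float), header)
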