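"""Regions, binned coverage profiles, filters, and the standard file formats.

A *profile* is one peak region together with its coverage sequence: the
region is split into non-overlapping bins of fixed genomic width (50 bp by
default) and each bin holds the number of sequencing fragments overlapping
it, one column per epigenomic track.  Profiles are what the warping and
clustering machinery consumes.

Supported inputs are BED for regions, BAM/SAM for read coverage (reads are
extended to the fragment length before counting), and a plain tab-separated
profile table for alignment-free workflows such as simulations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "Profile",
    "ProfileSet",
    "read_regions",
    "write_regions",
    "compute_binned_coverage",
    "assemble_multitrack",
    "filter_profiles",
    "normalize_by_height",
    "write_cluster_beds",
    "read_profile_table",
    "write_profile_table",
]


@dataclass(frozen=True)
class Region:
    """A genomic interval in BED convention: 0-based, half-open."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"region {self.name!r}: strand must be '+', '-' or '.'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def n_bins(self, bin_size: int) -> int:
        return -(-self.length // bin_size)  # ceil division


class Profile:
    """A region plus its binned coverage matrix of shape (n_bins, n_tracks).

    The last bin may cover fewer base pairs than ``bin_size`` when the region
    length is not a multiple of the bin width; it still counts as a full bin.
    """

    __slots__ = ("region", "values", "bin_size", "track_names")

    def __init__(
        self,
        region: Region,
        values: np.ndarray,
        bin_size: int,
        track_names: Sequence[str] | None = None,
    ):
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError("values must be 1-D or (n_bins, n_tracks)")
        if (arr < 0).any():
            raise ValueError(f"profile {region.name!r}: negative bin values")
        expected = region.n_bins(bin_size)
        if arr.shape[0] != expected:
            raise ValueError(
                f"profile {region.name!r}: {arr.shape[0]} bins but region spans "
                f"{expected} bins of {bin_size} bp"
            )
        self.region = region
        self.values = arr
        self.bin_size = bin_size
        self.track_names = (
            list(track_names) if track_names is not None else [f"track_{t}" for t in range(arr.shape[1])]
        )
        if len(self.track_names) != arr.shape[1]:
            raise ValueError("track_names length must match the number of value columns")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.values.shape[1]

    @property
    def total_count(self) -> float:
        return float(self.values.sum())

    @property
    def name(self) -> str:
        return self.region.name

    def reversed(self) -> "Profile":
        """Bin order reversed jointly across tracks (the strand flip)."""
        return Profile(self.region, self.values[::-1].copy(), self.bin_size, self.track_names)

    def __repr__(self) -> str:
        return (
            f"Profile({self.region.name}, {self.n_bins} bins x {self.n_tracks} "
            f"track{'s' if self.n_tracks != 1 else ''})"
        )


@dataclass
class ProfileSet:
    """An ordered collection of profiles; order is the input order and is
    preserved by every operation in the package."""

    profiles: list[Profile] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.profiles)

    @property
    def regions(self) -> list[Region]:
        return [p.region for p in self.profiles]

    @property
    def names(self) -> list[str]:
        return [p.region.name for p in self.profiles]

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[Profile]:
        return iter(self.profiles)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ProfileSet(self.profiles[i])
        return self.profiles[i]


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def read_regions(path: str | Path) -> list[Region]:
    """Parse a BED3+ file into regions.

    Coordinates follow the BED convention (0-based, half-open).  Records
    without a name column are named ``peak_<line-index>`` (1-based line
    numbers, counting data lines).  Duplicate names are rejected so that
    downstream outputs stay unambiguous.
    """
    path = Path(path)
    regions: list[Region] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in {"", "."} else f"peak_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            try:
                region = Region(chrom, start, end, name, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate region name {name!r}")
            seen.add(name)
            regions.append(region)
    return regions


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as BED6 (score column fixed at 0)."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# coverage binning
# ---------------------------------------------------------------------------


def _fragment_interval(read, fragment_length: int) -> tuple[int, int]:
    """Genomic interval of the sequenced fragment a read represents.

    Paired-end reads use the actual template length; single-end reads are
    extended from their 5' end to ``fragment_length`` in the strand
    direction, the standard surrogate for the unsequenced fragment tail.
    """
    if read.is_paired and read.is_proper_pair and read.template_length != 0:
        tlen = abs(read.template_length)
        if read.template_length > 0:
            return read.reference_start, read.reference_start + tlen
        return read.reference_end - tlen, read.reference_end
    if read.is_reverse:
        return read.reference_end - fragment_length, read.reference_end
    return read.reference_start, read.reference_start + fragment_length


def compute_binned_coverage(
    alignment_source,
    region: Region,
    bin_size: int = 50,
    fragment_length: int = 200,
    track_name: str | None = None,
) -> Profile:
    """Binned fragment coverage of one region from a BAM/SAM file.

    ``alignment_source`` is a path or an open :class:`pysam.AlignmentFile`.
    A fragment contributes 1 to every bin it overlaps by at least one base
    pair (integer pileup semantics, not fractional).  Reads whose extended
    fragment misses the region entirely contribute nothing.
    """
    import pysam

    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    own = isinstance(alignment_source, (str, Path))
    af = pysam.AlignmentFile(str(alignment_source)) if own else alignment_source
    try:
        n_bins = region.n_bins(bin_size)
        counts = np.zeros(n_bins, dtype=np.float64)
        ref_len = None
        try:
            ref_len = af.get_reference_length(region.chrom)
        except (KeyError, ValueError):
            raise IOError(f"chromosome {region.chrom!r} absent from alignment file")
        fetch_end = region.end
        if ref_len is not None and region.end > ref_len:
            warnings.warn(
                f"region {region.name!r} extends past the end of {region.chrom} "
                f"({region.end} > {ref_len}); clipping"
            )
            fetch_end = ref_len
        # widen the fetch window so fragments starting outside still count
        fetch_start = max(0, region.start - fragment_length)
        try:
            reads = af.fetch(region.chrom, fetch_start, fetch_end)
        except ValueError:
            # no index (e.g. plain SAM): stream everything and filter
            if not own:
                raise IOError(
                    "alignment file has no index; pass a file path so the "
                    "stream can be re-read per region"
                )
            reads = (
                r
                for r in af.fetch(until_eof=True)
                if r.reference_name == region.chrom
                and r.reference_start < fetch_end
                and (r.reference_end or r.reference_start) > fetch_start
            )
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired and read.is_proper_pair and read.template_length < 0:
                continue  # count each template once, from the leftmost mate
            fstart, fend = _fragment_interval(read, fragment_length)
            lo = max(fstart, region.start)
            hi = min(fend, region.end)
            if hi <= lo:
                continue
            first = (lo - region.start) // bin_size
            last = (hi - 1 - region.start) // bin_size
            counts[first : last + 1] += 1
        name = track_name or (Path(str(alignment_source)).stem if own else "coverage")
        return Profile(region, counts, bin_size, [name])
    finally:
        if own:
            af.close()


def build_profiles(
    bam_path: str | Path,
    regions: Sequence[Region],
    bin_size: int = 50,
    fragment_length: int = 200,
    track_name: str | None = None,
) -> ProfileSet:
    """Binned coverage for every region from one alignment file."""
    import pysam

    name = track_name or Path(str(bam_path)).stem
    with pysam.AlignmentFile(str(bam_path)) as af:
        indexed = af.has_index()
        if indexed:
            return ProfileSet(
                [
                    compute_binned_coverage(af, r, bin_size, fragment_length, name)
                    for r in regions
                ]
            )
    # unindexed (e.g. plain SAM): re-stream the file for each region
    return ProfileSet(
        [
            compute_binned_coverage(bam_path, r, bin_size, fragment_length, name)
            for r in regions
        ]
    )


def assemble_multitrack(tracks: Sequence[ProfileSet]) -> ProfileSet:
    """Column-stack single-track profile sets over identical regions.

    All sets must list the same regions in the same order with the same bin
    size; the resulting profiles carry one value column per input set, in
    the given order, so every mark contributes with equal weight to the
    local distance.
    """
    if not tracks:
        raise ValueError("no tracks given")
    first = tracks[0]
    for other in tracks[1:]:
        if other.size != first.size:
            raise ValueError("track profile sets differ in size")
        for p0, p1 in zip(first, other):
            if p0.region != p1.region:
                raise ValueError(f"region mismatch between tracks at {p0.region.name!r}")
            if p0.bin_size != p1.bin_size:
                raise ValueError(f"bin size mismatch between tracks at {p0.region.name!r}")
    out = []
    for i in range(first.size):
        values = np.hstack([t[i].values for t in tracks])
        names = [n for t in tracks for n in t[i].track_names]
        out.append(Profile(first[i].region, values, first[i].bin_size, names))
    return ProfileSet(out)


# ---------------------------------------------------------------------------
# filters and transforms
# ---------------------------------------------------------------------------


def filter_profiles(
    profiles: ProfileSet,
    min_bins: int = 5,
    max_bins: int = 1000,
    min_total_count: float = 10,
    per_track_count: bool = False,
) -> tuple[ProfileSet, list[tuple[str, str]]]:
    """Drop profiles outside the length window or below the count floor.

    Keeps profiles with ``min_bins < n_bins < max_bins`` (both bounds
    strict) and total count >= ``min_total_count``.  The count is summed
    over all bins and all tracks by default; with ``per_track_count`` every
    track must individually reach the floor.  Returns the surviving subset
    in the original order and a log of (name, reason) discards.
    """
    if min_bins >= max_bins:
        raise ValueError("min_bins must be < max_bins")
    kept: list[Profile] = []
    discarded: list[tuple[str, str]] = []
    for p in profiles:
        if p.n_bins <= min_bins:
            discarded.append((p.name, f"too short ({p.n_bins} bins <= {min_bins})"))
        elif p.n_bins >= max_bins:
            discarded.append((p.name, f"too long ({p.n_bins} bins >= {max_bins})"))
        else:
            counts = p.values.sum(axis=0) if per_track_count else [p.total_count]
            if min(counts) < min_total_count:
                discarded.append((p.name, f"low count ({p.total_count:g} < {min_total_count:g})"))
            else:
                kept.append(p)
    if not kept:
        warnings.warn("all profiles were filtered out")
    return ProfileSet(kept), discarded


def normalize_by_height(profile: Profile) -> Profile:
    """Divide each track by its own maximum so that every track peaks at 1."""
    peaks = profile.values.max(axis=0)
    if (peaks <= 0).any():
        bad = profile.track_names[int(np.argmin(peaks))]
        raise ValueError(f"profile {profile.name!r}: track {bad!r} is all zero, cannot normalize")
    return Profile(profile.region, profile.values / peaks, profile.bin_size, profile.track_names)


# ---------------------------------------------------------------------------
# cluster exports
# ---------------------------------------------------------------------------


def write_cluster_beds(
    labels: Sequence[int], regions: Sequence[Region], out_dir: str | Path
) -> list[Path]:
    """One BED file per cluster, ``cluster_<k>.bed``, sorted by (chrom, start).

    The files partition the input: their union is exactly the input regions
    and no region appears in two files.
    """
    if len(labels) != len(regions):
        raise ValueError("labels and regions differ in length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for k in sorted(set(labels)):
        members = sorted(
            (r for r, lab in zip(regions, labels) if lab == k),
            key=lambda r: (r.chrom, r.start, r.end),
        )
        path = out_dir / f"cluster_{k}.bed"
        write_regions(members, path)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# TSV profile tables (alignment-free input path)
# ---------------------------------------------------------------------------

_TSV_HEADER = ("region", "chrom", "start", "end", "strand", "track", "values")


def write_profile_table(profiles: ProfileSet, path: str | Path) -> None:
    """Tab-separated profile table: one row per (region, track).

    Bin values are comma-joined in the last column so that profiles of
    different lengths share one rectangular file.
    """
    with Path(path).open("w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for p in profiles:
            r = p.region
            for t, tname in enumerate(p.track_names):
                vals = ",".join(format(v, "g") for v in p.values[:, t])
                fh.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{tname}\t{vals}\n")


def read_profile_table(path: str | Path, bin_size: int = 50) -> ProfileSet:
    """Read the TSV written by :func:`write_profile_table`."""
    path = Path(path)
    rows: dict[str, dict] = {}
    order: list[str] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TSV_HEADER:
            raise ValueError(f"{path}: unexpected profile-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_TSV_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_TSV_HEADER)} fields")
            name, chrom, start, end, strand, track, vals = fields
            values = np.array([float(v) for v in vals.split(",")], dtype=np.float64)
            if name not in rows:
                rows[name] = {
                    "region": Region(chrom, int(start), int(end), name, strand),
                    "tracks": [],
                    "values": [],
                }
                order.append(name)
            entry = rows[name]
            entry["tracks"].append(track)
            entry["values"].append(values)
    profiles = []
    for name in order:
        entry = rows[name]
        mat = np.column_stack(entry["values"])
        profiles.append(Profile(entry["region"], mat, bin_size, entry["tracks"]))
    return ProfileSet(profiles)
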