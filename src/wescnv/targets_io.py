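"""Reading and writing per-target count/GC files, cohort bundles and call tables.

The unit of analysis in exome read-depth CNV calling is the capture *target*:
a 1-based inclusive genomic interval with a known GC fraction.  Every sample
in a cohort is counted on the same ordered set of targets (the
:class:`TargetGrid`), which gives all per-sample vectors a shared coordinate
system.

File formats (all plain TSV, ``#`` comments allowed):

``*.gc``
    4 columns: chrom, start (1-based), end (inclusive), GC fraction in [0, 1].
``*.count``
    4 columns: chrom, start, end, non-negative integer read count.  The
    interval set must match the grid exactly (any row order).
``*.tar.gz`` bundle
    exactly one ``*.gc`` member plus one ``*.count`` member per sample.
call table (TSV dialect)
    9 columns: chrom, start, end, copy_number, gain_loss, score, sample_id,
    share_count, known_overlap ("." when the call matches no catalog record).
BED dialect
    BED5 with 0-based half-open coordinates, name ``sample:copy_number`` and
    the reliability score clamped to [0, 1000].
"""

from __future__ import annotations

import os
import tarfile
import tempfile
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    AssignmentError,
    FormatError,
    ParseError,
    ValidationError,
)

__all__ = [
    "TargetRegion",
    "TargetGrid",
    "SampleCounts",
    "CohortBundle",
    "read_gc_file",
    "write_gc_file",
    "read_count_file",
    "write_count_file",
    "read_bundle",
    "write_bundle",
    "write_calls",
    "read_calls",
]

CALL_TABLE_COLUMNS = (
    "chrom",
    "start",
    "end",
    "copy_number",
    "gain_loss",
    "score",
    "sample_id",
    "share_count",
    "known_overlap",
)


@dataclass(frozen=True)
class TargetRegion:
    """One exome capture interval (1-based inclusive) with its GC fraction."""

    chrom: str
    start: int
    end: int
    gc: float

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(
                f"target {self.chrom}:{self.start}-{self.end}: start must be >= 1"
            )
        if self.end < self.start:
            raise ValidationError(
                f"target {self.chrom}:{self.start}-{self.end}: end < start"
            )
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError(
                f"target {self.chrom}:{self.start}-{self.end}: "
                f"GC fraction {self.gc} outside [0, 1]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class TargetGrid:
    """Canonically ordered, non-overlapping target regions shared by a cohort.

    Regions are sorted by (chromosome lexical, start ascending); ordinal
    positions 0..n-1 index every per-sample vector.  Chromosome names are
    compared as plain strings — no "chr" prefix or build is assumed.
    """

    def __init__(self, regions: Sequence[TargetRegion]):
        regs = sorted(regions, key=lambda r: (r.chrom, r.start))
        prev: TargetRegion | None = None
        for r in regs:
            if prev is not None and r.chrom == prev.chrom and r.start <= prev.end:
                raise ValidationError(
                    f"overlapping targets on {r.chrom}: "
                    f"{prev.start}-{prev.end} and {r.start}-{r.end}"
                )
            prev = r
        self.regions: tuple[TargetRegion, ...] = tuple(regs)
        self.index: dict[tuple[str, int, int], int] = {
            (r.chrom, r.start, r.end): i for i, r in enumerate(self.regions)
        }
        self.chroms = np.array([r.chrom for r in self.regions], dtype=object)
        self.starts = np.array([r.start for r in self.regions], dtype=np.int64)
        self.ends = np.array([r.end for r in self.regions], dtype=np.int64)
        self.gc = np.array([r.gc for r in self.regions], dtype=float)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[TargetRegion]:
        return iter(self.regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetGrid):
            return NotImplemented
        return self.regions == other.regions

    def __repr__(self) -> str:
        nchrom = len(dict.fromkeys(r.chrom for r in self.regions))
        return f"TargetGrid({len(self)} targets on {nchrom} chromosomes)"

    def chrom_ranges(self) -> list[tuple[str, int, int]]:
        """Contiguous ordinal ranges ``(chrom, lo, hi)`` (half-open) per chromosome."""
        out: list[tuple[str, int, int]] = []
        lo = 0
        for i in range(1, len(self.regions) + 1):
            if i == len(self.regions) or self.regions[i].chrom != self.regions[lo].chrom:
                out.append((self.regions[lo].chrom, lo, i))
                lo = i
        return out


@dataclass
class SampleCounts:
    """Per-target read counts for one sample, aligned to a grid."""

    sample_id: str
    counts: np.ndarray
    role: str = "patient"  # "patient" | "control"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.role not in ("patient", "control"):
            raise ValidationError(f"unknown sample role {self.role!r}")
        if np.any(self.counts < 0):
            raise ValidationError(f"sample {self.sample_id}: negative read count")


@dataclass
class CohortBundle:
    """A target grid plus every sample counted on it."""

    grid: TargetGrid
    samples: list[SampleCounts] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in cohort")
        for s in self.samples:
            if len(s.counts) != len(self.grid):
                raise AlignmentError(
                    f"sample {s.sample_id}: {len(s.counts)} counts for a grid "
                    f"of {len(self.grid)} targets"
                )
        if not self.patients:
            raise ValidationError("a cohort needs at least one patient sample")

    @property
    def patients(self) -> list[SampleCounts]:
        return [s for s in self.samples if s.role == "patient"]

    @property
    def controls(self) -> list[SampleCounts]:
        return [s for s in self.samples if s.role == "control"]

    @property
    def reference_required(self) -> bool:
        """True when no controls are present and an external reference is needed."""
        return len(self.controls) == 0


def _iter_interval_rows(path: str):
    """Yield (lineno, chrom, start, end, value_string) from a 4-column TSV."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, value = (f.strip() for f in fields)
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            yield lineno, chrom, start, end, value


def read_gc_file(path: str) -> TargetGrid:
    """Read a ``*.gc`` file into a canonically sorted :class:`TargetGrid`.

    Rows may appear in any order; the grid sorts them.  Malformed lines raise
    :class:`ParseError` naming the line; out-of-range GC, end < start or
    overlapping intervals raise :class:`ValidationError`.
    """
    regions = []
    for lineno, chrom, start, end, value in _iter_interval_rows(path):
        try:
            gc = float(value)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric GC value {value!r}") from None
        regions.append(TargetRegion(chrom, start, end, gc))
    return TargetGrid(regions)


def write_gc_file(grid: TargetGrid, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgc\n")
        for r in grid:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{float(r.gc)!r}\n")


def read_count_file(path: str, grid: TargetGrid) -> SampleCounts:
    """Read a ``*.count`` file aligned to *grid*.

    The file's intervals must match the grid one-to-one (any row order).  The
    sample id defaults to the file basename without its extension.
    """
    seen: dict[tuple[str, int, int], int] = {}
    order: list[tuple[str, int, int]] = []
    for lineno, chrom, start, end, value in _iter_interval_rows(path):
        try:
            count = int(value)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric count {value!r}") from None
        if count < 0:
            raise ValidationError(f"{path}:{lineno}: negative count {count}")
        key = (chrom, start, end)
        if key in seen:
            raise AlignmentError(
                f"{path}:{lineno}: duplicate row for {chrom}:{start}-{end}"
            )
        seen[key] = count
        order.append(key)

    counts = np.empty(len(grid), dtype=np.int64)
    for i, r in enumerate(grid):
        key = (r.chrom, r.start, r.end)
        if key not in seen:
            raise AlignmentError(
                f"{path}: target {r.chrom}:{r.start}-{r.end} missing "
                "(count file does not match the grid)"
            )
        counts[i] = seen.pop(key)
    if seen:
        chrom, start, end = next(k for k in order if k in seen)
        raise AlignmentError(
            f"{path}: row {chrom}:{start}-{end} has no matching grid target"
        )
    sample_id = os.path.splitext(os.path.basename(path))[0]
    return SampleCounts(sample_id=sample_id, counts=counts)


def write_count_file(sample: SampleCounts, grid: TargetGrid, path: str) -> None:
    if len(sample.counts) != len(grid):
        raise AlignmentError(
            f"sample {sample.sample_id} not aligned to grid when writing {path}"
        )
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcount\n")
        for r, c in zip(grid, sample.counts):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{int(c)}\n")


def read_bundle(
    path: str,
    patient_ids: set[str],
    control_ids: set[str] | None = None,
) -> CohortBundle:
    """Unpack a ``*.tar.gz`` cohort bundle and assign sample roles.

    The archive must contain exactly one ``*.gc`` member and at least one
    ``*.count`` member.  Every count file's basename (without extension) must
    appear in *patient_ids* or *control_ids*.  With no controls assigned the
    bundle is flagged ``reference_required`` and downstream calling needs an
    external reference profile.
    """
    control_ids = control_ids or set()
    with tarfile.open(path, "r:*") as tar, tempfile.TemporaryDirectory() as tmp:
        members = [m for m in tar.getmembers() if m.isfile()]
        gc_members = [m for m in members if m.name.endswith(".gc")]
        count_members = [m for m in members if m.name.endswith(".count")]
        if len(gc_members) != 1:
            raise FormatError(
                f"{path}: expected exactly one .gc member, found {len(gc_members)}"
            )
        if not count_members:
            raise FormatError(f"{path}: no .count members")

        def extract(member: tarfile.TarInfo) -> str:
            # flatten paths: archives may nest members in a directory
            dest = os.path.join(tmp, os.path.basename(member.name))
            src = tar.extractfile(member)
            assert src is not None
            with open(dest, "wb") as out:
                out.write(src.read())
            return dest

        grid = read_gc_file(extract(gc_members[0]))
        samples = []
        for m in sorted(count_members, key=lambda m: m.name):
            sc = read_count_file(extract(m), grid)
            if sc.sample_id in patient_ids:
                sc.role = "patient"
            elif sc.sample_id in control_ids:
                sc.role = "control"
            else:
                raise AssignmentError(
                    f"sample {sc.sample_id!r} assigned neither patient nor control"
                )
            samples.append(sc)
    return CohortBundle(grid=grid, samples=samples)


def write_bundle(bundle: CohortBundle, path: str, gc_name: str = "targets.gc") -> None:
    """Write a cohort as a gzip-compressed tar of one .gc + per-sample .count files."""
    with tempfile.TemporaryDirectory() as tmp, tarfile.open(path, "w:gz") as tar:
        gc_path = os.path.join(tmp, gc_name)
        write_gc_file(bundle.grid, gc_path)
        tar.add(gc_path, arcname=gc_name)
        for s in bundle.samples:
            cpath = os.path.join(tmp, f"{s.sample_id}.count")
            write_count_file(s, bundle.grid, cpath)
            tar.add(cpath, arcname=os.path.basename(cpath))


def _format_score(score: float) -> str:
    # scores are stored to 1 decimal; print "95" rather than "95.0"
    return f"{score:g}"


def write_calls(calls: Sequence, path: str, dialect: str = "tsv") -> None:
    """Write calls as a 9-column TSV table or as BED5.

    TSV keeps 1-based inclusive coordinates; BED converts to 0-based
    half-open (``bed_start = start - 1``, ``bed_end = end``) with name
    ``sample_id:copy_number`` and the score clamped to [0, 1000].
    """
    if dialect not in ("tsv", "bed"):
        raise FormatError(f"unknown call-table dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
            for c in calls:
                known = ";".join(c.known_ids) if c.known_ids else "."
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_number}\t"
                    f"{c.gain_loss}\t{_format_score(c.score)}\t{c.sample_id}\t"
                    f"{c.share_count}\t{known}\n"
                )
        else:
            for c in calls:
                bed_score = int(round(min(max(c.score, 0.0), 1000.0)))
                fh.write(
                    f"{c.chrom}\t{c.start - 1}\t{c.end}\t"
                    f"{c.sample_id}:{c.copy_number}\t{bed_score}\n"
                )


def read_calls(path: str) -> list:
    """Read a TSV call table written by :func:`write_calls` back into calls.

    Grid ordinals are not part of the table and come back as ``None``.
    """
    from .hmm_caller import CNVCall

    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CALL_TABLE_COLUMNS:
            raise FormatError(f"{path}: unexpected call-table header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(CALL_TABLE_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(CALL_TABLE_COLUMNS)} columns"
                )
            chrom, start, end, cn, gain_loss, score, sample_id, share, known = fields
            call = CNVCall(
                sample_id=sample_id,
                chrom=chrom,
                start=int(start),
                end=int(end),
                copy_number=int(cn),
                score=float(score),
                share_count=int(share),
                known_ids=tuple(known.split(";")) if known != "." else (),
            )
            if call.gain_loss != gain_loss:
                raise ValidationError(
                    f"{path}:{lineno}: gain_loss column {gain_loss!r} contradicts "
                    f"copy number {cn}"
                )
            calls.append(call)
    return calls
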