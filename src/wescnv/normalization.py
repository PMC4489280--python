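"""From raw per-target read counts to GC-corrected log2 ratio profiles.

The chain, applied per patient against a pooled-control reference:

1. **Sample normalization** — divide each target's count by the sample's
   total, so samples of different sequencing depth are comparable.
2. **Reference** — the arithmetic mean of the *normalized* control profiles.
   (Controls are normalized before averaging; averaging raw counts would
   weight deep controls more.)
3. **Ratio** — patient / reference per target; for copy number ``c`` on an
   autosome this sits near ``c / 2``.
4. **GC correction** — sequencing depth depends systematically on a target's
   GC fraction.  Targets are binned by GC (default bin width 0.02) and each
   ratio is divided by its bin's median ratio; sparse bins (< ``min_bin``
   targets) fall back to the global median.  Median-of-bin division is the
   robust, deterministic correction used throughout read-depth callers;
   setting ``method="none"`` skips it.
5. **log2 + re-centering** — ratios are log2-transformed (so one copy-number
   doubling is +1) and the genome-wide median log2 ratio is subtracted,
   pinning the diploid baseline at 0.

Masking: targets where the reference is exactly 0 carry no information and
are masked.  A patient zero against a positive reference is kept as a
pseudo-ratio ``eps / reference`` with ``eps`` = half the smallest positive
normalized patient value — this preserves the strong homozygous-deletion
signal without producing ``-inf``.  No step ever unmasks a target.

Sex chromosomes are treated like autosomes; callers analysing chrX/chrY in
mixed-sex cohorts should restrict or interpret those calls themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateSampleError,
    EmptyProfileError,
    ValidationError,
)
from .targets_io import SampleCounts, TargetGrid, _iter_interval_rows

__all__ = [
    "NormalizedProfile",
    "ReferenceProfile",
    "RatioProfile",
    "normalize_sample",
    "build_reference",
    "compute_ratio",
    "correct_gc_bias",
    "make_observations",
    "read_reference",
    "write_reference",
]


@dataclass
class NormalizedProfile:
    """Per-target fraction of a sample's total reads (sums to 1)."""

    sample_id: str
    values: np.ndarray


@dataclass
class ReferenceProfile:
    """Mean normalized control profile; the read-depth model of a normal genome."""

    values: np.ndarray
    n_controls: int = 0


@dataclass
class RatioProfile:
    """Per-target patient/reference ratios, raw or log2-corrected.

    ``mask`` marks excluded targets (True = excluded); their values are NaN.
    ``space`` is ``"ratio"`` before GC correction and ``"log2"`` after.
    When built through :func:`make_observations` the profile carries its
    grid, which the HMM uses to split per-chromosome chains.
    """

    sample_id: str
    values: np.ndarray
    mask: np.ndarray
    space: str = "ratio"
    grid: TargetGrid | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise AlignmentError("ratio values and mask have different lengths")

    @property
    def log2_ratio(self) -> np.ndarray:
        if self.space != "log2":
            raise ValidationError("profile is not in log2 space yet")
        return self.values

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())


def normalize_sample(sample: SampleCounts) -> NormalizedProfile:
    """Divide each target's count by the sample total."""
    total = int(sample.counts.sum())
    if total <= 0:
        raise DegenerateSampleError(f"sample {sample.sample_id}: all counts are zero")
    return NormalizedProfile(sample.sample_id, sample.counts / total)


def build_reference(controls: list[SampleCounts]) -> ReferenceProfile:
    """Average the normalized control profiles into a common reference."""
    if not controls:
        raise ValidationError(
            "no control samples: supply an external reference profile "
            "(see read_reference / the CLI --reference option)"
        )
    stacked = np.vstack([normalize_sample(c).values for c in controls])
    return ReferenceProfile(values=stacked.mean(axis=0), n_controls=len(controls))


def compute_ratio(
    patient: NormalizedProfile, reference: ReferenceProfile
) -> RatioProfile:
    """Per-target patient/reference ratio (pre-log).

    Zero-reference targets are masked; zero-patient targets against a
    positive reference get the pseudo-ratio described in the module notes.
    """
    p = np.asarray(patient.values, dtype=float)
    r = np.asarray(reference.values, dtype=float)
    if p.shape != r.shape:
        raise AlignmentError(
            f"patient profile has {p.size} targets, reference {r.size}"
        )
    mask = r == 0.0
    values = np.full(p.shape, np.nan)
    ok = ~mask
    pos = ok & (p > 0)
    values[pos] = p[pos] / r[pos]
    zero = ok & (p == 0)
    if zero.any():
        positive = p[p > 0]
        if positive.size == 0:
            raise DegenerateSampleError(
                f"sample {patient.sample_id}: no positive normalized values"
            )
        eps = 0.5 * positive.min()
        values[zero] = eps / r[zero]
    return RatioProfile(patient.sample_id, values, mask, space="ratio")


def correct_gc_bias(
    raw: RatioProfile,
    grid: TargetGrid,
    bin_width: float = 0.02,
    min_bin: int = 10,
    method: str = "median_bin",
) -> RatioProfile:
    """GC-bin median correction, log2 transform and genome-median re-centering.

    Invariant under global rescaling of the raw ratios: multiplying every
    ratio by a constant changes neither the corrected values nor the mask.
    """
    if raw.space != "ratio":
        raise ValidationError("correct_gc_bias expects a raw (pre-log) ratio profile")
    if method not in ("median_bin", "none"):
        raise ValidationError(f"unknown gc correction method {method!r}")
    if len(raw.values) != len(grid):
        raise AlignmentError("ratio profile not aligned to grid")
    unmasked = ~raw.mask
    if not unmasked.any():
        raise EmptyProfileError(f"sample {raw.sample_id}: no unmasked targets")

    values = raw.values.copy()
    if method == "median_bin":
        gc = np.clip(grid.gc, 0.0, np.nextafter(1.0, 0.0))
        bins = np.floor(gc / bin_width).astype(np.int64)
        global_med = float(np.median(values[unmasked]))
        for b in np.unique(bins[unmasked]):
            sel = unmasked & (bins == b)
            med = float(np.median(values[sel])) if sel.sum() >= min_bin else global_med
            if med > 0:
                values[sel] = values[sel] / med

    log2 = np.full(values.shape, np.nan)
    log2[unmasked] = np.log2(values[unmasked])
    log2[unmasked] -= np.median(log2[unmasked])
    return RatioProfile(raw.sample_id, log2, raw.mask.copy(), space="log2", grid=grid)


def make_observations(
    patient: SampleCounts,
    grid: TargetGrid,
    *,
    controls: list[SampleCounts] | None = None,
    reference: ReferenceProfile | None = None,
    gc_method: str = "median_bin",
    bin_width: float = 0.02,
    min_bin: int = 10,
) -> RatioProfile:
    """Full normalization chain: counts -> GC-corrected log2 ratio profile.

    Exactly one of *controls* or *reference* must be given.
    """
    if (controls is None) == (reference is None):
        raise ValidationError("give exactly one of controls= or reference=")
    if reference is None:
        reference = build_reference(controls)  # type: ignore[arg-type]
    if len(reference.values) != len(grid):
        raise AlignmentError("reference profile not aligned to grid")
    norm = normalize_sample(patient)
    raw = compute_ratio(norm, reference)
    return correct_gc_bias(raw, grid, bin_width=bin_width, min_bin=min_bin, method=gc_method)


def write_reference(reference: ReferenceProfile, grid: TargetGrid, path: str) -> None:
    """Export a reference profile as 4-column TSV (chrom, start, end, value)."""
    if len(reference.values) != len(grid):
        raise AlignmentError("reference profile not aligned to grid")
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\treference\n")
        for r, v in zip(grid, reference.values):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{float(v)!r}\n")


def read_reference(path: str, grid: TargetGrid) -> ReferenceProfile:
    """Import a reference profile TSV, validated against *grid*.

    The file format does not record how many controls went into the profile,
    so ``n_controls`` is 0, meaning "external".
    """
    seen: dict[tuple[str, int, int], float] = {}
    for lineno, chrom, start, end, value in _iter_interval_rows(path):
        try:
            v = float(value)
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: non-numeric reference value {value!r}"
            ) from None
        if v < 0:
            raise ValidationError(f"{path}:{lineno}: negative reference value")
        seen[(chrom, start, end)] = v
    values = np.empty(len(grid))
    for i, r in enumerate(grid):
        key = (r.chrom, r.start, r.end)
        if key not in seen:
            raise AlignmentError(
                f"{path}: target {r.chrom}:{r.start}-{r.end} missing from reference"
            )
        values[i] = seen.pop(key)
    if seen:
        k = next(iter(seen))
        raise AlignmentError(f"{path}: row {k[0]}:{k[1]}-{k[2]} not on the grid")
    return ReferenceProfile(values=values, n_controls=0)
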