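"""Annotation of CNV calls against user-supplied flat files.

Four annotation layers, each driven by a plain file the user provides:

* **Gene content** — gene models from BED (0-based half-open) or GFF3
  (``gene`` features); a gene is CNV-associated when the fraction of its
  length covered by a call exceeds ``min_coverage`` (default 0.9, strict).
* **Known-CNV catalogs** — a TSV of previously reported CNVs (chrom, start,
  end, id, optional gain/loss type; 1-based inclusive coordinates).  A call
  matches a record at reciprocal overlap ≥ ``min_recip`` (default 0.5):
  the overlap must cover that fraction of *both* intervals.
* **Term enrichment** — GMT term sets (GO, pathways, domains...); one-sided
  Fisher's exact test (hypergeometric upper tail) per term with Bonferroni
  correction over the tested terms.
* **Per-gene side tables** — free-form TSVs keyed by gene id (disease
  variants, knockout phenotypes, expression...), left-joined onto the gene
  hits while keeping the sample attribution, so each annotation row still
  says which sample carries the CNV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .errors import FormatError, InputError, ParseError, ValidationError
from .hmm_caller import CNVCall

__all__ = [
    "GeneModel",
    "GeneHit",
    "KnownCNV",
    "EnrichmentResult",
    "load_gene_models",
    "load_known_cnvs",
    "read_gmt",
    "annotate_genes",
    "match_known_cnvs",
    "fisher_enrichment",
    "join_sample_annotations",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"gene {self.gene_id}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneHit:
    """One (call, gene) association with the fraction of the gene covered."""

    gene_id: str
    call: CNVCall
    coverage: float

    @property
    def sample_id(self) -> str:
        return self.call.sample_id


@dataclass(frozen=True)
class KnownCNV:
    record_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str | None = None  # "gain" | "loss" | None


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    p_adj: float


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for piece in attr.strip().split(";"):
        if "=" in piece:
            key, _, value = piece.partition("=")
            out[key.strip()] = value.strip()
    return out


def _load_genes_bed(path: str) -> list[tuple[str, str, int, int]]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED gene rows need >= 4 columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric BED coordinates") from None
            rows.append((name, chrom, start0 + 1, end0))  # to 1-based inclusive
    return rows


def _load_genes_gff3(path: str) -> list[tuple[str, str, int, int]]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        attrs = {k: v[0] for k, v in feat.attributes.items() if v}
        gene_id = attrs.get("gene_name") or attrs.get("Name") or attrs.get("ID")
        if gene_id is None:
            raise FormatError(
                f"{path}: gene feature at {feat.seqid}:{feat.start}-{feat.end} "
                "has no ID/Name/gene_name attribute"
            )
        rows.append((gene_id, feat.seqid, int(feat.start), int(feat.end)))
    return rows


def load_gene_models(path: str, fmt: str | None = None) -> list[GeneModel]:
    """Load gene models from BED or GFF3 into 1-based inclusive intervals.

    Format is inferred from the extension unless *fmt* ("bed"/"gff3") is
    given.  Duplicate gene ids on one chromosome collapse to their spanning
    interval.
    """
    if fmt is None:
        lower = path.lower()
        if lower.endswith((".bed", ".bed.txt")):
            fmt = "bed"
        elif lower.endswith((".gff", ".gff3")):
            fmt = "gff3"
        else:
            raise FormatError(
                f"{path}: cannot infer gene-model format; pass fmt='bed' or 'gff3'"
            )
    if fmt == "bed":
        rows = _load_genes_bed(path)
    elif fmt == "gff3":
        rows = _load_genes_gff3(path)
    else:
        raise FormatError(f"unknown gene-model format {fmt!r}")

    merged: dict[str, list] = {}
    for gene_id, chrom, start, end in rows:
        if gene_id in merged:
            prev = merged[gene_id]
            if prev[0] != chrom:
                raise ValidationError(
                    f"gene {gene_id} appears on both {prev[0]} and {chrom}"
                )
            prev[1] = min(prev[1], start)
            prev[2] = max(prev[2], end)
        else:
            merged[gene_id] = [chrom, start, end]
    return [
        GeneModel(gene_id=g, chrom=c, start=s, end=e)
        for g, (c, s, e) in sorted(merged.items())
    ]


def load_known_cnvs(path: str) -> list[KnownCNV]:
    """Read a known-CNV catalog: chrom, start, end, id [, gain/loss type]."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: catalog rows need >= 4 columns")
            chrom, start_s, end_s, rec_id = fields[:4]
            cnv_type = fields[4].strip().lower() if len(fields) > 4 and fields[4].strip() else None
            if cnv_type is not None and cnv_type not in ("gain", "loss"):
                raise ParseError(
                    f"{path}:{lineno}: CNV type must be gain/loss, got {cnv_type!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from None
            records.append(KnownCNV(rec_id, chrom, start, end, cnv_type))
    return records


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read GMT term sets (term, description, gene, gene, ...)."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT rows need term, description and >= 1 gene"
                )
            terms[fields[0]] = {g for g in fields[2:] if g}
    return terms


def annotate_genes(
    calls: list[CNVCall],
    genes: list[GeneModel],
    min_coverage: float = 0.9,
) -> list[GeneHit]:
    """Find genes covered by calls above the coverage threshold (strict >)."""
    if not 0.0 <= min_coverage <= 1.0:
        raise ValidationError(f"min_coverage {min_coverage} outside [0, 1]")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    hits: list[GeneHit] = []
    for call in calls:
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(call.start, call.end + 1)):
            gene: GeneModel = iv.data
            overlap = min(call.end, gene.end) - max(call.start, gene.start) + 1
            coverage = overlap / gene.length
            if coverage > min_coverage:
                hits.append(GeneHit(gene_id=gene.gene_id, call=call, coverage=coverage))
    return hits


def _reciprocal_match(
    a_start: int, a_end: int, b_start: int, b_end: int, min_recip: float
) -> bool:
    overlap = min(a_end, b_end) - max(a_start, b_start) + 1
    if overlap <= 0:
        return False
    len_a = a_end - a_start + 1
    len_b = b_end - b_start + 1
    return overlap >= min_recip * len_a and overlap >= min_recip * len_b


def match_known_cnvs(
    calls: list[CNVCall],
    catalog: list[KnownCNV],
    min_recip: float = 0.5,
    match_type: bool = False,
) -> list[CNVCall]:
    """Flag calls reported in a catalog at reciprocal overlap >= *min_recip*.

    With ``match_type=True`` a record only matches a call of the same
    gain/loss direction (untyped records match either).  Matched record ids
    are attached to each call; a call with none is novel.
    """
    if not 0.0 < min_recip <= 1.0:
        raise ValidationError(f"min_recip {min_recip} outside (0, 1]")
    by_chrom: dict[str, list[KnownCNV]] = {}
    for rec in catalog:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    out = []
    for call in calls:
        ids = []
        for rec in by_chrom.get(call.chrom, ()):
            if match_type and rec.cnv_type is not None and rec.cnv_type != call.gain_loss:
                continue
            if _reciprocal_match(call.start, call.end, rec.start, rec.end, min_recip):
                ids.append(rec.record_id)
        out.append(replace(call, known_ids=tuple(sorted(ids))))
    return out


def fisher_enrichment(
    foreground: set[str],
    background: set[str],
    term_sets: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """Over-representation of each term set in the foreground genes.

    One-sided Fisher exact p = hypergeometric tail P(X >= k) with N =
    |background|, K = |term ∩ background|, n = |foreground|, k = |term ∩
    foreground|.  Terms with k = 0 are skipped; Bonferroni multiplies by
    the number of tested terms.  Results sort by p, ties by term id.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground <= background:
        raise InputError("foreground gene set is not a subset of the background")
    n_fg, n_bg = len(foreground), len(background)
    if n_bg == 0:
        raise InputError("empty background universe")

    tested: list[tuple[str, int, int]] = []
    for term_id, genes in term_sets.items():
        in_bg = genes & background
        k = len(in_bg & foreground)
        if k == 0:
            continue
        tested.append((term_id, k, len(in_bg)))
    m = len(tested)
    results = []
    for term_id, k, big_k in tested:
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_fg))
        fold = (k / n_fg) / (big_k / n_bg)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                k=k,
                n=n_fg,
                K=big_k,
                N=n_bg,
                fold=fold,
                p=p,
                p_adj=min(1.0, p * m),
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def join_sample_annotations(
    hits: list[GeneHit],
    tables: dict[str, str | pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Left-join per-gene side tables onto gene hits, keeping sample attribution.

    *tables* maps a label to a TSV path (first column = gene id) or a
    DataFrame (first column likewise).  Duplicate rows for one gene are
    concatenated with ';'; genes absent from a table render ".".
    """
    base = pd.DataFrame(
        {
            "sample_id": [h.sample_id for h in hits],
            "gene_id": [h.gene_id for h in hits],
            "chrom": [h.call.chrom for h in hits],
            "cnv_start": [h.call.start for h in hits],
            "cnv_end": [h.call.end for h in hits],
            "copy_number": [h.call.copy_number for h in hits],
            "gain_loss": [h.call.gain_loss for h in hits],
            "coverage": [round(h.coverage, 4) for h in hits],
        }
    )
    for label, table in (tables or {}).items():
        if isinstance(table, (str, bytes)):
            df = pd.read_csv(table, sep="\t", dtype=str, comment="#")
        else:
            df = table.astype(str)
        key = df.columns[0]
        value_cols = list(df.columns[1:])
        if not value_cols:
            raise FormatError(f"annotation table {label!r} has no value columns")
        agg = df.groupby(key, sort=False)[value_cols].agg(lambda s: ";".join(s))
        agg.columns = [f"{label}.{c}" for c in value_cols]
        base = base.merge(
            agg, how="left", left_on="gene_id", right_index=True
        )
        for c in agg.columns:
            base[c] = base[c].fillna(".")
    return base
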