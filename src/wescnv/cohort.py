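"""Shared-CNV extraction across patients.

Calls from different patients that overlap by at least 1 bp on the same
chromosome in the same direction (gain with gain, loss with loss — copy
numbers need not be identical) are grouped into connected components of the
pairwise-overlap graph.  Each component reports one shared CNV whose common
region is the intersection of its member intervals; a chained component with
an empty common intersection is split greedily left-to-right into maximal
sub-groups that do share a region.  The share count is the number of
distinct samples carrying the CNV; a solitary call reports share count 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ParameterError
from .hmm_caller import CNVCall

__all__ = ["SharedCNV", "find_shared_cnvs", "attach_share_counts", "write_shared"]


@dataclass
class SharedCNV:
    """A common region carried by one or more samples in the same direction."""

    chrom: str
    start: int
    end: int
    direction: str
    sample_ids: frozenset[str]
    member_calls: list[CNVCall]

    @property
    def share_count(self) -> int:
        return len(self.sample_ids)


def _split_groups(members: list[CNVCall]) -> list[list[CNVCall]]:
    """Greedy left-to-right split into maximal runs with non-empty intersection."""
    groups: list[list[CNVCall]] = []
    cur: list[CNVCall] = []
    lo = hi = 0
    for call in members:  # already sorted by (start, end)
        if not cur:
            cur, lo, hi = [call], call.start, call.end
            continue
        new_lo, new_hi = max(lo, call.start), min(hi, call.end)
        if new_lo <= new_hi:
            cur.append(call)
            lo, hi = new_lo, new_hi
        else:
            groups.append(cur)
            cur, lo, hi = [call], call.start, call.end
    if cur:
        groups.append(cur)
    return groups


def find_shared_cnvs(calls: list[CNVCall], min_share: int = 1) -> list[SharedCNV]:
    """Group overlapping same-direction calls into shared CNVs.

    Components whose distinct-sample count is below *min_share* are dropped
    (``min_share=1`` keeps everything, including solitary calls).
    """
    if min_share < 1:
        raise ParameterError("min_share must be >= 1")
    by_key: dict[tuple[str, str], list[CNVCall]] = {}
    for c in calls:
        by_key.setdefault((c.chrom, c.gain_loss), []).append(c)

    shared: list[SharedCNV] = []
    for (chrom, direction), group in sorted(by_key.items()):
        group = sorted(group, key=lambda c: (c.start, c.end, c.sample_id))
        # sweep: consecutive calls belong to one component while they reach
        # back into the running maximum end
        comp: list[CNVCall] = []
        comp_end = -1
        components: list[list[CNVCall]] = []
        for c in group:
            if comp and c.start > comp_end:
                components.append(comp)
                comp = []
            comp.append(c)
            comp_end = max(comp_end, c.end)
        if comp:
            components.append(comp)

        for component in components:
            for sub in _split_groups(component):
                ids = frozenset(c.sample_id for c in sub)
                if len(ids) < min_share:
                    continue
                shared.append(
                    SharedCNV(
                        chrom=chrom,
                        start=max(c.start for c in sub),
                        end=min(c.end for c in sub),
                        direction=direction,
                        sample_ids=ids,
                        member_calls=sub,
                    )
                )
    shared.sort(key=lambda s: (s.chrom, s.start, s.end, s.direction))
    return shared


def attach_share_counts(
    calls: list[CNVCall], shared: list[SharedCNV]
) -> list[CNVCall]:
    """Return calls annotated with the share count of their component.

    A call in no listed component (solitary, or its component fell below
    ``min_share``) carries share count 1.
    """
    counts: dict[int, int] = {}
    for s in shared:
        for member in s.member_calls:
            counts[id(member)] = s.share_count
    return [replace(c, share_count=counts.get(id(c), 1)) for c in calls]


def write_shared(shared: list[SharedCNV], path: str) -> None:
    """TSV export: chrom, start, end, direction, share_count, sample ids."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tdirection\tshare_count\tsample_ids\n")
        for s in shared:
            ids = ",".join(sorted(s.sample_ids))
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.direction}\t{s.share_count}\t{ids}\n"
            )
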