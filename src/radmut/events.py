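"""Merging of proximal calls into mutation events and 7-way classification.

Categories: SBS, DEL1, DEL_GE2, INS1, INS_GE2, COMPLEX, SV.  A deletion
accompanied by an insertion is sized by its net reference-length change
(e.g. a 10-base deletion plus a 3-base insertion is a 7-base deletion).
Calls separated by fewer than 10 unmutated reference bases merge into a
single complex event, as do runs of consecutive substitutions; a merged
event counts once in all downstream frequency statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .filtering import HET, FilteredCall
from .io import VariantCall

__all__ = [
    "SBS",
    "DEL1",
    "DEL_GE2",
    "INS1",
    "INS_GE2",
    "COMPLEX",
    "SV",
    "CATEGORIES",
    "MutationEvent",
    "net_length",
    "merge_events",
    "categorize",
    "deletion_size_bin",
    "DELETION_BINS",
]

SBS = "SBS"
DEL1 = "DEL1"
DEL_GE2 = "DEL_GE2"
INS1 = "INS1"
INS_GE2 = "INS_GE2"
COMPLEX = "COMPLEX"
SV = "SV"
CATEGORIES = (SBS, DEL1, DEL_GE2, INS1, INS_GE2, COMPLEX, SV)

DELETION_BINS = ("1", "2-9", "10-49", ">=50")

# constituents this long or longer never merge into a complex event
MAX_MERGE_CONSTITUENT = 50


@dataclass(frozen=True)
class MutationEvent:
    """A merged, classified mutation event.

    ``start``/``end`` span the reference footprint (for pure insertions the
    footprint is empty: ``end == start - 1`` with ``start`` the first base
    after the insertion point).
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    category: str
    net_length: int
    deleted_seq: str
    inserted_seq: str
    zygosity: str
    constituents: tuple[FilteredCall, ...]
    separators: tuple[tuple[int, int], ...] = ()  # unmutated runs >=2 inside
    flags: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return abs(self.net_length)

    @property
    def is_deletion(self) -> bool:
        return self.category in (DEL1, DEL_GE2)

    @property
    def is_insertion(self) -> bool:
        return self.category in (INS1, INS_GE2)

    @property
    def is_indel(self) -> bool:
        return self.is_deletion or self.is_insertion


def net_length(ref_segment: str, alt_segment: str) -> int:
    """Signed length change of an edit: len(alt) - len(ref)."""
    return len(alt_segment) - len(ref_segment)


def _footprint(call: VariantCall) -> tuple[int, int]:
    """Reference bases altered by a normalized, anchored call (1-based incl.).

    Substitution at POS p of length k: (p, p+k-1).  Deletion anchored at p:
    first..last deleted base.  Pure insertion anchored at p: empty interval
    (p+1, p) at the insertion point.
    """
    ref, alt, pos = call.ref_allele, call.alt_allele, call.position
    if call.is_symbolic:
        return (pos, call.sv_end if call.sv_end is not None else pos)
    if len(ref) == len(alt):
        return (pos, pos + len(ref) - 1)
    if len(ref) > 1 and len(alt) >= 1 and ref[0] == alt[0] and len(alt) == 1:
        return (pos + 1, pos + len(ref) - 1)  # pure deletion
    if len(alt) > 1 and len(ref) == 1 and ref[0] == alt[0]:
        return (pos + 1, pos)  # pure insertion
    # mixed edit (deletion + insertion): footprint is the replaced ref bases
    if len(ref) > 1 and ref[0] == alt[0]:
        return (pos + 1, pos + len(ref) - 1)
    return (pos, pos + len(ref) - 1)


def _mergeable(call: VariantCall) -> bool:
    if call.is_symbolic:
        return False
    return abs(call.net_length) < MAX_MERGE_CONSTITUENT


def merge_events(
    calls: Sequence[FilteredCall],
    gap_threshold: int = 10,
    min_consecutive_sbs_complex: int = 2,
) -> list[MutationEvent]:
    """Merge one sample's filtered calls into mutation events.

    Two adjacent calls join one event when fewer than ``gap_threshold``
    unmutated reference bases separate their footprints and both edits are
    shorter than 50 bp.  Any event with >= ``min_consecutive_sbs_complex``
    constituents is complex.  The result is independent of input order.
    """
    if not calls:
        return []
    samples = {fc.call.sample_id for fc in calls}
    if len(samples) > 1:
        raise ValueError("merge_events operates on a single sample")
    ordered = sorted(calls, key=lambda fc: (fc.call.chromosome, _footprint(fc.call)))
    groups: list[list[FilteredCall]] = [[ordered[0]]]
    for fc in ordered[1:]:
        prev = groups[-1][-1]
        same_chrom = fc.call.chromosome == prev.call.chromosome
        gap = _footprint(fc.call)[0] - _footprint(prev.call)[1] - 1
        if (
            same_chrom
            and gap < gap_threshold
            and _mergeable(fc.call)
            and _mergeable(prev.call)
        ):
            groups[-1].append(fc)
        else:
            groups.append([fc])
    return [_build_event(g, min_consecutive_sbs_complex) for g in groups]


def _build_event(
    group: list[FilteredCall], min_consecutive_sbs_complex: int
) -> MutationEvent:
    calls = [fc.call for fc in group]
    footprints = [_footprint(c) for c in calls]
    start = min(f[0] for f in footprints)
    end = max(f[1] for f in footprints)
    net = sum(c.net_length for c in calls)
    zygosities = {fc.zygosity for fc in group}
    flags: tuple[str, ...] = ()
    if len(zygosities) > 1:
        zygosity, flags = HET, ("mixed_zygosity",)
    else:
        zygosity = zygosities.pop()
    deleted = inserted = ""
    if len(group) == 1:
        c = calls[0]
        if not c.is_symbolic:
            ref, alt = c.ref_allele, c.alt_allele
            if len(ref) > 1 and len(alt) >= 1 and ref[0] == alt[0]:
                deleted = ref[1:]
                inserted = alt[1:]
            elif len(alt) > 1 and len(ref) == 1 and ref[0] == alt[0]:
                inserted = alt[1:]
            elif len(ref) == len(alt) == 1:
                pass
            else:
                deleted, inserted = ref, alt
    # unmutated separators (>= 2 identical-to-reference bases) inside the event
    separators = []
    for (a1, b1), (a2, b2) in zip(footprints, footprints[1:]):
        if a2 - b1 - 1 >= 2:
            separators.append((b1 + 1, a2 - 1))
    category = categorize_parts(calls, net, min_consecutive_sbs_complex)
    return MutationEvent(
        sample_id=group[0].call.sample_id,
        chromosome=group[0].call.chromosome,
        start=start,
        end=end,
        category=category,
        net_length=net,
        deleted_seq=deleted,
        inserted_seq=inserted,
        zygosity=zygosity,
        constituents=tuple(group),
        separators=tuple(separators),
        flags=flags,
    )


def categorize_parts(
    calls: Sequence[VariantCall], net: int, min_consecutive_sbs_complex: int = 2
) -> str:
    """Category of a (possibly merged) group of constituent calls."""
    if len(calls) >= min_consecutive_sbs_complex and len(calls) >= 2:
        return COMPLEX
    c = calls[0]
    if c.is_symbolic:
        return SV
    ref, alt = c.ref_allele, c.alt_allele
    if len(ref) == len(alt) == 1:
        return SBS
    if len(ref) == len(alt):
        # multi-base substitution == consecutive SBSs in one record
        return COMPLEX
    if net == -1:
        return DEL1
    if net <= -2:
        return DEL_GE2
    if net == 1:
        return INS1
    if net >= 2:
        return INS_GE2
    raise ValueError("zero-net multi-allele edit cannot be categorized")


def categorize(event: MutationEvent) -> str:
    """Category of an already-built event (re-derived from constituents)."""
    return categorize_parts(
        [fc.call for fc in event.constituents], event.net_length
    )


def deletion_size_bin(event: MutationEvent) -> str:
    """Bin a deletion event's size into 1, 2-9, 10-49 or >=50 bp."""
    if event.category not in (DEL1, DEL_GE2):
        raise ValueError(f"not a deletion event: {event.category}")
    size = event.size
    if size == 1:
        return "1"
    if size <= 9:
        return "2-9"
    if size <= 49:
        return "10-49"
    return ">=50"
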