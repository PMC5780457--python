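"""Sequence-context annotation of indel events.

Three signatures are scored, reflecting the repair processes thought to
produce radiation-induced indels:

* **homopolymer** — the edited base(s) sit in a run of >= 3 identical
  reference bases (replication slippage signature of 1-bp indels);
* **polynucleotide repeat** — a short tandem repeat (unit 2-6 bp, >= 2
  exact copies) overlaps the edit footprint;
* **junction microhomology** — the terminal bases of a deleted (or
  inserted) segment are repeated in the retained flank, the signature of
  microhomology-mediated end joining.

Single-base indels are additionally classed by the identity of the edited
base (A/T vs G/C).  Flags are invariant to left/right alignment of the
input variant because runs and repeats are measured on the reference
around the normalized footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .events import (DEL1, DEL_GE2, INS1, INS_GE2, MutationEvent,
                     deletion_size_bin)
from .io import ReferenceGenome

__all__ = [
    "ContextAnnotation",
    "detect_homopolymer",
    "detect_polynucleotide_repeat",
    "detect_microhomology",
    "classify_site_base",
    "annotate_event",
    "annotate_events",
    "summarize_context",
    "percent",
]


@dataclass(frozen=True)
class ContextAnnotation:
    """Context flags for one indel event (non-exclusive columns)."""

    event: MutationEvent
    homopolymer: bool = False
    homopolymer_base: str | None = None
    homopolymer_run: int = 0
    repeat: bool = False
    repeat_unit: str | None = None
    microhomology: bool = False
    microhomology_len: int = 0
    microhomology_seq: str = ""
    site_base_class: str = "NA"  # AT, GC or NA

    @property
    def repeat_or_microhomology(self) -> bool:
        return self.repeat or self.microhomology

    @property
    def primary_label(self) -> str:
        """Mutually exclusive label: homopolymer > repeat > microhomology."""
        if self.homopolymer:
            return "homopolymer"
        if self.repeat:
            return "repeat"
        if self.microhomology:
            return "microhomology"
        return "none"


def _require_indel(event: MutationEvent) -> None:
    if event.category not in (DEL1, DEL_GE2, INS1, INS_GE2):
        raise ValueError(f"context annotation needs an indel, got {event.category}")


def _run_around(seq: str, lo: int, hi: int, base: str) -> int:
    """Length of the maximal run of ``base`` covering 0-based slice [lo, hi)."""
    n = len(seq)
    left = lo
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = hi
    while right < n and seq[right] == base:
        right += 1
    return right - left


def detect_homopolymer(
    genome: ReferenceGenome, event: MutationEvent, min_run: int = 3
) -> tuple[bool, str | None, int]:
    """Is the indel inside a homopolymeric run of >= ``min_run`` bases?

    For deletions, the run is the deleted bases plus identical flanking
    reference bases; for insertions, the inserted bases plus the identical
    reference run at the insertion point (the post-edit run).
    """
    _require_indel(event)
    seq = genome.chromosomes[event.chromosome]
    if event.is_deletion:
        segment = event.deleted_seq
        if not segment or len(set(segment)) != 1:
            return (False, None, 0)
        base = segment[0]
        run = _run_around(seq, event.start - 1, event.end, base)
        return (run >= min_run, base, run)
    segment = event.inserted_seq
    if not segment or len(set(segment)) != 1:
        return (False, None, 0)
    base = segment[0]
    # empty footprint: start is the first base after the insertion point
    run = _run_around(seq, event.start - 1, event.start - 1, base) + len(segment)
    return (run >= min_run, base, run)


def detect_polynucleotide_repeat(
    genome: ReferenceGenome,
    event: MutationEvent,
    unit_range: tuple[int, int] = (2, 6),
    min_copies: int = 2,
) -> tuple[bool, str | None]:
    """Does a short tandem repeat overlap the edit footprint?

    A repeat is >= ``min_copies`` exact tandem copies of a unit of
    ``unit_range`` bp that is not itself a single-base run; homopolymeric
    context is excluded (period-1 blocks never qualify).  The smallest
    qualifying unit is reported.
    """
    _require_indel(event)
    seq = genome.chromosomes[event.chromosome]
    lo_unit, hi_unit = unit_range
    margin = hi_unit * min_copies
    # 0-based footprint [fs, fe); insertions get the two flanking bases
    if event.is_deletion:
        fs, fe = event.start - 1, event.end
    else:
        fs, fe = max(event.start - 2, 0), min(event.start, len(seq))
    win_lo = max(fs - margin, 0)
    win_hi = min(fe + margin, len(seq))
    window = seq[win_lo:win_hi]
    for u in range(lo_unit, hi_unit + 1):
        for i in range(len(window) - 2 * u + 1):
            unit = window[i : i + u]
            if len(set(unit)) == 1:
                continue
            k = 1
            while window[i + k * u : i + (k + 1) * u] == unit:
                k += 1
            if k >= min_copies:
                block_lo = win_lo + i
                block_hi = block_lo + k * u
                if block_lo < fe and fs < block_hi or (fs == fe and block_lo <= fs <= block_hi):
                    return (True, unit)
    return (False, None)


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def detect_microhomology(
    genome: ReferenceGenome,
    event: MutationEvent,
    min_len: int = 2,
    max_len: int = 10,
) -> tuple[bool, int, str]:
    """Microhomology between an edited segment and its retained flanks.

    For a deletion of segment D with upstream flank U and downstream flank
    W, the microhomology length is max(longest common suffix of U and D,
    longest common prefix of D and W), capped at ``max_len``.  For
    insertions the inserted sequence plays the role of D.
    """
    if event.category not in (DEL_GE2, INS_GE2):
        raise ValueError(
            f"microhomology is defined for DEL_GE2/INS_GE2, got {event.category}"
        )
    seq = genome.chromosomes[event.chromosome]
    if event.is_deletion:
        d = event.deleted_seq
        up_end = event.start - 1  # 0-based exclusive end of upstream flank
        down_start = event.end  # 0-based start of downstream flank
    else:
        d = event.inserted_seq
        up_end = event.start - 1
        down_start = event.start - 1
    upstream = seq[max(up_end - max_len, 0) : up_end]
    downstream = seq[down_start : down_start + max_len]
    suffix = _common_prefix_len(upstream[::-1], d[::-1])
    prefix = _common_prefix_len(d, downstream)
    length = min(max(suffix, prefix), max_len, len(d))
    if prefix >= suffix:
        mh_seq = d[:length]
    else:
        mh_seq = d[len(d) - length :]
    return (length >= min_len, length, mh_seq if length else "")


def classify_site_base(genome: ReferenceGenome, event: MutationEvent) -> str:
    """A/T vs G/C class of the base edited by a single-base indel."""
    if event.category == DEL1:
        base = event.deleted_seq
    elif event.category == INS1:
        base = event.inserted_seq
    else:
        return "NA"
    if base in ("A", "T"):
        return "AT"
    if base in ("G", "C"):
        return "GC"
    return "NA"


def annotate_event(
    genome: ReferenceGenome,
    event: MutationEvent,
    min_run: int = 3,
    mh_min_len: int = 2,
    mh_max_len: int = 10,
) -> ContextAnnotation:
    """Compute all applicable context flags for one indel event."""
    _require_indel(event)
    hp, hp_base, hp_run = detect_homopolymer(genome, event, min_run=min_run)
    rep, rep_unit = detect_polynucleotide_repeat(genome, event)
    mh, mh_len, mh_seq = (False, 0, "")
    if event.category in (DEL_GE2, INS_GE2):
        mh, mh_len, mh_seq = detect_microhomology(
            genome, event, min_len=mh_min_len, max_len=mh_max_len
        )
    return ContextAnnotation(
        event=event,
        homopolymer=hp,
        homopolymer_base=hp_base,
        homopolymer_run=hp_run,
        repeat=rep,
        repeat_unit=rep_unit,
        microhomology=mh,
        microhomology_len=mh_len,
        microhomology_seq=mh_seq,
        site_base_class=classify_site_base(genome, event),
    )


def annotate_events(
    genome: ReferenceGenome, events: Iterable[MutationEvent], **kwargs
) -> list[ContextAnnotation]:
    """Annotate all indel events; SBS/COMPLEX/SV events are skipped."""
    return [
        annotate_event(genome, ev, **kwargs)
        for ev in events
        if ev.category in (DEL1, DEL_GE2, INS1, INS_GE2)
    ]


def percent(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer (0 for an empty class)."""
    if denominator == 0:
        return 0
    return round(100 * numerator / denominator)


def summarize_context(
    annotations: Sequence[ContextAnnotation],
    group_of_sample: Mapping[str, str] | Callable[[str], str] | None = None,
) -> pd.DataFrame:
    """Per-group, per-category context contingency summary.

    Columns report (non-exclusively) the number and percentage of events
    with homopolymeric context and with repeat-or-microhomology context,
    plus A/T site counts for single-base indels; DEL_GE2 rows are further
    broken down by deletion size bin.
    """
    if group_of_sample is None:
        lookup = lambda s: "all"
    elif callable(group_of_sample):
        lookup = group_of_sample
    else:
        lookup = lambda s: group_of_sample[s]

    rows = []
    for ann in annotations:
        ev = ann.event
        keys = [(lookup(ev.sample_id), ev.category)]
        if ev.category == DEL_GE2:
            keys.append((lookup(ev.sample_id), f"DEL_GE2[{deletion_size_bin(ev)}]"))
        for g, cat in keys:
            rows.append(
                {
                    "group": g,
                    "category": cat,
                    "homopolymer": ann.homopolymer,
                    "repeat_or_mh": ann.repeat_or_microhomology,
                    "at_site": ann.site_base_class == "AT",
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["group", "category", "n", "homopolymer_n", "homopolymer_pct",
                     "repeat_or_mh_n", "repeat_or_mh_pct", "at_site_n", "at_site_pct"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "category"])
        .agg(
            n=("homopolymer", "size"),
            homopolymer_n=("homopolymer", "sum"),
            repeat_or_mh_n=("repeat_or_mh", "sum"),
            at_site_n=("at_site", "sum"),
        )
        .reset_index()
    )
    out["homopolymer_pct"] = [
        percent(a, b) for a, b in zip(out["homopolymer_n"], out["n"])
    ]
    out["repeat_or_mh_pct"] = [
        percent(a, b) for a, b in zip(out["repeat_or_mh_n"], out["n"])
    ]
    out["at_site_pct"] = [percent(a, b) for a, b in zip(out["at_site_n"], out["n"])]
    return out
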