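"""Cohort-level filtering and zygosity assignment of candidate mutation calls.

The rules implemented here mirror the read-support, allele-frequency,
cross-sample and background criteria used for mutation detection in M2
resequencing cohorts:

* a candidate needs a minimum number of mutant reads (default 3);
* candidates with AF <= 0.25 are excluded as likely false positives;
* a site+allele seen with appreciable AF in more than two samples is a
  shared background artifact and is removed everywhere;
* surviving candidates are heterozygous for AF in (0.25, 0.80) and
  homozygous for AF >= 0.80, provided every other sample shows AF < 0.05
  at that site+allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import VariantCall

__all__ = [
    "FilterPolicy",
    "FilteredCall",
    "Exclusion",
    "apply_support_filter",
    "filter_background",
    "assign_zygosity",
    "filter_cohort",
]

HET = "HET"
HOM = "HOM"


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for call filtering and zygosity assignment."""

    min_mutant_reads: int = 3
    af_exclude_max: float = 0.25       # AF <= this -> excluded
    het_min_af: float = 0.25           # exclusive lower HET bound
    het_max_af: float = 0.80           # exclusive upper HET bound
    hom_min_af: float = 0.80           # inclusive HOM bound
    cross_sample_max_af: float = 0.05  # other samples must be below this
    background_max_samples: int = 2    # present in more -> background

    def __post_init__(self):
        if not (0 <= self.af_exclude_max <= self.het_min_af
                < self.het_max_af <= self.hom_min_af <= 1):
            raise ValueError("inconsistent AF thresholds")


@dataclass(frozen=True)
class FilteredCall:
    """A call that survived all filters, with its zygosity call."""

    call: VariantCall
    zygosity: str  # HET or HOM
    filter_trace: tuple[str, ...] = ()

    @property
    def sample_id(self) -> str:
        return self.call.sample_id


@dataclass(frozen=True)
class Exclusion:
    """An excluded call with the rule that removed it."""

    call: VariantCall
    reason: str


def apply_support_filter(
    calls: Sequence[VariantCall], policy: FilterPolicy
) -> list[VariantCall]:
    """Keep calls with at least ``policy.min_mutant_reads`` mutant reads."""
    return [c for c in calls if c.mutant_reads >= policy.min_mutant_reads]


def _af_index(
    cohort_calls: Mapping[str, Sequence[VariantCall]]
) -> dict[tuple, dict[str, float]]:
    """site+allele -> {sample: af} over all calls with defined AF."""
    index: dict[tuple, dict[str, float]] = {}
    for sample, calls in cohort_calls.items():
        for c in calls:
            if c.af is not None:
                index.setdefault(c.site_key(), {})[sample] = c.af
    return index


def filter_background(
    cohort_calls: Mapping[str, Sequence[VariantCall]], policy: FilterPolicy
) -> dict[str, list[VariantCall]]:
    """Remove site+alleles present in more than ``background_max_samples``.

    A sample "has" the site when its AF there exceeds
    ``policy.cross_sample_max_af``.  Matching is on
    (chromosome, position, ref, alt); calls are assumed normalized.
    """
    if len(cohort_calls) < 2:
        raise ValueError("background filtering needs a cohort of >= 2 samples")
    index = _af_index(cohort_calls)
    background = {
        key
        for key, per_sample in index.items()
        if sum(af > policy.cross_sample_max_af for af in per_sample.values())
        > policy.background_max_samples
    }
    return {
        sample: [c for c in calls if c.site_key() not in background]
        for sample, calls in cohort_calls.items()
    }


def assign_zygosity(
    call: VariantCall,
    cohort_calls: Mapping[str, Sequence[VariantCall]],
    policy: FilterPolicy,
) -> FilteredCall | Exclusion:
    """Classify one call as HET/HOM or exclude it, using cohort context."""
    index = _af_index(cohort_calls)
    return _assign_zygosity_indexed(call, index, policy)


def _assign_zygosity_indexed(
    call: VariantCall,
    index: Mapping[tuple, Mapping[str, float]],
    policy: FilterPolicy,
) -> FilteredCall | Exclusion:
    af = call.af
    if af is None:
        return Exclusion(call, "no_depth")
    if af <= policy.af_exclude_max:
        return Exclusion(call, "low_af")
    others = index.get(call.site_key(), {})
    if any(
        sample != call.sample_id and other_af >= policy.cross_sample_max_af
        for sample, other_af in others.items()
    ):
        return Exclusion(call, "cross_sample")
    if policy.het_min_af < af < policy.het_max_af:
        return FilteredCall(call, HET, ("het_band",))
    if af >= policy.hom_min_af:
        return FilteredCall(call, HOM, ("hom_band",))
    # printed gap between the HET band and the HOM bound (empty with defaults)
    return Exclusion(call, "af_band_gap")


def filter_cohort(
    cohort_calls: Mapping[str, Sequence[VariantCall]],
    policy: FilterPolicy | None = None,
) -> tuple[dict[str, list[FilteredCall]], list[Exclusion]]:
    """Run support -> background -> zygosity filtering over a whole cohort.

    Returns retained calls per sample plus the audit list of exclusions.
    Cross-sample AFs are taken from the raw (pre-filter) call sets, so that a
    low-AF trace of an artifact in another sample still vetoes a candidate.
    """
    policy = policy or FilterPolicy()
    exclusions: list[Exclusion] = []
    raw_index = _af_index(cohort_calls)

    supported = {}
    for sample, calls in cohort_calls.items():
        kept = []
        for c in calls:
            if c.mutant_reads >= policy.min_mutant_reads:
                kept.append(c)
            else:
                exclusions.append(Exclusion(c, "low_support"))
        supported[sample] = kept

    cleaned = filter_background(supported, policy)
    for sample, calls in supported.items():
        kept = set(id(c) for c in cleaned[sample])
        exclusions.extend(
            Exclusion(c, "background") for c in calls if id(c) not in kept
        )

    retained: dict[str, list[FilteredCall]] = {}
    for sample, calls in cleaned.items():
        out = []
        for c in calls:
            res = _assign_zygosity_indexed(c, raw_index, policy)
            if isinstance(res, FilteredCall):
                out.append(res)
            else:
                exclusions.append(res)
        retained[sample] = out
    return retained, exclusions
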