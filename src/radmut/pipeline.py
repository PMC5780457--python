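"""End-to-end orchestration: simulate a cohort, filter calls, build events,
annotate and write the report bundle."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import context as ctx
from . import impact as imp
from .events import MutationEvent, merge_events
from .filtering import Exclusion, FilteredCall, FilterPolicy, filter_cohort
from .io import GeneModel, ReferenceGenome, VariantCall, normalize_variant
from .simulate import (SimulationProfile, TruthRecord, emit_calls,
                       generate_gene_models, generate_reference,
                       simulate_mutations)
from .stats import (GroupSummary, category_table, compare_groups,
                    derived_rates, het_hom_stats, summarize_group)

__all__ = ["SyntheticCohort", "CohortAnalysis", "simulate_cohort",
           "analyze_cohort", "build_report"]


@dataclass
class SyntheticCohort:
    """A fully simulated multi-group cohort plus its ground truth."""

    genome: ReferenceGenome
    gene_models: list[GeneModel]
    truth: list[TruthRecord]
    calls: dict[str, list[VariantCall]]
    group_of_sample: dict[str, str]

    def truth_event_ids(self) -> set[tuple[str, str]]:
        return {(t.sample_id, t.event_id) for t in self.truth}


@dataclass
class CohortAnalysis:
    """Filtered calls and classified events for every sample."""

    events_by_sample: dict[str, list[MutationEvent]]
    retained_by_sample: dict[str, list[FilteredCall]]
    exclusions: list[Exclusion]

    def events_of_group(
        self, group_of_sample: Mapping[str, str], group: str
    ) -> dict[str, list[MutationEvent]]:
        return {
            s: evs
            for s, evs in self.events_by_sample.items()
            if group_of_sample[s] == group
        }


def simulate_cohort(
    profiles: Sequence[SimulationProfile],
    genome_length: int = 300_000,
    n_chromosomes: int = 2,
    gc_fraction: float = 0.36,
    homopolymer_enrichment: float = 2.0,
    n_genes: int = 40,
    seed: int = 0,
    out_dir=None,
    genome: ReferenceGenome | None = None,
    gene_models: Sequence[GeneModel] | None = None,
) -> SyntheticCohort:
    """Build a complete synthetic cohort across several group profiles.

    The reference and gene models may be supplied to reuse them across
    replicates; otherwise they are generated from ``seed``.  Per-group
    mutation seeds and the emission seed are derived from ``seed`` and the
    profiles' own seeds so that identical inputs are byte-reproducible.
    """
    if genome is None:
        genome = generate_reference(
            genome_length, n_chromosomes, gc_fraction,
            homopolymer_enrichment, seed=seed,
        )
        gene_models = generate_gene_models(genome, n_genes, seed=seed + 1)
    gene_models = list(gene_models or [])
    truth: list[TruthRecord] = []
    group_of_sample: dict[str, str] = {}
    all_samples: list[str] = []
    for k, profile in enumerate(profiles):
        profile = _reseed(profile, seed * 1000 + k)
        truth.extend(simulate_mutations(genome, gene_models, profile))
        for s in profile.sample_ids:
            group_of_sample[s] = profile.group_name
            all_samples.append(s)
    noise = profiles[0].noise
    calls = emit_calls(
        truth, noise, seed=seed * 1000 + 999, genome=genome,
        sample_ids=all_samples, out_dir=out_dir,
    )
    return SyntheticCohort(
        genome=genome, gene_models=gene_models, truth=truth,
        calls=calls, group_of_sample=group_of_sample,
    )


def _reseed(profile: SimulationProfile, seed: int) -> SimulationProfile:
    from dataclasses import replace

    return replace(profile, seed=(profile.seed + seed) % (2**31 - 1))


def analyze_cohort(
    genome: ReferenceGenome,
    cohort_calls: Mapping[str, Sequence[VariantCall]],
    policy: FilterPolicy | None = None,
    gap_threshold: int = 10,
) -> CohortAnalysis:
    """Normalize, filter and merge a cohort's call sets into events."""
    normalized = {
        sample: [normalize_variant(c, genome) for c in calls]
        for sample, calls in cohort_calls.items()
    }
    retained, exclusions = filter_cohort(normalized, policy)
    events = {
        sample: merge_events(fcs, gap_threshold=gap_threshold)
        for sample, fcs in retained.items()
    }
    return CohortAnalysis(
        events_by_sample=events,
        retained_by_sample=retained,
        exclusions=exclusions,
    )


def build_report(
    analysis: CohortAnalysis,
    genome: ReferenceGenome,
    group_of_sample: Mapping[str, str],
    out_dir,
    gene_models: Sequence[GeneModel] | None = None,
    genome_length: int | None = None,
    run_log: Mapping | None = None,
) -> dict:
    """Write the report bundle (TSV tables + JSON) and return the summaries.

    Raises if a sample has no group assignment (incomplete upstream stage).
    """
    missing = [s for s in analysis.events_by_sample if s not in group_of_sample]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = genome_length or genome.total_length
    groups = sorted(set(group_of_sample.values()))
    summaries: dict[str, GroupSummary] = {}
    for g in groups:
        evs = analysis.events_of_group(group_of_sample, g)
        summaries[g] = summarize_group(g, evs, L)

    category_table(
        {g: s.category_counts for g, s in summaries.items()}
    ).to_csv(out / "category_table.tsv", sep="\t", index=False)

    mf_rows = []
    for g, s in summaries.items():
        for sample, n, mf in zip(
            analysis.events_of_group(group_of_sample, g), s.per_sample_event_counts,
            s.per_sample_mf,
        ):
            mf_rows.append({"group": g, "sample": sample, "n_events": n, "mf": mf})
    pd.DataFrame(mf_rows).to_csv(out / "mutation_frequency.tsv", sep="\t",
                                 index=False)

    pd.DataFrame(
        [{"group": g, **s.spectrum6, "ti_tv": s.ti_tv} for g, s in summaries.items()]
    ).to_csv(out / "sbs_spectrum.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"group": g, **s.deletion_bins} for g, s in summaries.items()]
    ).to_csv(out / "deletion_bins.tsv", sep="\t", index=False)

    comparisons = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            comparisons[f"{a}_vs_{b}"] = compare_groups(
                summaries[a].per_sample_mf, summaries[b].per_sample_mf
            )

    hh = pd.concat(
        [
            het_hom_stats(analysis.events_of_group(group_of_sample, g)).assign(group=g)
            for g in groups
        ]
    )
    hh.to_csv(out / "het_hom.tsv", sep="\t", index=False)

    annotations = ctx.annotate_events(
        genome,
        [e for evs in analysis.events_by_sample.values() for e in evs],
    )
    ctx.summarize_context(annotations, dict(group_of_sample)).to_csv(
        out / "context_summary.tsv", sep="\t", index=False
    )

    if gene_models:
        impacts = imp.predict_effects(
            [e for evs in analysis.events_by_sample.values() for e in evs],
            list(gene_models),
            genome,
        )
        per_sample, per_group = imp.count_affected_genes(
            impacts, sorted(analysis.events_by_sample), dict(group_of_sample)
        )
        per_sample.to_csv(out / "affected_genes_per_sample.tsv", sep="\t",
                          index=False)
        per_group.to_csv(out / "affected_genes_per_group.tsv", sep="\t",
                         index=False)

    derived = {
        g: derived_rates(s.mean_mf).__dict__ for g, s in summaries.items()
    }
    bundle = {
        "genome_length": L,
        "groups": {
            g: {
                "mean_mf": s.mean_mf,
                "se_mf": s.se_mf,
                "category_counts": s.category_counts,
                "category_percent": s.category_percent,
                "ti_tv": s.ti_tv,
                "het": s.het_count,
                "hom": s.hom_count,
                "het_hom_ratio": s.het_hom_ratio,
            }
            for g, s in summaries.items()
        },
        "comparisons": comparisons,
        "derived_rates": derived,
        "run_log": dict(run_log or {}),
    }
    (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
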