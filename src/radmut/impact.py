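"""Prediction of coding impact and per-sample affected-gene counting.

A simplified effect predictor over CDS features: substitutions are
translated codon-wise on the gene's strand; in-frame indels inside a CDS
are called non-synonymous and frame-disrupting ones frameshift; deletions
that remove a gene's entire CDS span produce a gene-loss record per gene.
Splice, UTR and intronic changes all count as noncoding, because the
tallies of interest are protein-coding genes with amino-acid changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .events import SBS, SV, MutationEvent
from .filtering import HET, HOM
from .io import GeneModel, ReferenceGenome

__all__ = [
    "ImpactRecord",
    "FUNCTION_AFFECTING",
    "predict_effect",
    "predict_effects",
    "count_affected_genes",
    "affecting_event_fraction",
]

FUNCTION_AFFECTING = frozenset(
    {"nonsynonymous", "frameshift", "stop_gain", "stop_loss", "gene_deleted"}
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table.get(codon, "X")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ImpactRecord:
    """Predicted effect of one event on one gene (or noncoding)."""

    sample_id: str
    event_start: int
    chromosome: str
    gene_id: str | None
    effect: str
    zygosity: str

    @property
    def affects_function(self) -> bool:
        return self.effect in FUNCTION_AFFECTING


def _sbs_effect(
    event: MutationEvent, gene: GeneModel, genome: ReferenceGenome
) -> str:
    call = event.constituents[0].call
    idx = gene.cds_index_of(call.position)
    assert idx is not None
    ref_base, alt_base = call.ref_allele, call.alt_allele
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    cds = gene.cds_sequence(genome)
    codon_i = idx // 3
    within = idx % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "nonsynonymous"  # truncated terminal codon; conservative
    assert codon[within] == ref_base, "reference/CDS mismatch"
    new_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_old, aa_new = _translate_codon(codon), _translate_codon(new_codon)
    if aa_old == aa_new:
        return "synonymous"
    if aa_new == "*":
        return "stop_gain"
    if aa_old == "*":
        return "stop_loss"
    return "nonsynonymous"


def predict_effect(
    event: MutationEvent,
    gene_models: Sequence[GeneModel],
    genome: ReferenceGenome,
) -> list[ImpactRecord]:
    """Impact records for one event: one per affected gene, or one noncoding."""
    records: list[ImpactRecord] = []
    fs, fe = event.start, event.end
    is_del = event.net_length < 0 or event.category == SV
    for gene in gene_models:
        if gene.chromosome != event.chromosome:
            continue
        span_a, span_b = gene.span
        if is_del and fs <= span_a and fe >= span_b:
            # deletion removes the gene's whole CDS span
            records.append(_rec(event, gene.gene_id, "gene_deleted"))
            continue
        # an insertion's empty footprint (fe == fs - 1) intersects a CDS only
        # when the insertion point lies strictly inside an interval
        if not gene.overlaps_cds(fs, fe):
            continue
        if not gene.translatable:
            continue
        if event.category == SBS:
            records.append(_rec(event, gene.gene_id, _sbs_effect(event, gene, genome)))
        elif event.category == SV:
            records.append(_rec(event, gene.gene_id, "gene_deleted"))
        else:
            # indel or complex intersecting CDS: frame decides
            if event.net_length % 3 == 0:
                records.append(_rec(event, gene.gene_id, "nonsynonymous"))
            else:
                records.append(_rec(event, gene.gene_id, "frameshift"))
    if not records:
        records.append(_rec(event, None, "noncoding"))
    return records


def _rec(event: MutationEvent, gene_id: str | None, effect: str) -> ImpactRecord:
    return ImpactRecord(
        sample_id=event.sample_id,
        event_start=event.start,
        chromosome=event.chromosome,
        gene_id=gene_id,
        effect=effect,
        zygosity=event.zygosity,
    )


def predict_effects(
    events: Iterable[MutationEvent],
    gene_models: Sequence[GeneModel],
    genome: ReferenceGenome,
) -> list[ImpactRecord]:
    out: list[ImpactRecord] = []
    for ev in events:
        out.extend(predict_effect(ev, gene_models, genome))
    return out


def count_affected_genes(
    impacts: Sequence[ImpactRecord],
    samples: Sequence[str],
    group_of_sample: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-group counts of genes with function-affecting hits.

    A gene counts once per sample; a gene hit both heterozygously and
    homozygously counts under the homozygous (stronger) state.  Group
    summaries report mean +/- standard error (sd/sqrt(n)) over samples.
    """
    state: dict[tuple[str, str], str] = {}
    for rec in impacts:
        if rec.gene_id is None or not rec.affects_function:
            continue
        key = (rec.sample_id, rec.gene_id)
        if state.get(key) != HOM:
            state[key] = rec.zygosity
    per_sample = pd.DataFrame(
        {
            "sample": list(samples),
            "hom_genes": [
                sum(1 for (s, _), z in state.items() if s == smp and z == HOM)
                for smp in samples
            ],
            "het_genes": [
                sum(1 for (s, _), z in state.items() if s == smp and z == HET)
                for smp in samples
            ],
        }
    )
    per_sample["total_genes"] = per_sample["hom_genes"] + per_sample["het_genes"]
    if group_of_sample is None:
        per_sample["group"] = "all"
    else:
        per_sample["group"] = [group_of_sample[s] for s in per_sample["sample"]]
    rows = []
    for group, sub in per_sample.groupby("group"):
        row = {"group": group, "n_samples": len(sub)}
        for col in ("hom_genes", "het_genes", "total_genes"):
            vals = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = vals.mean()
            row[f"{col}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else float("nan")
            )
            row[f"{col}_total"] = int(vals.sum())
        rows.append(row)
    return per_sample, pd.DataFrame(rows)


def affecting_event_fraction(
    impacts: Sequence[ImpactRecord], n_events_by_sample: Mapping[str, int]
) -> float:
    """Fraction of mutation events with a function-affecting impact."""
    affecting_events = {
        (r.sample_id, r.chromosome, r.event_start)
        for r in impacts
        if r.affects_function
    }
    total = sum(n_events_by_sample.values())
    if total == 0:
        return 0.0
    return len(affecting_events) / total
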