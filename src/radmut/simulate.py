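"""Synthetic mutagenesis cohorts: reference genome, gene models, ground-truth
mutations and noisy per-sample call sets.

The generator emulates the statistical structure of an M2 resequencing
cohort after heavy-ion mutagenesis: Poisson per-category event counts per
plant, Mendelian 1:2:1 segregation of M1-heterozygous mutations (so a
detectable mutation is heterozygous with probability 2/3), binomial read
support around AF 0.5 (heterozygous) or ~1.0 (homozygous), context-biased
indel placement (homopolymer runs for 1-bp deletions, junction
microhomology for >= 2-bp indels), low-AF false positives, and background
artifacts shared across more than two samples.  It does not simulate
reads, base qualities or mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .events import COMPLEX, DEL1, DEL_GE2, INS1, INS_GE2, SBS, SV
from .filtering import HET, HOM
from .io import GeneModel, ReferenceGenome, VariantCall, write_fasta, write_gff3, write_vcf

__all__ = [
    "CapacityError",
    "NoiseProfile",
    "SimulationProfile",
    "TruthRecord",
    "generate_reference",
    "generate_gene_models",
    "simulate_mutations",
    "emit_calls",
    "dry_seed_profile",
    "seedling_profile",
    "write_truth_table",
]

_BASES = np.array(list("ACGT"))

# default SBS class weights (strand-merged classes; G:A transitions dominate,
# Ti/Tv ~ 0.8, within the 0.67-0.88 range typical of carbon-ion cohorts)
DEFAULT_SBS_WEIGHTS = {
    "G:C>A:T": 0.30,
    "A:T>G:C": 0.15,
    "G:C>T:A": 0.15,
    "G:C>C:G": 0.10,
    "A:T>T:A": 0.20,
    "A:T>C:G": 0.10,
}

_CLASS_TO_PAIRS = {
    "G:C>A:T": (("G", "A"), ("C", "T")),
    "A:T>G:C": (("A", "G"), ("T", "C")),
    "G:C>T:A": (("G", "T"), ("C", "A")),
    "G:C>C:G": (("G", "C"), ("C", "G")),
    "A:T>T:A": (("A", "T"), ("T", "A")),
    "A:T>C:G": (("A", "C"), ("T", "G")),
}


class CapacityError(ValueError):
    """The genome is too small for the requested construct."""


@dataclass(frozen=True)
class NoiseProfile:
    """Sequencing-noise knobs for call emission."""

    false_positive_low_af_rate: float = 0.0  # expected FP calls per sample
    n_background_sites_shared: int = 0       # artifact sites shared by >2 samples
    depth_mean: float = 30.0
    hom_read_prob: float = 0.98  # < 1 so the AF >= 0.8 rule stays meaningful

    def __post_init__(self):
        if self.depth_mean < 10:
            raise ValueError("depth_mean must be >= 10")
        if self.false_positive_low_af_rate < 0 or self.n_background_sites_shared < 0:
            raise ValueError("noise rates must be non-negative")


@dataclass(frozen=True)
class SimulationProfile:
    """Study-condition profile for one experimental group.

    Default per-sample category expectations correspond to a dry-seed
    125 Gy-like group (about 32 events per plant, deletion-rich); use
    :func:`dry_seed_profile` / :func:`seedling_profile` for the four
    standard groups.
    """

    group_name: str = "group"
    n_samples: int = 6
    events_per_sample_by_category: Mapping[str, float] = field(
        default_factory=lambda: {
            SBS: 12.0, DEL1: 3.83, DEL_GE2: 11.33,
            INS1: 1.33, INS_GE2: 0.83, COMPLEX: 2.33, SV: 0.0,
        }
    )
    zygosity_mode: str = "mendelian_m2"  # or fixed_het / fixed_hom
    homopolymer_fraction_for_del1: float = 0.45
    repeat_or_microhomology_fraction_for_del_ge2: float = 0.49
    homopolymer_fraction_for_ins1: float = 0.44
    repeat_or_microhomology_fraction_for_ins_ge2: float = 0.76
    deletion_size_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"2-9": 80.0, "10-49": 40.0, ">=50": 9.0}
    )
    sbs_class_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SBS_WEIGHTS)
    )
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in (
            "homopolymer_fraction_for_del1",
            "repeat_or_microhomology_fraction_for_del_ge2",
            "homopolymer_fraction_for_ins1",
            "repeat_or_microhomology_fraction_for_ins_ge2",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(v < 0 for v in self.events_per_sample_by_category.values()):
            raise ValueError("expected counts must be >= 0")
        if self.zygosity_mode not in ("mendelian_m2", "fixed_het", "fixed_hom"):
            raise ValueError(f"unknown zygosity_mode {self.zygosity_mode!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{self.group_name}-{i + 1}" for i in range(self.n_samples)]


def dry_seed_profile(dose: int = 125, seed: int = 0, **overrides) -> SimulationProfile:
    """Dry-seed-irradiation-like group: deletion-rich, ~32-38 events/plant."""
    per_sample = {
        125: {SBS: 12.0, DEL1: 3.83, DEL_GE2: 11.33, INS1: 1.33,
              INS_GE2: 0.83, COMPLEX: 2.33, SV: 0.0},
        175: {SBS: 16.33, DEL1: 4.67, DEL_GE2: 11.67, INS1: 1.33,
              INS_GE2: 1.33, COMPLEX: 2.67, SV: 0.0},
    }[dose]
    return SimulationProfile(
        group_name=f"dryseed{dose}",
        events_per_sample_by_category=per_sample,
        deletion_size_distribution={"2-9": 80.0, "10-49": 40.0, ">=50": 9.0},
        homopolymer_fraction_for_del1=0.45,
        repeat_or_microhomology_fraction_for_del_ge2=0.49,
        seed=seed,
        **overrides,
    )


def seedling_profile(dose: int = 30, seed: int = 0, **overrides) -> SimulationProfile:
    """Seedling-irradiation-like group: SBS-dominated, ~20-22 events/plant."""
    per_sample = {
        20: {SBS: 13.0, DEL1: 1.5, DEL_GE2: 4.5, INS1: 0.33,
             INS_GE2: 0.17, COMPLEX: 2.5, SV: 0.0},
        30: {SBS: 12.0, DEL1: 1.33, DEL_GE2: 3.5, INS1: 0.33,
             INS_GE2: 0.5, COMPLEX: 1.83, SV: 0.0},
    }[dose]
    return SimulationProfile(
        group_name=f"seedling{dose}",
        events_per_sample_by_category=per_sample,
        deletion_size_distribution={"2-9": 19.0, "10-49": 19.0, ">=50": 6.0},
        homopolymer_fraction_for_del1=0.50,
        repeat_or_microhomology_fraction_for_del_ge2=0.43,
        seed=seed,
        **overrides,
    )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted mutation (one constituent of an event).

    Constituents of a planted complex event share an ``event_id``; for all
    other categories each record is its own event.  ``start`` is the first
    edited reference base (for insertions, the base immediately left of the
    insertion point); ``ref_segment``/``alt_segment`` are the unanchored
    deleted/inserted sequences (both single bases for an SBS).
    """

    sample_id: str
    chromosome: str
    start: int
    category: str
    ref_segment: str
    alt_segment: str
    zygosity: str
    planted_context: str = "none"  # none|homopolymer|repeat|microhomology
    event_id: str = ""
    sv_end: int | None = None


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

def generate_reference(
    total_length: int,
    n_chromosomes: int = 2,
    gc_fraction: float = 0.36,
    homopolymer_enrichment: float = 0.0,
    seed: int = 0,
) -> ReferenceGenome:
    """Random reference genome with optional homopolymer enrichment.

    Bases are drawn i.i.d. with the requested GC fraction; with
    ``homopolymer_enrichment`` w > 0, each base copies its predecessor with
    probability w/(w+10), raising the density of runs >= 3 while leaving
    base composition unbiased (the copy channel preserves the stationary
    distribution).
    """
    if total_length < 10_000:
        raise ValueError("total_length must be >= 10 kb")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    q = homopolymer_enrichment / (homopolymer_enrichment + 10.0)
    per = total_length // n_chromosomes
    lengths = [per] * n_chromosomes
    lengths[-1] += total_length - per * n_chromosomes
    chroms = {}
    for i, length in enumerate(lengths):
        idx = rng.choice(4, size=length, p=p)
        if q > 0:
            copy_mask = rng.random(length) < q
            copy_mask[0] = False
            for j in np.flatnonzero(copy_mask):
                idx[j] = idx[j - 1]
        chroms[f"chr{i + 1}"] = "".join(_BASES[idx])
    return ReferenceGenome(chroms)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS and a + b + c != "ATG"]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def generate_gene_models(
    genome: ReferenceGenome,
    n_genes: int,
    cds_length_codons: tuple[int, int] = (50, 100),
    seed: int = 0,
    intron_fraction: float = 0.3,
) -> list[GeneModel]:
    """Embed non-overlapping protein-coding genes into the genome.

    Each gene's spliced CDS starts with ATG, contains no internal stop and
    ends with a stop codon; a fraction of genes carry one intron.  The
    genome's chromosome sequences are rewritten in place at the gene loci.
    Raises :class:`CapacityError` when the genes cannot be placed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = cds_length_codons
    max_span = hi * 3 + 80 + 20
    if n_genes * max_span > 0.8 * genome.total_length:
        raise CapacityError(
            f"{n_genes} genes of up to {max_span} bp do not fit in "
            f"{genome.total_length} bp"
        )
    seqs = {name: list(seq) for name, seq in genome.chromosomes.items()}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in seqs}
    chrom_names = list(seqs)
    genes: list[GeneModel] = []
    attempts = 0
    for gi in range(n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        coding = "ATG" + "".join(
            _CODONS[k] for k in rng.integers(0, len(_CODONS), size=n_codons - 2)
        ) + _STOPS[rng.integers(0, 3)]
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < intron_fraction and n_codons >= 10:
            split = int(rng.integers(3, len(coding) - 3))
            intron_len = int(rng.integers(50, 81))
            intron = "".join(_BASES[rng.integers(0, 4, size=intron_len)])
            pieces = [coding[:split], coding[split:]]
        else:
            intron = ""
            pieces = [coding]
        transcript = pieces[0] + intron + (pieces[1] if len(pieces) == 2 else "")
        span = len(transcript)
        placed = False
        while attempts < 200 * n_genes:
            attempts += 1
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            limit = len(seqs[chrom]) - span - 1
            if limit < 2:
                continue
            start = int(rng.integers(2, limit))  # 1-based start of gene span
            end = start + span - 1
            if any(a <= end + 10 and start - 10 <= b for a, b in occupied[chrom]):
                continue
            genomic = transcript if strand == "+" else _revcomp(transcript)
            seqs[chrom][start - 1 : end] = list(genomic)
            occupied[chrom].append((start, end))
            if len(pieces) == 1:
                intervals = ((start, end),)
            else:
                e1, e2 = len(pieces[0]), len(pieces[1])
                if strand == "+":
                    intervals = (
                        (start, start + e1 - 1),
                        (start + e1 + len(intron), end),
                    )
                else:
                    # transcript-first exon is rightmost on the genome
                    intervals = (
                        (start, start + e2 - 1),
                        (start + e2 + len(intron), end),
                    )
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    chromosome=chrom,
                    strand=strand,
                    cds_intervals=intervals,
                )
            )
            placed = True
            break
        if not placed:
            raise CapacityError(f"could not place gene {gi + 1} of {n_genes}")
    for name in seqs:
        genome.chromosomes[name] = "".join(seqs[name])
    return genes


# ---------------------------------------------------------------------------
# Mutation simulation
# ---------------------------------------------------------------------------

def _find_runs(genome: ReferenceGenome, min_run: int = 3):
    """All maximal single-base runs >= min_run as (chrom, start, end, base)."""
    pattern = re.compile(r"(A{%d,}|C{%d,}|G{%d,}|T{%d,})" % ((min_run,) * 4))
    runs = []
    for name, seq in genome.chromosomes.items():
        for m in pattern.finditer(seq):
            runs.append((name, m.start() + 1, m.end(), seq[m.start()]))
    return runs


def _max_run_at(seq: str, lo: int, hi: int) -> int:
    """Longest single-base run intersecting 0-based slice [lo, hi)."""
    best = 0
    for i in range(lo, hi):
        base = seq[i]
        left = i
        while left > 0 and seq[left - 1] == base:
            left -= 1
        right = i + 1
        while right < len(seq) and seq[right] == base:
            right += 1
        best = max(best, right - left)
    return best


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _del_left_aligned_start0(seq: str, s0: int, size: int) -> int:
    """Leftmost 0-based start of a deletion equivalent to seq[s0:s0+size]."""
    while s0 > 0 and seq[s0 - 1] == seq[s0 + size - 1]:
        s0 -= 1
    return s0


def _ins_left_aligned(seq: str, anchor0: int, ins: str) -> tuple[int, str]:
    """Leftmost equivalent of an insertion after 0-based ``anchor0``."""
    while anchor0 >= 0 and ins[-1] == seq[anchor0]:
        ins = seq[anchor0] + ins[:-1]
        anchor0 -= 1
    return anchor0, ins


def _has_tandem_repeat(seq: str, fs0: int, fe0: int,
                       unit_range: tuple[int, int] = (2, 6),
                       min_copies: int = 2) -> bool:
    """A non-homopolymeric tandem repeat (unit 2-6, >= 2 exact copies)
    overlaps the 0-based footprint slice [fs0, fe0)."""
    lo_u, hi_u = unit_range
    margin = hi_u * min_copies
    win_lo = max(fs0 - margin, 0)
    win_hi = min(fe0 + margin, len(seq))
    window = seq[win_lo:win_hi]
    for u in range(lo_u, hi_u + 1):
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
                if block_lo < fe0 and fs0 < block_hi:
                    return True
    return False


def _has_microhomology(seq: str, start0: int, length: int, k: int = 2) -> bool:
    """Deleted segment seq[start0:start0+length] shares >= k terminal bases
    with its retained flank on either side."""
    d = seq[start0 : start0 + length]
    up = seq[max(start0 - k, 0) : start0]
    down = seq[start0 + length : start0 + length + k]
    return (
        _common_prefix_len(d, down) >= k
        or _common_prefix_len(up[::-1], d[::-1]) >= k
    )


class _Placer:
    """Tracks per-chromosome blocked intervals for one sample."""

    MARGIN = 60  # keep independent events well clear of the merge window

    def __init__(self, genome: ReferenceGenome, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.blocked: dict[str, list[tuple[int, int]]] = {
            name: [] for name in genome.chromosomes
        }
        names = list(genome.chromosomes)
        lengths = np.array([len(genome.chromosomes[n]) for n in names], dtype=float)
        self._names = names
        self._weights = lengths / lengths.sum()

    def free(self, chrom: str, start: int, end: int) -> bool:
        m = self.MARGIN
        return not any(
            a - m <= end and start <= b + m for a, b in self.blocked[chrom]
        )

    def block(self, chrom: str, start: int, end: int) -> None:
        self.blocked[chrom].append((start, end))

    def random_site(self, span: int) -> tuple[str, int] | None:
        """A free (chrom, start) for a footprint of ``span`` bases."""
        for _ in range(300):
            chrom = self._names[
                self.rng.choice(len(self._names), p=self._weights)
            ]
            limit = len(self.genome.chromosomes[chrom]) - span - 2
            if limit < 3:
                continue
            start = int(self.rng.integers(3, limit))
            if self.free(chrom, start, start + span - 1):
                return chrom, start
        return None


def _draw_zygosity(mode: str, rng: np.random.Generator) -> str:
    if mode == "fixed_het":
        return HET
    if mode == "fixed_hom":
        return HOM
    # mendelian_m2: 1:2:1 segregation with hom-wild-type undetectable
    return HOM if rng.random() < 1.0 / 3.0 else HET


def simulate_mutations(
    genome: ReferenceGenome,
    gene_models: Sequence[GeneModel] | None,
    profile: SimulationProfile,
) -> list[TruthRecord]:
    """Plant ground-truth mutations for every sample of one group.

    Per-sample category counts are Poisson around the profile expectations;
    events are placed pairwise >= 60 bp apart within a sample so that
    independent events never merge.  Context biases are honoured exactly:
    a fraction of DEL1/INS1 events sit in homopolymer runs >= 3 and a
    fraction of DEL_GE2/INS_GE2 events carry >= 2 bp junction microhomology,
    while the remaining events are placed at context-free sites.
    """
    rng = np.random.default_rng(profile.seed)
    runs = _find_runs(genome, min_run=3)
    if not runs:
        raise CapacityError("reference genome has no homopolymer runs >= 3")
    bins = list(profile.deletion_size_distribution)
    bin_w = np.array([profile.deletion_size_distribution[b] for b in bins], dtype=float)
    bin_w = bin_w / bin_w.sum()
    sbs_classes = list(profile.sbs_class_weights)
    sbs_w = np.array([profile.sbs_class_weights[c] for c in sbs_classes], dtype=float)
    sbs_w = sbs_w / sbs_w.sum()

    truths: list[TruthRecord] = []
    for sample in profile.sample_ids:
        placer = _Placer(genome, rng)
        counter = 0
        for category, expected in profile.events_per_sample_by_category.items():
            n = int(rng.poisson(expected)) if expected > 0 else 0
            for _ in range(n):
                counter += 1
                zyg = _draw_zygosity(profile.zygosity_mode, rng)
                event_id = f"{sample}:e{counter}"
                recs = _plant_one(
                    category, genome, profile, placer, rng, sample, zyg,
                    event_id, bins, bin_w, sbs_classes, sbs_w, runs,
                )
                truths.extend(recs)
    return truths


def _random_sbs(
    genome: ReferenceGenome,
    placer: _Placer,
    rng: np.random.Generator,
    sbs_classes: list[str],
    sbs_w: np.ndarray,
) -> tuple[str, int, str, str] | None:
    cls = sbs_classes[rng.choice(len(sbs_classes), p=sbs_w)]
    pairs = _CLASS_TO_PAIRS[cls]
    for _ in range(400):
        site = placer.random_site(1)
        if site is None:
            return None
        chrom, pos = site
        ref = genome.base(chrom, pos)
        for pref, palt in pairs:
            if ref == pref:
                return chrom, pos, ref, palt
    return None


def _plant_one(
    category: str,
    genome: ReferenceGenome,
    profile: SimulationProfile,
    placer: _Placer,
    rng: np.random.Generator,
    sample: str,
    zyg: str,
    event_id: str,
    bins: list[str],
    bin_w: np.ndarray,
    sbs_classes: list[str],
    sbs_w: np.ndarray,
    runs: list,
) -> list[TruthRecord]:
    seq_of = genome.chromosomes

    def record(chrom, start, ref, alt, context="none", sv_end=None):
        placer.block(chrom, start, max(start + max(len(ref), 1) - 1, start))
        return TruthRecord(
            sample_id=sample, chromosome=chrom, start=start, category=category,
            ref_segment=ref, alt_segment=alt, zygosity=zyg,
            planted_context=context, event_id=event_id, sv_end=sv_end,
        )

    if category == SBS:
        got = _random_sbs(genome, placer, rng, sbs_classes, sbs_w)
        if got is None:
            return []
        chrom, pos, ref, alt = got
        return [record(chrom, pos, ref, alt)]

    if category == COMPLEX:
        # two substitutions separated by a gap of 1..8 unmutated bases
        gap = int(rng.integers(1, 9))
        site = placer.random_site(gap + 2)
        if site is None:
            return []
        chrom, pos = site
        out = []
        for p in (pos, pos + gap + 1):
            ref = genome.base(chrom, p)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            out.append(
                TruthRecord(
                    sample_id=sample, chromosome=chrom, start=p,
                    category=COMPLEX, ref_segment=ref, alt_segment=alt,
                    zygosity=zyg, planted_context="none", event_id=event_id,
                )
            )
        placer.block(chrom, pos, pos + gap + 1)
        return out

    if category == DEL1:
        if rng.random() < profile.homopolymer_fraction_for_del1:
            for _ in range(300):
                chrom, a, b, base = runs[rng.integers(0, len(runs))]
                if a >= 3 and placer.free(chrom, a, b):
                    # delete the first base of the run (left-aligned form)
                    placer.block(chrom, a, b)
                    return [record(chrom, a, base, "", context="homopolymer")]
            return []
        for _ in range(300):
            site = placer.random_site(1)
            if site is None:
                return []
            chrom, pos = site
            if _max_run_at(seq_of[chrom], pos - 1, pos) < 3:
                return [record(chrom, pos, genome.base(chrom, pos), "")]
        return []

    if category == INS1:
        if rng.random() < profile.homopolymer_fraction_for_ins1:
            for _ in range(300):
                chrom, a, b, base = runs[rng.integers(0, len(runs))]
                if a >= 3 and placer.free(chrom, a, b):
                    placer.block(chrom, a, b)
                    # insert one more copy just before the run
                    return [
                        TruthRecord(
                            sample_id=sample, chromosome=chrom, start=a - 1,
                            category=INS1, ref_segment="", alt_segment=base,
                            zygosity=zyg, planted_context="homopolymer",
                            event_id=event_id,
                        )
                    ]
            return []
        for _ in range(300):
            site = placer.random_site(2)
            if site is None:
                return []
            chrom, pos = site
            seq = seq_of[chrom]
            base = str(rng.choice(list("ACGT")))
            # run after insertion between pos and pos+1 must stay < 3
            left = 1 if seq[pos - 1] == base else 0
            left += 1 if left and pos >= 2 and seq[pos - 2] == base else 0
            right = 1 if seq[pos] == base else 0
            right += 1 if right and pos + 1 < len(seq) and seq[pos + 1] == base else 0
            if left + right + 1 < 3:
                placer.block(chrom, pos, pos + 1)
                return [
                    TruthRecord(
                        sample_id=sample, chromosome=chrom, start=pos,
                        category=INS1, ref_segment="", alt_segment=base,
                        zygosity=zyg, planted_context="none", event_id=event_id,
                    )
                ]
        return []

    if category == DEL_GE2:
        b = bins[rng.choice(len(bins), p=bin_w)]
        if b == "2-9":
            size = int(rng.integers(2, 10))
        elif b == "10-49":
            size = int(rng.integers(10, 50))
        else:
            size = int(50 * 10 ** rng.uniform(0, 1.3))
        want_mh = rng.random() < profile.repeat_or_microhomology_fraction_for_del_ge2
        for _ in range(500):
            site = placer.random_site(size)
            if site is None:
                return []
            chrom, pos = site
            seq = seq_of[chrom]
            has = _has_microhomology(seq, pos - 1, size, k=2)
            uniform = len(set(seq[pos - 1 : pos - 1 + size])) == 1
            if want_mh and has:
                return [
                    record(chrom, pos, seq[pos - 1 : pos - 1 + size], "",
                           context="microhomology")
                ]
            # "none" sites must stay context-free after left-alignment,
            # which is where the downstream detectors look
            s0 = _del_left_aligned_start0(seq, pos - 1, size)
            if (
                not want_mh
                and not has
                and not uniform
                and not _has_tandem_repeat(seq, pos - 1, pos - 1 + size)
                and len(set(seq[s0 : s0 + size])) > 1
                and not _has_microhomology(seq, s0, size, k=2)
                and not _has_tandem_repeat(seq, s0, s0 + size)
            ):
                return [record(chrom, pos, seq[pos - 1 : pos - 1 + size], "")]
        return []

    if category == INS_GE2:
        size = int(rng.integers(2, 11))
        want_mh = rng.random() < profile.repeat_or_microhomology_fraction_for_ins_ge2
        for _ in range(500):
            site = placer.random_site(2)
            if site is None:
                return []
            chrom, pos = site
            seq = seq_of[chrom]
            if want_mh:
                # tandem-duplication-like insertion: copy the downstream flank
                ins = seq[pos : pos + size]
                if len(ins) < size or len(set(ins)) == 1:
                    continue
                context = "microhomology"
            else:
                ins = "".join(
                    str(b) for b in rng.choice(list("ACGT"), size=size)
                )
                if len(set(ins)) == 1:
                    continue
                up = seq[max(pos - 2, 0) : pos]
                down = seq[pos : pos + 2]
                a0, ins_n = _ins_left_aligned(seq, pos - 1, ins)
                down_n = seq[a0 + 1 : a0 + 3]
                if (
                    _common_prefix_len(ins, down) >= 2
                    or _common_prefix_len(up[::-1], ins[::-1]) >= 2
                    or _has_tandem_repeat(seq, pos - 1, pos + 1)
                    # and again at the left-aligned representation the
                    # downstream detectors will see
                    or len(set(ins_n)) == 1
                    or _common_prefix_len(ins_n, down_n) >= 2
                    or _has_tandem_repeat(seq, max(a0, 0), a0 + 2)
                ):
                    continue
                context = "none"
            placer.block(chrom, pos, pos + 1)
            return [
                TruthRecord(
                    sample_id=sample, chromosome=chrom, start=pos,
                    category=INS_GE2, ref_segment="", alt_segment=ins,
                    zygosity=zyg, planted_context=context, event_id=event_id,
                )
            ]
        return []

    if category == SV:
        if genome.total_length < 10_000:
            raise CapacityError("SV simulation needs a genome >= 10 kb")
        size = int(rng.integers(2000, 8000))
        site = placer.random_site(min(size, genome.total_length // 4))
        if site is None:
            return []
        chrom, pos = site
        end = min(pos + size, len(seq_of[chrom]) - 1)
        placer.block(chrom, pos, end)
        return [
            TruthRecord(
                sample_id=sample, chromosome=chrom, start=pos, category=SV,
                ref_segment=genome.base(chrom, pos), alt_segment="<DEL>",
                zygosity=zyg, planted_context="none", event_id=event_id,
                sv_end=end,
            )
        ]

    raise ValueError(f"unknown category {category!r}")


# ---------------------------------------------------------------------------
# Call emission
# ---------------------------------------------------------------------------

def _truth_to_call(t: TruthRecord, genome: ReferenceGenome,
                   mutant: int, depth: int) -> VariantCall:
    seq = genome.chromosomes[t.chromosome]
    if t.category == SV:
        return VariantCall(
            sample_id=t.sample_id, chromosome=t.chromosome, position=t.start,
            ref_allele=t.ref_segment, alt_allele="<DEL>",
            mutant_reads=mutant, depth=depth, sv_end=t.sv_end,
        )
    if t.ref_segment and t.alt_segment:  # substitution constituent
        return VariantCall(
            sample_id=t.sample_id, chromosome=t.chromosome, position=t.start,
            ref_allele=t.ref_segment, alt_allele=t.alt_segment,
            mutant_reads=mutant, depth=depth,
        )
    if t.ref_segment:  # deletion: anchor at the base before the first deleted
        anchor = seq[t.start - 2]
        return VariantCall(
            sample_id=t.sample_id, chromosome=t.chromosome,
            position=t.start - 1,
            ref_allele=anchor + t.ref_segment, alt_allele=anchor,
            mutant_reads=mutant, depth=depth,
        )
    # insertion: anchored at t.start (base left of the insertion point)
    anchor = seq[t.start - 1]
    return VariantCall(
        sample_id=t.sample_id, chromosome=t.chromosome, position=t.start,
        ref_allele=anchor, alt_allele=anchor + t.alt_segment,
        mutant_reads=mutant, depth=depth,
    )


def emit_calls(
    truth: Sequence[TruthRecord],
    noise: NoiseProfile,
    seed: int,
    genome: ReferenceGenome,
    sample_ids: Sequence[str] | None = None,
    out_dir=None,
) -> dict[str, list[VariantCall]]:
    """Turn truth records into noisy per-sample call sets (optionally on disk).

    Read support: depth ~ Poisson(depth_mean); mutant reads ~
    Binomial(depth, 0.5) for heterozygous and Binomial(depth, 0.98) for
    homozygous truths.  False positives are injected at AF <= 0.25 with
    >= 3 supporting reads; background artifact sites are injected into more
    than two samples.  With ``out_dir``, one VCF per sample plus a truth
    table TSV are written.
    """
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = sorted({t.sample_id for t in truth})
    calls: dict[str, list[VariantCall]] = {s: [] for s in sample_ids}
    for t in truth:
        depth = max(int(rng.poisson(noise.depth_mean)), 1)
        p = 0.5 if t.zygosity == HET else noise.hom_read_prob
        mutant = int(rng.binomial(depth, p))
        calls.setdefault(t.sample_id, []).append(
            _truth_to_call(t, genome, mutant, depth)
        )

    chrom_names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chrom_names], float)
    weights = lengths / lengths.sum()

    def random_snv(sample, mutant, depth):
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        pos = int(rng.integers(2, len(genome.chromosomes[chrom]) - 1))
        ref = genome.base(chrom, pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return VariantCall(
            sample_id=sample, chromosome=chrom, position=pos,
            ref_allele=ref, alt_allele=alt, mutant_reads=mutant, depth=depth,
        )

    if noise.false_positive_low_af_rate > 0:
        for sample in sample_ids:
            for _ in range(int(rng.poisson(noise.false_positive_low_af_rate))):
                depth = max(int(rng.poisson(noise.depth_mean)), 16)
                hi = int(0.25 * depth)
                mutant = int(rng.integers(3, max(hi, 3) + 1))
                mutant = min(mutant, hi)
                if mutant < 3:
                    continue
                calls[sample].append(random_snv(sample, mutant, depth))

    if noise.n_background_sites_shared > 0 and len(sample_ids) >= 3:
        for _ in range(noise.n_background_sites_shared):
            m = int(rng.integers(3, len(sample_ids) + 1))
            chosen = rng.choice(len(sample_ids), size=m, replace=False)
            proto = None
            for k in chosen:
                sample = sample_ids[int(k)]
                depth = max(int(rng.poisson(noise.depth_mean)), 1)
                mutant = int(rng.binomial(depth, 0.5))
                if proto is None:
                    proto = random_snv(sample, mutant, depth)
                    calls[sample].append(proto)
                else:
                    calls[sample].append(
                        replace(proto, sample_id=sample,
                                mutant_reads=mutant, depth=depth)
                    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample in sample_ids:
            write_vcf(calls[sample], out / f"{sample}.vcf", sample, genome)
        write_truth_table(truth, out / "truth.tsv")
    return calls


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    cols = ("sample", "chrom", "pos", "category", "ref", "alt",
            "zygosity", "planted_context", "event_id", "sv_end")
    lines = ["\t".join(cols)]
    for t in sorted(truth, key=lambda t: (t.sample_id, t.chromosome, t.start)):
        lines.append("\t".join(map(str, (
            t.sample_id, t.chromosome, t.start, t.category, t.ref_segment,
            t.alt_segment, t.zygosity, t.planted_context, t.event_id,
            t.sv_end if t.sv_end is not None else "",
        ))))
    Path(path).write_text("\n".join(lines) + "\n")
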