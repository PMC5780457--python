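"""Group-level statistics: mutation frequency, SBS spectrum, Ti/Tv,
deletion-size distributions, zygosity ratios, derived per-generation and
per-locus rates, and single-hit multitarget survival fitting.

Mutation frequency (MF) is mutation events per base pair: the event count
of a sample divided by the reference genome length (119,146,348 bp for
the Arabidopsis TAIR10.27 assembly when that reference is used).
Structural variants are excluded from all frequency comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .events import (CATEGORIES, COMPLEX, DEL1, DEL_GE2, SBS, SV,
                     MutationEvent, deletion_size_bin)
from .filtering import HET, HOM

__all__ = [
    "TAIR10_GENOME_LENGTH",
    "SPONTANEOUS_MF",
    "SPECTRUM6_CLASSES",
    "GroupSummary",
    "SurvivalFit",
    "DerivedRates",
    "mean_se",
    "category_table",
    "mutation_frequency",
    "sbs_spectrum",
    "compare_groups",
    "het_hom_stats",
    "mendelian_expectation",
    "derived_rates",
    "locus_mf",
    "fit_survival",
    "summarize_group",
]

TAIR10_GENOME_LENGTH = 119_146_348
#: spontaneous per-bp per-generation mutation frequency in Arabidopsis
SPONTANEOUS_MF = 7.1e-9

#: the six strand-merged substitution classes; the first two are transitions
SPECTRUM6_CLASSES = (
    "G:C>A:T",
    "A:T>G:C",
    "G:C>T:A",
    "G:C>C:G",
    "A:T>T:A",
    "A:T>C:G",
)

_SPECTRUM_LOOKUP = {
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
}


def mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(n), sample sd) of a vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return (float("nan"), float("nan"))
    se = arr.std(ddof=1) / math.sqrt(arr.size) if arr.size > 1 else float("nan")
    return (float(arr.mean()), float(se))


@dataclass
class GroupSummary:
    """Per-group backbone of the report."""

    group: str
    per_sample_event_counts: list[int]
    per_sample_mf: list[float]
    mean_mf: float
    se_mf: float
    category_counts: dict[str, int]
    category_percent: dict[str, int]
    spectrum6: dict[str, int]
    ti_tv: float
    deletion_bins: dict[str, int]
    het_count: int
    hom_count: int
    het_hom_ratio: float | None


@dataclass(frozen=True)
class SurvivalFit:
    """Single-hit multitarget fit S(D) = 1 - (1 - exp(-D/D0))^n."""

    d0: float  # mean lethal dose, Gy
    n_extrapolation: float

    @property
    def dq(self) -> float:
        """Quasi-threshold (shoulder) dose: D0 * ln(n)."""
        return self.d0 * math.log(self.n_extrapolation)

    def survival(self, dose):
        dose = np.asarray(dose, dtype=float)
        return 1.0 - (1.0 - np.exp(-dose / self.d0)) ** self.n_extrapolation


@dataclass(frozen=True)
class DerivedRates:
    """M1-extrapolated rates and fold change over the spontaneous MF."""

    mf_m2: float
    mf_m1: float
    fold_over_spontaneous: float
    spontaneous_mf: float = SPONTANEOUS_MF


# ---------------------------------------------------------------------------
# Category tables and mutation frequency
# ---------------------------------------------------------------------------

def category_table(counts_by_group: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Per-group category counts with deletion/insertion subtotals and
    integer percentages of each group total (SVs excluded)."""
    rows = []
    for group, counts in counts_by_group.items():
        c = {cat: int(counts.get(cat, 0)) for cat in CATEGORIES if cat != SV}
        total = sum(c.values())
        deletions = c[DEL1] + c[DEL_GE2]
        insertions = c["INS1"] + c["INS_GE2"]
        row = {"group": group, **c, "deletion_total": deletions,
               "insertion_total": insertions, "grand_total": total}
        for cat in (SBS, COMPLEX):
            row[f"{cat}_pct"] = _pct(c[cat], total)
        row["deletion_pct"] = _pct(deletions, total)
        row["insertion_pct"] = _pct(insertions, total)
        rows.append(row)
    return pd.DataFrame(rows)


def _pct(n: int, d: int) -> int:
    return round(100 * n / d) if d else 0


def mutation_frequency(
    events_by_sample: Mapping[str, Sequence[MutationEvent]],
    genome_length: int,
) -> pd.DataFrame:
    """Per-sample MF = event count / genome length; SVs are excluded."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    rows = []
    for sample, events in events_by_sample.items():
        n = sum(1 for e in events if e.category != SV)
        rows.append({"sample": sample, "n_events": n, "mf": n / genome_length})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SBS spectrum
# ---------------------------------------------------------------------------

def sbs_spectrum(
    events: Sequence[MutationEvent],
) -> tuple[dict[str, int], float]:
    """Six-class strand-merged SBS spectrum and the Ti/Tv ratio."""
    spectrum = {cls: 0 for cls in SPECTRUM6_CLASSES}
    for ev in events:
        if ev.category != SBS:
            continue
        call = ev.constituents[0].call
        cls = _SPECTRUM_LOOKUP.get((call.ref_allele, call.alt_allele))
        if cls is not None:
            spectrum[cls] += 1
    transitions = spectrum["G:C>A:T"] + spectrum["A:T>G:C"]
    transversions = sum(spectrum[c] for c in SPECTRUM6_CLASSES[2:])
    ti_tv = transitions / transversions if transversions else float("nan")
    return spectrum, ti_tv


def deletion_bin_counts(events: Sequence[MutationEvent]) -> dict[str, int]:
    """Deletion-size histogram over bins 1, 2-9, 10-49 and >=50 bp."""
    bins = {"1": 0, "2-9": 0, "10-49": 0, ">=50": 0}
    for ev in events:
        if ev.category in (DEL1, DEL_GE2):
            bins[deletion_size_bin(ev)] += 1
    return bins


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    mf_a: Sequence[float],
    mf_b: Sequence[float],
    table: pd.DataFrame | np.ndarray | None = None,
    welch: bool = True,
) -> dict:
    """Two-sample t-test on per-sample MFs, plus an optional chi-squared
    homogeneity test on a category/spectrum/size contingency table."""
    a = np.asarray(mf_a, dtype=float)
    b = np.asarray(mf_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs >= 2 samples per group")
    result: dict = {}
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        result["t"] = 0.0
        result["t_pvalue"] = 1.0
    else:
        t = sps.ttest_ind(a, b, equal_var=not welch)
        result["t"] = float(t.statistic)
        result["t_pvalue"] = float(t.pvalue)
    if table is not None:
        obs = np.asarray(table, dtype=float)
        obs = obs[:, obs.sum(axis=0) > 0]
        chi2 = sps.chi2_contingency(obs, correction=False)
        result["chi2"] = float(chi2.statistic)
        result["chi2_pvalue"] = float(chi2.pvalue)
        result["chi2_low_expected"] = bool((chi2.expected_freq < 5).any())
    return result


def het_hom_stats(
    events_by_sample: Mapping[str, Sequence[MutationEvent]],
) -> pd.DataFrame:
    """Per-sample het/hom counts and ratio (NaN when hom == 0)."""
    rows = []
    for sample, events in events_by_sample.items():
        het = sum(1 for e in events if e.category != SV and e.zygosity == HET)
        hom = sum(1 for e in events if e.category != SV and e.zygosity == HOM)
        rows.append(
            {
                "sample": sample,
                "het": het,
                "hom": hom,
                "ratio": het / hom if hom else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def het_hom_group_test(ratios: Sequence[float], expected: float = 2.0) -> dict:
    """Mean +/- SE of the defined ratios and a one-sample t-test vs 2.0."""
    finite = [r for r in ratios if np.isfinite(r)]
    mean, se = mean_se(finite)
    out = {"mean": mean, "se": se, "n_defined": len(finite),
           "n_undefined": len(ratios) - len(finite)}
    if len(finite) >= 2 and np.std(finite) > 0:
        t = sps.ttest_1samp(finite, expected)
        out["t"] = float(t.statistic)
        out["pvalue"] = float(t.pvalue)
    else:
        out["t"] = float("nan")
        out["pvalue"] = float("nan")
    return out


def mendelian_expectation(n_mutations: int, seed: int) -> float:
    """Simulated het:hom ratio of detectable M2 mutations.

    Each M1-heterozygous mutation segregates 1:2:1 in a single M2 plant;
    homozygous wild type is undetectable, so a detectable mutation is
    heterozygous with probability 2/3.  The analytic limit is 2.0.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    rng = np.random.default_rng(seed)
    het = int(rng.binomial(n_mutations, 2.0 / 3.0))
    hom = n_mutations - het
    return het / hom if hom else float("inf")


# ---------------------------------------------------------------------------
# Derived rates
# ---------------------------------------------------------------------------

def derived_rates(mean_mf_m2: float, spontaneous: float = SPONTANEOUS_MF) -> DerivedRates:
    """M1 extrapolation (x4/3) and fold over the spontaneous frequency.

    M2 plants carry on average 3/4 of the M1 mutation load (a segregating
    mutation is absent from a given M2 plant with probability 1/4), so the
    M1 frequency is 4/3 times the M2 frequency.
    """
    if spontaneous <= 0:
        raise ValueError("spontaneous MF must be positive")
    if mean_mf_m2 < 0:
        raise ValueError("MF must be non-negative")
    mf_m1 = mean_mf_m2 * 4.0 / 3.0
    return DerivedRates(
        mf_m2=mean_mf_m2,
        mf_m1=mf_m1,
        fold_over_spontaneous=mf_m1 / spontaneous,
        spontaneous_mf=spontaneous,
    )


def locus_mf(
    mutant_count: int, n_plants: int, n_loci: int, n_genes_genome: int
) -> tuple[float, float]:
    """Phenotype-screen per-locus MF and expected affected genes per plant.

    per-locus MF = mutants / (plants x loci); the expected number of genes
    with a homozygous loss-of-function mutation per plant is that frequency
    times the number of protein-coding genes in the genome.
    """
    if n_plants <= 0 or n_loci <= 0:
        raise ValueError("plant and locus counts must be positive")
    mf = mutant_count / (n_plants * n_loci)
    return (mf, mf * n_genes_genome)


# ---------------------------------------------------------------------------
# Survival-curve fitting
# ---------------------------------------------------------------------------

def fit_survival(
    doses: Sequence[float], survival_fractions: Sequence[float]
) -> SurvivalFit:
    """Least-squares fit of the single-hit multitarget survival model.

    S(D) = 1 - (1 - exp(-D/D0))^n with D0 > 0 and n >= 1.  Requires at
    least three dose points including 0 Gy and a real dose response.
    """
    d = np.asarray(doses, dtype=float)
    s = np.asarray(survival_fractions, dtype=float)
    if d.size < 3 or 0.0 not in d:
        raise ValueError("need >= 3 dose points including 0 Gy")
    if np.all(s >= 0.999):
        raise ValueError("no dose response: all survival fractions are ~1")

    def model(dose, d0, n):
        return 1.0 - (1.0 - np.exp(-dose / d0)) ** n

    # moment-style start: D0 from the terminal slope, n from the intercept
    d0_init = max(d[d > 0].max() / max(-np.log(max(s.min(), 1e-6)), 1e-6), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model, d, s,
            p0=[d0_init, 5.0],
            bounds=([1e-6, 1.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise ValueError(f"survival fit did not converge: {exc}") from exc
    return SurvivalFit(d0=float(popt[0]), n_extrapolation=float(popt[1]))


# ---------------------------------------------------------------------------
# Group summary assembly
# ---------------------------------------------------------------------------

def summarize_group(
    group: str,
    events_by_sample: Mapping[str, Sequence[MutationEvent]],
    genome_length: int,
) -> GroupSummary:
    """Assemble the per-group report backbone from classified events."""
    mf = mutation_frequency(events_by_sample, genome_length)
    mean_mf, se_mf = mean_se(mf["mf"])
    all_events = [e for evs in events_by_sample.values() for e in evs
                  if e.category != SV]
    counts = {cat: 0 for cat in CATEGORIES if cat != SV}
    for e in all_events:
        counts[e.category] += 1
    total = sum(counts.values())
    spectrum, ti_tv = sbs_spectrum(all_events)
    hh = het_hom_stats(events_by_sample)
    het, hom = int(hh["het"].sum()), int(hh["hom"].sum())
    return GroupSummary(
        group=group,
        per_sample_event_counts=mf["n_events"].tolist(),
        per_sample_mf=mf["mf"].tolist(),
        mean_mf=mean_mf,
        se_mf=se_mf,
        category_counts=counts,
        category_percent={c: _pct(n, total) for c, n in counts.items()},
        spectrum6=spectrum,
        ti_tv=ti_tv,
        deletion_bins=deletion_bin_counts(all_events),
        het_count=het,
        hom_count=hom,
        het_hom_ratio=het / hom if hom else None,
    )
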