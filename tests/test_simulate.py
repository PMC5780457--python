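"""Synthetic reference, gene embedding, mutation planting and call emission."""

import collections

import pytest
from Bio.Seq import Seq

from radmut.context import annotate_event
from radmut.events import (COMPLEX, DEL1, DEL_GE2, INS1, INS_GE2, SBS, SV,
                           merge_events)
from radmut.filtering import HET, HOM, FilteredCall
from radmut.io import normalize_variant, read_vcf
from radmut.simulate import (CapacityError, NoiseProfile, SimulationProfile,
                             dry_seed_profile, emit_calls,
                             generate_gene_models, generate_reference,
                             seedling_profile, simulate_mutations,
                             _truth_to_call)


def _gc(genome):
    seq = "".join(genome.chromosomes.values())
    return (seq.count("G") + seq.count("C")) / len(seq)


def _run_count(genome, min_run=3):
    import re
    pat = re.compile(r"A{3,}|C{3,}|G{3,}|T{3,}")
    return sum(len(pat.findall(s)) for s in genome.chromosomes.values())


class TestReference:
    def test_length_and_gc(self):
        g = generate_reference(200_000, n_chromosomes=3, gc_fraction=0.36,
                               seed=1)
        assert g.total_length == 200_000
        assert len(g.chromosomes) == 3
        assert abs(_gc(g) - 0.36) < 0.02

    def test_enrichment_raises_run_density_not_composition(self):
        plain = generate_reference(100_000, gc_fraction=0.36,
                                   homopolymer_enrichment=0.0, seed=2)
        rich = generate_reference(100_000, gc_fraction=0.36,
                                  homopolymer_enrichment=3.0, seed=2)
        assert _run_count(rich) > 1.3 * _run_count(plain)
        assert abs(_gc(rich) - 0.36) < 0.02

    def test_deterministic(self):
        a = generate_reference(20_000, seed=9)
        b = generate_reference(20_000, seed=9)
        c = generate_reference(20_000, seed=10)
        assert a.chromosomes == b.chromosomes
        assert a.chromosomes != c.chromosomes

    @pytest.mark.parametrize("kwargs", [
        dict(total_length=5_000),
        dict(total_length=20_000, gc_fraction=0.0),
        dict(total_length=20_000, n_chromosomes=0),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            generate_reference(**kwargs)


class TestGeneModels:
    def test_orf_invariants(self, genome_with_genes):
        genome, genes = genome_with_genes
        assert len(genes) == 25
        for gene in genes:
            cds = gene.cds_sequence(genome)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = str(Seq(cds).translate())
            assert protein.endswith("*")
            assert protein.count("*") == 1

    def test_some_genes_have_introns_and_both_strands(self, genome_with_genes):
        _, genes = genome_with_genes
        assert any(len(g.cds_intervals) > 1 for g in genes)
        assert {g.strand for g in genes} == {"+", "-"}

    def test_no_overlap(self, genome_with_genes):
        _, genes = genome_with_genes
        by_chrom = collections.defaultdict(list)
        for g in genes:
            by_chrom[g.chromosome].append(g.span)
        for spans in by_chrom.values():
            spans.sort()
            assert all(a2 > b1 for (_, b1), (a2, _) in zip(spans, spans[1:]))

    def test_capacity_error(self):
        g = generate_reference(10_000, seed=3)
        with pytest.raises(CapacityError):
            generate_gene_models(g, 500, seed=4)


class TestProfiles:
    def test_standard_profiles_distinct(self):
        names = {p.group_name for p in (
            dry_seed_profile(125), dry_seed_profile(175),
            seedling_profile(20), seedling_profile(30))}
        assert len(names) == 4

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimulationProfile(homopolymer_fraction_for_del1=1.5)

    def test_invalid_zygosity_mode(self):
        with pytest.raises(ValueError):
            SimulationProfile(zygosity_mode="diploid")


@pytest.fixture(scope="module")
def planted(genome):
    prof = dry_seed_profile(125, seed=13, n_samples=6)
    return simulate_mutations(genome, None, prof), prof


@pytest.fixture(scope="module")
def truths(genome):
    prof = dry_seed_profile(125, seed=17, n_samples=4)
    return simulate_mutations(genome, None, prof)


class TestPlanting:
    def test_all_categories_present(self, planted):
        truths, _ = planted
        cats = {t.category for t in truths}
        assert {SBS, DEL1, DEL_GE2, COMPLEX}.issubset(cats)

    def test_ref_segments_match_reference(self, genome, planted):
        truths, _ = planted
        for t in truths:
            if t.ref_segment and t.category != SV:
                got = genome.lookup(t.chromosome, t.start,
                                    t.start + len(t.ref_segment) - 1)
                assert got == t.ref_segment

    def test_events_well_separated(self, planted):
        truths, _ = planted
        by_sample = collections.defaultdict(list)
        for t in truths:
            by_sample[(t.sample_id, t.chromosome)].append(t)
        for recs in by_sample.values():
            recs.sort(key=lambda t: t.start)
            for a, b in zip(recs, recs[1:]):
                if a.event_id != b.event_id:
                    a_end = a.start + max(len(a.ref_segment), 1) - 1
                    assert b.start - a_end > 10

    def test_complex_constituents_share_event_and_zygosity(self, planted):
        truths, _ = planted
        by_event = collections.defaultdict(list)
        for t in truths:
            by_event[t.event_id].append(t)
        complexes = [v for v in by_event.values()
                     if any(t.category == COMPLEX for t in v)]
        assert complexes
        for group in complexes:
            assert len(group) >= 2
            assert len({t.zygosity for t in group}) == 1
            assert len({t.sample_id for t in group}) == 1

    def test_planted_contexts_recovered_by_detectors(self, genome, planted):
        """Integration oracle: run each planted indel through normalization,
        merging and the context detectors; planted labels must be honoured."""
        truths, _ = planted
        for t in truths:
            if t.category not in (DEL1, INS1, DEL_GE2, INS_GE2):
                continue
            call = normalize_variant(_truth_to_call(t, genome, 15, 30), genome)
            (ev,) = merge_events([FilteredCall(call, t.zygosity)])
            ann = annotate_event(genome, ev)
            if t.planted_context == "homopolymer":
                assert ann.homopolymer, t
            elif t.planted_context == "microhomology":
                assert ann.microhomology, t
            elif t.category in (DEL1, INS1):
                assert not ann.homopolymer, t
            else:
                assert not ann.repeat_or_microhomology, t

    def test_mendelian_zygosity_ratio(self, genome):
        prof = dry_seed_profile(125, seed=21, n_samples=60)
        truths = simulate_mutations(genome, None, prof)
        zyg_by_event = {t.event_id: t.zygosity for t in truths}
        het = sum(1 for z in zyg_by_event.values() if z == HET)
        hom = len(zyg_by_event) - het
        assert len(zyg_by_event) > 1500
        assert 1.8 <= het / hom <= 2.2

    def test_deterministic(self, genome):
        prof = dry_seed_profile(125, seed=5, n_samples=2)
        assert (simulate_mutations(genome, None, prof)
                == simulate_mutations(genome, None, prof))


class TestEmission:
    def test_noise_free_bijection(self, genome, truths):
        calls = emit_calls(truths, NoiseProfile(), seed=1, genome=genome)
        per_sample_truth = collections.Counter(t.sample_id for t in truths)
        for sample, cs in calls.items():
            assert len(cs) == per_sample_truth[sample]

    def test_het_and_hom_allele_fractions(self, genome, truths):
        calls = emit_calls(truths, NoiseProfile(), seed=1, genome=genome)
        zyg = {(t.sample_id, t.chromosome, t.start): t.zygosity for t in truths}
        het_afs, hom_afs = [], []
        for cs in calls.values():
            for c in cs:
                z = zyg.get((c.sample_id, c.chromosome, c.position))
                if z is None:  # anchored indels shift position by one
                    z = zyg.get((c.sample_id, c.chromosome, c.position + 1))
                if z == HET:
                    het_afs.append(c.af)
                elif z == HOM:
                    hom_afs.append(c.af)
        assert het_afs and hom_afs
        assert 0.45 < sum(het_afs) / len(het_afs) < 0.55
        assert sum(hom_afs) / len(hom_afs) > 0.9

    def test_false_positives_all_low_af(self, genome):
        noise = NoiseProfile(false_positive_low_af_rate=6.0)
        calls = emit_calls([], noise, seed=3, genome=genome,
                           sample_ids=["a", "b", "c"])
        fps = [c for cs in calls.values() for c in cs]
        assert fps
        assert all(c.mutant_reads >= 3 and c.af <= 0.25 for c in fps)

    def test_background_sites_shared_by_three_or_more(self, genome):
        noise = NoiseProfile(n_background_sites_shared=3)
        calls = emit_calls([], noise, seed=3, genome=genome,
                           sample_ids=[f"s{i}" for i in range(6)])
        sites = collections.Counter(
            (c.chromosome, c.position, c.alt_allele)
            for cs in calls.values() for c in cs
        )
        assert len(sites) == 3
        assert all(n >= 3 for n in sites.values())

    def test_deterministic_and_seed_sensitive(self, genome, truths):
        a = emit_calls(truths, NoiseProfile(), seed=8, genome=genome)
        b = emit_calls(truths, NoiseProfile(), seed=8, genome=genome)
        c = emit_calls(truths, NoiseProfile(), seed=9, genome=genome)
        assert a == b
        assert a != c

    def test_writes_vcfs_and_truth_table(self, genome, truths, tmp_path):
        calls = emit_calls(truths, NoiseProfile(), seed=1, genome=genome,
                           out_dir=tmp_path)
        samples = sorted(calls)
        assert sorted(p.name for p in tmp_path.glob("*.vcf")) == [
            f"{s}.vcf" for s in samples
        ]
        assert (tmp_path / "truth.tsv").exists()
        for s in samples:
            on_disk = read_vcf(tmp_path / f"{s}.vcf", s)
            assert sorted(on_disk, key=lambda c: (c.chromosome, c.position)) \
                == sorted(calls[s], key=lambda c: (c.chromosome, c.position))

    def test_noise_validation(self):
        with pytest.raises(ValueError):
            NoiseProfile(depth_mean=5)
        with pytest.raises(ValueError):
            NoiseProfile(false_positive_low_af_rate=-1)
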