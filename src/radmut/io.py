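"""Reference, variant and gene-model I/O, plus canonical variant representation.

All coordinates are 1-based inclusive internally, matching VCF and GFF3;
conversions happen only at format boundaries.  Variants are stored in the
anchored VCF representation (ref and alt alleles both non-empty) and can be
brought to a canonical left-aligned, minimal form with
:func:`normalize_variant`.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "FormatError",
    "ReferenceGenome",
    "VariantCall",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "normalize_variant",
    "read_gff3",
    "write_gff3",
]

_IUPAC = set("ACGTNRYSWKMBDHV")

# gene/feature types never counted as protein-coding gene models
_SKIP_GENE_TYPES = {"pseudogene", "transposable_element_gene", "transposable_element"}


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


class ReferenceGenome:
    """Named chromosome sequences with 1-based inclusive subsequence lookup."""

    def __init__(self, chromosomes: Mapping[str, str]):
        self.chromosomes: dict[str, str] = {
            name: seq.upper() for name, seq in chromosomes.items()
        }
        for name, seq in self.chromosomes.items():
            bad = set(seq) - _IUPAC
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def lookup(self, chrom: str, start: int, end: int) -> str:
        """Subsequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive."""
        seq = self.chromosomes[chrom]
        if start < 1 or end > len(seq) or start > end + 1:
            raise IndexError(f"{chrom}:{start}-{end} outside 1..{len(seq)}")
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.lookup(chrom, pos, pos)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ReferenceGenome({len(self.chromosomes)} chromosomes, "
            f"{self.total_length} bp)"
        )


@dataclass(frozen=True)
class VariantCall:
    """One per-sample candidate mutation site in anchored VCF representation.

    ``sv_end`` is set only for symbolic structural-variant records
    (``alt_allele == "<DEL>"``), which are carried through unchanged.
    """

    sample_id: str
    chromosome: str
    position: int  # 1-based VCF POS
    ref_allele: str
    alt_allele: str
    mutant_reads: int
    depth: int
    sv_end: int | None = None

    @property
    def af(self) -> float | None:
        """Allele frequency (mutant reads / depth); None when depth is 0."""
        if self.depth <= 0:
            return None
        return self.mutant_reads / self.depth

    @property
    def is_symbolic(self) -> bool:
        return self.alt_allele.startswith("<")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 == len(self.alt_allele) and not self.is_symbolic

    @property
    def net_length(self) -> int:
        """Signed alt-minus-ref length; 0 for substitutions."""
        if self.is_symbolic:
            if self.sv_end is None:
                return 0
            return -(self.sv_end - self.position)
        return len(self.alt_allele) - len(self.ref_allele)

    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as ordered CDS intervals on one strand."""

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    cds_intervals: tuple[tuple[int, int], ...]  # genomic order, 1-based inclusive
    translatable: bool = True

    def __post_init__(self):
        ivs = self.cds_intervals
        if any(a > b for a, b in ivs):
            raise ValueError(f"{self.gene_id}: malformed CDS interval")
        if any(ivs[i][1] >= ivs[i + 1][0] for i in range(len(ivs) - 1)):
            raise ValueError(f"{self.gene_id}: CDS intervals overlap or are unsorted")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        """Spliced CDS in translation order (reverse-complemented on '-')."""
        s = "".join(genome.lookup(self.chromosome, a, b) for a, b in self.cds_intervals)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def cds_index_of(self, pos: int) -> int | None:
        """0-based index of genomic position ``pos`` in the spliced CDS, or None."""
        offset = 0
        for a, b in self.cds_intervals:
            if a <= pos <= b:
                idx = offset + (pos - a)
                if self.strand == "-":
                    idx = self.cds_length - 1 - idx
                return idx
            offset += b - a + 1
        return None

    def overlaps_cds(self, start: int, end: int) -> bool:
        return any(a <= end and start <= b for a, b in self.cds_intervals)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> ReferenceGenome:
    """Read a (possibly gzipped) FASTA file into a :class:`ReferenceGenome`.

    Headers are truncated at the first whitespace; sequences are upper-cased.
    Duplicate labels and non-IUPAC characters raise :class:`FormatError`.
    """
    chroms: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name = rec.id
            if name in chroms:
                raise FormatError(f"duplicate chromosome label {name!r}")
            chroms[name] = str(rec.seq).upper()
    return ReferenceGenome(chroms)


def write_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_id: str | None = None) -> list[VariantCall]:
    """Read per-sample calls from a VCF 4.x file with FORMAT AD (and DP).

    Multi-allelic records are split into one call per alternate allele, with
    the allelic depth of that allele as the mutant read count.  Records with
    no usable depth yield calls with ``depth = 0`` (``af`` undefined).
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    calls: list[VariantCall] = []
    with vf:
        samples = list(vf.header.samples)
        if sample_id is None:
            if len(samples) != 1:
                raise FormatError("sample_id required for multi-sample VCF")
            sample_id = samples[0]
        elif sample_id not in samples:
            raise FormatError(f"sample {sample_id!r} not in VCF header")
        for rec in vf:
            if rec.alts is None:
                continue
            fmt = rec.samples[sample_id]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            for i, alt in enumerate(rec.alts):
                if ad is not None and len(ad) > i + 1 and ad[0] is not None:
                    mutant = int(ad[i + 1])
                    depth = int(dp) if dp is not None else int(sum(x or 0 for x in ad))
                else:
                    mutant, depth = 0, 0
                sv_end = None
                if alt.startswith("<"):
                    sv_end = rec.stop  # pysam: 0-based exclusive == 1-based END
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        chromosome=rec.chrom,
                        position=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt if alt.startswith("<") else alt.upper(),
                        mutant_reads=mutant,
                        depth=depth,
                        sv_end=sv_end,
                    )
                )
    return calls


def write_vcf(calls: Sequence[VariantCall], path, sample_id: str,
              genome: ReferenceGenome | None = None) -> None:
    """Write single-sample VCF 4.2 with GT:AD:DP, sorted by position."""
    lines = ["##fileformat=VCFv4.2"]
    if genome is not None:
        for name, seq in genome.chromosomes.items():
            lines.append(f"##contig=<ID={name},length={len(seq)}>")
    else:
        for name in dict.fromkeys(c.chromosome for c in calls):
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of SV">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id,
    ]
    for c in sorted(calls, key=lambda c: (c.chromosome, c.position, c.alt_allele)):
        info = f"END={c.sv_end}" if c.sv_end is not None else "."
        ref_reads = max(c.depth - c.mutant_reads, 0)
        gt = "0/1"
        if c.af is not None and c.af >= 0.8:
            gt = "1/1"
        lines.append(
            f"{c.chromosome}\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}"
            f"\t.\tPASS\t{info}\tGT:AD:DP\t{gt}:{ref_reads},{c.mutant_reads}:{c.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def normalize_variant(call: VariantCall, genome: ReferenceGenome) -> VariantCall:
    """Left-align and minimize a variant (shared-base trimming + left shifting).

    Symbolic records are returned unchanged.  The operation is idempotent and
    never changes the edit's net length.
    """
    if call.is_symbolic:
        return call
    ref, alt, pos = call.ref_allele, call.alt_allele, call.position
    if not ref or not alt:
        raise ValueError("anchored representation required (non-empty ref and alt)")
    chrom_seq = genome.chromosomes[call.chromosome]
    # iterate: strip identical trailing bases, extending left when one allele
    # would become empty (classic left-alignment)
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break
                prev = chrom_seq[pos - 2]
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
                pos -= 1
            else:
                ref = ref[:-1]
                alt = alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return replace(call, position=pos, ref_allele=ref, alt_allele=alt)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[GeneModel]:
    """Read protein-coding gene models (CDS features of the first transcript).

    Pseudogenes and transposable-element genes are skipped.  Genes whose CDS
    length is not divisible by 3 are flagged non-translatable with a warning.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.featuretype in _SKIP_GENE_TYPES:
            continue
        transcripts = list(db.children(gene, level=1, order_by="start"))
        cds = []
        for tx in transcripts:
            if tx.featuretype in _SKIP_GENE_TYPES:
                cds = []
                break
            cds = list(db.children(tx, featuretype="CDS", order_by="start"))
            if cds:
                break  # first transcript with CDS only
        if not cds:
            # CDS may be attached to the gene directly
            cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        intervals = tuple((f.start, f.end) for f in cds)
        total = sum(b - a + 1 for a, b in intervals)
        translatable = total % 3 == 0
        if not translatable:
            warnings.warn(
                f"gene {gene.id}: CDS length {total} not divisible by 3; "
                "flagged non-translatable"
            )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_intervals=intervals,
                translatable=translatable,
            )
        )
    # skip features typed as TE/pseudogene at top level without 'gene' type
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as gene/mRNA/CDS features, 1-based inclusive."""
    lines = ["##gff-version 3"]
    for g in genes:
        start, end = g.span
        lines.append(
            f"{g.chromosome}\tradmut\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        tx = f"{g.gene_id}.1"
        lines.append(
            f"{g.chromosome}\tradmut\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
            f"ID={tx};Parent={g.gene_id}"
        )
        # phase of each CDS piece in genomic order
        phases = _cds_phases(g)
        for (a, b), ph in zip(g.cds_intervals, phases):
            lines.append(
                f"{g.chromosome}\tradmut\tCDS\t{a}\t{b}\t.\t{g.strand}\t{ph}\t"
                f"ID=cds-{g.gene_id};Parent={tx}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _cds_phases(g: GeneModel) -> list[int]:
    lengths = [b - a + 1 for a, b in g.cds_intervals]
    order = lengths if g.strand == "+" else lengths[::-1]
    phases, consumed = [], 0
    for ln in order:
        phases.append((3 - consumed % 3) % 3)
        consumed += ln
    return phases if g.strand == "+" else phases[::-1]
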