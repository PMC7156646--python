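"""Annotation parsing, filtering, and isoform-specific region discovery.

A gene model here is deliberately minimal: genes own transcript isoforms,
each isoform owns a genomic exon chain and exactly one annotated ORF given
as a transcript-local half-open interval that *includes* the stop codon.
All transcript-local sequences are stored 5'->3' on the coding strand;
minus-strand exons are reverse-complemented once, at load time.

Isoform-specific regions come in two kinds:

``sequence``
    maximal ORF sub-intervals whose genomic bases are exonic in no other
    ORF of the same gene (unique nucleotide sequence among the gene's
    isoforms).
``orf_frame``
    a superset of the above: additionally, stretches shared at the
    nucleotide level but read in a different codon frame by every other
    isoform that contains them, so the amino-acid product is unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import DataError

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Ensembl biotypes excluded by default: anything containing "pseudogene".
DEFAULT_PSEUDOGENE_MARKER = "pseudogene"


@dataclass
class SpecificRegion:
    """A transcript-local interval unique to one isoform of a gene."""

    transcript_id: str
    kind: str  # "sequence" | "orf_frame"
    start: int  # transcript-local, 0-based half-open
    end: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class IsoformModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic 0-based half-open, sorted by start
    orf: tuple[int, int] | None  # transcript-local half-open, stop included
    cdna: str
    biotype: str = "protein_coding"

    _gpos: np.ndarray | None = field(default=None, repr=False, compare=False)
    _gindex: dict | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.cdna)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def orf_seq(self) -> str:
        s, e = self.orf
        return self.cdna[s:e]

    @property
    def protein(self) -> str:
        """Amino-acid sequence of the ORF, stop codon excluded."""
        seq = self.orf_seq
        if seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        return str(Seq(seq).translate())

    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinate of every transcript position, 5'->3'."""
        if self._gpos is None:
            parts = []
            if self.strand == "+":
                for s, e in self.exons:
                    parts.append(np.arange(s, e, dtype=np.int64))
            else:
                for s, e in reversed(self.exons):
                    parts.append(np.arange(e - 1, s - 1, -1, dtype=np.int64))
            self._gpos = np.concatenate(parts) if parts else np.empty(0, np.int64)
        return self._gpos

    def genomic_index(self) -> dict:
        """Map genomic coordinate -> transcript position."""
        if self._gindex is None:
            self._gindex = {int(g): i for i, g in enumerate(self.genomic_positions())}
        return self._gindex

    def transcript_to_genomic(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project a transcript-local half-open interval onto genomic blocks."""
        gp = self.genomic_positions()[start:end]
        if len(gp) == 0:
            return []
        blocks = []
        lo = hi = int(gp[0])
        step = 1 if self.strand == "+" else -1
        for g in gp[1:]:
            g = int(g)
            if g == hi + step:
                hi = g
            else:
                blocks.append((min(lo, hi), max(lo, hi) + 1))
                lo = hi = g
        blocks.append((min(lo, hi), max(lo, hi) + 1))
        blocks.sort()
        return blocks

    def orf_genomic_blocks(self) -> list[tuple[int, int]]:
        if self.orf is None:
            return []
        return self.transcript_to_genomic(*self.orf)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    isoforms: list[IsoformModel] = field(default_factory=list)

    def __post_init__(self):
        for iso in self.isoforms:
            if iso.strand != self.strand or iso.chrom != self.chrom:
                raise DataError(
                    f"isoform {iso.transcript_id} disagrees with gene "
                    f"{self.gene_id} on chromosome/strand"
                )


@dataclass
class AnnotationSet:
    genes: dict[str, GeneModel]
    assembly_tag: str = ""
    filters_applied: list[str] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)

    def isoforms(self):
        for gene in self.genes.values():
            yield from gene.isoforms

    def isoform(self, transcript_id: str) -> IsoformModel:
        iso = self.isoform_index().get(transcript_id)
        if iso is None:
            raise DataError(f"unknown transcript {transcript_id!r}")
        return iso

    def isoform_index(self) -> dict[str, IsoformModel]:
        if not hasattr(self, "_index") or self._index is None:
            self._index = {i.transcript_id: i for i in self.isoforms()}
        return self._index

    @property
    def n_isoforms(self) -> int:
        return sum(len(g.isoforms) for g in self.genes.values())


# ---------------------------------------------------------------------------
# GTF + FASTA loading


def _parse_gtf(gtf: Path):
    """Collect transcript skeletons from an Ensembl-dialect GTF."""
    import gffutils

    db = gffutils.create_db(
        str(gtf),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def attr(feat, *names, default=None):
        for n in names:
            if n in feat.attributes:
                return feat.attributes[n][0]
        return default

    transcripts = []
    for t in db.features_of_type("transcript"):
        tid = attr(t, "transcript_id")
        gid = attr(t, "gene_id")
        biotype = attr(
            t, "transcript_biotype", "gene_biotype", "biotype",
            default="protein_coding",
        )
        exons = [
            (f.start - 1, f.end)
            for f in db.children(t, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(t, featuretype="CDS", order_by="start")
        ]
        stops = [
            (f.start - 1, f.end)
            for f in db.children(t, featuretype="stop_codon", order_by="start")
        ]
        transcripts.append(
            dict(
                transcript_id=tid,
                gene_id=gid,
                chrom=t.seqid,
                strand=t.strand,
                biotype=biotype,
                exons=exons,
                cds=sorted(cds + stops),
            )
        )
    return transcripts


def _orf_transcript_interval(iso: IsoformModel, cds_blocks) -> tuple[int, int] | None:
    """Map genomic CDS blocks to one contiguous transcript-local interval."""
    if not cds_blocks:
        return None
    index = iso.genomic_index()
    length = sum(e - s for s, e in cds_blocks)
    if iso.strand == "+":
        first = cds_blocks[0][0]
    else:
        first = cds_blocks[-1][1] - 1
    start = index.get(first)
    if start is None:
        return None
    return (start, start + length)


def _check_exons(exons: list[tuple[int, int]], tid: str) -> None:
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 > s2:
            raise DataError(f"overlapping exons in transcript {tid}")


def load_annotation(
    gtf,
    cdna_fasta,
    min_tx_len: int = 200,
    pseudogene_biotypes: set[str] | None = None,
    require_start_stop: bool = True,
    assembly_tag: str = "",
) -> AnnotationSet:
    """Load and filter a transcript annotation.

    Three filters are applied, mirroring standard annotation cleanup for
    translation analysis: pseudogene biotypes are removed, isoforms shorter
    than ``min_tx_len`` nucleotides are removed, and isoforms whose ORF is
    incomplete (length not divisible by three, or missing a start/stop
    codon when ``require_start_stop``) are removed. Removal counts per rule
    are kept on the returned :class:`AnnotationSet` and logged.

    Raises :class:`DataError` when a retained transcript has no sequence
    in ``cdna_fasta`` or when exon bookkeeping is inconsistent.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cdna_fasta), "fasta")}
    skeletons = _parse_gtf(Path(gtf))

    dropped = {"pseudogene": 0, "short": 0, "incomplete": 0}
    genes: dict[str, GeneModel] = {}

    for sk in skeletons:
        tid = sk["transcript_id"]
        biotype = sk["biotype"]
        if pseudogene_biotypes is not None:
            is_pseudo = biotype in pseudogene_biotypes
        else:
            is_pseudo = DEFAULT_PSEUDOGENE_MARKER in biotype
        if is_pseudo:
            dropped["pseudogene"] += 1
            continue

        exons = sorted(sk["exons"])
        _check_exons(exons, tid)
        exonic_len = sum(e - s for s, e in exons)
        if exonic_len < min_tx_len:
            dropped["short"] += 1
            continue

        if tid not in seqs:
            raise DataError(f"no cDNA sequence for retained transcript {tid!r}")
        cdna = seqs[tid]
        if len(cdna) != exonic_len:
            raise DataError(
                f"transcript {tid}: cDNA length {len(cdna)} != exonic length {exonic_len}"
            )

        iso = IsoformModel(
            transcript_id=tid,
            gene_id=sk["gene_id"],
            chrom=sk["chrom"],
            strand=sk["strand"],
            exons=exons,
            orf=None,
            cdna=cdna,
            biotype=biotype,
        )
        orf = _orf_transcript_interval(iso, sk["cds"])
        if orf is None:
            dropped["incomplete"] += 1
            logger.warning("transcript %s has no usable CDS; dropped as incomplete", tid)
            continue
        s, e = orf
        orf_seq = cdna[s:e]
        complete = (e - s) % 3 == 0
        if complete and require_start_stop:
            complete = orf_seq.startswith("ATG") and orf_seq[-3:] in STOP_CODONS
        if not complete:
            dropped["incomplete"] += 1
            logger.warning("transcript %s has an incomplete ORF; dropped", tid)
            continue
        iso.orf = orf

        gene = genes.get(sk["gene_id"])
        if gene is None:
            gene = genes[sk["gene_id"]] = GeneModel(
                gene_id=sk["gene_id"], chrom=sk["chrom"], strand=sk["strand"]
            )
        gene.isoforms.append(iso)

    for rule, n in dropped.items():
        if n:
            logger.info("annotation filter %r removed %d isoform(s)", rule, n)

    return AnnotationSet(
        genes=genes,
        assembly_tag=assembly_tag,
        filters_applied=["pseudogene", "short", "incomplete"],
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Serialization


def write_gtf(annotation: AnnotationSet, path) -> None:
    """Write the annotation back out as an Ensembl-dialect GTF."""
    lines = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        g_start = min(s for iso in gene.isoforms for s, _ in iso.exons)
        g_end = max(e for iso in gene.isoforms for _, e in iso.exons)

        def fmt(feature, s, e, tid=None, biotype="protein_coding"):
            attrs = f'gene_id "{gid}"; gene_biotype "{biotype}";'
            if tid is not None:
                attrs += f' transcript_id "{tid}"; transcript_biotype "{biotype}";'
            return (
                f"{gene.chrom}\tisoribo\t{feature}\t{s + 1}\t{e}\t.\t"
                f"{gene.strand}\t.\t{attrs}"
            )

        lines.append(fmt("gene", g_start, g_end, biotype=gene.isoforms[0].biotype))
        for iso in sorted(gene.isoforms, key=lambda i: i.transcript_id):
            t_start = iso.exons[0][0]
            t_end = iso.exons[-1][1]
            lines.append(fmt("transcript", t_start, t_end, iso.transcript_id, iso.biotype))
            for s, e in iso.exons:
                lines.append(fmt("exon", s, e, iso.transcript_id, iso.biotype))
            if iso.orf is not None:
                o0, o1 = iso.orf
                for s, e in iso.transcript_to_genomic(o0, o1 - 3):
                    lines.append(fmt("CDS", s, e, iso.transcript_id, iso.biotype))
                for s, e in iso.transcript_to_genomic(o1 - 3, o1):
                    lines.append(fmt("stop_codon", s, e, iso.transcript_id, iso.biotype))
    Path(path).write_text("\n".join(lines) + "\n")


def write_cdna_fasta(annotation: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            for iso in sorted(annotation.genes[gid].isoforms, key=lambda i: i.transcript_id):
                fh.write(f">{iso.transcript_id}\n{iso.cdna}\n")


def write_protein_fasta(annotation: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            for iso in sorted(annotation.genes[gid].isoforms, key=lambda i: i.transcript_id):
                if iso.orf is not None:
                    fh.write(f">{iso.transcript_id}\n{iso.protein}\n")


def write_regions_tsv(regions: list[SpecificRegion], path) -> None:
    """BED-like TSV in transcript space: transcript_id, start, end, kind."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tstart\tend\tkind\n")
        for r in regions:
            fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.kind}\n")


# ---------------------------------------------------------------------------
# Isoform-specific regions


def _mask_to_regions(mask: np.ndarray, offset: int, tid: str, kind: str):
    regions = []
    if not mask.any():
        return regions
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    for s, e in zip(starts, ends):
        regions.append(SpecificRegion(tid, kind, offset + int(s), offset + int(e)))
    return regions


def find_isoform_specific_sequences(gene: GeneModel) -> list[SpecificRegion]:
    """Maximal ORF intervals whose genomic bases no sibling ORF contains.

    A single-isoform gene yields its whole ORF as one region (uniqueness is
    vacuous); identical exon structures yield no regions.
    """
    regions: list[SpecificRegion] = []
    isoforms = [i for i in gene.isoforms if i.orf is not None]
    orf_positions = {
        iso.transcript_id: set(
            map(int, iso.genomic_positions()[iso.orf[0]: iso.orf[1]])
        )
        for iso in isoforms
    }
    for iso in isoforms:
        others: set[int] = set()
        for other in isoforms:
            if other.transcript_id != iso.transcript_id:
                others |= orf_positions[other.transcript_id]
        o0, o1 = iso.orf
        gp = iso.genomic_positions()[o0:o1]
        mask = np.fromiter((int(g) not in others for g in gp), bool, len(gp))
        regions.extend(_mask_to_regions(mask, o0, iso.transcript_id, "sequence"))
    return regions


def find_isoform_specific_orf_regions(gene: GeneModel) -> list[SpecificRegion]:
    """Regions translating to a unique amino-acid product within the gene.

    A position is specific when every other isoform either lacks the
    genomic base in its ORF (sequence-specific) or reads it in a shifted
    codon frame (frame-specific). The output therefore contains the
    ``sequence``-kind regions as sub-intervals.
    """
    regions: list[SpecificRegion] = []
    isoforms = [i for i in gene.isoforms if i.orf is not None]
    phase_maps = {}
    for iso in isoforms:
        o0, o1 = iso.orf
        gp = iso.genomic_positions()[o0:o1]
        phase_maps[iso.transcript_id] = {
            int(g): (i % 3) for i, g in enumerate(gp)
        }
    for iso in isoforms:
        o0, o1 = iso.orf
        gp = iso.genomic_positions()[o0:o1]
        mask = np.empty(len(gp), bool)
        others = [
            phase_maps[o.transcript_id]
            for o in isoforms
            if o.transcript_id != iso.transcript_id
        ]
        for i, g in enumerate(map(int, gp)):
            phase = i % 3
            specific = True
            for pm in others:
                other_phase = pm.get(g)
                if other_phase is not None and other_phase == phase:
                    specific = False
                    break
            mask[i] = specific
        regions.extend(_mask_to_regions(mask, o0, iso.transcript_id, "orf_frame"))
    return regions
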