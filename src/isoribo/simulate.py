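"""Synthetic annotation, footprint reads, and condition designs.

Every stage of the pipeline is testable without downloads: this module
plants a toy annotation whose genes realize all seven splicing-event
types (including microexons at and below the defining length boundaries),
ribosome-footprint reads whose P-sites carry configurable frame bias and
coverage evenness, and replicated two-condition abundance designs with
known inclusion changes. The seed fully determines every output.

Translated ORFs emit reads whose P-sites fall in frame 0 with probability
``frame0_bias`` at codon positions drawn from a high-concentration
Dirichlet (even coverage); untranslated ORFs emit frame-uniform, bursty
(low-concentration Dirichlet) coverage. Read 5' ends are back-shifted
from the P-site by the planted per-length offsets.

Coding sequence bodies are built from the {A, C, G} alphabet, so no stop
codon or spurious ATG can occur anywhere except where planted; a short
pad carrying stop codons in all three frames terminates every reading
frame, which keeps every isoform's ORF complete even across planted
frameshifts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, IsoformModel, STOP_CODONS
from .errors import DataError
from .quantify import AbundanceTable, AlignmentRecord

CODING_ALPHABET = np.array(list("ACG"))
#: stop codons in all three frames: TAA@0, TAA@4 (frame 1), TAA@8 (frame 2)
STOP_PAD = "TAAATAAATAA"

EVENT_KINDS = ("SE", "A3", "A5", "MX", "RI", "AF", "AL",
               "SE_micro", "SE_short", "SE_shift")

CONDITIONS = ("c1", "c2")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 20
    isoforms_per_gene: int = 2  # 1 or 2; 1 yields no splicing events
    fraction_single: float = 0.25  # share of single-isoform genes when 2
    force_single_translated: bool = True  # singles act as positive controls
    orf_codons: tuple[int, int] = (40, 120)  # head/tail size range, codons
    utr5: int = 50
    utr3: int = 30
    intron_len: int = 80
    translated_fraction: float = 0.5
    frame0_bias: float = 0.9
    alpha_translated: float = 50.0  # Dirichlet concentration: even coverage
    alpha_null: float = 0.15  # bursty coverage
    mean_reads_per_orf: float = 200.0
    read_length_probs: dict = field(
        default_factory=lambda: {28: 0.3, 29: 0.4, 30: 0.3}
    )
    psite_offsets: dict = field(default_factory=lambda: {28: 12, 29: 12, 30: 13})
    positional_noise: float = 0.0  # fraction of reads 5'-shifted by +-1 nt
    dpsi_effects: tuple = ()
    n_replicates: int = 3
    replicate_noise_sd: float = 0.01
    psi_range: tuple[float, float] = (0.2, 0.8)
    gene_abundance_lognorm: tuple[float, float] = (2.5, 0.8)
    ribo_mode: str = "proportional"  # proportional | coupled_noise | decoupled
    chrom: str = "chr1"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)


@dataclass
class PlantedEvent:
    gene_id: str
    kind: str
    alt_len: int | None
    inclusion_tx: str  # the isoform whose abundance share psi modulates


@dataclass
class GroundTruth:
    translated: dict[str, bool] = field(default_factory=dict)
    planted_events: list[PlantedEvent] = field(default_factory=list)
    offsets: dict[int, int] = field(default_factory=dict)
    control_ids: list[str] = field(default_factory=list)
    read_sources: dict[str, str] = field(default_factory=dict)
    reads_per_orf: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        data = {
            "translated": self.translated,
            "planted_events": [asdict(e) for e in self.planted_events],
            "offsets": {str(k): v for k, v in self.offsets.items()},
            "control_ids": self.control_ids,
            "reads_per_orf": self.reads_per_orf,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Gene construction


def _coding(rng, n_nt: int) -> str:
    return "".join(rng.choice(CODING_ALPHABET, size=n_nt))


def _scan_orf(cdna: str, start: int) -> tuple[int, int]:
    for i in range(start, len(cdna) - 2, 3):
        if cdna[i:i + 3] in STOP_CODONS:
            return (start, i + 3)
    raise DataError("no in-frame stop codon found in simulated transcript")


def _build_gene(gene_id, chrom, strand, cursor, segments, iso_exons, atg_segment,
                atg_offset, intron_gap):
    """Assemble a GeneModel from template-order segments.

    ``segments``: [(name, seq_or_len)] in transcript (5'->3') order; an
    int entry is a pure intron spacer. ``iso_exons``: transcript_id ->
    list of exons, each a tuple of segment names that must be adjacent in
    template order. ``atg_segment``/``atg_offset`` locate the start codon
    (per-isoform dict values allowed).
    """
    seqs = {}
    lengths = {}
    for name, payload in segments:
        if isinstance(payload, int):
            seqs[name] = None
            lengths[name] = payload
        else:
            seqs[name] = payload
            lengths[name] = len(payload)

    order = [name for name, _ in segments]
    coords = {}
    pos = cursor
    layout = order if strand == "+" else list(reversed(order))
    for name in layout:
        coords[name] = (pos, pos + lengths[name])
        pos += lengths[name]
    gene_end = pos

    template_index = {name: i for i, name in enumerate(order)}
    isoforms = []
    for tx in sorted(iso_exons):
        exon_defs = iso_exons[tx]
        exons = []
        cdna_parts = []
        for exon in exon_defs:
            idxs = [template_index[n] for n in exon]
            if idxs != list(range(idxs[0], idxs[0] + len(idxs))):
                raise DataError(f"non-adjacent segments in exon of {tx}")
            gstart = min(coords[n][0] for n in exon)
            gend = max(coords[n][1] for n in exon)
            exons.append((gstart, gend))
            for n in exon:
                if seqs[n] is None:
                    raise DataError(f"intron spacer {n} used as exon sequence")
                cdna_parts.append(seqs[n])
        cdna = "".join(cdna_parts)
        seg_of_tx = [n for exon in exon_defs for n in exon]
        atg_seg = atg_segment[tx] if isinstance(atg_segment, dict) else atg_segment
        atg_off = atg_offset[tx] if isinstance(atg_offset, dict) else atg_offset
        pre = 0
        for n in seg_of_tx:
            if n == atg_seg:
                break
            pre += lengths[n]
        else:
            raise DataError(f"ATG segment {atg_seg} missing from {tx}")
        orf = _scan_orf(cdna, pre + atg_off)
        isoforms.append(
            IsoformModel(
                transcript_id=tx,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=sorted(exons),
                orf=orf,
                cdna=cdna,
            )
        )
    gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, isoforms=isoforms)
    return gene, gene_end


def _gene_template(rng, cfg: SimulationConfig, gid: str, strand: str, kind: str | None):
    """Segment layout + isoform exon definitions for one gene."""
    u5 = _coding(rng, cfg.utr5)
    u3 = _coding(rng, cfg.utr3)
    lo, hi = cfg.orf_codons
    head = "ATG" + _coding(rng, 3 * int(rng.integers(lo, hi)))
    tail = _coding(rng, 3 * int(rng.integers(lo, hi))) + "TAA" + STOP_PAD
    gap = cfg.intron_len
    t1, t2 = f"{gid}T1", f"{gid}T2"

    if kind is None:  # single-isoform gene, two exons
        segs = [("E1", u5 + head), ("i1", gap), ("E3", tail + u3)]
        return segs, {t1: [("E1",), ("E3",)]}, "E1", cfg.utr5, None

    # When the gene sits on the minus strand, the genomic mirror of an A3
    # pattern is an A5 (and AF <-> AL); swap templates so the annotated
    # event type matches the requested kind.
    tpl = kind.split("_")[0]
    if strand == "-":
        tpl = {"A3": "A5", "A5": "A3", "AF": "AL", "AL": "AF"}.get(tpl, tpl)

    alt_len = None
    if tpl == "SE":
        if kind == "SE_micro":
            alt_len = 45
        elif kind == "SE_short":
            alt_len = 21
        elif kind == "SE_shift":
            alt_len = 3 * int(rng.integers(15, 25)) + 1
        else:
            alt_len = 3 * int(rng.integers(20, 35))
        segs = [("E1", u5 + head), ("i1", gap), ("ALT", _coding(rng, alt_len)),
                ("i2", gap), ("E3", tail + u3)]
        iso = {t1: [("E1",), ("ALT",), ("E3",)], t2: [("E1",), ("E3",)]}
        return segs, iso, "E1", cfg.utr5, alt_len

    if tpl == "A3":
        ext = 3 * int(rng.integers(8, 16))
        segs = [("E1", u5 + head), ("i1", gap), ("EXT", _coding(rng, ext)),
                ("E3", tail + u3)]
        iso = {t1: [("E1",), ("EXT", "E3")], t2: [("E1",), ("E3",)]}
        return segs, iso, "E1", cfg.utr5, ext

    if tpl == "A5":
        ext = 3 * int(rng.integers(8, 16))
        segs = [("E1", u5 + head), ("EXT", _coding(rng, ext)), ("i1", gap),
                ("E3", tail + u3)]
        iso = {t1: [("E1", "EXT"), ("E3",)], t2: [("E1",), ("E3",)]}
        return segs, iso, "E1", cfg.utr5, ext

    if tpl == "MX":
        la = 3 * int(rng.integers(20, 30))
        lb = 3 * int(rng.integers(20, 30))
        segs = [("E1", u5 + head), ("i1", gap), ("MA", _coding(rng, la)),
                ("i2", gap), ("MB", _coding(rng, lb)), ("i3", gap),
                ("E3", tail + u3)]
        iso = {t1: [("E1",), ("MA",), ("E3",)], t2: [("E1",), ("MB",), ("E3",)]}
        return segs, iso, "E1", cfg.utr5, la

    if tpl == "RI":
        ilen = 3 * int(rng.integers(20, 30))
        segs = [("E1", u5 + head), ("IR", _coding(rng, ilen)), ("E3", tail + u3)]
        iso = {t1: [("E1", "IR", "E3")], t2: [("E1",), ("E3",)]}
        return segs, iso, "E1", cfg.utr5, ilen

    if tpl == "AF":
        head2 = "ATG" + _coding(rng, 3 * int(rng.integers(lo, hi)))
        u5b = _coding(rng, cfg.utr5)
        segs = [("F1", u5 + head), ("i1", gap), ("F2", u5b + head2),
                ("i2", gap), ("E3", tail + u3)]
        iso = {t1: [("F1",), ("E3",)], t2: [("F2",), ("E3",)]}
        return segs, iso, {t1: "F1", t2: "F2"}, cfg.utr5, None

    if tpl == "AL":
        tail2 = _coding(rng, 3 * int(rng.integers(lo, hi))) + "TAA" + STOP_PAD
        u3b = _coding(rng, cfg.utr3)
        segs = [("E1", u5 + head), ("i1", gap), ("L1", tail + u3),
                ("i2", gap), ("L2", tail2 + u3b)]
        iso = {t1: [("E1",), ("L1",)], t2: [("E1",), ("L2",)]}
        return segs, iso, "E1", cfg.utr5, None

    raise DataError(f"unknown event kind {kind!r}")


def simulate_annotation(config: SimulationConfig) -> tuple[AnnotationSet, GroundTruth]:
    """Plant a toy annotation with all event types and known translation.

    Single-isoform genes double as positive controls for threshold
    calibration (forced translated when ``force_single_translated``),
    emulating single-ORF genes with independent protein evidence.
    Running twice with the same config is byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(offsets=dict(config.psite_offsets))
    genes: dict[str, GeneModel] = {}
    cursor = 1000
    multi_count = 0
    period = max(int(round(1.0 / config.fraction_single)), 1) if config.fraction_single > 0 else 0

    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        if config.isoforms_per_gene <= 1:
            single = True
        else:
            single = period > 0 and (i % period) == (period - 1)
        kind = None
        if not single:
            kind = EVENT_KINDS[multi_count % len(EVENT_KINDS)]
            multi_count += 1
        segs, iso_exons, atg_seg, atg_off, alt_len = _gene_template(
            rng, config, gid, strand, kind
        )
        gene, gene_end = _build_gene(
            gid, config.chrom, strand, cursor, segs, iso_exons, atg_seg, atg_off,
            config.intron_len,
        )
        cursor = gene_end + 500
        genes[gid] = gene
        if kind is not None:
            truth.planted_events.append(PlantedEvent(gid, kind, alt_len, f"{gid}T1"))
        for iso in gene.isoforms:
            if single and config.force_single_translated and config.isoforms_per_gene > 1:
                translated = True
                truth.control_ids.append(iso.transcript_id)
            else:
                translated = bool(rng.random() < config.translated_fraction)
            truth.translated[iso.transcript_id] = translated

    ann = AnnotationSet(
        genes=genes, assembly_tag=f"isoribo-sim", filters_applied=[]
    )
    return ann, truth


def random_gene(rng, gene_id: str, n_isoforms: int, chrom: str = "chr1",
                strand: str = "+", cursor: int = 1000) -> GeneModel:
    """A random multi-isoform gene for oracle-style testing.

    Builds a template with optional middle exons and optional splice-site
    extensions, then draws ``n_isoforms`` distinct exon-chain subsets, so
    the resulting gene realizes a random mix of SE/A3/A5/MX-like
    structures with complete ORFs.
    """
    cfg = SimulationConfig(orf_codons=(20, 40))
    u5 = _coding(rng, cfg.utr5)
    head = "ATG" + _coding(rng, 3 * int(rng.integers(20, 40)))
    tail = _coding(rng, 3 * int(rng.integers(20, 40))) + "TAA" + STOP_PAD
    u3 = _coding(rng, cfg.utr3)
    gap = cfg.intron_len

    n_mid = int(rng.integers(1, 4))
    segs = [("E1", u5 + head), ("X1", _coding(rng, int(rng.integers(15, 40))))]
    mids = []
    for j in range(n_mid):
        segs.append((f"i{j}a", gap))
        name = f"M{j}"
        length = int(rng.choice([21, 45, 60, 61, 90]))
        segs.append((name, _coding(rng, length)))
        mids.append(name)
    segs.append(("iz", gap))
    segs.append(("X3", _coding(rng, int(rng.integers(15, 40)))))
    segs.append(("E3", tail + u3))

    chains = {}
    attempts = 0
    while len(chains) < n_isoforms and attempts < 50 * n_isoforms:
        attempts += 1
        use_ext5 = bool(rng.random() < 0.4)  # extend E1 3' end (A5-like)
        use_ext3 = bool(rng.random() < 0.4)  # extend E3 5' end (A3-like)
        included = [m for m in mids if rng.random() < 0.5]
        exons = []
        exons.append(("E1", "X1") if use_ext5 else ("E1",))
        for m in included:
            exons.append((m,))
        exons.append(("X3", "E3") if use_ext3 else ("E3",))
        key = tuple(map(tuple, exons))
        if key not in chains:
            chains[key] = None
    iso_exons = {
        f"{gene_id}T{k + 1}": list(map(tuple, key))
        for k, key in enumerate(sorted(chains))
    }
    gene, _ = _build_gene(
        gene_id, chrom, strand, cursor, segs, iso_exons, "E1", cfg.utr5, gap
    )
    return gene


# ---------------------------------------------------------------------------
# Footprint read simulation


def _pair_position_map(src: IsoformModel, dst: IsoformModel) -> np.ndarray:
    """dst transcript position of each src position (-1 where absent)."""
    index = dst.genomic_index()
    gp = src.genomic_positions()
    out = np.full(len(gp), -1, dtype=np.int64)
    for i, g in enumerate(map(int, gp)):
        j = index.get(g)
        if j is not None:
            out[i] = j
    return out


def simulate_ribo_reads(
    annotation: AnnotationSet,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample: str = "s1",
    expected_reads: dict[str, float] | None = None,
) -> list[AlignmentRecord]:
    """Emit footprint alignment records with planted signal properties.

    Reads from translated ORFs carry frame-0 bias and even coverage;
    untranslated ORFs emit frame-uniform bursty coverage. Multi-mapping
    records are emitted for every sibling isoform sharing the read's
    genomic bases contiguously. Per-ORF emitted read counts are recorded
    in ``truth.reads_per_orf[sample]``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lengths = np.array(sorted(config.read_length_probs), dtype=np.int64)
    probs = np.array([config.read_length_probs[int(l)] for l in lengths], float)
    probs = probs / probs.sum()
    offsets = {int(l): int(config.psite_offsets.get(int(l), 12)) for l in lengths}
    off_arr = np.array([offsets[int(l)] for l in lengths], dtype=np.int64)

    records: list[AlignmentRecord] = []
    counts_out: dict[str, int] = {}
    read_counter = 0

    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        pair_maps = {}
        if len(gene.isoforms) > 1:
            for a in gene.isoforms:
                for b in gene.isoforms:
                    if a.transcript_id != b.transcript_id:
                        pair_maps[(a.transcript_id, b.transcript_id)] = (
                            _pair_position_map(a, b)
                        )
        for iso in sorted(gene.isoforms, key=lambda i: i.transcript_id):
            tx = iso.transcript_id
            mean = (
                expected_reads.get(tx, 0.0)
                if expected_reads is not None
                else config.mean_reads_per_orf
            )
            n = int(rng.poisson(mean))
            counts_out[tx] = n
            if n == 0 or iso.orf is None:
                continue
            o0, o1 = iso.orf
            n_codons = (o1 - o0) // 3 - 1  # coding codons, stop excluded
            translated = truth.translated.get(tx, False)
            alpha = config.alpha_translated if translated else config.alpha_null
            bias = config.frame0_bias if translated else 1.0 / 3.0
            codon_p = rng.dirichlet(np.full(n_codons, alpha))
            codons = rng.choice(n_codons, size=n, p=codon_p)
            u = rng.random(n)
            frames = np.where(
                u < bias, 0, np.where(u < bias + (1 - bias) / 2, 1, 2)
            ).astype(np.int64)
            li = rng.choice(len(lengths), size=n, p=probs)
            rlen = lengths[li]
            five = o0 + 3 * codons + frames - off_arr[li]
            if config.positional_noise > 0:
                hit = rng.random(n) < config.positional_noise
                shift = rng.choice([-1, 1], size=n)
                five = five + np.where(hit, shift, 0)
            valid = (five >= 0) & (five + rlen <= len(iso.cdna))
            five, rlen = five[valid], rlen[valid]
            sibs = [
                (other.transcript_id, pair_maps[(tx, other.transcript_id)])
                for other in sorted(gene.isoforms, key=lambda i: i.transcript_id)
                if other.transcript_id != tx
            ]
            for f, L in zip(five.tolist(), rlen.tolist()):
                rid = f"{sample}:r{read_counter}"
                read_counter += 1
                records.append(AlignmentRecord(rid, tx, f, L))
                truth.read_sources[rid] = tx
                for other_tx, pmap in sibs:
                    j0 = pmap[f]
                    j1 = pmap[f + L - 1]
                    if j0 >= 0 and j1 == j0 + L - 1:
                        records.append(AlignmentRecord(rid, other_tx, int(j0), L))
    truth.reads_per_orf[sample] = counts_out
    return records


# ---------------------------------------------------------------------------
# Abundance / condition designs


def _table_from_rates(rates: pd.Series, eff_len: pd.Series, unit: str,
                      sample: str) -> AbundanceTable:
    total = rates.sum()
    vals = 1e6 * rates / total if total > 0 else rates * 0.0
    return AbundanceTable(
        unit=unit,
        values=pd.DataFrame({sample: vals}),
        effective_lengths=eff_len,
        est_counts=pd.DataFrame({sample: rates * eff_len}),
    )


def _effective_lengths(annotation: AnnotationSet, config: SimulationConfig) -> pd.Series:
    mrl = sum(l * p for l, p in config.read_length_probs.items())
    return pd.Series(
        {
            iso.transcript_id: max(len(iso.cdna) - (mrl - 1.0), 1.0)
            for iso in annotation.isoforms()
        }
    ).sort_index()


def simulate_rna_quant(
    annotation: AnnotationSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample: str = "s1",
) -> AbundanceTable:
    """Independent lognormal isoform abundances, normalized to TPM."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    mu, sigma = config.gene_abundance_lognorm
    ids = sorted(i.transcript_id for i in annotation.isoforms())
    rates = pd.Series(rng.lognormal(mu, sigma, size=len(ids)), index=ids)
    return _table_from_rates(rates, _effective_lengths(annotation, config), "TPM", sample)


@dataclass
class ConditionDesign:
    rna: dict[str, AbundanceTable]  # condition -> multi-replicate TPM table
    ribo: dict[str, AbundanceTable]  # condition -> multi-replicate OPM table
    events: list
    true_dpsi: pd.Series  # per event id, inclusion-form sign convention
    reads: dict[tuple[str, str], list[AlignmentRecord]] | None = None


def simulate_condition_design(
    annotation: AnnotationSet,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    emit_reads: bool = False,
) -> ConditionDesign:
    """Two-condition, replicated design with planted inclusion changes.

    The first ``len(config.dpsi_effects)`` multi-isoform genes (sorted by
    id) change their inclusion-isoform share by the planted amounts
    between conditions; all other events are null. Replicate noise is
    Gaussian on the inclusion share. Ribosome-space abundances follow
    ``config.ribo_mode``: strictly ``proportional`` to RNA (PSI == RA per
    replicate), ``coupled_noise`` (same means, independent replicate
    noise), or ``decoupled`` (no inclusion change in ribosome space).
    """
    from .events import generate_events, flag_microexons

    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    events = flag_microexons(generate_events(annotation))
    eff_len = _effective_lengths(annotation, config)
    mu, sigma = config.gene_abundance_lognorm
    lo, hi = config.psi_range
    sd = config.replicate_noise_sd

    gene_ids = sorted(annotation.genes)
    multi = [g for g in gene_ids if len(annotation.genes[g].isoforms) >= 2]
    effects = {g: 0.0 for g in multi}
    for g, d in zip(multi, config.dpsi_effects):
        effects[g] = float(d)

    totals = {g: float(rng.lognormal(mu, sigma)) for g in gene_ids}
    psi_base = {}
    for g in multi:
        d = effects[g]
        lo_g = max(lo, lo - d)
        hi_g = min(hi, hi - d)
        psi_base[g] = float(rng.uniform(lo_g, hi_g))

    def share_rates(psi_of_gene: dict[str, float]) -> pd.Series:
        rates = {}
        for g in gene_ids:
            isos = sorted(i.transcript_id for i in annotation.genes[g].isoforms)
            if len(isos) == 1:
                rates[isos[0]] = totals[g]
            else:
                p = psi_of_gene[g]
                rates[isos[0]] = p * totals[g]
                for other in isos[1:]:
                    rates[other] = (1.0 - p) * totals[g] / (len(isos) - 1)
        return pd.Series(rates).sort_index()

    rna: dict[str, AbundanceTable] = {}
    ribo: dict[str, AbundanceTable] = {}
    reads: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for ci, cond in enumerate(CONDITIONS):
        rna_cols = []
        ribo_cols = []
        for r in range(config.n_replicates):
            name = f"{cond}_r{r + 1}"
            psi_rep = {
                g: float(np.clip(psi_base[g] + (effects[g] if ci == 1 else 0.0)
                                 + rng.normal(0.0, sd), 0.0, 1.0))
                for g in multi
            }
            rates = share_rates(psi_rep)
            rna_cols.append(_table_from_rates(rates, eff_len, "TPM", name))
            if config.ribo_mode == "proportional":
                ribo_rates = rates
            elif config.ribo_mode == "coupled_noise":
                psi_ribo = {
                    g: float(np.clip(psi_base[g] + (effects[g] if ci == 1 else 0.0)
                                     + rng.normal(0.0, sd), 0.0, 1.0))
                    for g in multi
                }
                ribo_rates = share_rates(psi_ribo)
            elif config.ribo_mode == "decoupled":
                psi_ribo = {
                    g: float(np.clip(psi_base[g] + rng.normal(0.0, sd), 0.0, 1.0))
                    for g in multi
                }
                ribo_rates = share_rates(psi_ribo)
            else:
                raise DataError(f"unknown ribo_mode {config.ribo_mode!r}")
            ribo_cols.append(_table_from_rates(ribo_rates, eff_len, "OPM", name))
            if emit_reads:
                depth = config.mean_reads_per_orf * max(len(eff_len), 1)
                expected = (ribo_rates / max(ribo_rates.sum(), 1e-12) * depth).to_dict()
                reads[(cond, name)] = simulate_ribo_reads(
                    annotation, truth, config, rng=rng, sample=name,
                    expected_reads=expected,
                )
        from .quantify import combine_tables

        rna[cond] = combine_tables(rna_cols)
        ribo[cond] = combine_tables(ribo_cols)

    incl_of_t1 = {}
    for ev in events:
        isos = sorted(
            i.transcript_id for i in annotation.genes[ev.gene_id].isoforms
        )
        t1 = isos[0]
        incl_of_t1[ev.event_id] = t1 in ev.inclusion

    true_dpsi = pd.Series(
        {
            ev.event_id: (effects.get(ev.gene_id, 0.0)
                          * (1.0 if incl_of_t1[ev.event_id] else -1.0))
            for ev in events
        }
    ).sort_index()

    return ConditionDesign(
        rna=rna, ribo=ribo, events=events, true_dpsi=true_dpsi,
        reads=reads if emit_reads else None,
    )
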