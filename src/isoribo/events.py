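"""Alternative-splicing events, PSI/RA, and differential inclusion.

Events of the seven classical types (SE, A3, A5, MX, RI, AF, AL) are
enumerated from the exon chains of a gene's retained protein-coding
isoforms, following the ioe convention of event files: every event names
the isoforms whose structure realizes the inclusion form and the full set
of isoforms relevant to the event, and its inclusion value in any
abundance space is

    inclusion = sum(abundance over inclusion isoforms)
                / sum(abundance over all event isoforms)

With TPM abundances this is the familiar percent-spliced-in (PSI); with
OPM (ribosome-space) abundances it is the event's relative abundance (RA)
in translation. Only events whose alternative region overlaps an
annotated ORF are kept.

Differential inclusion between two replicated conditions is tested
empirically: the observed between-condition difference of mean inclusion
is compared against the distribution of between-replicate differences
pooled within conditions from events of similar total abundance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "A3", "A5", "MX", "RI", "AF", "AL")

MICROEXON_MAX_NT = 51  # exons of this length or less are microexons
SHORT_MICROEXON_NT = 28  # "short" microexons are strictly below this


@dataclass
class SplicingEvent:
    event_id: str
    gene_id: str
    etype: str
    chrom: str
    strand: str
    inclusion: frozenset
    total: frozenset
    region: tuple[int, int]  # genomic differential region, 0-based half-open
    alt_exon: tuple[int, int] | None = None  # the alternative exon (SE/MX)
    anchors: tuple[int, int] | None = None  # flanking junction anchors (e1, s3)
    microexon: bool = False
    short_microexon: bool = False

    @property
    def alt_exon_len(self) -> int | None:
        if self.alt_exon is None:
            return None
        return self.alt_exon[1] - self.alt_exon[0]

    @property
    def exclusion(self) -> frozenset:
        return self.total - self.inclusion


def _junctions(chain):
    return {(chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)}


def _j(e, s):  # junction in 1-based display form "end-start"
    return f"{e}-{s + 1}"


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


class _GeneIndex:
    """Per-gene lookup tables shared by the event detectors."""

    def __init__(self, gene):
        self.gene = gene
        self.chains = {
            i.transcript_id: list(i.exons) for i in gene.isoforms if len(i.exons) >= 1
        }
        self.junc = {t: _junctions(c) for t, c in self.chains.items()}
        self.exonset = {t: set(map(tuple, c)) for t, c in self.chains.items()}
        self.orf_blocks = {
            i.transcript_id: i.orf_genomic_blocks() for i in gene.isoforms
        }

    def with_junction(self, j):
        return frozenset(t for t, js in self.junc.items() if j in js)

    def with_junctions(self, *js):
        out = None
        for j in js:
            s = self.with_junction(j)
            out = s if out is None else out & s
        return out or frozenset()

    def with_exon(self, exon):
        return frozenset(t for t, es in self.exonset.items() if tuple(exon) in es)

    def orf_overlap(self, region, transcripts) -> bool:
        for t in transcripts:
            for blk in self.orf_blocks.get(t, ()):
                if _overlaps(region, blk):
                    return True
        return False


def _emit(events, gene, etype, coords_str, inclusion, total, region,
          alt_exon=None, anchors=None):
    if not inclusion or inclusion == total or not (total - inclusion):
        return
    event_id = f"{gene.gene_id};{etype}:{gene.chrom}:{coords_str}:{gene.strand}"
    if event_id not in events:
        events[event_id] = SplicingEvent(
            event_id=event_id,
            gene_id=gene.gene_id,
            etype=etype,
            chrom=gene.chrom,
            strand=gene.strand,
            inclusion=frozenset(inclusion),
            total=frozenset(total),
            region=region,
            alt_exon=alt_exon,
            anchors=anchors,
        )


def _detect_se(gx: _GeneIndex, events):
    gene = gx.gene
    for t, chain in gx.chains.items():
        for i in range(1, len(chain) - 1):
            s2, e2 = chain[i]
            e1 = chain[i - 1][1]
            s3 = chain[i + 1][0]
            excl = gx.with_junction((e1, s3))
            if not excl:
                continue
            incl = gx.with_junctions((e1, s2), (e2, s3))
            _emit(
                events, gene, "SE",
                f"{_j(e1, s2)}:{_j(e2, s3)}",
                incl, incl | excl, (s2, e2),
                alt_exon=(s2, e2), anchors=(e1, s3),
            )


def _detect_a3_a5(gx: _GeneIndex, events):
    gene = gx.gene
    all_junc = set().union(*gx.junc.values()) if gx.junc else set()
    by_donor: dict[int, set[int]] = {}
    by_acceptor: dict[int, set[int]] = {}
    for d, a in all_junc:
        by_donor.setdefault(d, set()).add(a)
        by_acceptor.setdefault(a, set()).add(d)

    def exon_starting(a, txs):
        for t in txs:
            for exon in gx.chains[t]:
                if exon[0] == a:
                    return exon
        return None

    def exon_ending(d, txs):
        for t in txs:
            for exon in gx.chains[t]:
                if exon[1] == d:
                    return exon
        return None

    # shared donor, alternative acceptors -> A3 on '+', A5 on '-'
    for d, accs in by_donor.items():
        for a1, a2 in itertools.combinations(sorted(accs), 2):
            incl = gx.with_junction((d, a1))
            excl = gx.with_junction((d, a2))
            ex1 = exon_starting(a1, incl)
            ex2 = exon_starting(a2, excl)
            if ex1 is None or ex2 is None or not _overlaps(ex1, ex2):
                continue
            etype = "A3" if gene.strand == "+" else "A5"
            _emit(
                events, gene, etype,
                f"{_j(d, a1)}:{_j(d, a2)}",
                incl, incl | excl, (a1, a2), anchors=(d, a2),
            )

    # shared acceptor, alternative donors -> A5 on '+', A3 on '-'
    for a, donors in by_acceptor.items():
        for d1, d2 in itertools.combinations(sorted(donors), 2):
            incl = gx.with_junction((d2, a))  # longer exon carries the region
            excl = gx.with_junction((d1, a))
            ex1 = exon_ending(d1, excl)
            ex2 = exon_ending(d2, incl)
            if ex1 is None or ex2 is None or not _overlaps(ex1, ex2):
                continue
            etype = "A5" if gene.strand == "+" else "A3"
            _emit(
                events, gene, etype,
                f"{_j(d2, a)}:{_j(d1, a)}",
                incl, incl | excl, (d1, d2), anchors=(d1, a),
            )


def _detect_mx(gx: _GeneIndex, events):
    gene = gx.gene
    candidates = []  # (e1, s4, alt_exon, transcripts containing it internally)
    for t, chain in gx.chains.items():
        for i in range(1, len(chain) - 1):
            s2, e2 = chain[i]
            e1 = chain[i - 1][1]
            s4 = chain[i + 1][0]
            candidates.append((e1, s4, (s2, e2)))
    grouped: dict[tuple[int, int], set] = {}
    for e1, s4, exon in candidates:
        grouped.setdefault((e1, s4), set()).add(exon)
    for (e1, s4), exons in grouped.items():
        for exA, exB in itertools.combinations(sorted(exons), 2):
            if _overlaps(exA, exB):
                continue
            inclA = gx.with_junctions((e1, exA[0]), (exA[1], s4))
            inclB = gx.with_junctions((e1, exB[0]), (exB[1], s4))
            if not inclA or not inclB or (inclA & inclB):
                continue
            # mutually exclusive only if no isoform carries both exons
            both = {
                t for t in gx.chains
                if exA in gx.exonset[t] and exB in gx.exonset[t]
            }
            if both:
                continue
            _emit(
                events, gene, "MX",
                f"{_j(e1, exA[0])}:{_j(exA[1], s4)}:{_j(e1, exB[0])}:{_j(exB[1], s4)}",
                inclA, inclA | inclB, (exA[0], exB[1]),
                alt_exon=exA, anchors=(e1, s4),
            )


def _detect_ri(gx: _GeneIndex, events):
    gene = gx.gene
    for t, chain in gx.chains.items():
        for (s_up, e_up), (s_dn, e_dn) in zip(chain, chain[1:]):
            retained = (s_up, e_dn)
            incl = gx.with_exon(retained)
            if not incl:
                continue
            excl = frozenset(
                u for u in gx.chains
                if (e_up, s_dn) in gx.junc[u]
                and (s_up, e_up) in gx.exonset[u]
                and (s_dn, e_dn) in gx.exonset[u]
            )
            _emit(
                events, gene, "RI",
                f"{s_up + 1}:{_j(e_up, s_dn)}:{e_dn}",
                incl, incl | excl, (e_up, s_dn),
                alt_exon=None, anchors=(e_up, s_dn),
            )


def _detect_af_al(gx: _GeneIndex, events):
    gene = gx.gene
    multi = {t: c for t, c in gx.chains.items() if len(c) >= 2}

    # alternative genomically-first exons sharing their first junction target
    first = {t: c[0] for t, c in multi.items()}
    targets: dict[tuple, set] = {}
    for t, c in multi.items():
        targets.setdefault((c[0][1], c[1][0]), set())
    for exA, exB in itertools.combinations(sorted(set(first.values())), 2):
        if _overlaps(exA, exB):
            continue
        txA = {t for t, e in first.items() if e == exA}
        txB = {t for t, e in first.items() if e == exB}
        shared = {
            (multi[a][1][0], multi[b][1][0])
            for a in txA for b in txB
            if multi[a][1][0] == multi[b][1][0]
        }
        for x, _ in shared:
            inclA = frozenset(t for t in txA if multi[t][1][0] == x)
            inclB = frozenset(t for t in txB if multi[t][1][0] == x)
            etype = "AF" if gene.strand == "+" else "AL"
            _emit(
                events, gene, etype,
                f"{exA[0] + 1}:{_j(exA[1], x)}:{exB[0] + 1}:{_j(exB[1], x)}",
                inclA, inclA | inclB, (exA[0], exB[1]), alt_exon=exA,
            )

    # alternative genomically-last exons sharing their incoming junction source
    last = {t: c[-1] for t, c in multi.items()}
    for exA, exB in itertools.combinations(sorted(set(last.values())), 2):
        if _overlaps(exA, exB):
            continue
        txA = {t for t, e in last.items() if e == exA}
        txB = {t for t, e in last.items() if e == exB}
        shared = {
            (multi[a][-2][1], multi[b][-2][1])
            for a in txA for b in txB
            if multi[a][-2][1] == multi[b][-2][1]
        }
        for y, _ in shared:
            inclA = frozenset(t for t in txA if multi[t][-2][1] == y)
            inclB = frozenset(t for t in txB if multi[t][-2][1] == y)
            etype = "AL" if gene.strand == "+" else "AF"
            _emit(
                events, gene, etype,
                f"{_j(y, exA[0])}:{exA[1]}:{_j(y, exB[0])}:{exB[1]}",
                inclA, inclA | inclB, (exA[0], exB[1]), alt_exon=exA,
            )


def generate_events(annotation, require_orf_overlap: bool = True) -> list[SplicingEvent]:
    """Enumerate SE/A3/A5/MX/RI/AF/AL events from every gene's exon chains.

    Events whose differential genomic region does not overlap the
    annotated ORF of any involved isoform are discarded when
    ``require_orf_overlap`` (the default), restricting the catalogue to
    events with consequences for the coding sequence.
    """
    out: list[SplicingEvent] = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        if len(gene.isoforms) < 2:
            continue
        gx = _GeneIndex(gene)
        events: dict[str, SplicingEvent] = {}
        _detect_se(gx, events)
        _detect_a3_a5(gx, events)
        _detect_mx(gx, events)
        _detect_ri(gx, events)
        _detect_af_al(gx, events)
        for ev in events.values():
            if require_orf_overlap and not gx.orf_overlap(ev.region, ev.total):
                continue
            out.append(ev)
    out.sort(key=lambda e: e.event_id)
    return out


def flag_microexons(events: list[SplicingEvent]) -> list[SplicingEvent]:
    """Flag SE events whose alternative exon is a microexon.

    Microexons are alternative exons of 51 nt or less; the "short"
    subclass is strictly below 28 nt. Only SE-type events are flagged.
    """
    for ev in events:
        if ev.etype == "SE" and ev.alt_exon_len is not None:
            ev.microexon = ev.alt_exon_len <= MICROEXON_MAX_NT
            ev.short_microexon = ev.alt_exon_len < SHORT_MICROEXON_NT
        else:
            ev.microexon = False
            ev.short_microexon = False
    return events


# ---------------------------------------------------------------------------
# Inclusion quantification


def compute_event_inclusion(
    events: list[SplicingEvent],
    table,
    denom_min: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample inclusion values (PSI with TPM input, RA with OPM input).

    Returns ``(inclusion, denominator)`` DataFrames indexed by event id.
    Inclusion is NaN wherever the event's total abundance falls below
    ``denom_min`` in that sample. Isoforms absent from the abundance
    table contribute zero.
    """
    values = table if isinstance(table, pd.DataFrame) else table.values
    samples = list(values.columns)
    inc = np.full((len(events), len(samples)), np.nan)
    den = np.zeros((len(events), len(samples)))
    for i, ev in enumerate(events):
        incl = [t for t in ev.inclusion if t in values.index]
        tot = [t for t in ev.total if t in values.index]
        inc_sum = values.loc[incl].sum(axis=0) if incl else pd.Series(0.0, index=samples)
        tot_sum = values.loc[tot].sum(axis=0) if tot else pd.Series(0.0, index=samples)
        den[i] = tot_sum.to_numpy()
        ok = tot_sum.to_numpy() >= denom_min
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = inc_sum.to_numpy() / tot_sum.to_numpy()
        inc[i, ok] = ratio[ok]
    ids = [ev.event_id for ev in events]
    return (
        pd.DataFrame(inc, index=ids, columns=samples),
        pd.DataFrame(den, index=ids, columns=samples),
    )


# ---------------------------------------------------------------------------
# Differential inclusion


def _null_points(psi: pd.DataFrame, scale: float) -> pd.DataFrame:
    cols = list(psi.columns)
    diffs = []
    for a, b in itertools.combinations(cols, 2):
        diffs.append((psi[a] - psi[b]).abs() * scale)
    return pd.concat(diffs, axis=1)


def differential_inclusion(
    psi1: pd.DataFrame,
    psi2: pd.DataFrame,
    denom1: pd.DataFrame | None = None,
    denom2: pd.DataFrame | None = None,
    min_effect: float = 0.1,
    alpha: float = 0.05,
    n_bins: int = 10,
    min_per_bin: int = 100,
    scale_null: bool = True,
) -> pd.DataFrame:
    """Empirical test of differential inclusion between two conditions.

    The observed statistic per event is ``dpsi = mean(cond2) -
    mean(cond1)``. The null distribution pools absolute between-replicate
    differences within each condition across events of similar total
    abundance (``n_bins`` equal-width bins of log10 mean abundance,
    borrowing from neighboring bins below ``min_per_bin`` points). With
    ``scale_null`` the replicate differences are scaled by
    ``sqrt((1/n1 + 1/n2)/2)`` so the null matches the sampling law of a
    difference of replicate means under homoscedastic noise. The p-value
    is the fraction of null points at or above ``|dpsi|``; the
    ``significant`` flag additionally requires ``|dpsi| > min_effect``.

    Events with a missing inclusion value in any replicate are excluded
    (their count is available in ``DataFrame.attrs["n_excluded"]``).
    """
    if psi1.shape[1] < 2 or psi2.shape[1] < 2:
        raise DataError("differential testing needs >= 2 replicates per condition")
    events = psi1.index.intersection(psi2.index)
    psi1 = psi1.loc[events]
    psi2 = psi2.loc[events]
    complete = psi1.notna().all(axis=1) & psi2.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    psi1, psi2 = psi1[complete], psi2[complete]

    n1, n2 = psi1.shape[1], psi2.shape[1]
    scale = np.sqrt((1.0 / n1 + 1.0 / n2) / 2.0) if scale_null else 1.0
    null = pd.concat(
        [_null_points(psi1, scale), _null_points(psi2, scale)], axis=1
    )

    dpsi = psi2.mean(axis=1) - psi1.mean(axis=1)

    if denom1 is not None and denom2 is not None:
        denom = pd.concat(
            [denom1.loc[psi1.index], denom2.loc[psi2.index]], axis=1
        ).mean(axis=1)
    else:
        denom = pd.Series(1.0, index=psi1.index)
    log_ab = np.log10(denom.clip(lower=1e-9))

    if len(psi1) == 0:
        res = pd.DataFrame(columns=["dpsi", "pval", "significant"])
        res.attrs["n_excluded"] = n_excluded
        return res

    lo, hi = float(log_ab.min()), float(log_ab.max())
    if hi <= lo:
        bins = np.zeros(len(log_ab), int)
        n_bins = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(log_ab, edges[1:-1]), 0, n_bins - 1)

    null_by_bin = [
        np.sort(null.to_numpy()[bins == b].ravel()) for b in range(n_bins)
    ]

    pooled_cache: dict[int, np.ndarray] = {}

    def pooled(b: int) -> np.ndarray:
        if b not in pooled_cache:
            k = 0
            while True:
                sel = range(max(0, b - k), min(n_bins, b + k + 1))
                pool = np.concatenate([null_by_bin[j] for j in sel])
                if len(pool) >= min_per_bin or (b - k <= 0 and b + k + 1 >= n_bins):
                    break
                k += 1
            pooled_cache[b] = np.sort(pool)
        return pooled_cache[b]

    pvals = np.empty(len(dpsi))
    for i, (ev, d) in enumerate(dpsi.items()):
        pool = pooled(int(bins[i]))
        if len(pool) == 0:
            pvals[i] = 1.0
            continue
        # fraction of null >= |d|
        idx = np.searchsorted(pool, abs(d), side="left")
        pvals[i] = (len(pool) - idx) / len(pool)

    res = pd.DataFrame(
        {
            "dpsi": dpsi,
            "pval": pvals,
            "significant": (dpsi.abs() > min_effect) & (pvals < alpha),
        }
    )
    res.attrs["n_excluded"] = n_excluded
    return res


# ---------------------------------------------------------------------------
# Cross-species event matching


def match_conserved_events(
    events_a: list[SplicingEvent],
    events_b: list[SplicingEvent],
    coord_map: pd.DataFrame,
) -> tuple[list[tuple[SplicingEvent, SplicingEvent]], dict[str, int]]:
    """Pair events across species via a precomputed coordinate mapping.

    ``coord_map`` carries six columns (chrom_a, start_a, end_a, chrom_b,
    start_b, end_b; 1-based inclusive intervals). An event pair requires
    both alternative-exon boundaries to map onto the other event's
    boundaries; many-to-many candidates are dropped and counted.
    """
    cols = list(coord_map.columns[:6])
    mapping: dict[tuple, list[tuple]] = {}
    for row in coord_map.itertuples(index=False):
        key = (str(row[0]), int(row[1]), int(row[2]))
        mapping.setdefault(key, []).append((str(row[3]), int(row[4]), int(row[5])))

    by_exon_b: dict[tuple, list[SplicingEvent]] = {}
    for ev in events_b:
        if ev.alt_exon is None:
            continue
        key = (ev.chrom, ev.alt_exon[0] + 1, ev.alt_exon[1])
        by_exon_b.setdefault(key, []).append(ev)

    pairs = []
    counters = {"unmapped": 0, "ambiguous": 0, "no_partner": 0}
    for ev in events_a:
        if ev.alt_exon is None:
            continue
        key = (ev.chrom, ev.alt_exon[0] + 1, ev.alt_exon[1])
        targets = mapping.get(key)
        if not targets:
            counters["unmapped"] += 1
            continue
        if len(targets) > 1:
            counters["ambiguous"] += 1
            continue
        partners = by_exon_b.get(targets[0], [])
        if len(partners) == 1:
            pairs.append((ev, partners[0]))
        elif len(partners) > 1:
            counters["ambiguous"] += 1
        else:
            counters["no_partner"] += 1
    return pairs, counters


def direction_concordance(pairs, dpsi_a: pd.Series, dpsi_b: pd.Series) -> float:
    """Fraction of paired events whose inclusion changes share a sign."""
    signs = []
    for ev_a, ev_b in pairs:
        da = dpsi_a.get(ev_a.event_id)
        db = dpsi_b.get(ev_b.event_id)
        if da is None or db is None or np.isnan(da) or np.isnan(db):
            continue
        if da == 0 or db == 0:
            continue
        signs.append(np.sign(da) == np.sign(db))
    if not signs:
        return float("nan")
    return float(np.mean(signs))


# ---------------------------------------------------------------------------
# ioe-style serialization


def write_ioe(events: list[SplicingEvent], path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("seqname\tgene_id\tevent_id\talternative_transcripts\ttotal_transcripts\n")
        for ev in sorted(events, key=lambda e: e.event_id):
            fh.write(
                f"{ev.chrom}\t{ev.gene_id}\t{ev.event_id}\t"
                f"{','.join(sorted(ev.inclusion))}\t{','.join(sorted(ev.total))}\n"
            )


def read_ioe(path) -> list[SplicingEvent]:
    """Read an ioe-style event file (enough structure for PSI and flags)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    events = []
    for row in df.itertuples(index=False):
        event_id = str(row.event_id)
        gene_id, rest = event_id.split(";", 1)
        parts = rest.split(":")
        etype, strand = parts[0], parts[-1]
        chrom = parts[1]
        alt_exon = None
        region = (0, 0)
        anchors = None
        try:
            if etype == "SE":
                j1 = parts[2].split("-")
                j2 = parts[3].split("-")
                alt_exon = (int(j1[1]) - 1, int(j2[0]))
                region = alt_exon
                anchors = (int(j1[0]), int(j2[1]) - 1)
            elif etype in ("A3", "A5"):
                j1 = parts[2].split("-")
                j2 = parts[3].split("-")
                b1, b2 = int(j1[1]) - 1, int(j2[1]) - 1
                region = (min(b1, b2), max(b1, b2))
            elif etype == "RI":
                j = parts[3].split("-")
                region = (int(j[0]), int(j[1]) - 1)
        except (IndexError, ValueError):
            logger.warning("could not parse coordinates of %s", event_id)
        events.append(
            SplicingEvent(
                event_id=event_id,
                gene_id=gene_id,
                etype=etype,
                chrom=chrom,
                strand=strand,
                inclusion=frozenset(str(row.alternative_transcripts).split(",")),
                total=frozenset(str(row.total_transcripts).split(",")),
                region=region,
                alt_exon=alt_exon,
                anchors=anchors,
            )
        )
    return flag_microexons(events)
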