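"""Abundance quantification in RNA space (TPM) and ribosome space (OPM).

Both units share one length-normalized form: for ORF/transcript *i* with
estimated counts ``n_i`` and effective length ``l_i``,

    value_i = 1e6 * (n_i / l_i) / sum_j (n_j / l_j)

so every sample column sums to one million over entries with a defined
length. In RNA space the counts are RNA-seq read counts per transcript
(TPM); in ribosome space they are fractionally assigned ribosome-protected
fragment counts per ORF (OPM).

Ribosome-footprint reads are distributed among the transcript isoforms
compatible with their aligned position using the RNA-seq abundances as
priors, optionally refined by EM iterations on the ribosome-space
abundances themselves.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

MIN_READ_LENGTH = 26  # nt; shorter footprints are discarded


class AlignmentRecord(NamedTuple):
    """One (read, transcript) alignment in transcript coordinates."""

    read_id: str
    transcript_id: str
    pos: int  # 0-based 5' end on the transcript
    length: int


@dataclass
class AbundanceTable:
    """ORF x sample matrix in TPM or OPM units."""

    unit: str  # "TPM" | "OPM"
    values: pd.DataFrame  # index: orf/transcript ids; columns: samples
    effective_lengths: pd.Series
    est_counts: pd.DataFrame | None = None

    def mean_values(self) -> pd.Series:
        """Per-ORF mean across samples (replicate averaging)."""
        return self.values.mean(axis=1)

    def column(self, sample) -> pd.Series:
        return self.values[sample]


def _normalize_column(counts: np.ndarray, eff_len: np.ndarray) -> np.ndarray:
    if np.any(eff_len <= 0):
        raise DataError("effective lengths must be positive")
    rate = counts / eff_len
    total = rate.sum()
    if total <= 0:
        warnings.warn("all counts are zero; emitting an all-zero column")
        return np.zeros_like(rate)
    return 1e6 * rate / total


def _as_series(x, name="value") -> pd.Series:
    if isinstance(x, pd.Series):
        return x.astype(float)
    return pd.Series(x, dtype=float)


def compute_tpm(counts, eff_len, sample: str = "sample") -> AbundanceTable:
    """Transcripts-per-million from counts and effective lengths."""
    counts = _as_series(counts)
    eff_len = _as_series(eff_len).reindex(counts.index)
    if eff_len.isna().any():
        missing = list(eff_len.index[eff_len.isna()])[:3]
        raise DataError(f"missing effective length for {missing}")
    vals = _normalize_column(counts.to_numpy(), eff_len.to_numpy())
    return AbundanceTable(
        unit="TPM",
        values=pd.DataFrame({sample: vals}, index=counts.index),
        effective_lengths=eff_len,
        est_counts=pd.DataFrame({sample: counts}, index=counts.index),
    )


def compute_opm(assignment: "RiboAssignment", eff_len, sample: str = "sample") -> AbundanceTable:
    """ORFs-per-million from fractionally assigned ribosome footprints."""
    counts = assignment.totals
    eff_len = _as_series(eff_len).reindex(counts.index)
    if eff_len.isna().any():
        missing = list(eff_len.index[eff_len.isna()])[:3]
        raise DataError(f"missing effective length for {missing}")
    vals = _normalize_column(counts.to_numpy(), eff_len.to_numpy())
    return AbundanceTable(
        unit="OPM",
        values=pd.DataFrame({sample: vals}, index=counts.index),
        effective_lengths=eff_len,
        est_counts=pd.DataFrame({sample: counts}, index=counts.index),
    )


def combine_tables(tables: list[AbundanceTable]) -> AbundanceTable:
    """Column-concatenate single-sample tables of the same unit."""
    units = {t.unit for t in tables}
    if len(units) != 1:
        raise DataError(f"cannot combine tables with mixed units {units}")
    values = pd.concat([t.values for t in tables], axis=1).fillna(0.0)
    counts = pd.concat(
        [t.est_counts for t in tables if t.est_counts is not None], axis=1
    ).fillna(0.0)
    eff = tables[0].effective_lengths
    for t in tables[1:]:
        eff = eff.combine_first(t.effective_lengths)
    return AbundanceTable(units.pop(), values, eff.reindex(values.index), counts)


# ---------------------------------------------------------------------------
# Ribosome-footprint assignment


@dataclass
class RiboAssignment:
    """Fractional assignment of footprint reads to isoforms.

    ``positions[tx]`` holds parallel arrays (pos, length, weight); the
    weight of one read sums to one across its compatible isoforms.
    """

    totals: pd.Series  # estimated counts n_i per transcript
    positions: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    read_weights: dict[str, list[tuple[str, float]]]
    n_retained: float
    mean_read_length: float
    counters: dict[str, int] = field(default_factory=dict)

    def pooled_with(self, other: "RiboAssignment") -> "RiboAssignment":
        return pool_assignments([self, other])


def pool_assignments(assignments: list[RiboAssignment]) -> RiboAssignment:
    """Pool replicates by summing assigned counts and concatenating positions."""
    totals = assignments[0].totals.copy()
    for a in assignments[1:]:
        totals = totals.add(a.totals, fill_value=0.0)
    positions: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    keys = set()
    for a in assignments:
        keys |= set(a.positions)
    for tx in keys:
        ps, ls, ws = [], [], []
        for a in assignments:
            if tx in a.positions:
                p, l, w = a.positions[tx]
                ps.append(p), ls.append(l), ws.append(w)
        positions[tx] = (np.concatenate(ps), np.concatenate(ls), np.concatenate(ws))
    read_weights: dict[str, list[tuple[str, float]]] = {}
    for i, a in enumerate(assignments):
        for rid, w in a.read_weights.items():
            read_weights[f"{i}:{rid}" if rid in read_weights else rid] = w
    n = sum(a.n_retained for a in assignments)
    mrl = (
        sum(a.mean_read_length * a.n_retained for a in assignments) / n if n else 0.0
    )
    counters: dict[str, int] = defaultdict(int)
    for a in assignments:
        for k, v in a.counters.items():
            counters[k] += v
    return RiboAssignment(totals, positions, read_weights, n, mrl, dict(counters))


def assign_ribo_reads(
    alignments: Iterable[AlignmentRecord],
    rna_tpm: AbundanceTable,
    min_read_len: int = MIN_READ_LENGTH,
    em: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
    prior: str = "transcript",
) -> RiboAssignment:
    """Distribute footprint reads among compatible isoforms.

    Reads shorter than ``min_read_len`` are discarded. Uniquely mapping
    reads get weight 1. Multi-mapping reads are first split proportionally
    to the RNA abundance of their compatible isoforms (``prior`` selects
    TPM per transcript, or TPM density per base with ``"per_base"``); when
    ``em`` is true the split is refined by EM updates on the current
    ribosome-space abundances until the relative change drops below
    ``tol`` or ``max_iter`` iterations. Reads whose compatible isoforms
    all carry zero prior mass are split uniformly (counted).
    """
    tpm = rna_tpm.mean_values()
    eff_len = rna_tpm.effective_lengths
    known = set(tpm.index)

    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    counters = {"too_short": 0, "unknown_transcript": 0, "zero_prior_uniform": 0}
    dropped_short: set[str] = set()
    for rec in alignments:
        if rec.length < min_read_len:
            counters["too_short"] += 1
            dropped_short.add(rec.read_id)
            continue
        if rec.transcript_id not in known:
            counters["unknown_transcript"] += 1
            continue
        by_read[rec.read_id].append(rec)
    for rid in dropped_short:  # a short alignment disqualifies the whole read
        by_read.pop(rid, None)

    if prior == "per_base":
        prior_weight = (tpm / eff_len.reindex(tpm.index)).to_dict()
    else:
        prior_weight = tpm.to_dict()

    # Equivalence classes: reads sharing a compatible transcript set share
    # their weight vector (the prior is positional only through membership).
    classes: dict[tuple[str, ...], list[list[AlignmentRecord]]] = defaultdict(list)
    for rid, recs in by_read.items():
        txs = tuple(sorted({r.transcript_id for r in recs}))
        classes[txs].append(recs)

    class_weights: dict[tuple[str, ...], np.ndarray] = {}
    for txs in classes:
        w = np.array([prior_weight[t] for t in txs], float)
        if w.sum() <= 0:
            w = np.ones(len(txs))
            counters["zero_prior_uniform"] += len(classes[txs])
        class_weights[txs] = w / w.sum()

    if em and any(len(txs) > 1 for txs in classes):
        lengths = eff_len.reindex(tpm.index).to_dict()
        for _ in range(max_iter):
            n = defaultdict(float)
            for txs, groups in classes.items():
                w = class_weights[txs]
                for t, wt in zip(txs, w):
                    n[t] += wt * len(groups)
            theta = {t: n[t] / max(lengths.get(t, 1.0), 1.0) for t in n}
            delta = 0.0
            for txs in classes:
                if len(txs) == 1:
                    continue
                w = np.array([theta.get(t, 0.0) for t in txs], float)
                if w.sum() <= 0:
                    w = np.ones(len(txs))
                w = w / w.sum()
                old = class_weights[txs]
                delta = max(delta, float(np.max(np.abs(w - old))))
                class_weights[txs] = w
            if delta < tol:
                break

    totals: dict[str, float] = defaultdict(float)
    pos_acc: dict[str, list[list]] = defaultdict(lambda: [[], [], []])
    read_weights: dict[str, list[tuple[str, float]]] = {}
    n_retained = 0
    length_sum = 0.0
    for txs, groups in classes.items():
        w = dict(zip(txs, class_weights[txs]))
        for recs in groups:
            rid = recs[0].read_id
            n_retained += 1
            length_sum += recs[0].length
            rw = []
            for rec in recs:
                wt = float(w[rec.transcript_id])
                totals[rec.transcript_id] += wt
                acc = pos_acc[rec.transcript_id]
                acc[0].append(rec.pos)
                acc[1].append(rec.length)
                acc[2].append(wt)
                rw.append((rec.transcript_id, wt))
            read_weights[rid] = rw

    positions = {
        tx: (
            np.array(acc[0], dtype=np.int64),
            np.array(acc[1], dtype=np.int64),
            np.array(acc[2], dtype=float),
        )
        for tx, acc in pos_acc.items()
    }
    totals_series = pd.Series(totals, dtype=float).reindex(tpm.index).fillna(0.0)
    mrl = length_sum / n_retained if n_retained else 0.0
    return RiboAssignment(
        totals=totals_series,
        positions=positions,
        read_weights=read_weights,
        n_retained=float(n_retained),
        mean_read_length=mrl,
        counters=counters,
    )


def orf_effective_lengths(annotation, mean_read_length: float) -> pd.Series:
    """ORF length minus (mean read length - 1), floored at 1 nt."""
    correction = max(mean_read_length - 1.0, 0.0)
    data = {}
    for iso in annotation.isoforms():
        if iso.orf is not None:
            data[iso.transcript_id] = max((iso.orf[1] - iso.orf[0]) - correction, 1.0)
    return pd.Series(data, dtype=float)


# ---------------------------------------------------------------------------
# Readers / writers


def read_alignments_tsv(path) -> list[AlignmentRecord]:
    """Simplified tabular alignments: read_id, transcript_id, pos, length."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AlignmentRecord(str(r.read_id), str(r.transcript_id), int(r.pos), int(r.length))
        for r in df.itertuples(index=False)
    ]


def write_alignments_tsv(records: Iterable[AlignmentRecord], path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("read_id\ttranscript_id\tpos\tlength\n")
        for r in records:
            fh.write(f"{r.read_id}\t{r.transcript_id}\t{r.pos}\t{r.length}\n")


def read_alignments_sam(path) -> list[AlignmentRecord]:
    """Transcriptome-space SAM/BAM alignments (primary + secondary)."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    aln.query_name,
                    aln.reference_name,
                    int(aln.reference_start),
                    int(aln.query_length or aln.infer_read_length() or 0),
                )
            )
    return records


def read_quant_tsv(path, sample: str = "sample", unit: str = "TPM") -> AbundanceTable:
    """Salmon-style quantification table (Name, EffectiveLength, TPM, NumReads)."""
    df = pd.read_csv(path, sep="\t", comment="#").set_index("Name")
    return AbundanceTable(
        unit=unit,
        values=pd.DataFrame({sample: df["TPM"].astype(float)}),
        effective_lengths=df["EffectiveLength"].astype(float),
        est_counts=pd.DataFrame({sample: df["NumReads"].astype(float)})
        if "NumReads" in df
        else None,
    )


def write_quant_tsv(table: AbundanceTable, sample, path, length=None, header_lines=()) -> None:
    vals = table.values[sample]
    counts = (
        table.est_counts[sample]
        if table.est_counts is not None and sample in table.est_counts
        else pd.Series(0.0, index=vals.index)
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
        for name in vals.index:
            eff = table.effective_lengths.get(name, float("nan"))
            ln = length.get(name, eff) if length is not None else eff
            fh.write(f"{name}\t{ln:.3f}\t{eff:.3f}\t{vals[name]:.6f}\t{counts[name]:.6f}\n")


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out = df.copy()
        out.index.name = index_name
        out.to_csv(fh, sep="\t", float_format="%.6g", lineterminator="\n")
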