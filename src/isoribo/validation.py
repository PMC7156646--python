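"""Independent evidence layers for translated-isoform predictions.

Four sources of evidence support (or fail to support) a translated
isoform call: footprint read density over isoform-specific sequence
regions, P-site counts over isoform-specific ORF regions (including
frame-shifted shared sequence), uniquely mapping peptides from shotgun
proteomics, and cross-species conservation (membership in an orthologous
protein-isoform pair). Polysome-fraction relative abundances provide an
orthogonal, transcript-level view of translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import SpecificRegion
from .errors import DataError
from .psite import OrfProfile

POLYSOME_FRACTIONS = ("high_poly", "low_poly", "monosome")


@dataclass
class RegionEvidence:
    transcript_id: str
    kind: str
    density: float  # evidence units per nt of region
    n_unique_reads: float
    validated: bool


@dataclass
class PeptideMatchRecord:
    peptide: str
    hit_orfs_exact: set[str] = field(default_factory=set)
    near_hit_orfs: set[str] = field(default_factory=set)

    @property
    def kept(self) -> bool:
        return (
            len(self.hit_orfs_exact) == 1
            and not (self.near_hit_orfs - self.hit_orfs_exact)
        )


def region_density(
    region: SpecificRegion,
    unique_reads: list[tuple[int, int]] | None = None,
    profile: OrfProfile | None = None,
    min_unique_reads: int = 10,
    min_psite_count: float = 1.0,
    orf_start: int = 0,
) -> RegionEvidence:
    """Evidence density over one isoform-specific region.

    ``sequence``-kind regions take uniquely mapping reads as transcript
    intervals (pos, length); a read counts when it overlaps the region by
    at least one nucleotide, which credits junction-spanning reads.
    Validation requires >= ``min_unique_reads``. ``orf_frame``-kind
    regions take a P-site profile (ORF-local coordinates shifted by
    ``orf_start``); validation requires >= ``min_psite_count`` of summed
    P-site weight.
    """
    length = region.length_nt
    if length <= 0:
        raise DataError(f"zero-length region on {region.transcript_id}")
    if region.kind == "sequence":
        if unique_reads is None:
            raise DataError("sequence-kind regions need uniquely mapping reads")
        n = sum(
            1
            for pos, rlen in unique_reads
            if pos < region.end and pos + rlen > region.start
        )
        return RegionEvidence(
            region.transcript_id, region.kind, n / length, float(n),
            validated=n >= min_unique_reads,
        )
    if profile is None:
        raise DataError("orf_frame-kind regions need a P-site profile")
    lo = max(region.start - orf_start, 0)
    hi = max(region.end - orf_start, 0)
    units = float(profile.counts[lo:hi].sum())
    return RegionEvidence(
        region.transcript_id, region.kind, units / length, units,
        validated=units >= min_psite_count,
    )


def match_peptides(
    peptides: list[str],
    orf_proteome: dict[str, str],
    max_mismatch: int = 2,
    min_pep_len: int = 7,
    collapse_il: bool = False,
) -> list[PeptideMatchRecord]:
    """Match peptides against all annotated ORF proteins.

    A peptide is kept only when it matches exactly one ORF perfectly and
    no *other* ORF within ``max_mismatch`` amino-acid mismatches over any
    equal-length window (gap-free Hamming distance). ``collapse_il``
    treats isoleucine and leucine as equivalent, as they are
    indistinguishable by mass.
    """

    def norm(s: str) -> str:
        return s.replace("I", "L") if collapse_il else s

    encoded = {
        orf: np.frombuffer(norm(seq).encode(), dtype=np.uint8)
        for orf, seq in orf_proteome.items()
    }
    records = []
    for pep in peptides:
        if len(pep) < min_pep_len:
            continue
        rec = PeptideMatchRecord(peptide=pep)
        p = np.frombuffer(norm(pep).encode(), dtype=np.uint8)
        k = len(p)
        for orf, arr in encoded.items():
            n = len(arr)
            if n < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, k)
            mismatches = (windows != p).sum(axis=1)
            best = int(mismatches.min())
            if best == 0:
                rec.hit_orfs_exact.add(orf)
            if best <= max_mismatch:
                rec.near_hit_orfs.add(orf)
        records.append(rec)
    return records


def polysome_relative_abundance(tpm: pd.DataFrame) -> pd.DataFrame:
    """Relative abundance of each transcript across sedimentation fractions.

    Input columns are TPM values for the high-polysome, low-polysome and
    monosome fractions; each fraction's abundance is divided by the
    three-fraction sum, so the relative abundances sum to one. Rows with
    a zero sum are NaN.
    """
    missing = [c for c in POLYSOME_FRACTIONS if c not in tpm.columns]
    if missing:
        raise DataError(f"missing polysome fraction column(s): {missing}")
    vals = tpm[list(POLYSOME_FRACTIONS)].astype(float)
    if (vals.to_numpy() < 0).any():
        raise DataError("negative TPM in polysome table")
    total = vals.sum(axis=1)
    out = vals.div(total.where(total > 0), axis=0)
    return out


def aggregate_validation(
    calls: pd.DataFrame,
    region_evidence: list[RegionEvidence],
    peptide_records: list[PeptideMatchRecord],
    pairing,
    length_strata: tuple[int, ...] = (200, 1000, 10000),
) -> pd.DataFrame:
    """Per translated isoform, which independent evidence sources agree.

    Sources: ``conservation`` (member of an orthologous isoform pair),
    ``unique_region`` (a validated sequence-kind region),
    ``orf_counts`` (a validated orf_frame-kind region), and ``peptide``
    (a kept uniquely matching peptide). ``any_evidence`` is their union.
    """
    conserved = {a for a, _, _ in getattr(pairing, "pairs", [])} | {
        b for _, b, _ in getattr(pairing, "pairs", [])
    }
    seq_ok = {e.transcript_id for e in region_evidence if e.kind == "sequence" and e.validated}
    orf_ok = {e.transcript_id for e in region_evidence if e.kind == "orf_frame" and e.validated}
    pep_ok = set()
    for rec in peptide_records:
        if rec.kept:
            pep_ok |= rec.hit_orfs_exact

    translated = calls[calls["status"] == "translated"]
    rows = []
    for r in translated.itertuples(index=False):
        sources = {
            "conservation": r.orf_id in conserved,
            "unique_region": r.orf_id in seq_ok,
            "orf_counts": r.orf_id in orf_ok,
            "peptide": r.orf_id in pep_ok,
        }
        rows.append(
            dict(transcript_id=r.orf_id, **sources, any_evidence=any(sources.values()))
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "conservation", "unique_region", "orf_counts",
                 "peptide", "any_evidence"],
    )
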