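"""Translation calling from P-site profiles.

Two metrics decide whether an ORF is actively translated:

periodicity
    the fraction of P-site signal falling in the annotated reading frame
    (frame 0). Actively translated ORFs show strong 3-nt phasing.

PME (proportion of maximum entropy)
    Shannon entropy of the read distribution across the ORF's codons,
    divided by the entropy of a perfectly even distribution over the same
    codons. 1 means completely even coverage; 0 means all reads piled in
    a single codon.

Thresholds are calibrated on positive-control ORFs (genes with a single
annotated ORF and independent evidence of protein expression): each
threshold is the lower quantile of the control distribution leaving a
``coverage_fraction`` of controls above it. ORFs with fewer than
``read_min`` pooled footprint reads or mean RNA abundance at or below
``tpm_min`` TPM are not evaluated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import DataError
from .psite import OrfProfile

STATUS_TRANSLATED = "translated"
STATUS_NOT_TRANSLATED = "not_translated"
STATUS_NOT_EVALUATED = "not_evaluated"


@dataclass
class CalibrationThresholds:
    periodicity_min: float
    pme_min: float
    coverage_fraction: float = 0.90
    control_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationThresholds":
        with open(path) as fh:
            return cls(**json.load(fh))


def _region_counts(profile_or_counts, bin_width: int | None = None) -> np.ndarray:
    if isinstance(profile_or_counts, OrfProfile):
        if bin_width is None or bin_width == 3:
            return profile_or_counts.codon_counts()
        counts = profile_or_counts.counts
        n = len(counts)
        edges = np.arange(0, n + bin_width, bin_width)
        return np.add.reduceat(counts, edges[:-1][edges[:-1] < n])
    return np.asarray(profile_or_counts, dtype=float)


def compute_pme(profile_or_counts, bin_width: int | None = None) -> float:
    """Proportion of maximum entropy of the per-region read distribution.

    Regions are codons by default (``bin_width`` switches to fixed-width
    nucleotide bins); an :class:`OrfProfile` is binned accordingly, while
    a plain array is taken as region counts directly. Degenerate ORFs
    with a single region cannot be non-uniform and return 1.0.
    """
    counts = _region_counts(profile_or_counts, bin_width)
    n_regions = len(counts)
    total = counts.sum()
    if total <= 0:
        raise DataError("PME undefined for an ORF with zero reads")
    if n_regions <= 1:
        return 1.0
    p = counts[counts > 0] / total
    h = -(p * np.log2(p)).sum()
    h_max = np.log2(n_regions)
    return float(h / h_max)


def compute_periodicity(profile: OrfProfile) -> float:
    """Fraction of P-site signal in the annotated frame, f0/(f0+f1+f2)."""
    f0, f1, f2 = profile.frame_counts
    total = f0 + f1 + f2
    if total <= 0:
        raise DataError("periodicity undefined for an ORF with zero reads")
    return float(f0 / total)


def calibrate_thresholds(
    periodicity,
    pme,
    coverage_fraction: float = 0.90,
    two_sided: bool = False,
    min_controls: int = 20,
    control_ids: list[str] | None = None,
) -> CalibrationThresholds:
    """Quantile thresholds from positive-control metric distributions.

    One-sided by default: each threshold is the empirical
    ``1 - coverage_fraction`` quantile (type-7 interpolation), so a
    ``coverage_fraction`` share of controls lies at or above it. With
    ``two_sided`` the lower bound of the central ``coverage_fraction``
    interval is used instead.
    """
    periodicity = np.asarray(periodicity, float)
    pme = np.asarray(pme, float)
    if len(periodicity) < min_controls or len(pme) < min_controls:
        raise DataError(
            f"calibration needs >= {min_controls} control ORFs, got "
            f"{min(len(periodicity), len(pme))}"
        )
    q = (1.0 - coverage_fraction) / 2.0 if two_sided else (1.0 - coverage_fraction)
    return CalibrationThresholds(
        periodicity_min=float(np.quantile(periodicity, q)),
        pme_min=float(np.quantile(pme, q)),
        coverage_fraction=coverage_fraction,
        control_ids=list(control_ids or []),
    )


def classify_orfs(
    profiles: dict[str, OrfProfile],
    mean_tpm: pd.Series,
    thresholds: CalibrationThresholds,
    read_min: float = 10.0,
    tpm_min: float = 0.1,
    sample: str = "sample",
) -> pd.DataFrame:
    """Classify each ORF as translated / not_translated / not_evaluated.

    ``profiles`` must already be pooled over replicates and ``mean_tpm``
    averaged over replicates. ORFs failing the read-count or expression
    filter are not evaluated and carry NaN metrics.
    """
    rows = []
    orf_ids = sorted(set(mean_tpm.index) | set(profiles))
    for orf_id in orf_ids:
        prof = profiles.get(orf_id)
        n_reads = prof.n_reads if prof is not None else 0.0
        tpm = float(mean_tpm.get(orf_id, 0.0))
        if n_reads < read_min or tpm <= tpm_min:
            rows.append((orf_id, sample, STATUS_NOT_EVALUATED, np.nan, np.nan, n_reads, tpm))
            continue
        periodicity = compute_periodicity(prof)
        pme = compute_pme(prof)
        ok = periodicity >= thresholds.periodicity_min and pme >= thresholds.pme_min
        status = STATUS_TRANSLATED if ok else STATUS_NOT_TRANSLATED
        rows.append((orf_id, sample, status, periodicity, pme, n_reads, tpm))
    return pd.DataFrame(
        rows,
        columns=["orf_id", "sample", "status", "periodicity", "pme", "n_reads", "mean_tpm"],
    )


def summarize_gene_isoform_status(
    calls: pd.DataFrame, mean_tpm: pd.Series, annotation
) -> pd.DataFrame:
    """Label translated isoforms per gene by their RNA abundance rank.

    ``single`` for the lone isoform of a single-isoform gene, ``main``
    for the most RNA-abundant isoform of a multi-isoform gene,
    ``secondary`` for the second most abundant, ``other`` otherwise.
    Untranslated isoforms get an empty label.
    """
    status = calls.set_index("orf_id")["status"]
    rows = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        isoforms = sorted(
            gene.isoforms,
            key=lambda i: (-float(mean_tpm.get(i.transcript_id, 0.0)), i.transcript_id),
        )
        n_translated = sum(
            1 for i in isoforms if status.get(i.transcript_id) == STATUS_TRANSLATED
        )
        for rank, iso in enumerate(isoforms):
            st = status.get(iso.transcript_id, STATUS_NOT_EVALUATED)
            if st != STATUS_TRANSLATED:
                label = ""
            elif len(isoforms) == 1:
                label = "single"
            elif rank == 0:
                label = "main"
            elif rank == 1:
                label = "secondary"
            else:
                label = "other"
            rows.append((gid, iso.transcript_id, st, rank + 1, label, n_translated))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "transcript_id", "status", "tpm_rank", "label", "n_translated_in_gene"],
    )
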