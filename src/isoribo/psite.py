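"""P-site offset estimation and per-ORF P-site count profiles.

The P site is the ribosome's peptidyl-tRNA site; localizing each
footprint read to its P site turns read 5' ends into codon-resolved
occupancy. The offset between a read's 5' end and its P site depends on
read length and is estimated from a metagene around annotated ATG start
codons: for each read length, the distance from the leftmost 5' position
covered by reads (within a fixed upstream window) to the ATG.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_OFFSET = 12  # canonical distance from footprint 5' end to the P site


@dataclass
class OffsetTable:
    """Per-read-length P-site offsets with supporting read counts."""

    offsets: dict[int, int]
    support: dict[int, float] = field(default_factory=dict)
    defaulted: set[int] = field(default_factory=set)

    def get(self, length: int) -> int:
        return self.offsets.get(length, DEFAULT_OFFSET)

    def write_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("length\toffset\tsupport\tdefaulted\n")
            for length in sorted(self.offsets):
                fh.write(
                    f"{length}\t{self.offsets[length]}\t"
                    f"{self.support.get(length, 0.0):.3f}\t"
                    f"{int(length in self.defaulted)}\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "OffsetTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            offsets={int(r.length): int(r.offset) for r in df.itertuples()},
            support={int(r.length): float(r.support) for r in df.itertuples()},
            defaulted={int(r.length) for r in df.itertuples() if int(r.defaulted)},
        )


@dataclass
class OrfProfile:
    """Per-nucleotide P-site weight along one ORF for one (pooled) sample."""

    orf_id: str
    counts: np.ndarray  # length == ORF length in nt
    dropped_outside: float = 0.0

    @property
    def n_reads(self) -> float:
        return float(self.counts.sum())

    @property
    def frame_counts(self) -> tuple[float, float, float]:
        n = len(self.counts)
        return tuple(float(self.counts[f:n:3].sum()) for f in range(3))

    def codon_counts(self) -> np.ndarray:
        n = (len(self.counts) // 3) * 3
        return self.counts[:n].reshape(-1, 3).sum(axis=1)


def estimate_psite_offsets(
    assignment,
    annotation,
    window: tuple[int, int] = (-40, -1),
    min_support: float = 50.0,
    default_offset: int = DEFAULT_OFFSET,
    min_covered_weight: float = 2.0,
) -> OffsetTable:
    """Estimate the P-site offset for each read length.

    For every read length a metagene of 5' end positions relative to
    annotated ATGs is aggregated over all ORFs (only 5' ends inside
    ``window`` count). The offset is the distance from the leftmost
    covered position to the ATG, where "covered" requires at least
    ``min_covered_weight`` of assigned read weight to guard against
    stray alignments. Length classes supported by fewer than
    ``min_support`` in-window reads fall back to ``default_offset``
    with a warning.
    """
    index = annotation.isoform_index()
    hist: dict[int, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    support: dict[int, float] = defaultdict(float)
    lengths_seen: set[int] = set()

    for tx, (pos, lens, wts) in assignment.positions.items():
        iso = index.get(tx)
        if iso is None or iso.orf is None:
            continue
        atg = iso.orf[0]
        rel = pos - atg
        in_window = (rel >= window[0]) & (rel <= window[1])
        lengths_seen.update(map(int, np.unique(lens)))
        for r, l, w in zip(rel[in_window], lens[in_window], wts[in_window]):
            hist[int(l)][int(r)] += float(w)
            support[int(l)] += float(w)

    offsets: dict[int, int] = {}
    defaulted: set[int] = set()
    for length in sorted(lengths_seen):
        if support[length] < min_support:
            warnings.warn(
                f"read length {length}: only {support[length]:.1f} reads near "
                f"annotated starts; falling back to offset {default_offset}"
            )
            offsets[length] = default_offset
            defaulted.add(length)
            continue
        covered = [r for r, w in hist[length].items() if w >= min_covered_weight]
        if not covered:
            offsets[length] = default_offset
            defaulted.add(length)
            continue
        offsets[length] = -min(covered)
    return OffsetTable(offsets=offsets, support=dict(support), defaulted=defaulted)


def build_orf_profiles(
    assignment, offsets: OffsetTable, annotation
) -> dict[str, OrfProfile]:
    """Accumulate fractional read weights at P-site positions along each ORF.

    Each read contributes its weight at 5' end + offset(read length) in
    transcript coordinates; P sites falling outside the ORF (UTRs) are
    dropped and accounted in ``dropped_outside``, so total profile mass
    plus dropped mass equals the assigned weight per transcript.
    """
    index = annotation.isoform_index()
    profiles: dict[str, OrfProfile] = {}
    for tx, (pos, lens, wts) in assignment.positions.items():
        iso = index.get(tx)
        if iso is None or iso.orf is None:
            continue
        o0, o1 = iso.orf
        counts = np.zeros(o1 - o0, dtype=float)
        off = np.fromiter((offsets.get(int(l)) for l in lens), dtype=np.int64, count=len(lens))
        psites = pos + off - o0
        inside = (psites >= 0) & (psites < (o1 - o0))
        np.add.at(counts, psites[inside], wts[inside])
        profiles[tx] = OrfProfile(
            orf_id=tx, counts=counts, dropped_outside=float(wts[~inside].sum())
        )
    return profiles


def write_profiles_tsv(profiles: dict[str, OrfProfile], path, header_lines=()) -> None:
    """Long-format per-transcript profile TSV (ORF-local position, count)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("transcript_id\tpos\tcount\n")
        for tx in sorted(profiles):
            prof = profiles[tx]
            fh.write(f"{tx}\t-1\t{prof.dropped_outside:.6g}\n")  # sentinel row
            for p in np.nonzero(prof.counts)[0]:
                fh.write(f"{tx}\t{int(p)}\t{prof.counts[p]:.6g}\n")


def read_profiles_tsv(path, annotation) -> dict[str, OrfProfile]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    index = annotation.isoform_index()
    profiles: dict[str, OrfProfile] = {}
    for tx, grp in df.groupby("transcript_id", sort=True):
        iso = index.get(str(tx))
        if iso is None or iso.orf is None:
            continue
        counts = np.zeros(iso.orf[1] - iso.orf[0], dtype=float)
        dropped = 0.0
        for p, c in zip(grp["pos"].to_numpy(), grp["count"].to_numpy()):
            if p < 0:
                dropped = float(c)
            else:
                counts[int(p)] = float(c)
        profiles[str(tx)] = OrfProfile(str(tx), counts, dropped)
    return profiles
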