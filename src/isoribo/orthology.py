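"""Ortholog protein-isoform pairing between two species.

For each 1-to-1 orthologous gene pair, all protein isoforms of the two
genes are globally aligned (Needleman-Wunsch, BLOSUM62, affine gaps) and
each pair scored as the fraction of identical aligned positions over the
total alignment length. Pairs scoring at least ``min_score`` (default
0.8) are candidates; the final one-to-one assignment extracts the
globally best-scoring remaining pair repeatedly (mutual-best greedy).
Under strict preferences this yields a stable matching: no two proteins
left unpaired (or paired worse) would both prefer each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .errors import DataError


@dataclass
class ProteinPairScore:
    id_a: str
    id_b: str
    matches: int
    aln_len: int

    @property
    def score(self) -> float:
        return self.matches / self.aln_len


@dataclass
class IsoformPairing:
    pairs: list[tuple[str, str, float]]
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align_score(
    seq_a: str,
    seq_b: str,
    id_a: str = "a",
    id_b: str = "b",
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    aligner: Align.PairwiseAligner | None = None,
) -> ProteinPairScore:
    """Identity fraction of the optimal global alignment of two proteins.

    The score is (identical aligned columns) / (total alignment columns,
    gaps included), so it lies in [0, 1] and the alignment length is at
    least the longer sequence.
    """
    if not seq_a or not seq_b:
        raise DataError("cannot align an empty protein sequence")
    if aligner is None:
        aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(seq_a.replace("*", "X"), seq_b.replace("*", "X"))[0]
    counts = aln.counts()
    return ProteinPairScore(
        id_a=id_a, id_b=id_b, matches=int(counts.identities), aln_len=int(aln.length)
    )


def score_matrix(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> list[ProteinPairScore]:
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return [
        global_align_score(sa, sb, ida, idb, aligner=aligner)
        for ida, sa in proteins_a.items()
        for idb, sb in proteins_b.items()
    ]


def pair_isoforms(
    scores: list[ProteinPairScore],
    min_score: float = 0.8,
) -> IsoformPairing:
    """Symmetric stable one-to-one matching from a pair-score list.

    Candidate pairs with score >= ``min_score`` are processed from the
    globally highest score down (ties broken by lexicographic ids);
    whenever both members are still free the pair is fixed. The result
    contains no blocking pair: any rejected candidate loses to a
    higher-scoring assignment of one of its members.
    """
    ids_a = sorted({s.id_a for s in scores})
    ids_b = sorted({s.id_b for s in scores})
    candidates = sorted(
        (s for s in scores if s.score >= min_score),
        key=lambda s: (-s.score, s.id_a, s.id_b),
    )
    matched_a: dict[str, tuple[str, float]] = {}
    matched_b: set[str] = set()
    for s in candidates:
        if s.id_a in matched_a or s.id_b in matched_b:
            continue
        matched_a[s.id_a] = (s.id_b, s.score)
        matched_b.add(s.id_b)
    pairs = sorted(
        (a, b, score) for a, (b, score) in matched_a.items()
    )
    return IsoformPairing(
        pairs=pairs,
        unmatched_a=[a for a in ids_a if a not in matched_a],
        unmatched_b=[b for b in ids_b if b not in matched_b],
    )


def has_blocking_pair(scores: list[ProteinPairScore], pairing: IsoformPairing,
                      min_score: float = 0.8) -> bool:
    """Exhaustively check the stability of a matching."""
    score_of_a = {a: s for a, _, s in pairing.pairs}
    score_of_b = {b: s for _, b, s in pairing.pairs}
    matched = {(a, b) for a, b, _ in pairing.pairs}
    for s in scores:
        if s.score < min_score or (s.id_a, s.id_b) in matched:
            continue
        a_would = s.score > score_of_a.get(s.id_a, -1.0)
        b_would = s.score > score_of_b.get(s.id_b, -1.0)
        if a_would and b_would:
            return True
    return False


def pair_gene_isoforms(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    gene_of_a: dict[str, str],
    gene_of_b: dict[str, str],
    gene_orthologs: dict[str, str],
    min_score: float = 0.8,
    **align_kwargs,
) -> IsoformPairing:
    """Pair isoforms gene-by-gene across a 1-to-1 gene ortholog table."""
    all_pairs: list[tuple[str, str, float]] = []
    unmatched_a: list[str] = []
    unmatched_b: list[str] = []
    by_gene_a: dict[str, dict[str, str]] = {}
    for pid, seq in proteome_a.items():
        by_gene_a.setdefault(gene_of_a[pid], {})[pid] = seq
    by_gene_b: dict[str, dict[str, str]] = {}
    for pid, seq in proteome_b.items():
        by_gene_b.setdefault(gene_of_b[pid], {})[pid] = seq
    for ga in sorted(gene_orthologs):
        gb = gene_orthologs[ga]
        prots_a = by_gene_a.get(ga, {})
        prots_b = by_gene_b.get(gb, {})
        if not prots_a or not prots_b:
            unmatched_a.extend(sorted(prots_a))
            unmatched_b.extend(sorted(prots_b))
            continue
        scores = score_matrix(prots_a, prots_b, **align_kwargs)
        pairing = pair_isoforms(scores, min_score=min_score)
        all_pairs.extend(pairing.pairs)
        unmatched_a.extend(pairing.unmatched_a)
        unmatched_b.extend(pairing.unmatched_b)
    return IsoformPairing(sorted(all_pairs), sorted(unmatched_a), sorted(unmatched_b))


def derive_control_orthologs(
    gene_orthologs: dict[str, str], control_genes_a: list[str]
) -> tuple[list[str], int]:
    """Project a control gene list into species B via 1-to-1 orthology.

    Returns the projected list and the number of controls without an
    ortholog.
    """
    projected = []
    missing = 0
    for g in control_genes_a:
        if g in gene_orthologs:
            projected.append(gene_orthologs[g])
        else:
            missing += 1
    return projected, missing


# ---------------------------------------------------------------------------
# I/O helpers


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_ortholog_table(path) -> dict[str, str]:
    """Two-column TSV (gene_a, gene_b) of 1-to-1 orthologs."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["a", "b"])
    return dict(zip(df["a"].astype(str), df["b"].astype(str)))


def write_pairing_tsv(pairing: IsoformPairing, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("tx_a\ttx_b\tscore\n")
        for a, b, s in pairing.pairs:
            fh.write(f"{a}\t{b}\t{s:.6f}\n")
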