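"""Pairwise protein alignment, BBH orthologs and family construction.

Alignment is exact Smith-Waterman (BLOSUM62, affine gaps: the first gap
residue costs 11, each further residue 1), feasible at panel scale where
heuristic search engines would normally be used.  Identity is percent
identical pairs over aligned columns (gap columns included in the
denominator); query coverage is the percent of query residues spanned by the
local alignment.  Orthologs are reciprocal best hits passing strict identity
and coverage thresholds; families are connected components of the union BBH
graph over all genome pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .model import OrthologFamily
from .utils import round_half_up

__all__ = [
    "AlignmentResult",
    "make_aligner",
    "align",
    "bbh",
    "build_families",
    "partition_summary",
    "core_percentage",
    "find_duplicates",
]


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    identity: float  # % identical pairs over aligned columns
    query_coverage: float  # % of query residues inside the aligned region


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = make_aligner()


def _pairwise(a_seq: str, b_seq: str) -> tuple[float, float, float, float]:
    """(score, identity%, coverage of a%, coverage of b%) for one pair.

    Computed on the lexicographically sorted pair so that the reported
    identity does not depend on argument order when several co-optimal
    local alignments exist.
    """
    if not a_seq or not b_seq:
        raise ValueError("align requires non-empty sequences")
    if a_seq > b_seq:
        score, identity, cov_b, cov_a = _pairwise(b_seq, a_seq)
        return score, identity, cov_a, cov_b
    score = _ALIGNER.score(a_seq, b_seq)
    if score <= 0:
        return 0.0, 0.0, 0.0, 0.0
    aln = _ALIGNER.align(a_seq, b_seq)[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.internal_gaps
    identity = 100.0 * c.identities / columns if columns else 0.0
    coords = aln.coordinates
    span_a = int(coords[0, -1] - coords[0, 0])
    span_b = int(coords[1, -1] - coords[1, 0])
    return (
        float(score),
        identity,
        100.0 * span_a / len(a_seq),
        100.0 * span_b / len(b_seq),
    )


def align(
    a_seq: str, b_seq: str, query_id: str = "query", subject_id: str = "subject"
) -> AlignmentResult:
    """Local alignment of *a* (query) against *b* (subject)."""
    score, identity, cov_a, _ = _pairwise(a_seq, b_seq)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        identity=identity,
        query_coverage=cov_a,
    )


def bbh(
    a_proteins: dict[str, str],
    b_proteins: dict[str, str],
    identity_min: float = 40.0,
    coverage_min: float = 75.0,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two genomes' protein sets.

    A hit qualifies only when identity > ``identity_min`` and the query's
    coverage > ``coverage_min`` (both strict).  The best hit is the highest
    score; ties break by higher identity, then lexicographically smaller
    subject id.  A pair is kept only when best in both directions.
    """
    cache: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for a_id, a_seq in a_proteins.items():
        for b_id, b_seq in b_proteins.items():
            cache[(a_id, b_id)] = _pairwise(a_seq, b_seq)

    def best(
        query_ids: list[str], subject_ids: list[str], forward: bool
    ) -> dict[str, str]:
        out = {}
        for q in query_ids:
            candidates = []
            for s in subject_ids:
                score, identity, cov_a, cov_b = cache[(q, s) if forward else (s, q)]
                cov_q = cov_a if forward else cov_b
                if identity > identity_min and cov_q > coverage_min:
                    candidates.append((-score, -identity, s))
            if candidates:
                out[q] = min(candidates)[2]
        return out

    a_best = best(sorted(a_proteins), sorted(b_proteins), forward=True)
    b_best = best(sorted(b_proteins), sorted(a_proteins), forward=False)
    pairs = [
        (a_id, b_id)
        for a_id, b_id in a_best.items()
        if b_best.get(b_id) == a_id
    ]
    return sorted(pairs)


def build_families(
    panel: dict[str, dict[str, str]],
    identity_min: float = 40.0,
    coverage_min: float = 75.0,
) -> list[OrthologFamily]:
    """Ortholog families over a genome panel.

    ``panel`` maps genome_id -> {protein_id: sequence} (TCS proteins only).
    Families are connected components of the BBH graph unioned over all
    genome pairs; every protein belongs to exactly one family, so proteins
    with no reciprocal hit form singleton (strain-specific) families.
    """
    genomes = sorted(panel)
    graph: nx.Graph = nx.Graph()
    for g in genomes:
        for pid in panel[g]:
            graph.add_node((g, pid))
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            for a_id, b_id in bbh(
                panel[ga], panel[gb], identity_min=identity_min, coverage_min=coverage_min
            ):
                graph.add_edge((ga, a_id), (gb, b_id))
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    families = []
    for i, comp in enumerate(components):
        members: dict[str, list[str]] = {}
        for g, pid in sorted(comp):
            members.setdefault(g, []).append(pid)
        families.append(
            OrthologFamily(family_id=f"F{i:04d}", members=members, panel=genomes)
        )
    return families


def core_percentage(n_core: int, n_total: int) -> float:
    """Percent of genes in core families, half-up to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_up(100.0 * n_core / n_total, 1)


def partition_summary(families: list[OrthologFamily]) -> dict:
    """Core/accessory/strain-specific family and gene counts plus the core
    gene percentage."""
    fam_counts = {"core": 0, "accessory": 0, "strain-specific": 0}
    gene_counts = {"core": 0, "accessory": 0, "strain-specific": 0}
    for fam in families:
        cls = fam.partition_class()
        fam_counts[cls] += 1
        gene_counts[cls] += fam.n_members
    total_genes = sum(gene_counts.values())
    return {
        "families": fam_counts,
        "genes": gene_counts,
        "total_genes": total_genes,
        "core_gene_pct": core_percentage(gene_counts["core"], total_genes)
        if total_genes
        else None,
    }


def find_duplicates(
    family: OrthologFamily,
    sequences: dict[tuple[str, str], str],
    identity_min: float = 95.0,
) -> list[tuple[str, str, str, float]]:
    """Within-genome member pairs at or above the identity threshold —
    putative duplications (100% reproduces a single-acquisition-then-
    duplication signature)."""
    flagged = []
    for genome, pids in sorted(family.members.items()):
        for i, p1 in enumerate(sorted(pids)):
            for p2 in sorted(pids)[i + 1 :]:
                _, identity, _, _ = _pairwise(
                    sequences[(genome, p1)], sequences[(genome, p2)]
                )
                if identity >= identity_min:
                    flagged.append((genome, p1, p2, identity))
    return flagged
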