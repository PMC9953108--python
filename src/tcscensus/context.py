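"""Genomic-context clustering of TCS genes (orphan / paired / complex).

Two consecutive TCS genes on a contig chain into one cluster when (i) their
intergenic distance is strictly less than the gap threshold (default 200 bp),
(ii) their orientation is compatible (same strand, or divergent ``<- ->``;
convergent ``-> <-`` breaks the chain), and (iii) no non-TCS gene lies
between them.  Chains are maximal; singletons are orphans.  The rules are
applied pairwise along the chain.
"""

from __future__ import annotations

import warnings

from .model import GeneCluster, ProteinRecord, TCSProtein

__all__ = ["intergenic_distance", "orientation_compatible", "build_clusters"]


def intergenic_distance(a: ProteinRecord, b: ProteinRecord) -> int:
    """Base pairs between gene *a* and the downstream gene *b*.

    Negative for overlapping genes (which always satisfy a ``< gap`` test).
    """
    if a.contig_id != b.contig_id:
        raise ValueError(
            f"{a.protein_id} and {b.protein_id} lie on different contigs"
        )
    if a.start > b.start:
        raise ValueError("a must precede b (a.start <= b.start)")
    return b.start - a.end - 1


def orientation_compatible(a: ProteinRecord, b: ProteinRecord) -> bool:
    """True for same-strand or divergent (``- +``) pairs; convergent
    (``+ -``) pairs are the only excluded arrangement."""
    if a.strand == b.strand:
        return True
    return a.strand == "-" and b.strand == "+"


def build_clusters(
    tcs_genes: list[TCSProtein],
    all_records: list[ProteinRecord] | None = None,
    max_gap: int = 200,
    break_on_intervening: bool = True,
) -> list[GeneCluster]:
    """Partition one genome's TCS genes into maximal genomic chains.

    ``all_records`` supplies non-TCS gene coordinates; when
    ``break_on_intervening`` is set (default), any intervening gene that is
    not itself a TCS gene breaks a chain.  Genes lacking coordinates are
    excluded with a warning.  The partition is independent of input order.
    """
    genomes = {t.protein.genome_id for t in tcs_genes}
    if len(genomes) > 1:
        raise ValueError(f"genes span multiple genomes: {sorted(genomes)}")
    tcs_ids = {t.protein_id for t in tcs_genes}
    usable = []
    for t in tcs_genes:
        if t.protein.start is None or t.protein.end is None:  # defensive
            warnings.warn(f"{t.protein_id}: missing coordinates; excluded")
            continue
        usable.append(t)

    # full gene order per contig (TCS + others) to detect intervening genes
    by_contig: dict[str, list[ProteinRecord]] = {}
    pool = {r.protein_id: r for r in (all_records or [])}
    for t in usable:
        pool.setdefault(t.protein_id, t.protein)
    for rec in pool.values():
        by_contig.setdefault(rec.contig_id, []).append(rec)
    for recs in by_contig.values():
        recs.sort(key=lambda r: (r.start, r.end, r.protein_id))

    tcs_by_id = {t.protein_id: t for t in usable}
    clusters: list[GeneCluster] = []
    for contig in sorted(by_contig):
        recs = by_contig[contig]
        chain: list[TCSProtein] = []
        prev_rec: ProteinRecord | None = None
        for rec in recs:
            is_tcs = rec.protein_id in tcs_ids and rec.protein_id in tcs_by_id
            if not is_tcs:
                if break_on_intervening and chain:
                    clusters.append(_close(chain))
                    chain = []
                    prev_rec = None
                continue
            t = tcs_by_id[rec.protein_id]
            if chain and prev_rec is not None:
                gap = intergenic_distance(prev_rec, rec)
                if gap < max_gap and orientation_compatible(prev_rec, rec):
                    chain.append(t)
                else:
                    clusters.append(_close(chain))
                    chain = [t]
            else:
                chain = [t]
            prev_rec = rec
        if chain:
            clusters.append(_close(chain))
    return clusters


def _close(chain: list[TCSProtein]) -> GeneCluster:
    first = chain[0].protein
    return GeneCluster(
        genome_id=first.genome_id, contig_id=first.contig_id, members=list(chain)
    )
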