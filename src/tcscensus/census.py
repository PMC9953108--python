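"""Genome-level summaries: category counts, ratios, organization,
sensing-domain and architecture censuses, RR family breakdowns.

Ratios and fractions are rounded half-up to one decimal, the precision used
in printed census tables.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    HATPASE,
    HISKA,
    REC,
    SENSING,
    Category,
    GeneCluster,
    Role,
    TCSProtein,
)
from .utils import round_half_up

__all__ = [
    "GenomeSummary",
    "genome_summary",
    "rt_ratio",
    "organization_summary",
    "sensing_census",
    "architecture_string",
    "architecture_census",
    "rr_family_census",
    "pearson",
    "assemble_tables",
]

_CATEGORY_COLUMNS = [
    Category.CHK,
    Category.HYHK,
    Category.UNORTHODOX_HK,
    Category.CHEA,
    Category.RR,
    Category.PP_HISKA,
    Category.PP_HPT,
]


@dataclass
class GenomeSummary:
    """One genome's row of the summary table."""

    genome_id: str
    genome_size_mb: float
    n_cds: int
    counts: dict[Category, int]
    rt_ratio: float | None

    @property
    def total_tcs(self) -> int:
        return sum(self.counts.values())

    @property
    def orf_fraction(self) -> float:
        return round_half_up(100.0 * self.total_tcs / self.n_cds, 1)

    def to_row(self) -> dict:
        row = {
            "genome_id": self.genome_id,
            "genome_size_mb": self.genome_size_mb,
            "n_cds": self.n_cds,
        }
        for cat in _CATEGORY_COLUMNS:
            row[cat.value] = self.counts.get(cat, 0)
        row["total_tcs"] = self.total_tcs
        row["orf_fraction"] = self.orf_fraction
        row["rt_ratio"] = self.rt_ratio if self.rt_ratio is not None else "NA"
        return row


def genome_summary(
    tcs_proteins: list[TCSProtein], n_cds: int, genome_size_mb: float
) -> GenomeSummary:
    """Category counts, total, ORF fraction and receiver/transmitter ratio."""
    if n_cds <= 0:
        raise ValueError("n_cds must be positive")
    counts = Counter(t.category for t in tcs_proteins if t.is_tcs)
    genome_ids = {t.protein.genome_id for t in tcs_proteins}
    gid = genome_ids.pop() if len(genome_ids) == 1 else "panel"
    return GenomeSummary(
        genome_id=gid,
        genome_size_mb=genome_size_mb,
        n_cds=n_cds,
        counts={cat: counts.get(cat, 0) for cat in _CATEGORY_COLUMNS},
        rt_ratio=rt_ratio(tcs_proteins),
    )


def rt_ratio(tcs_proteins: list[TCSProtein]) -> float | None:
    """Receiver/transmitter ratio.

    Receivers are REC domains carried by RRs and hybrid HKs; transmitters are
    HisKA+HATPase units carried by classic and hybrid HKs.  Unorthodox HKs
    and CheA are excluded from both sums.  Rounded half-up to one decimal;
    ``None`` (NA) when the transmitter sum is zero.
    """
    receivers = sum(
        t.n_rec for t in tcs_proteins if t.category in (Category.RR, Category.HYHK)
    )
    transmitters = sum(
        t.n_transmitter
        for t in tcs_proteins
        if t.category in (Category.CHK, Category.HYHK)
    )
    if transmitters == 0:
        return None
    return round_half_up(receivers / transmitters, 1)


def organization_summary(clusters: list[GeneCluster]) -> dict:
    """Counts of orphan/pair/triad/tetrad/pentad/complex-n clusters and the
    total gene count (which equals the sum of size x count)."""
    sizes = Counter(c.size for c in clusters)
    row = {
        "orphan": sizes.get(1, 0),
        "pair": sizes.get(2, 0),
        "triad": sizes.get(3, 0),
        "tetrad": sizes.get(4, 0),
        "pentad": sizes.get(5, 0),
    }
    complexes = {k: v for k, v in sizes.items() if k > 5}
    for k in sorted(complexes):
        row[f"complex-{k}"] = complexes[k]
    row["total_tcs"] = sum(k * v for k, v in sizes.items())
    return row


def sensing_census(hk_proteins: list[TCSProtein]) -> dict[str, tuple[int, int]]:
    """Per sensing tag, (occurrences in cHKs, occurrences in hyHKs).

    Counts domain occurrences, not proteins: a kinase with two PAS domains
    contributes 2 to the PAS tally.
    """
    chk: Counter = Counter()
    hyhk: Counter = Counter()
    for t in hk_proteins:
        if t.category is Category.CHK:
            chk.update(t.sensing)
        elif t.category is Category.HYHK:
            hyhk.update(t.sensing)
    tags = sorted(set(chk) | set(hyhk))
    return {tag: (chk.get(tag, 0), hyhk.get(tag, 0)) for tag in tags}


def architecture_string(roles: list[Role]) -> str:
    """Reduce an N->C role list to S/T/R tokens.

    S = any sensing domain, T = a transmitter unit (HisKA consuming its
    downstream HATPase; an unpaired HisKA from a rescued kinase also counts),
    R = a receiver domain.  Other roles do not appear in the architecture.
    """
    tokens: list[str] = []
    consumed: set[int] = set()
    n = len(roles)
    for i, r in enumerate(roles):
        if i in consumed:
            continue
        if r.kind == SENSING:
            tokens.append("S")
        elif r.kind == REC:
            tokens.append("R")
        elif r.kind == HISKA:
            tokens.append("T")
            for j in range(i + 1, n):
                if roles[j].kind == HISKA:
                    break
                if roles[j].kind == HATPASE and j not in consumed:
                    consumed.add(j)
                    break
    return "-".join(tokens)


def architecture_census(
    hk_proteins: list[TCSProtein],
) -> tuple[dict[str, int], int]:
    """Counts per distinct S/T/R architecture string over the given HKs,
    plus the number of HKs carrying no sensing domain."""
    archs = Counter(architecture_string(t.roles) for t in hk_proteins)
    no_sensing = sum(1 for t in hk_proteins if not t.sensing)
    return dict(archs), no_sensing


def rr_family_census(tcs_proteins: list[TCSProtein]) -> dict[str, int]:
    """RR output-family counts; the families partition the RR set, so the
    counts sum to the RR total."""
    fams = Counter(
        t.rr_family or "Unclassified"
        for t in tcs_proteins
        if t.category is Category.RR
    )
    return dict(fams)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value (t transform,
    n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson requires two equal-length vectors, n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def assemble_tables(
    summaries: list[GenomeSummary],
    organization_rows: dict[str, dict],
    sensing_rows: dict[str, dict[str, tuple[int, int]]],
    architecture_rows: dict[str, tuple[dict[str, int], int]],
    rr_rows: dict[str, dict[str, int]],
) -> dict[str, pd.DataFrame]:
    """Shape per-genome census results into the five output tables."""
    t1 = pd.DataFrame([s.to_row() for s in summaries])

    org_records = []
    for gid, row in organization_rows.items():
        org_records.append({"genome_id": gid, **row})
    t2 = pd.DataFrame(org_records).fillna(0)
    count_cols = [c for c in t2.columns if c not in ("genome_id",)]
    t2[count_cols] = t2[count_cols].astype(int)

    sense_records = []
    for gid, tagmap in sensing_rows.items():
        for tag, (c, h) in sorted(tagmap.items()):
            sense_records.append(
                {"genome_id": gid, "sensing_domain": tag, "cHK": c, "hyHK": h}
            )
    t3 = pd.DataFrame(sense_records, columns=["genome_id", "sensing_domain", "cHK", "hyHK"])

    arch_records = []
    for gid, (archs, no_sensing) in architecture_rows.items():
        for arch, cnt in sorted(archs.items()):
            arch_records.append({"genome_id": gid, "architecture": arch, "count": cnt})
        arch_records.append(
            {"genome_id": gid, "architecture": "<no sensing domain>", "count": no_sensing}
        )
    t4 = pd.DataFrame(arch_records, columns=["genome_id", "architecture", "count"])

    rr_records = []
    for gid, fams in rr_rows.items():
        for fam, cnt in sorted(fams.items()):
            rr_records.append({"genome_id": gid, "rr_family": fam, "count": cnt})
    t5 = pd.DataFrame(rr_records, columns=["genome_id", "rr_family", "count"])

    return {
        "genome_summary": t1,
        "organization": t2,
        "sensing_domains": t3,
        "architectures": t4,
        "rr_families": t5,
    }
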