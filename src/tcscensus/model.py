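"""Core data model shared by every pipeline stage.

Two-component systems (TCS) are bacterial signalling pairs built from sensor
histidine kinases (HKs) and response regulators (RRs) that communicate by
His->Asp phosphotransfer.  Proteins are represented here as coordinate-bearing
records, domain annotations as hits against a raw domain vocabulary, and the
classified output as :class:`TCSProtein` objects carrying the canonical role
string (HisKA/HATPase transmitter units, REC receiver domains, Hpt
phosphotransfer domains, sensing and output domains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Category",
    "HK_CATEGORIES",
    "Role",
    "HISKA",
    "HATPASE",
    "REC",
    "HPT",
    "CHEW",
    "SENSING",
    "OUTPUT",
    "OTHER",
    "ProteinRecord",
    "DomainHit",
    "TCSProtein",
    "GeneCluster",
    "AniMatrix",
    "OrthologFamily",
    "Event",
    "EventSet",
]

# Canonical role kinds.
HISKA = "HISKA"  # dimerization/phosphoacceptor domain
HATPASE = "HATPASE"  # histidine-kinase ATPase catalytic domain
REC = "REC"  # receiver domain
HPT = "HPT"  # histidine phosphotransfer domain
CHEW = "CHEW"  # CheW docking module (chemotaxis)
SENSING = "SENSING"  # input/sensing domain, carries a tag (PAS, GAF, ...)
OUTPUT = "OUTPUT"  # RR output domain, carries a family tag (OmpR, NarL, ...)
OTHER = "OTHER"


class Category(str, Enum):
    """Protein-level TCS categories."""

    CHK = "cHK"  # classic histidine kinase (transmitter only)
    HYHK = "hyHK"  # hybrid HK (transmitter + receiver domain)
    UNORTHODOX_HK = "uHK"  # hybrid plus an Hpt domain
    CHEA = "CheA"  # chemotaxis-type kinase (HATPase + Hpt + CheW, no HisKA)
    RR = "RR"  # response regulator
    PP_HISKA = "PP-HisKA"  # standalone-HisKA phosphotransfer protein
    PP_HPT = "PP-Hpt"  # standalone-Hpt phosphotransfer protein
    NONE = "none"  # not a TCS protein

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


HK_CATEGORIES = frozenset({Category.CHK, Category.HYHK, Category.UNORTHODOX_HK})

#: categories counted as TCS genes
TCS_CATEGORIES = frozenset(c for c in Category if c is not Category.NONE)


@dataclass(frozen=True)
class Role:
    """A canonical domain role; sensing and output roles carry a tag."""

    kind: str
    tag: str | None = None

    def __str__(self) -> str:
        return f"{self.kind}({self.tag})" if self.tag else self.kind


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with genomic coordinates (1-based, inclusive)."""

    protein_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.protein_id}: strand must be '+' or '-'")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """One raw domain annotation on a protein (aa coordinates, 1-based)."""

    protein_id: str
    raw_name: str
    ali_start: int
    ali_end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError(
                f"{self.protein_id}/{self.raw_name}: bad coordinates "
                f"{self.ali_start}..{self.ali_end}"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}/{self.raw_name}: negative evalue")

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1


@dataclass
class TCSProtein:
    """A classified protein with its canonical role string and annotations."""

    protein: ProteinRecord
    category: Category
    roles: list[Role] = field(default_factory=list)
    n_rec: int = 0
    n_transmitter: int = 0
    sensing: list[str] = field(default_factory=list)
    rr_family: str | None = None
    tm_count: int = 0
    localization: str = "cytosolic"
    rescued: bool = False  # lone-HisKA protein promoted to cHK by gene context

    @property
    def protein_id(self) -> str:
        return self.protein.protein_id

    @property
    def is_tcs(self) -> bool:
        return self.category is not Category.NONE


_SIZE_NAMES = {1: "orphan", 2: "pair", 3: "triad", 4: "tetrad", 5: "pentad"}

#: composition labels per category (hyphen-joined in genomic order)
COMPOSITION_LABELS = {
    Category.CHK: "cHK",
    Category.HYHK: "hyHK",
    Category.UNORTHODOX_HK: "uHK",
    Category.CHEA: "CheA",
    Category.RR: "RR",
    Category.PP_HISKA: "PP",
    Category.PP_HPT: "PP",
}


@dataclass
class GeneCluster:
    """A maximal genomic chain of TCS genes on one contig."""

    genome_id: str
    contig_id: str
    members: list[TCSProtein]

    def __post_init__(self) -> None:
        self.members = sorted(self.members, key=lambda t: t.protein.start)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def category(self) -> str:
        return _SIZE_NAMES.get(self.size, f"complex-{self.size}")

    @property
    def composition(self) -> str:
        return "-".join(COMPOSITION_LABELS[m.category] for m in self.members)


@dataclass
class AniMatrix:
    """Square symmetric matrix of pairwise average nucleotide identities (%)."""

    genome_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"ANI matrix must be {n}x{n}, got {self.values.shape}"
            )
        if len(set(self.genome_ids)) != n:
            raise ValueError("duplicate genome ids in ANI matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0.0):
            raise ValueError("ANI matrix is not symmetric")
        if not np.all(np.diag(self.values) == 100.0):
            raise ValueError("ANI matrix diagonal must be exactly 100")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("ANI values must lie in [0, 100]")

    def distance(self) -> np.ndarray:
        """100 - ANI, the dissimilarity used for UPGMA clustering."""
        return 100.0 - self.values

    def __len__(self) -> int:
        return len(self.genome_ids)


@dataclass
class OrthologFamily:
    """A cross-genome ortholog family with its presence/absence vector."""

    family_id: str
    members: dict[str, list[str]]  # genome_id -> protein ids
    panel: list[str]  # ordered genome panel

    @property
    def presence(self) -> dict[str, int]:
        return {g: int(bool(self.members.get(g))) for g in self.panel}

    @property
    def n_genomes(self) -> int:
        return sum(self.presence.values())

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())

    def partition_class(self) -> str:
        """'core', 'accessory' or 'strain-specific' over the panel."""
        n = self.n_genomes
        if n == len(self.panel):
            return "core"
        if n == 1:
            return "strain-specific"
        return "accessory"


@dataclass(frozen=True)
class Event:
    """A single gain or loss on a tree branch (branch named by child node)."""

    branch: str
    type: str  # GAIN or LOSS

    def __post_init__(self) -> None:
        if self.type not in ("GAIN", "LOSS"):
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass
class EventSet:
    """Minimum-cost gain/loss scenario for one family on a tree."""

    family_id: str
    events: list[Event]
    cost: float

    @property
    def n_gains(self) -> int:
        return sum(1 for e in self.events if e.type == "GAIN")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e.type == "LOSS")
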