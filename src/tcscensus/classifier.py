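"""Domain-role canonicalization and TCS protein classification.

The classifier maps raw domain names (Pfam-style) onto canonical roles and
applies a fixed decision ladder:

1. one or more transmitter units (a HisKA with a HATPase downstream of it
   before the next HisKA): with >= 1 REC and >= 1 Hpt -> unorthodox HK; with
   >= 1 REC and no Hpt -> hybrid HK; otherwise classic HK;
2. HATPase + Hpt + CheW without HisKA -> CheA-type kinase;
3. >= 1 REC and no HATPase -> response regulator;
4. a lone HisKA (no HATPase): classic HK when its gene is adjacent to another
   TCS gene (the incomplete-HK rescue), otherwise a HisKA-type phosphotransfer
   protein;
5. a lone Hpt -> Hpt-type phosphotransfer protein;
6. anything else is not a TCS protein.

Classification is total and deterministic: every protein receives exactly one
category.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .model import (
    CHEW,
    HATPASE,
    HISKA,
    HPT,
    OTHER,
    OUTPUT,
    REC,
    SENSING,
    Category,
    DomainHit,
    Role,
)

__all__ = [
    "DomainVocabulary",
    "DEFAULT_VOCABULARY",
    "RR_FAMILIES",
    "canonicalize",
    "count_transmitters",
    "classify",
    "rr_family",
    "tm_count",
    "localize",
]

#: RR output families with known output domains
RR_FAMILIES = (
    "NarL",
    "OmpR",
    "CheB",
    "RpfG",
    "PleD",
    "PleD-VieA",
    "RsbU",
    "TrxB",
    "YesN",
    "CyC-C",
)

_SENSING_TAGS = (
    "PAS",
    "HAMP",
    "GAF",
    "PHY",
    "CHASE",
    "MASE",
    "Cache",
    "cNMP_binding",
    "S_TKc",
    "NIT",
    "FHA",
    "CBS",
    "Pkinase",
)

# Default raw-name -> role table (Pfam names; families, not accessions).
_DEFAULT_TABLE: dict[str, Role] = {
    # signalling core
    "HisKA": Role(HISKA),
    "HisKA_2": Role(HISKA),
    "HisKA_3": Role(HISKA),
    "HATPase_c": Role(HATPASE),
    "Response_reg": Role(REC),
    "Hpt": Role(HPT),
    "CheW": Role(CHEW),
    # sensing domains (PAS and PAC are counted jointly as PAS)
    "PAS": Role(SENSING, "PAS"),
    "PAC": Role(SENSING, "PAS"),
    "HAMP": Role(SENSING, "HAMP"),
    "GAF": Role(SENSING, "GAF"),
    "PHY": Role(SENSING, "PHY"),
    "CHASE": Role(SENSING, "CHASE"),
    "CHASE2": Role(SENSING, "CHASE"),
    "CHASE3": Role(SENSING, "CHASE"),
    "MASE1": Role(SENSING, "MASE"),
    "MASE2": Role(SENSING, "MASE"),
    "Cache_1": Role(SENSING, "Cache"),
    "Cache_2": Role(SENSING, "Cache"),
    "cNMP_binding": Role(SENSING, "cNMP_binding"),
    "S_TKc": Role(SENSING, "S_TKc"),
    "NIT": Role(SENSING, "NIT"),
    "FHA": Role(SENSING, "FHA"),
    "CBS": Role(SENSING, "CBS"),
    "Pkinase": Role(SENSING, "Pkinase"),
    # RR output domains
    "GerE": Role(OUTPUT, "NarL"),
    "Trans_reg_C": Role(OUTPUT, "OmpR"),
    "CheB_methylest": Role(OUTPUT, "CheB"),
    "HD": Role(OUTPUT, "RpfG"),
    "GGDEF": Role(OUTPUT, "PleD"),
    "EAL": Role(OUTPUT, "EAL"),  # with GGDEF on the same protein -> PleD-VieA
    "PP2C": Role(OUTPUT, "RsbU"),
    "Pyr_redox": Role(OUTPUT, "TrxB"),
    "HTH_AraC": Role(OUTPUT, "YesN"),
    "Guanylate_cyc": Role(OUTPUT, "CyC-C"),
}


class DomainVocabulary:
    """Mapping from raw domain names to canonical roles.

    Every raw name maps to exactly one role; unknown names map to OTHER.
    The default table ships with the package and can be overridden from a TSV
    ``raw_name<TAB>role<TAB>tag``.
    """

    def __init__(self, table: dict[str, Role] | None = None):
        self.table = dict(_DEFAULT_TABLE if table is None else table)

    def role_for(self, raw_name: str) -> Role:
        return self.table.get(raw_name, Role(OTHER, raw_name))

    @classmethod
    def from_tsv(cls, path: str | Path, extend_default: bool = True) -> "DomainVocabulary":
        table = dict(_DEFAULT_TABLE) if extend_default else {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\r\n").rstrip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split("\t")]
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected raw_name<TAB>role[<TAB>tag]")
                raw, kind = parts[0], parts[1].upper()
                tag = parts[2] if len(parts) > 2 and parts[2] else None
                table[raw] = Role(kind, tag)
        return cls(table)


DEFAULT_VOCABULARY = DomainVocabulary()


def canonicalize(
    hits: list[DomainHit],
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
    evalue_max: float = 1e-4,
) -> list[Role]:
    """Resolve one protein's domain hits into an N->C ordered role list.

    Hits above the e-value inclusion threshold are discarded; overlapping
    hits are resolved greedily by descending bit-score, discarding the loser
    when the overlap exceeds 50% of the shorter hit.
    """
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    candidates = [h for h in hits if h.evalue <= evalue_max]
    # greedy by descending score; start/name tie-breaks keep it deterministic
    candidates.sort(key=lambda h: (-h.score, h.ali_start, h.raw_name))
    kept: list[DomainHit] = []
    for h in candidates:
        ok = True
        for k in kept:
            overlap = min(h.ali_end, k.ali_end) - max(h.ali_start, k.ali_start) + 1
            if overlap > 0.5 * min(h.length, k.length):
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: (h.ali_start, h.ali_end, h.raw_name))
    return [vocab.role_for(h.raw_name) for h in kept]


def count_transmitters(roles: list[Role]) -> int:
    """Number of transmitter units: a HisKA with a HATPase downstream of it
    before the next HisKA.  A lone HATPase (no HisKA anywhere) does not form
    a transmitter."""
    count = 0
    i = 0
    n = len(roles)
    while i < n:
        if roles[i].kind == HISKA:
            j = i + 1
            paired = False
            while j < n and roles[j].kind != HISKA:
                if roles[j].kind == HATPASE:
                    paired = True
                    break
                j += 1
            if paired:
                count += 1
                i = j + 1
                continue
        i += 1
    return count


def classify(roles: list[Role], has_adjacent_tcs_gene: bool = False) -> tuple[Category, bool]:
    """Apply the decision ladder; returns (category, rescued flag).

    ``rescued`` is True only for a lone-HisKA protein promoted to classic HK
    because its gene sits next to another TCS gene.
    """
    kinds = [r.kind for r in roles]
    n_rec = kinds.count(REC)
    n_trans = count_transmitters(roles)
    has = set(kinds)
    if n_trans >= 1:
        if n_rec >= 1 and HPT in has:
            return Category.UNORTHODOX_HK, False
        if n_rec >= 1:
            return Category.HYHK, False
        return Category.CHK, False
    if HATPASE in has and HPT in has and CHEW in has and HISKA not in has:
        return Category.CHEA, False
    if n_rec >= 1 and HATPASE not in has:
        return Category.RR, False
    if HISKA in has and HATPASE not in has:
        if has_adjacent_tcs_gene:
            return Category.CHK, True
        return Category.PP_HISKA, False
    if HPT in has:
        return Category.PP_HPT, False
    return Category.NONE, False


def rr_family(roles: list[Role]) -> str:
    """Output-domain family of a response regulator.

    A stand-alone REC (no output domain) is CheY; otherwise the family is
    read from the first output domain C-terminal of the first REC.  A protein
    carrying both diguanylate-cyclase (GGDEF) and phosphodiesterase (EAL)
    outputs is PleD-VieA.  Output domains not in the family table fall
    through to ``Unclassified``.
    """
    kinds = [r.kind for r in roles]
    if REC not in kinds:
        raise ValueError("rr_family called on a protein without a REC domain")
    output_tags = [r.tag for r in roles if r.kind == OUTPUT]
    if not output_tags:
        return "CheY"
    if "PleD" in output_tags and "EAL" in output_tags:
        return "PleD-VieA"
    first_rec = kinds.index(REC)
    for r in roles[first_rec + 1 :]:
        if r.kind == OUTPUT:
            return r.tag if r.tag in RR_FAMILIES else "Unclassified"
    return "Unclassified"


# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def tm_count(
    sequence: str, window: int = 19, threshold: float = 1.6, merge_gap: int = 5
) -> int:
    """Predicted transmembrane segment count from Kyte-Doolittle hydropathy.

    Sliding windows of ``window`` residues with mean hydropathy above
    ``threshold`` mark candidate segments; overlapping or near-adjacent
    candidates (< ``merge_gap`` residues apart) are merged.  Non-standard
    residues contribute hydropathy 0 with a warning.  This is an explicit
    stand-in predictor; supply external annotations via the domain-table
    override column when available.
    """
    if not sequence:
        raise ValueError("tm_count requires a non-empty sequence")
    seq = sequence.upper()
    unknown = sorted({aa for aa in seq if aa not in KYTE_DOOLITTLE})
    if unknown:
        warnings.warn(f"non-standard residues {unknown} assigned hydropathy 0")
    vals = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq])
    if len(vals) < window:
        return 0
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    starts = np.nonzero(means > threshold)[0]
    if starts.size == 0:
        return 0
    segments = 0
    prev_end = None
    for s in starts:
        lo, hi = int(s), int(s) + window - 1
        if prev_end is not None and lo - prev_end - 1 < merge_gap:
            prev_end = max(prev_end, hi)
        else:
            segments += 1
            prev_end = hi
    return segments


def localize(tm: int) -> str:
    """Zero transmembrane segments -> cytosolic; one or more -> membrane."""
    if tm < 0:
        raise ValueError("tm count must be >= 0")
    return "cytosolic" if tm == 0 else "membrane"
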