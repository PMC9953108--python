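"""Readers and writers for all external formats.

Inputs per genome are a protein FASTA, gene coordinates (a GFF3 CDS subset or
a 5-column TSV) and domain annotations (hmmscan ``--domtblout`` or a 6-column
TSV).  The tree stage additionally consumes a square ANI matrix as TSV.
Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import AniMatrix, DomainHit, ProteinRecord

COORDS_COLUMNS = ["protein_id", "contig_id", "start", "end", "strand"]
DOMAINS_COLUMNS = ["protein_id", "domain", "ali_start", "ali_end", "score", "evalue"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA -> ordered ``{protein_id: sequence}``; duplicate ids are fatal."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper().rstrip("*")
    return seqs


def _looks_like_gff(path: Path) -> bool:
    if path.suffix.lower() in (".gff", ".gff3"):
        return True
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#"):
                continue
            return len(line.split("\t")) == 9
    return False


def _parse_gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_coords(path: str | Path) -> pd.DataFrame:
    """Gene coordinates as a DataFrame with :data:`COORDS_COLUMNS`.

    Accepts either a GFF3 subset (CDS features; ``ID=`` attribute is the
    protein id) or a plain 5-column TSV with an optional header row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinates file not found: {path}")
    rows = []
    if _looks_like_gff(path):
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\r\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
                if parts[2] != "CDS":
                    continue
                attrs = _parse_gff_attributes(parts[8])
                pid = attrs.get("ID")
                if pid is None:
                    raise ValueError(f"{path}:{lineno}: CDS feature without ID=")
                start, end = int(parts[3]), int(parts[4])
                if start > end:
                    raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
                rows.append((pid, parts[0], start, end, parts[6]))
    else:
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\r\n").rstrip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split("\t")]
                if len(parts) < 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 TSV columns")
                if lineno == 1 and parts[0] == "protein_id":
                    continue  # header
                start, end = int(parts[2]), int(parts[3])
                if start > end:
                    raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
                rows.append((parts[0], parts[1], start, end, parts[4]))
    return pd.DataFrame(rows, columns=COORDS_COLUMNS)


def _looks_like_domtblout(path: Path) -> bool:
    with path.open() as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith("#"):
                return True
            return len(line.split()) >= 22 and len(line.split("\t")) < 6
    return False


def read_domains(
    path: str | Path, coordinates: str = "envelope"
) -> tuple[list[DomainHit], dict[str, int]]:
    """Domain annotations -> (hits, per-protein TM-count overrides).

    Accepts hmmscan ``--domtblout`` (target = domain model, query = protein;
    envelope coordinates by default, ``coordinates='alignment'`` switches) or a
    TSV ``protein_id  domain  ali_start  ali_end  score  evalue`` with an
    optional 7th ``tm_count`` override column carrying external transmembrane
    annotations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"domain file not found: {path}")
    if coordinates not in ("envelope", "alignment"):
        raise ValueError("coordinates must be 'envelope' or 'alignment'")
    hits: list[DomainHit] = []
    tm_overrides: dict[str, int] = {}
    if _looks_like_domtblout(path):
        lo, hi = (19, 20) if coordinates == "envelope" else (17, 18)
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 22:
                    raise ValueError(f"{path}:{lineno}: truncated domtblout line")
                hits.append(
                    DomainHit(
                        protein_id=parts[3],
                        raw_name=parts[0],
                        ali_start=int(parts[lo]),
                        ali_end=int(parts[hi]),
                        score=float(parts[13]),
                        evalue=float(parts[12]),
                    )
                )
    else:
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\r\n").rstrip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split("\t")]
                if lineno == 1 and parts[0] == "protein_id":
                    continue
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: expected >= 6 TSV columns")
                hits.append(
                    DomainHit(
                        protein_id=parts[0],
                        raw_name=parts[1],
                        ali_start=int(parts[2]),
                        ali_end=int(parts[3]),
                        score=float(parts[4]),
                        evalue=float(parts[5]),
                    )
                )
                if len(parts) >= 7 and parts[6] not in ("", "."):
                    tm_overrides[parts[0]] = int(parts[6])
    return hits, tm_overrides


def read_genome_inputs(
    fasta_path: str | Path,
    coords_path: str | Path,
    domains_path: str | Path,
    genome_id: str | None = None,
) -> tuple[list[ProteinRecord], list[DomainHit], dict[str, int]]:
    """Join FASTA sequences, coordinates and domain hits on protein_id.

    Coordinate rows whose protein is absent from the FASTA (and vice versa)
    are skipped with a warning; domain hits on unknown proteins likewise.
    Duplicate protein ids in the coordinate table are fatal (ids are join
    keys).
    """
    genome_id = genome_id or Path(fasta_path).stem
    seqs = read_fasta(fasta_path)
    coords = read_coords(coords_path)
    dup = coords["protein_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate protein ids in {coords_path}: "
            f"{sorted(coords.loc[dup, 'protein_id'])}"
        )
    records: list[ProteinRecord] = []
    seen = set()
    for row in coords.itertuples(index=False):
        if row.protein_id not in seqs:
            warnings.warn(
                f"{coords_path}: protein {row.protein_id!r} has coordinates "
                "but no FASTA sequence; skipped"
            )
            continue
        records.append(
            ProteinRecord(
                protein_id=row.protein_id,
                genome_id=genome_id,
                contig_id=row.contig_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                sequence=seqs[row.protein_id],
            )
        )
        seen.add(row.protein_id)
    missing = set(seqs) - seen
    if missing:
        warnings.warn(
            f"{fasta_path}: {len(missing)} protein(s) lack coordinates; skipped"
        )
    hits, tm_overrides = read_domains(domains_path)
    known = {r.protein_id for r in records}
    kept = []
    for h in hits:
        if h.protein_id not in known:
            warnings.warn(
                f"{domains_path}: domain hit on unknown protein {h.protein_id!r}; skipped"
            )
            continue
        kept.append(h)
    return records, kept, tm_overrides


def read_ani_matrix(path: str | Path) -> AniMatrix:
    """Square ANI TSV (header row and index column of genome ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ANI matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if list(map(str, df.index)) != ids:
        raise ValueError(f"{path}: row and column genome ids differ")
    return AniMatrix(genome_ids=ids, values=df.to_numpy(dtype=float))


def write_ani_matrix(ani: AniMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ani.values, index=ani.genome_ids, columns=ani.genome_ids)
    df.to_csv(path, sep="\t", float_format="%.6g")


CENSUS_TABLES = (
    "genome_summary",
    "organization",
    "sensing_domains",
    "architectures",
    "rr_families",
)


def write_census_tables(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write the five census TSVs plus a JSON run manifest; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in CENSUS_TABLES:
        df = tables.get(name, pd.DataFrame())
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest or {}, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths


def read_census_tables(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out_dir = Path(out_dir)
    tables = {}
    for name in CENSUS_TABLES:
        p = out_dir / f"{name}.tsv"
        if not p.exists():
            continue
        try:
            tables[name] = pd.read_csv(p, sep="\t")
        except pd.errors.EmptyDataError:
            tables[name] = pd.DataFrame()
    return tables


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
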