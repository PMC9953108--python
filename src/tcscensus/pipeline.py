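"""Stage orchestration: classify -> organize -> census -> ortho -> gainloss.

A *panel directory* holds one subdirectory per genome (``proteins.faa``,
``coords.tsv`` or ``coords.gff3``, ``domains.tsv``) and optionally an
``ani.tsv`` matrix for the tree stage.  ``run_pipeline`` executes the stages
in dependency order and writes all result tables plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .census import (
    architecture_census,
    assemble_tables,
    genome_summary,
    organization_summary,
    rr_family_census,
    sensing_census,
)
from .classifier import (
    DEFAULT_VOCABULARY,
    DomainVocabulary,
    canonicalize,
    classify,
    count_transmitters,
    localize,
    rr_family,
    tm_count,
)
from .config import RunConfig
from .context import build_clusters, intergenic_distance, orientation_compatible
from .gainloss import events_summary, infer_events, upgma
from .io import read_ani_matrix, read_genome_inputs, write_census_tables
from .model import (
    REC,
    SENSING,
    Category,
    DomainHit,
    GeneCluster,
    HK_CATEGORIES,
    ProteinRecord,
    TCSProtein,
)
from .orthology import build_families, partition_summary

log = logging.getLogger("tcscensus")


def classify_genome(
    records: list[ProteinRecord],
    hits: list[DomainHit],
    tm_overrides: dict[str, int] | None = None,
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
    config: RunConfig | None = None,
) -> dict[str, TCSProtein]:
    """Classify every protein of one genome; returns protein_id -> TCSProtein.

    Two passes: a provisional pass with the rescue rule off, then a second
    look at lone-HisKA proteins whose immediate genomic neighbor is a
    provisional TCS gene under the cluster rules (gap below the chain
    threshold, compatible orientation) — those are promoted to classic HK
    and flagged ``rescued``.
    """
    config = config or RunConfig()
    tm_overrides = tm_overrides or {}
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)

    roles_of = {
        r.protein_id: canonicalize(
            by_protein.get(r.protein_id, []),
            vocab=vocab,
            evalue_max=config.domain_evalue_max,
        )
        for r in records
    }
    provisional = {
        pid: classify(roles, has_adjacent_tcs_gene=False)[0]
        for pid, roles in roles_of.items()
    }

    # genomic neighbors for the lone-HisKA rescue
    by_contig: dict[str, list[ProteinRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)
    for recs in by_contig.values():
        recs.sort(key=lambda r: (r.start, r.end, r.protein_id))

    def has_adjacent_tcs(rec: ProteinRecord) -> bool:
        siblings = by_contig[rec.contig_id]
        idx = siblings.index(rec)
        for other_idx in (idx - 1, idx + 1):
            if not (0 <= other_idx < len(siblings)):
                continue
            other = siblings[other_idx]
            if provisional[other.protein_id] is Category.NONE:
                continue
            a, b = (other, rec) if other_idx < idx else (rec, other)
            if (
                intergenic_distance(a, b) < config.cluster_max_gap
                and orientation_compatible(a, b)
            ):
                return True
        return False

    out: dict[str, TCSProtein] = {}
    for rec in records:
        roles = roles_of[rec.protein_id]
        category, rescued = classify(roles, has_adjacent_tcs_gene=False)
        if category is Category.PP_HISKA and has_adjacent_tcs(rec):
            category, rescued = classify(roles, has_adjacent_tcs_gene=True)
        tm = tm_overrides.get(rec.protein_id)
        if tm is None:
            tm = (
                tm_count(
                    rec.sequence,
                    window=config.tm_window,
                    threshold=config.tm_threshold,
                )
                if rec.sequence
                else 0
            )
        fam = None
        if category is Category.RR:
            fam = rr_family(roles)
        out[rec.protein_id] = TCSProtein(
            protein=rec,
            category=category,
            roles=roles,
            n_rec=sum(1 for r in roles if r.kind == REC),
            n_transmitter=count_transmitters(roles),
            sensing=[r.tag for r in roles if r.kind == SENSING],
            rr_family=fam,
            tm_count=tm,
            localization=localize(tm),
            rescued=rescued,
        )
    return out


@dataclass
class GenomeResult:
    genome_id: str
    records: list[ProteinRecord]
    proteins: dict[str, TCSProtein]
    clusters: list[GeneCluster] = field(default_factory=list)

    @property
    def tcs(self) -> list[TCSProtein]:
        return [t for t in self.proteins.values() if t.is_tcs]


def analyze_genome(
    records: list[ProteinRecord],
    hits: list[DomainHit],
    tm_overrides: dict[str, int] | None = None,
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
    config: RunConfig | None = None,
) -> GenomeResult:
    """Classification plus genomic-context clustering for one genome."""
    config = config or RunConfig()
    genome_id = records[0].genome_id if records else "genome"
    proteins = classify_genome(records, hits, tm_overrides, vocab, config)
    tcs = [t for t in proteins.values() if t.is_tcs]
    clusters = build_clusters(
        tcs,
        all_records=records,
        max_gap=config.cluster_max_gap,
        break_on_intervening=config.break_on_intervening,
    )
    return GenomeResult(
        genome_id=genome_id, records=records, proteins=proteins, clusters=clusters
    )


def discover_panel(panel_dir: str | Path) -> list[Path]:
    panel_dir = Path(panel_dir)
    if not panel_dir.is_dir():
        raise FileNotFoundError(f"panel directory not found: {panel_dir}")
    dirs = sorted(
        p for p in panel_dir.iterdir() if p.is_dir() and (p / "proteins.faa").exists()
    )
    if not dirs:
        raise FileNotFoundError(f"no genome subdirectories under {panel_dir}")
    return dirs


def load_genome_dir(genome_dir: Path):
    coords = genome_dir / "coords.tsv"
    if not coords.exists():
        for alt in ("coords.gff3", "coords.gff"):
            if (genome_dir / alt).exists():
                coords = genome_dir / alt
                break
    return read_genome_inputs(
        genome_dir / "proteins.faa",
        coords,
        genome_dir / "domains.tsv",
        genome_id=genome_dir.name,
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def proteins_table(results: list[GenomeResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for t in sorted(res.proteins.values(), key=lambda t: t.protein_id):
            rows.append(
                {
                    "genome_id": res.genome_id,
                    "protein_id": t.protein_id,
                    "category": t.category.value,
                    "roles": ";".join(str(r) for r in t.roles),
                    "n_rec": t.n_rec,
                    "n_transmitter": t.n_transmitter,
                    "sensing": ";".join(t.sensing),
                    "rr_family": t.rr_family or "",
                    "tm_count": t.tm_count,
                    "localization": t.localization,
                    "rescued": t.rescued,
                }
            )
    return pd.DataFrame(rows)


def clusters_table(results: list[GenomeResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for c in res.clusters:
            rows.append(
                {
                    "genome_id": c.genome_id,
                    "contig_id": c.contig_id,
                    "members": ";".join(m.protein_id for m in c.members),
                    "size": c.size,
                    "category": c.category,
                    "composition": c.composition,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    panel_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    stages: set[str] | None = None,
) -> dict:
    """Run the requested stages (default: all) over a panel directory."""
    config = config or RunConfig()
    stages = stages or {"classify", "organize", "census", "ortho", "gainloss"}
    panel_dir, out_dir = Path(panel_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome_dirs = discover_panel(panel_dir)
    results: list[GenomeResult] = []
    input_digests = {}
    for gdir in genome_dirs:
        log.info("classifying %s", gdir.name)
        records, hits, tm_overrides = load_genome_dir(gdir)
        results.append(analyze_genome(records, hits, tm_overrides, config=config))
        for f in sorted(gdir.iterdir()):
            if f.is_file():
                input_digests[str(f.relative_to(panel_dir))] = _digest(f)

    summary: dict = {"genomes": [r.genome_id for r in results]}

    if "classify" in stages or "all" in stages:
        proteins_table(results).to_csv(
            out_dir / "tcs_proteins.tsv", sep="\t", index=False
        )
    if "organize" in stages:
        clusters_table(results).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    if "census" in stages:
        summaries, org_rows, sense_rows, arch_rows, rr_rows = [], {}, {}, {}, {}
        for res in results:
            n_cds = len(res.records)
            size_mb = (
                max((r.end for r in res.records), default=0) / 1e6 if res.records else 0.0
            )
            summaries.append(genome_summary(res.tcs, n_cds=n_cds, genome_size_mb=size_mb))
            org_rows[res.genome_id] = organization_summary(res.clusters)
            hks = [t for t in res.tcs if t.category in HK_CATEGORIES]
            sense_rows[res.genome_id] = sensing_census(hks)
            arch_rows[res.genome_id] = architecture_census(hks)
            rr_rows[res.genome_id] = rr_family_census(res.tcs)
        tables = assemble_tables(summaries, org_rows, sense_rows, arch_rows, rr_rows)
        manifest = {
            "tool": "tcscensus",
            "version": __version__,
            "config": config.to_dict(),
            "inputs": input_digests,
        }
        write_census_tables(tables, out_dir, manifest=manifest)

    families = None
    if "ortho" in stages:
        panel = {
            res.genome_id: {t.protein_id: t.protein.sequence for t in res.tcs}
            for res in results
        }
        log.info("building ortholog families over %d genomes", len(panel))
        families = build_families(
            panel,
            identity_min=config.bbh_identity_min,
            coverage_min=config.bbh_coverage_min,
        )
        fam_rows = [
            {
                "family_id": f.family_id,
                "class": f.partition_class(),
                "n_genomes": f.n_genomes,
                "members": ";".join(
                    f"{g}:{p}" for g in f.panel for p in f.members.get(g, [])
                ),
            }
            for f in families
        ]
        pd.DataFrame(fam_rows).to_csv(out_dir / "families.tsv", sep="\t", index=False)
        presence = pd.DataFrame(
            [f.presence for f in families], index=[f.family_id for f in families]
        ).T
        presence.index.name = "genome_id"
        presence.to_csv(out_dir / "presence.tsv", sep="\t")
        summary["partition"] = partition_summary(families)

    if "gainloss" in stages:
        ani_path = panel_dir / "ani.tsv"
        if not ani_path.exists():
            raise FileNotFoundError(
                f"gainloss stage requires an ANI matrix at {ani_path}"
            )
        ani = read_ani_matrix(ani_path)
        tree = upgma(ani)
        (out_dir / "tree.nwk").write_text(tree.to_newick() + "\n")
        if families is None:
            panel = {
                res.genome_id: {t.protein_id: t.protein.sequence for t in res.tcs}
                for res in results
            }
            families = build_families(
                panel,
                identity_min=config.bbh_identity_min,
                coverage_min=config.bbh_coverage_min,
            )
        event_sets = []
        for fam in families:
            pres = fam.presence
            if not any(pres.values()):
                continue
            event_sets.append(
                infer_events(
                    tree,
                    pres,
                    gain_penalty=config.gain_penalty,
                    family_id=fam.family_id,
                )
            )
        ev_rows = [
            {"family_id": es.family_id, "branch": e.branch, "event": e.type}
            for es in event_sets
            for e in es.events
        ]
        pd.DataFrame(ev_rows, columns=["family_id", "branch", "event"]).to_csv(
            out_dir / "events.tsv", sep="\t", index=False
        )
        events_summary(event_sets).to_csv(
            out_dir / "branch_events.tsv", sep="\t", index=False
        )
        summary["n_event_sets"] = len(event_sets)

    return summary
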