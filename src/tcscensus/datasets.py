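"""Published census counts for a 17-genome thermophilic cyanobacteria panel.

The packaged tables record, per genome, the printed TCS category counts
(classic/hybrid/unorthodox HKs, CheA, RRs, phosphotransfer proteins) together
with genome size and CDS count, and the genetic-organization breakdown
(orphan/pair/triad/tetrad/pentad cluster counts).  They serve as reference
inputs for the census arithmetic: totals, ORF fractions,
receiver/transmitter ratios and organization fractions are all recomputed
from these counts, never stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .utils import round_half_up

__all__ = [
    "load_thermophile_summary",
    "load_thermophile_organization",
    "organization_fractions",
    "orf_fractions",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("tcscensus.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_thermophile_summary() -> pd.DataFrame:
    """Per-genome TCS category counts, genome size (Mb) and CDS count."""
    return _load("thermophile_summary.tsv")


def load_thermophile_organization() -> pd.DataFrame:
    """Per-genome orphan/pair/triad/tetrad/pentad cluster counts."""
    return _load("thermophile_organization.tsv")


def organization_fractions(org: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percent of TCS genes in orphan, paired and complex contexts per genome.

    Paired genes count two per pair; complex genes are everything in clusters
    of three or more.  Fractions are percentages rounded half-up to one
    decimal of the genome's TCS gene total.
    """
    org = load_thermophile_organization() if org is None else org
    rows = []
    for r in org.itertuples(index=False):
        total = r.total_tcs
        orphan_genes = r.orphan
        paired_genes = 2 * r.pair
        complex_genes = 3 * r.triad + 4 * r.tetrad + 5 * r.pentad
        assert orphan_genes + paired_genes + complex_genes == total
        rows.append(
            {
                "genome_id": r.genome_id,
                "orphan_pct": round_half_up(100.0 * orphan_genes / total, 1),
                "paired_pct": round_half_up(100.0 * paired_genes / total, 1),
                "complex_pct": round_half_up(100.0 * complex_genes / total, 1),
            }
        )
    return pd.DataFrame(rows)


def orf_fractions(summary: pd.DataFrame | None = None) -> pd.Series:
    """Percent of each genome's CDS devoted to TCS genes (half-up, 1 dp)."""
    summary = load_thermophile_summary() if summary is None else summary
    cats = ["cHK", "hyHK", "uHK", "CheA", "RR", "PP-HisKA", "PP-Hpt"]
    totals = summary[cats].sum(axis=1)
    vals = [
        round_half_up(100.0 * t / n, 1) for t, n in zip(totals, summary["n_cds"])
    ]
    return pd.Series(vals, index=summary["genome_id"], name="orf_fraction")
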