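# tcscensus

A genomic census pipeline for bacterial **two-component signal transduction
systems (TCS)** — the sensor histidine kinase (HK) / response regulator (RR)
pairs that let bacteria sense and respond to their environment.  Given
per-genome protein sequences, gene coordinates and domain annotations, the
package classifies every protein into TCS categories, maps the genomic
organization of TCS genes, tabulates sensing-domain and domain-architecture
repertoires, partitions cross-genome ortholog families into core and
accessory sets, and reconstructs gene gain/loss histories on an ANI-derived
genome tree.  It is aimed at comparative genomicists studying signal
transduction repertoires — for example across panels of thermophilic
cyanobacteria, where TCS expansions track genome size and habitat.

## What it computes

**Classification.** Domain hits are mapped onto canonical roles (HisKA,
HATPase, REC, Hpt, CheW, sensing domains, RR output domains) and each protein
passes a fixed decision ladder:

- a *transmitter unit* is a HisKA with a HATPase downstream of it; one or
  more units make a **classic HK** (cHK), plus a REC domain a **hybrid HK**
  (hyHK), plus both REC and Hpt an **unorthodox HK**;
- HATPase + Hpt + CheW without HisKA is a **CheA**-type chemotaxis kinase;
- REC without HATPase is an **RR**, assigned an output family
  (CheY for stand-alone REC; NarL/OmpR DNA binding; RpfG/PleD/PleD-VieA
  c-di-GMP turnover; RsbU, TrxB, YesN, CyC-C; otherwise *Unclassified*);
- a lone HisKA is rescued to cHK when its gene is adjacent to another TCS
  gene, else it is a phosphotransfer protein (PP), as is a lone Hpt.

**Organization.** Consecutive TCS genes chain into one cluster when the
intergenic distance is < 200 bp, orientation is same-strand or divergent,
and no non-TCS gene intervenes; cluster sizes 1–5 are orphan / pair / triad /
tetrad / pentad, larger are complex-*n*.

**Census statistics.** Per-genome category counts; the ORF fraction
100·(TCS genes)/CDS; the receiver/transmitter ratio
Σ REC(RR, hyHK) / Σ transmitter(cHK, hyHK); sensing-domain occurrence counts
split by cHK/hyHK; S/T/R architecture strings (sensing–transmitter–receiver
order); RR family tables; Pearson correlation of TCS count vs genome size.

**Orthology.** Exact Smith–Waterman alignment (BLOSUM62, affine gaps 11/1);
orthologs are bidirectional best hits with identity > 40% and query coverage
> 75%; families are connected components of the BBH graph, partitioned into
core / accessory / strain-specific, with within-genome duplication flags.

**Gain/loss.** UPGMA on d = 100 − ANI gives an ultrametric genome tree;
per-family presence/absence vectors are explained by minimum-cost binary
ancestral reconstruction (Sankoff DP, gain:loss penalty 2:1, absent root),
yielding per-branch gain and loss counts.

A synthetic-data module generates fully annotated genome panels with planted
categories, clusters, divergence and gain/loss histories plus JSON truth
records, so the whole pipeline is testable without downloads.

## Worked example

```bash
tcscensus simulate --out demo/panel --genomes 4 --core-families 20 \
    --accessory-families 6 --seed 42
tcscensus all demo/panel --out demo/results
```

`demo/results/genome_summary.tsv` then contains, for example:

```
genome_id  n_cds  cHK  hyHK  uHK  CheA  RR  PP-HisKA  PP-Hpt  total_tcs  rt_ratio
G1         21     4    4     3    3     7   0         0       21         1.4
G2         25     5    5     4    4     7   0         0       25         1.2
```

i.e. genome G1 carries 21 TCS genes, and its receivers outnumber its
transmitters 1.4-fold (Σ REC over RRs and hyHKs divided by Σ transmitter
units over cHKs and hyHKs).  The tree and event tables show the inferred
history; for this seed:

```
$ cat demo/results/tree.nwk
((G1:2,G2:2):2,(G3:2,G4:2):2):0;
$ head -3 demo/results/events.tsv
family_id  branch       event
F0000      G1|G2|G3|G4  GAIN
F0000      G3           LOSS
```

family F0000 was gained on the branch above the root (ancestrally present)
and lost on the terminal branch of G3 — exactly the history planted by the
simulator, as `demo/panel/truth.json` records.  The family table partitions
the 26 planted families into 20 core, 3 accessory and 3 strain-specific.

Other outputs: `tcs_proteins.tsv` (per-protein classification, roles,
transmembrane count, localization), `clusters.tsv` (organization with
composition strings such as `RR-RR-hyHK-hyHK-hyHK`), `organization.tsv`,
`sensing_domains.tsv`, `architectures.tsv`, `rr_families.tsv`,
`families.tsv`/`presence.tsv`, `branch_events.tsv`, and a `manifest.json`
recording configuration and input digests.

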