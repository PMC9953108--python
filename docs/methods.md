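# Methods

This note documents the models and procedures implemented in `tcscensus`,
the defaults chosen where the underlying biology admits several readings,
and what the synthetic-data tests do and do not demonstrate.

## Protein classification

Raw domain names are first canonicalized against a vocabulary mapping
Pfam-style names onto roles: HisKA/HisKA_2/HisKA_3 → HISKA, HATPase_c →
HATPASE, Response_reg → REC, Hpt → HPT, CheW → CHEW; sensing domains carry a
tag (PAS and PAC are counted jointly as PAS; CHASE/CHASE2/CHASE3 collapse to
CHASE; Cache_1/Cache_2 to Cache; S_TKc and Pkinase are kept distinct); RR
output domains carry a family tag (GerE → NarL, Trans_reg_C → OmpR,
CheB_methylest → CheB, HD → RpfG, GGDEF → PleD, PP2C → RsbU, Pyr_redox →
TrxB, HTH_AraC → YesN, Guanylate_cyc → CyC-C).  The table is overridable
from a TSV because domain databases name these families inconsistently.

Hits with e-value above the inclusion threshold (default 1e-4, a
conservative proxy for the unpublished cutoffs of upstream annotation
servers) are dropped; overlapping hits are resolved greedily by descending
bit score, discarding the loser when the overlap exceeds half the shorter
hit.  The classification ladder (see README) is a total function; the only
context-dependent rule is the lone-HisKA rescue, for which adjacency means:
the nearest gene on the contig is itself a (provisionally classified) TCS
gene, within the cluster gap threshold and orientation rules.  The rescued
kinase is flagged, since its transmitter count stays 0.

An unorthodox HK is defined as transmitter + REC + Hpt on one protein, the
standard usage for multi-step phosphorelay kinases; the category boundary is
an assumption the upstream literature leaves implicit, and it is isolated in
one ladder branch should a different reading be preferred.

`rr_family` reads the family from the first output domain C-terminal of the
first REC; a protein carrying both GGDEF and EAL outputs is PleD-VieA
(composite diguanylate cyclase/phosphodiesterase); a lone EAL output is not
itself a named family and falls to Unclassified.

## Transmembrane prediction

Cellular localization is evaluated from predicted transmembrane helices:
zero segments → cytosolic, otherwise membrane.  The predictor is a
deliberately simple hydropathy scan — Kyte–Doolittle values averaged over a
19-residue window, windows with mean > 1.6 marking candidates, candidates
closer than 5 residues merged — because the intended use is coarse
(membrane vs cytosolic), and because external annotations, when available,
can be supplied per protein through the domain-table override column and
take precedence.  The 19/1.6 window/threshold pair is the classical
hydropathy setting for membrane-spanning segments.  This stand-in is not a
topology predictor and will miss marginally hydrophobic helices.

## Genomic organization

Clusters are maximal chains of consecutive TCS genes on one contig with
pairwise intergenic distance strictly below 200 bp, pairwise-compatible
orientation (same strand, or divergent `← →`; convergent `→ ←` breaks, the
only arrangement the same-or-divergent rule excludes) and no intervening
non-TCS gene (configurable off).  The orientation rule is applied pairwise
along the chain rather than to the whole cluster — with divergence allowed
only at the chain's strand switch from − to +, the two readings differ only
in rare multi-switch chains.  Overlapping genes have negative intergenic
distance and always chain.  Chains never span contigs.

## Census statistics

The receiver/transmitter ratio divides REC domains carried by RRs and
hybrid HKs by transmitter units carried by classic and hybrid HKs; it is a
domain-level (not protein-level) count, so a two-REC hybrid kinase
contributes two receivers.  Unorthodox HKs and CheA-type kinases are
excluded from both sums.  Ratios and fractions are rounded half-up to one
decimal, matching printed-table precision; a zero transmitter sum reports
NA.  Architecture strings reduce a kinase N→C to S/T/R tokens (sensing /
transmitter unit / receiver); the sensing census counts domain occurrences,
not proteins.  Pearson correlation is the standard product-moment statistic
with a two-sided t-test p-value (scipy).

The package ships a reference table of published census counts for a
17-genome thermophilic cyanobacteria panel; all derived quantities (totals,
ORF fractions, organization fractions, ratio extremes) are recomputed from
the counts at run time.

## Orthology

Panel sizes here are hundreds of TCS proteins, so exact Smith–Waterman
local alignment (BLOSUM62; first gap residue −11, each further residue −1)
replaces heuristic database search.  Identity is identical pairs over
aligned columns — gap columns count in the denominator, which is stricter
than identity-over-alignment-length conventions; adapters feeding external
tabular alignments should normalize to this definition.  Query coverage is
the fraction of the query spanned by the local alignment.  Because
co-optimal local alignments exist, the reported identity is computed on the
lexicographically sorted sequence pair, making all derived statistics
symmetric and deterministic.

Bidirectional best hits require identity > 40 and query coverage > 75
(strict, both directions, each direction's own coverage); ties break by
higher identity, then lexicographic subject id.  Families are connected
components of the union BBH graph over all genome pairs — the weakest
faithful formalization of "most probable ortholog sets"; a single-reference
scheme would only be narrower.  Strict reciprocity means within-genome
duplicates do not join a family through each other; `find_duplicates` flags
within-genome family members above an identity threshold (default 95%;
100% reproduces a single-acquisition-then-duplication signature).

## Genome tree and gain/loss inference

UPGMA is run on d = 100 − ANI with size-weighted arithmetic-mean linkage;
the merged node sits at height d/2, so the tree is ultrametric by
construction.  Distance ties merge the pair with the lexicographically
smallest combined member list, making the topology independent of input
order.  The implementation is local (a few dozen lines) because the
tie-break and d/2 height conventions must be documented and deterministic;
it is cross-checked against scipy's average-linkage heights in the tests.

Gain/loss histories use Sankoff dynamic programming over binary ancestral
states with asymmetric penalties: gain 2, loss 1 (acquisitions are treated
as rarer than losses; the ratio is configurable, and a gain penalty of
infinity yields strict Dollo parsimony).  The root's parent is fixed absent,
so every family requires at least one gain — core families receive a single
gain on the branch above the root, mirroring ancestral presence.  Multiple
independent gains are permitted whenever cheaper.  Ties resolve by the
lexicographic objective (total cost, number of gains, sum of event depths),
i.e. toward fewer gains, then toward events nearer the root; the DP is
verified against exhaustive enumeration of ancestral state assignments.
Replaying any returned event set from the root reproduces the leaf presence
vector exactly; this is asserted inside `infer_events` itself.

## Synthetic data

The generator emulates annotated genome panels: planted proteins are random
hydrophilic amino-acid chains with 55-residue domain segments at the
annotated coordinates (hydrophobic 25-mers only where transmembrane
segments are planted), genes laid out with controlled intergenic gaps and
strands, clusters separated by 500 bp so the chain rule cannot bridge them.
Panels evolve each family's root sequence down a Newick guide tree by
i.i.d. substitutions at the branch rate (expected substitutions/site);
presence/absence follows planted event lists validated by replay; the ANI
matrix derives from patristic distance t via ANI = 100 − min(30, 100·t), a
fixed monotone map recorded in the truth file — only the ordering matters
for UPGMA recovery.  Default panels for recovery testing use 4 genomes with
60 families (48 core, 12 accessory split between terminal losses and
terminal gains) at 0.02 substitutions/site per merge level, sizes at which
the full pipeline runs in well under two minutes on one CPU.

What passing recovery tests show: the classification ladder, chain rules,
BBH family construction and parsimony reconstruction are internally
consistent and exact on noise-free, indel-free, single-copy inputs whose
divergence respects the thresholds.  What they do not show: robustness to
real annotation noise (missed or spurious domain hits), indels and domain
shuffling, assembly fragmentation, paralogy beyond simple duplications, or
HGT donors — the generator does not model codon-level evolution, genome
rearrangement, or realistic intergenic length distributions.

## Degenerate inputs and numerical conventions

Coordinates are 1-based inclusive (GFF3 convention) in every format.
Envelope coordinates are the domtblout default (conservative extent);
alignment coordinates are available by option.  Duplicate protein ids are
fatal (they are join keys); unmatched coordinate or domain rows warn and
skip.  ANI matrices must be symmetric to 1e-9 with a diagonal of exactly
100.  Empty alignments (no positive-scoring cell) report score, identity
and coverage of 0.  All randomness flows from explicit integer seeds;
reruns are byte-identical.
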