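# Methods

## Scope and data model

`hlamatch` characterises HLA compatibility of unrelated patient–donor pairs
typed at two-field resolution over HLA-A, -B, -C, -DRB1, -DQB1 and -DPB1.
The unit of analysis is the pair; a cohort is a TSV with one row per pair
carrying the twelve genotypes plus transplant year, months from diagnosis
to transplant, and a PTCy (post-transplantation cyclophosphamide) flag.
Pairs with missing or one-field typing at any locus are excluded at load
and the exclusions reported — the same availability filter that defines
registry cohorts, made auditable.

## Nomenclature

Allele names follow the WHO convention `LOCUS*FF:FF[:FF[:FF]][SUFFIX]`.
Names are truncated to two fields (synonymous and non-coding variation is
irrelevant at the protein level used here) with a provenance flag.
One-field names parse but are rejected for pair annotation; the parser does
not silently upgrade low-resolution typing.  Of the expression suffixes,
only `N` (null) changes behaviour: a subject carrying a null allele is
treated as homozygous for the partner allele, because a non-expressed
product can neither present peptide nor act as an alloantigen.  A genotype
with two null alleles expresses nothing at the locus; there is no
defensible convention for it, so the library raises rather than guesses.

## Mismatch enumeration and grades

The mismatch count at a locus is `2 − m`, with `m` the size of a maximum
matching between the two 2-element allele multisets under two-field
equality.  With two alleles per subject only the two perfect pairings need
comparing; ties are broken by preferring the pairing that aligns identical
first fields, then lexicographically, so the unmatched-pair assignment
feeding the landscape tables is deterministic.  Direction vectors use set
semantics — a patient allele enters the GvH vector only if absent from the
donor's genotype — which is what makes homozygous-versus-heterozygous
constellations single-direction mismatches.  Any unshared allele counts
toward the grade regardless of direction.

Grades: `grade10 = 10 − Σ mismatches` over A/B/C/DRB1/DQB1;
`grade12 = grade10 + (2 − DPB1 mismatches)`; categories 10/10, 9/10, 8/10,
<8/10.  8/10 pairs are decomposed into two-locus versus single-locus-double
mismatches and by class mix (class I = A/B/C).  A single mismatch is
*low-resolution (antigen-level) matched* iff its two unshared alleles share
the first field.

Transplant eras are pre-2011, 2011–2015, 2016–2020 and 2021–2022; later
years raise, since the modelled cohorts end in 2022.

## Reference tables

* **P-groups** are read from the IPD-IMGT/HLA `hla_nom_p.txt` dialect
  (`LOCUS*;allele/.../allele;GROUP`, `#` comments, empty group = singleton),
  reduced to two fields.  Alleles absent from every group are their own
  singleton group, making the mapping total.  The packaged file is a
  curated miniature; users should substitute the full release file for
  production analyses.
* **Model tables** (DPB1 TCE groups, core/non-core TCE3, rs9277534
  expression linkage, B-leader −21 residues, PBM groups) ship as two-column
  TSVs.  They are curated knowledge from the immunogenetics literature, not
  computable from first principles here; computing TCE groups from
  functional-distance scores or PBM groups from immunopeptidome clustering
  is out of scope.  The packaged tables cover the alleles used by the
  packaged pools and tests.  The B-leader assignments keep threonine as the
  majority variant, so the dominant shared genotype in simulated cohorts is
  TTT, as in registry data; exact residues for rare alleles should be taken
  from a complete curated table.  Any lookup miss yields `unknown` and
  propagates to an explicit NA verdict — never a silent default.

## Functional models

* **ARD matching**: a mismatch is ARD-matched iff every unshared pairing
  lies within one P-group (identical antigen-recognition domain).
* **PBM-GvH matching** (single A/B/C/DRB1 mismatches): matched iff every
  patient allotype's PBM group occurs among the donor's; NA whenever any of
  the four allotypes lacks a PBM assignment.  Since P-group identity
  implies identical binding motifs, ARD-matched pairs are forced
  PBM-matched, keeping the containment `ARD ⊂ PBM` exact even for alleles
  missing from the PBM table.
* **B-leader** (single B mismatches): matched iff both unshared alleles
  carry the same −21 residue; the genotype string concatenates shared,
  patient-mismatched and donor-mismatched residues (e.g. `TTT`).
* **TCE** (DPB1): each subject's most immunogenic group is the minimum TCE
  group over their two alleles; equal minima = permissive, patient lower =
  non-permissive GvH, donor lower = non-permissive HvG; no DPB1 mismatch =
  allele-matched.
* **Core/non-core TCE3** (permissive pairs): considering the unshared
  alleles on each side — all core ⇒ *core permissive*; a non-core TCE3
  allele only among the patient's ⇒ *non-core permissive GvH* (the graft
  faces it); only among the donor's ⇒ *non-core permissive HvG*.  The
  residual *other permissive* covers non-core alleles on both sides and
  permissive mismatches that are not TCE3-vs-TCE3 (e.g. both minima in
  group 1).  The source literature leaves the residual handling open; this
  rule was chosen because it is directional, deterministic, and partitions
  the permissive set into exactly the five categories reported in registry
  tables.
* **Expression** (DPB1): applicable to pairs with a single DPB1 mismatch
  possessing a GvH vector; the verdict is the rs9277534 linkage (G → high,
  A → low) of the patient's mismatched allele.  The applicability rule is
  recorded in output metadata; double mismatches, GvH-vector-less single
  mismatches and unknown linkage give NA.
* **TPHE**: TCE-permissive AND high-expression; NA if either input is
  NA/unknown.

## Cohort summarisation

Allele frequencies are direct counts over 2N chromosomes per role.
Mismatch-combination tables are keyed by ordered (donor allele, patient
allele) pairs of single-mismatch pairs, with frequencies relative to the
number of pairs mismatched at that locus; DPB1 landscapes are computed
separately within the 10/10 and 9/10 strata.  An unordered (direction-free)
view supports aggregations over named combinations.  The representation
ratio of an allele is its frequency among unshared mismatch alleles divided
by its cohort frequency; values below 1 flag the depletion of common
alleles that donor selection produces.  Class-level and overall rates are
count-weighted means of locus rates.  Percentages are rounded half-up to
one decimal, the registry-table convention.

## Inference

Diagnosis-to-transplant times are compared across the eight era × matching
groups by a tie-corrected Kruskal–Wallis omnibus test (scipy) followed by
Dunn's post hoc z on pooled mid-ranks,

`z = (R̄_a − R̄_b) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_a + 1/n_b))`,

implemented here because no installed library provides Dunn's procedure;
tests verify it against a direct rank-sum oracle.  The adjustment family
defaults to the four within-era 10/10 vs <10/10 contrasts — the only
contrasts of interest — with the classical Dunn (Bonferroni-type)
correction; other statsmodels adjustment methods are selectable.
Significance is declared at adjusted p < 0.01.  Contrasts against empty
groups are reported as undefined rather than dropped.

## Synthetic cohort generator

The generator emulates the forces that shape registry cohorts:

* **Haplotype structure.**  Genotypes are two haplotypes drawn
  independently (haplotype-level Hardy–Weinberg) from a frequency-weighted
  six-locus pool; LD is whatever the pool encodes.  The `euro-toy` pool
  (17 haplotypes) mirrors common European extended haplotypes and places
  the allele pairs that dominate real mismatch landscapes
  (DRB1\*14:01/14:54, C\*03:03/03:04, DRB1\*11:01/11:04, DRB1\*04:01/04:04)
  on similar backgrounds, so their mismatches are enriched.  A
  `marginal_mode` switch discards LD as a null model.
* **DQ–DP recombination hotspot.**  Per transmitted chromosome the DPB1
  allele is redrawn from the locus marginal with probability 0.8
  (`dpb1_recombination`), reflecting the crossing-over hotspot that
  decouples DPB1 from the extended haplotype — the reason most otherwise
  10/10-matched real pairs are DPB1 mismatched.
* **Donor selection.**  The donor is the best candidate (by grade10, then
  grade12, ties to the first drawn) among `registry_size` independently
  drawn registry genotypes; 200 by default, deep enough that about three
  quarters of simulated transplants are 10/10 matched, as in real
  registries.  `random` and `grade-threshold` policies provide nulls.
* **Clinical metadata.**  Era weights default to the observed registry era
  mix (9/18/49/24% for pre-2011 through 2021–2022); PTCy adoption rises by
  era (0/3/12/25%); waiting time is log-normal (shape 0.6) with medians by
  matching status and era — 11.3 vs 14.9 months pre-2011 narrowing to 7.4
  vs 8.1 in 2021–2022, the reported early-era gap shrinking over time, with
  mid-era medians interpolated.

Determinism: one `numpy` generator seeded from the config; a fixed seed
yields a byte-identical cohort file.

What the generator does **not** emulate: real-world haplotype diversity
(thousands of haplotypes, not 17), population mixtures and ancestry
effects, within-haplotype recombination at the main loci, typing errors or
nomenclature drift, and centre-level selection practice.  Passing the
simulation-based tests therefore shows the pipeline's *operations* behave
correctly under controlled conditions — not that the generator reproduces
real mismatch frequencies.  Consequently the simulated category mix is more
extreme than a real cohort's (mismatched pairs concentrate in <8/10 rather
than 9/10, because a shallow toy pool leaves little room for near-misses).

## Problem sizes and numerical choices

Test simulations use cohorts of 600–4,000 pairs and registry searches of
1–200 candidates, sizes at which the checked properties (closed-form 10/10
fraction under random pairing at 4 equifrequent haplotypes = 7/64,
monotonicity in registry depth, representation-ratio depletion,
median recovery, type-I calibration of the within-era contrast at 500
replicates) are comfortably resolved against their Monte-Carlo error.
Exhaustive oracles cover all 625 allele 4-tuples for mismatch counting and
all 1,296 ordered DPB1 genotype pairs for TCE classification.  Published
registry counts are reproduced exactly to one decimal through the
summarisation operations.  Ties in rank statistics use mid-ranks with the
standard tie correction; empty denominators yield NaN flagged as
undefined, never 0.
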