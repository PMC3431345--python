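# Methods

## Scope and model

The package analyses the evolution of heteromeric protein–protein
interfaces at the resolution of residue–residue contacts. Two
homologous complexes are compared through a per-chain residue
correspondence; the contact networks of their interfaces are then
compared type by type. All statistics are restricted to residues that
have an equivalent in the partner complex, so alignment gaps never
masquerade as evolutionary contact loss.

### Interface and sub-regions

A residue belongs to the interface if it gains at least one structural
neighbour on complexation or makes at least one inter-chain atomic
contact. Structural neighbours are residue pairs whose Cβ atoms (Cα for
glycine) lie within 8 Å; extended neighbours use 10 Å. The burial index
maps the extended-neighbour count n to 0 for n ≤ 15, 1 for n ≥ 24 and
(n−15)/9 in between, computed once for the isolated chain and once for
the complex. Core residues gain more than 0.5 of burial index on
binding; support residues are buried in both states (mean index > 0.6);
everything else is rim. Boundary comparisons are strict, exactly as the
thresholds are written. The interface geometric centre is the centroid
of the interface residues' Cβ/Cα reference points (both chains pooled);
per-residue distances to it are normalised so the interface maximum is
exactly 1. Reference points rather than all atoms keep the centroid
consistent with the neighbour definitions.

The gained-neighbour criterion uses the 8 Å radius (the term
"structural neighbour" is defined at 8 Å; the 10 Å relation exists only
to feed the burial index).

### Solvent accessibility and anchors

SASA is computed with a Shrake–Rupley-style sphere-sampling method:
each heavy atom's expanded sphere (van der Waals radius + 1.4 Å probe)
is sampled with a deterministic Fibonacci-spiral point set, and a point
is buried if it falls inside any neighbour's expanded sphere. The
point set makes the computation seed-free; at 960 points an isolated
sphere is recovered to well under 1%, and the pipeline default of 240
points keeps per-complex cost low while leaving per-residue buried
areas accurate to a few Å². Radii are a fixed element table (C 1.70,
N 1.55, O 1.52, S 1.80 Å); reference SASA programs use slightly
different per-atom-type radii, so small systematic offsets against them
are expected. Waters and hydrogens are excluded everywhere;
hetero-residues without a Cα are excluded from SASA and contacts by
default (configurable), since their contribution to burial is
tool-dependent in the literature this follows.

ΔrASA of a residue is its SASA in the isolated chain minus its SASA in
the complex. Anchors are up to three core/support residues with
ΔrASA > 80 Å², ranked by ΔrASA, pooled across both chains (an
`anchors_per_chain` switch selects per-chain instead). Ties break
deterministically by chain id and residue number.

### Typed contacts

Atomic contacts are inter-chain heavy-atom pairs within 5.0 Å. This is
a deliberate simplification: the original analyses of this kind use an
α-shape (Delaunay-filtered) contact construction, which prunes pairs
whose contact is occluded by a third atom. A distance cutoff is
reproducible and dependency-free, and the conservation statistics
compare *relative* contact sets between two complexes computed the same
way, which buffers most of the systematic difference. Absolute per-
interface contact counts are therefore not comparable to α-shape-based
counts, and the per-complex reports should be read with that in mind.

Charged contacts join a side-chain nitrogen of Arg/Lys/His (His counted
as a positive donor) to a side-chain oxygen of Asp/Glu within 5.5 Å by
default; the literature is split between 5.5 and 6 Å for this relaxed
threshold, so 6.0 Å is available by flag and neither is guessed as
"intent". Salt bridges are the same pairs at 3.5 Å, which nests them
inside charged contacts by construction.

Hydrogen bonds use donor/acceptor heavy-atom typing over the 20 amino
acids, a donor–acceptor distance ≤ 3.5 Å and an antecedent–donor–
acceptor angle ≥ 90°, with hydrogen positions never required (crystal
structures usually lack them). Pairs where both atoms are backbone N/O
are excluded from all reports. When a donor's tabulated antecedent atom
is missing from the model, the nearest heavy atom of the same residue
stands in; with no antecedent at all the angle test is waived.

Apolar contacts are pairs of carbon/sulfur atoms of interface residues
within 4.5 Å, where both atoms must be solvent-exposed in the isolated
chain (monomer SASA > 0) and belong to side chains. The side-chain
restriction is this package's analogue of the α-shape surface
restriction: under a plain distance rule, the exposed backbone Cα/C
atoms present in every residue would chain unrelated surface regions
into a single component, which the α-shape surface naturally prevents.
A `include_backbone_apolar` flag restores the permissive behaviour. Any
residue type may contribute apolar atoms — lysine and arginine aliphatic
carbons count, as they should.

### Apolar patches, bundles, random patches

Patches are connected components of the per-chain graph on apolar
surface interface atoms with edges at ≤ 5.5 Å (one probe diameter
beyond van der Waals touching, approximating α-shape connectivity with
a 1.4 Å radius expansion); components need at least four atoms from at
least two residues. For cross-interolog comparison, patches are
iteratively merged until each patch overlaps (shares aligned residues
with) at most one patch in the partner complex; merged patches carry
the union of members and a provenance list. Two facing patches with at
least one apolar contact between them form a bundle; bundle-level
conservation treats each patch pair as one edge weighted by its apolar
atomic-contact count, with the same averaging rule as atomic contacts.

Random patches are the null model: for each real patch, a connected
patch of identical atom count is grown over the residue-adjacency graph
from a random seed residue, rejection-sampled (up to 1000 tries) toward
matching the real patch's core/support/rim composition within ±1
residue per class, and by default seeded only at residues that face the
partner side within apolar-contact reach. Growth is reproducible given
the seed; the last residue added is trimmed to the exact atom count,
keeping the atoms nearest the grown patch.

### Conservation statistics

For each contact type, conservation is the weighted Jaccard ratio
C/(C+N): edges present in both complexes (after mapping through the
correspondence) contribute the average of their two weights to C;
one-sided edges contribute their own weight to N. Atomic and apolar
edges are weighted by atomic-contact counts; charged contacts, salt
bridges and hydrogen bonds are unweighted (weight 1 per residue-pair
edge), since count-weighting is only meaningful for the dense contact
classes. An empty-versus-empty comparison is reported as missing, not
as zero, so pooled averages are not dragged down by interfaces that
simply lack a contact type. The weighting rule is symmetric, so
swapping the two interologs leaves every ratio unchanged.

A residue switches out when it is at the interface in one complex and
its equivalent exists but is not at the interface in the other;
unmapped residues are excluded. A conserved salt-bridge position pair
whose two charges swapped signs is a charge exchange and still counts
as conserved. For each salt bridge lost between complexes, every
endpoint whose equivalent is still charged is assigned the first
matching fate in the order: switched out; another interface salt
bridge; an intra-chain salt bridge; an inter-chain charged contact; an
intra-chain charged contact; other. The order is a design choice (the
categories are reported in the source analyses without a stated
precedence) and runs from the strongest to the weakest compensation.

Minimum interface identity is computed per chain pair over positions
that are mapped and at the interface in both complexes (intersection
rule; the union variant would mix in positions with no counterpart
interface environment), then the minimum over the two chains is binned
into [0,30), [30,50), [50,70), [70,100].

### Predictors

Each mapped interface residue with at least one mapped contacting
residue gets six features: BLOSUM62 score of the residue against its
equivalent; mean BLOSUM62 score of its contact environment (all
residues in atomic contact with it, in the reference complex); overall
minimum interface identity in percent (0–100, matching the magnitude of
the published per-percent coefficient); sub-region dummies with core as
reference; atomic-contact count in the reference complex (a pair-average
variant is available); and normalised centre distance. Residues with no
contacts have an undefined environment score and are excluded with a
warning.

Both published coefficient presets are shipped verbatim. Refitting uses
maximum likelihood (statsmodels, Newton/IRLS, tolerance 1e−8); perfect
separation raises with a diverging-coefficient report. ROC AUC is the
Mann–Whitney probability estimate with ties at half credit; feature
importance is the drop-one deviance increase; train/test splits operate
at the couple level (all residues of a couple stay together), repeated
with a seeded generator.

The outcome for the contact-conservation model labels a residue 1 when
at least 50% of its mapped atomic-contact weight is conserved. The
binarisation rule is not printed anywhere authoritative, so the
threshold is configurable (`conservation_threshold`).

### Resampling statistics

Confidence intervals on pooled means use the half-sample bootstrap:
draw ⌊n/2⌋ values without replacement 1000 times and take the
2.5th/97.5th percentiles of the resampled means (plain percentile
intervals, not BCa — matching the procedure being reproduced). Note
that for without-replacement half-samples the normal-theory width
carries the finite-population correction (n−k)/(n−1) ≈ 1/2, i.e. it is
≈ 2·1.96·σ/√n, narrower than the with-replacement half-sample formula.
Distribution comparisons use the two-sided Wilcoxon/Mann–Whitney
rank-sum test via scipy. Every stochastic operation takes an explicit
seed; nothing draws from global random state.

## The synthetic-data generator

Real structural interologs cannot be shipped with the package, so the
generator builds lattice pseudo-complexes on which every detector can
be validated against planted ground truth.

Each chain is a 9×9 interface layer of residues at 5.2 Å spacing with
pseudo side chains pointing across a 7.8 Å gap at the partner chain,
plus a backing layer 4.6 Å behind it that gives interface residues a
realistic monomer burial (interior residues classify as core, the
periphery as rim). Default residues are glycines whose backbone O
protrudes so that each facing pair shares exactly one atomic contact
(4.6 Å). Planted at interior cells, with exclusion margins so features
never interfere: Lys–Glu salt bridges (NZ–OE1 at 3.0 Å), Ser–Ser
hydrogen bonds (OG–OG at 3.3 Å with valid antecedent geometry), a 2×2
block of facing leucines whose side-chain carbons form one connected
patch per side in apolar contact across the gap (4.2 Å), isolated
leucine pairs providing apolar contacts outside any patch, and one
anchor: a phenylalanine stalk protruding into a four-leucine pocket on
the partner side, burying ≈ 108 Å² (> 100 Å², the regime described for
dominant anchors). Per-residue lateral jitter (± 0.15 Å) is applied
with a seeded generator; the geometry margins are chosen so no planted
relation can flip under jitter, making generation fully deterministic
given (spec, seed).

A derived interolog applies three event classes to a copy:

- **Substitutions** (rate per eligible default cell) relabel the
  residue identity with BLOSUM62-weighted target probabilities
  (∝ exp(score/2), excluding self). Geometry is not rebuilt, so
  substitutions act on the sequence-similarity features and charge
  typing; typed-contact changes come from the geometric events.
  Charge-fate scenarios are exercised in tests on hand-built miniature
  complexes instead.
- **Switching out** displaces the whole residue away from the
  interface plane so it loses both interface criteria. Because a
  default residue's partner has no other interface link, the partner's
  tip is simultaneously redirected toward a lateral neighbour
  (displacement ≤ 2.6 Å), forming a replacement contact that keeps the
  partner at the interface — without this, every switch would drag its
  partner out and double the realised rate. When no valid redirection
  target exists the switch is cancelled. The realised switched set
  therefore equals the planted set exactly, and the planted count is
  Binomial(n_eligible, switch_rate). An optional `rim_bias` restricts
  eligibility to the lattice periphery, mimicking the concentration of
  switching in the rim.
- **Rewiring** displaces side-chain tip atoms laterally by 2.5 Å,
  which severs the residue's contacts (and occasionally forms diagonal
  ones) while the residue stays at the interface — isolating contact
  plasticity from switching out. Planted patch residues are spared by
  default (`spare_planted_patches`), so patch bundles survive arbitrary
  peripheral rewiring, reproducing the bundle-versus-residue-level
  conservation gap directionally.

What the generator does *not* emulate: real amino-acid composition,
secondary structure, side-chain packing and energetics, water-mediated
interactions, and the α-shape contact topology of real interfaces.
Passing tests therefore demonstrate that the statistical machinery is
correct and self-consistent, not that database-scale numbers from real
structure sets are reproduced; the pipeline accepts real PDB/mmCIF
input for that purpose.

The feature-table simulator draws the six features from fixed
distributions (BLOSUM62 scores of uniform random residue pairs;
environment similarity N(1.5, 1.5²); identity U(10,100); region
categorical core .25 / support .25 / rim .50; contacts 1+Poisson(8);
centre distance U(0,1)), computes probabilities from a coefficient
preset and draws Bernoulli labels.

## Problem sizes and defaults

The default toy complex has 324 residues / ~1,400 heavy atoms; one full
per-complex analysis (two SASA contexts at 240 points, all contact
types, patches) takes well under a second, so the test suite and the
examples use the standard toy throughout. Coefficient-recovery runs
simulate 200,000 residues per model, the size at which every recovered
coefficient resolves to a few thousandths — comfortably inside three
standard errors of the published values.

## Known limitations

- Distance-cutoff contacts over-count relative to α-shape contacts;
  absolute contact statistics are not comparable across methods.
- Sequence-based correspondence cannot recover the structure-based
  alignments used for remote homologs (below ~30% identity); supplying
  curated alignments is first-class and preferred there.
- The SASA point sampling (240 default) quantises per-atom areas in
  ~0.5 Å² steps; raise `sasa_points` for publication-grade ΔrASA.
- Hydrogen-bond detection without hydrogens cannot resolve donor
  tautomers (His) or distinguish O–H···O directionality; typing is
  deliberately permissive.
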