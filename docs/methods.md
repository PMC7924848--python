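# Methods

## Pathway model

The model encodes the nine-step constitutive lipid A synthesis chain as
an ordered list of (enzyme, EC, substrate, product) steps:

| # | enzyme | EC | product |
|---|--------|-----|---------|
| 1 | LpxA | 2.3.1.129 | UDP-3-acyl-GlcNAc |
| 2 | LpxC | 3.5.1.108 | UDP-3-acyl-GlcN |
| 3 | LpxD | 2.3.1.191 | UDP-2,3-diacyl-GlcN |
| 4 | LpxH | 3.6.1.54 | lipid X |
| 5 | LpxB | 2.4.1.182 | lipid A disaccharide 1-P |
| 6 | LpxK | 2.7.1.130 | lipid IVA |
| 7 | WaaA | 2.4.99.12 | KDO2-lipid IVA |
| 8 | LpxL | 2.3.1.241 | KDO2-lipid A (penta) |
| 9 | LpxM | 2.3.1.243 | KDO2-lipid A (hexa) |

Products are tokens with ranks 0–9 (0 = no pathway); no chemistry —
structures, masses, stoichiometry (including the two KDO residues WaaA
transfers) — is modeled, because nothing downstream consumes it. The
LpxL and LpxM products get distinct tokens (`KDO2-lipid-A-penta`,
`KDO2-lipid-A`) so acylation is recoverable from the terminal token
alone. The nonstandard EC spellings `2.499.12`, `23.1.241`, `23.1.243`
that circulate for the last three enzymes are kept as aliases of the
standard forms.

**Terminal product.** A taxon's credited complement is walked from step
1; the terminal product is the product of the deepest step k whose whole
prefix 1..k is present-or-skippable *and* whose own enzyme is literally
present. Only LpxH is skippable by default (several organisms bypass the
lipid-X-forming hydrolysis via alternative enzymes); requiring presence
at step k means the bypass is only credited when a post-bypass enzyme
exists, so a complement ending just before LpxH terminates at the
UDP-2,3-diacyl-GlcN stage. The skip set is configurable
(`PathwayModel.skip_allowed`), and pathway variants can be supplied as
JSON without code changes. The implementation is verified against an
independent brute-force prefix walker on all 512 complements under both
skip policies, and terminal rank is provably monotone under set
inclusion (checked exhaustively).

**Acylation/phosphorylation.** For complements reaching at least lipid
IVA: hexa-acyl if LpxM is credited, else penta if LpxL, else tetra; two
phosphates minus one per credited LpxE/LpxF phosphatase. The
immunostimulant class is `high` exactly for hexa-acyl + bis-phosphate,
`reduced` otherwise. Whether the final stage ordering places KDO
transfer before the late acylations varies across organisms; the model
fixes the KEGG-style order (WaaA before LpxL/LpxM) and does not attempt
organism-specific reordering.

## Cohort statistics

AVD (average value distribution) is the arithmetic mean of per-sample
relative abundances (percent) within a group — the simplest reading of
the term as it is used for such cohorts; AVD vectors sum to 100 per
group. Gram splits apportion AVD *mass* (not genus counts) across the
negative/positive/unknown strata. Percent increase is
`100·(case − control)/control`; taxa with zero control AVD get a
`NOVEL_IN_CASE` flag instead of an infinite value and are excluded from
the most-increased ranking (they are reported separately), and taxa with
zero case AVD are flagged `ABSENT_IN_CASE`. All rankings sort the metric
descending with lexicographic tie-break, so results are deterministic
across platforms. The same taxon may legitimately appear in both the
most-abundant and most-increased lists; no deduplication is applied.
`top_abundant` reports cumulative share of the *filtered* mass when a
Gram filter is active (i.e. "percent of the Gram-negative population"),
and of total mass otherwise; `summary.json` labels which is which. No
hypothesis tests or compositional transforms (CLR etc.) are attached —
the statistics are descriptive summaries of relative abundances.

## End-product inference

Enzymes are credited by majority rule: availability ≥ 50% of a taxon's
sequenced strains, threshold configurable in (0, 100]. Majority is the
least arbitrary default when no principled cutoff exists; because
crediting is monotone in the threshold and terminal rank is monotone in
the complement, lowering the threshold can only move taxa forward, and
`summary.json` includes a sensitivity table at thresholds 10/50/90.

Product distributions weight each terminal product by AVD mass. The
"final stage" is the KDO2-bearing set {KDO2-lipid IVA, KDO2-lipid A
penta and hexa}. The headline fraction excludes no-pathway mass before
renormalizing (the "genera without enzymes excluded" convention); the
inclusive variant is also written, and renormalizing over a subset can
only inflate the fraction (asserted as an invariant). The end-product
delta is the case-minus-control final-stage difference in percentage
points, abundance-weighted; a genus-count-weighted variant per ranking
list is reported alongside, labelled. Taxa present in the abundance
table but absent from the enzyme matrix are assigned no-pathway with a
warning rather than dropped, keeping mass accounting explicit.

The species-level acylation distribution classifies mass into
hexa/penta/tetra-acyl bis-phosphate classes, a dephosphorylated class
(any credited LpxE/LpxF), and a "no late-stage" pool for species not
reaching lipid IVA; LpxE/LpxF columns are optional inputs and absent
columns mean no dephosphorylation.

## Synthetic cohorts

Sample compositions are Dirichlet-distributed around group mean vectors
with concentration = mean/dispersion, chosen over a log-normal model for
exact simplex support and a single dispersion knob; the analysis
consumes only relative abundances. Case means are control means times
planted fold changes, renormalized; NOVEL_IN_CASE taxa have zero control
mean. Enzyme profiles come from archetypes (`full_set`,
`truncated_at:K`, `bypass_lpxh`, `none`) with a cell-level noise rate
that cannot cross a majority threshold at rates < 0.5.

The packaged `paper_like.yaml` scenario fixes the study conditions: 36
case vs 21 control samples, 100 genera, ~77% Gram-negative control mass
with one dominant genus at base mean 44, ten planted increased
Gram-negative full-pathway genera at folds 5–8, five case-only taxa, and
dispersion 0.25 (per-sample CV ≈ 5% for the dominant genus, >100% for
rare ones — moderate inter-subject variability). These are scenario
parameters, not measurements of any real cohort. The generator emulates
compositionality, group mean shifts and presence/absence structure; it
does **not** simulate read-level noise, classification error,
zero-inflation beyond the Dirichlet's own, strain-level genome sampling,
or covariance between taxa — so passing recovery tests shows the
pipeline detects planted compositional signals under idealized sampling,
not that it would on raw sequencing data.

## Problem sizes and determinism

The exhaustive pathway checks enumerate all 2^9 complements and all
containment pairs; statistical checks use 20–50 random fixtures or 20
replicate cohorts of the default scenario, sizes at which every suite
runs in seconds. All randomness flows through explicit integer seeds
(NumPy `default_rng`); rerunning any stage with the same inputs and seed
reproduces `summary.json` byte-for-byte. Degenerate inputs fail loudly:
zero-sum samples, all-mass-excluded distributions, empty groups and
malformed statuses raise named validation errors rather than propagating
NaNs.

## Limitations

Enzyme presence is genomic potential: expression, regulation (e.g. LpxC
turnover), alternative pathways beyond the configurable skip set, and
non-constitutive lipid A remodeling are out of scope, as is any model of
TLR4/MD-2 signaling. Availability percentages inherit the biases of
whatever strain database produced them; the binarization threshold is a
policy choice surfaced to the user, not an estimated quantity.
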