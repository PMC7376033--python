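# Methods

`lcrkit` is a desk-scale re-implementation of the label-map analysis used
to study the 22q11.2 deletion region: localized haplotype reconstruction
of the LCR22A and LCR22D low-copy repeats from DLE-1 optical maps, and
localization of the NAHR (non-allelic homologous recombination) interval
on proband deletion contigs. Everything runs on synthetic data with known
truth; no downloads are required.

## The locus model

LCR22A and LCR22D are modeled as ordered strings of modules on an
hg38-like coordinate frame (LCR22A anchors at 18.0–18.15 and
19.035–19.15 Mbp; LCR22D anchors at 21.0–21.11 and 21.565–21.7 Mbp; each
anchor spans >100 kbp and >= 12 labels). The module inventory:

* **SD160** — the ~160 kbp segmental duplicon shared by both loci at >99%
  identity, copy-number and orientation variable in LCR22A. Paralogous
  label polymorphisms sit in the first ~40 kbp and last ~30 kbp
  (`POLY_5PRIME`/`POLY_3PRIME` slots); the middle ~110 kbp is identical
  between copies. Two slots realize documented single-base paralog
  differences: an A-only label at 18,746,350 and a D-only label at
  21,300,467 (a CTTAAG motif created/destroyed by one base change).
* **SD22_3** — an LCR22A-specific duplicon (120 kbp).
* **SD160_PARTIAL** — the 3'-most 50 kbp of SD160; only ever the 5'-most
  duplicon of a haplotype, reference orientation, no label variation.
* **INV64** — the frequent ~64 kbp LCR22D inversion segment; its first
  and last labels are pinned at 21,424,743 and 21,510,142.
* **SPACER_\*/ANCHOR_\*/FLANK_\*** — unique sequence. Flanks (80 kbp) lie
  outside the anchors so simulated molecules can fully span anchor labels,
  as real molecules extending beyond the locus do.

Label grids are fixed, irregular (gaps ~4.4–7.9 kbp, always above the
3.5 kbp imaging resolution), and deterministic: the catalog is a constant
of the package. Realized haplotype label density falls in the 15–17
labels/100 kbp operating band of DLE-1 maps. The default catalog holds
five LCR22A structures (single/multiple/inverted/partial 160 kbp copies,
with and without SD22-3) and three LCR22D structures; inversion-carrying
LCR22D haplotypes total 73.7%, the observed parental allele frequency. A
`dense_catalog()` variant adds mid-module polymorphic slots spaced
~15 kbp apart, used to demonstrate interval shrinkage.

## Molecule simulation

Molecules are drawn per haplotype with uniform starts; length is
150 kbp + Exponential(100 kbp) (mean 250 kbp), so the >150 kbp length
filter is built in and molecules can span whole duplicons. Error model:

* **Missed labels**: independent Bernoulli at `fn_rate` (default 0.13,
  inside the recommended 9–17% band).
* **Sizing error**: a cumulative (stretch-like) Brownian component plus
  per-label jitter, so a label at distance *d* from the molecule start has
  position-error std `sqrt(sf^2 + sd^2 d)` (sf = 250 bp, sd = 2.9
  bp^1/2) while an interval of length *D* keeps variance
  `2 sf^2 + sd^2 D` — the interval-scaling law that restriction-map
  aligners assume. The defaults sit at the scale of fitted vendor values.
* **False labels**: Poisson at `fp_rate` (default 0.04) per true label,
  placed uniformly as *observed* artifacts: after sizing noise and at
  least `res_bp` from any existing label. With 3.5 kbp resolution and
  ~6 kbp label gaps, unconditional placement would silently merge most
  false labels into true ones and no QC could recover the nominal rate;
  molecule-quality FP rates are post-resolution quantities.
* **Resolution**: labels closer than `res_bp` = 3,500 merge to their
  midpoint. Molecules flip end-for-end with probability 1/2.

Truth bookkeeping (source map, window, per-label truth flags) rides in
`Molecule.source_meta` and powers every recovery test.

What the generator does **not** emulate: chimeric molecules, fragile-site
breaks, optical intensity artifacts, non-exponential length tails, or
sequence-level variation below label resolution. Passing tests therefore
show the *logic* of anchoring/validation/localization is sound at
realistic error rates, not that the pipeline is robust to every failure
mode of real runs.

## Alignment and significance

Alignment is classic restriction-map DP over label pairs: extending a
chain from pair (i′, j′) to (i, j) scores
`match_reward − (Δq − Δr)^2 / (2 (sf^2 + sd^2 Δr)) − fp_cost·(skipped
query) − fn_cost·(skipped target)`. Skip costs default to negative log
error-rates; the match reward is the log-likelihood ratio of a true match
against a Poisson background label at the target's density (floored at
0.5). The DP bounds consecutive skips at `lookback` = 6; both
orientations are tried; the best chain per orientation is reported.
Ties resolve deterministically (first-found in scan order, which prefers
leftmost starts).

Significance is an analytic tail bound under a Poisson-label null: each
chain step must find a random label inside the 3-sigma sizing window
(probability `1 − exp(−2 λ tol)`) at least as close to prediction as
observed (`|z|/3`, floored at 1e-3), multiplied over steps and by the
number of possible chain starts. It is monotone non-increasing in matched
pairs, conservative for weak alignments, and validated against
gap-shuffled permuted targets in the tests. Because this scale is ours
(the vendor's is undisclosed), the confirmation threshold keeps the
recommended 1e-11 — which the calibration shows typical true molecule
alignments beat by several orders — while the decoy-screening default is
set to 1e-13, chosen so that a 5th-percentile-length molecule truly
originating from an off-locus map still clears it while best random
cross-locus chains sit around 1e-3–1e-7.

QC rate estimation aligns molecules to truth maps with deliberately
*cheap* skip costs (1.7/1.3) so the optimizer does not paper over error
events by pairing outlier labels, then greedily rescues chain ends
(local alignment censors its ends exactly where errors cluster) and
projects the full molecule window onto the target before counting
unmatched labels. Recovered rates land within ±0.01 of nominal at 50x.

## Haplotype validation

Candidate haplotypes (from the catalog; in a cohort run, the genome's two
drawn haplotypes) are validated against molecules, mirroring the
anchored-chaining procedure: a molecule is **assigned** to a candidate
when its best alignment passes 1e-11 and beats every other candidate by a
margin (0.75 score units, about one discriminating label); candidates
tying within the margin leave it **ambiguous**; molecules passing nowhere
are filtered. A call is **complete** when (i) assigned+ambiguous
molecules chain contiguously from 5' to 3' anchor, (ii) every duplicon
module has at least one uniquely-assigned spanning molecule, and (iii)
anchor and duplicon labels reach >= 5x coverage. Ambiguous molecules
count toward coverage by default (`coverage_counts_ambiguous=True`):
they confirm the shared backbone, and excluding them would make the
outermost anchor labels unattainable at any coverage given the molecule
length law, while unique support is still demanded exactly where
candidates differ. Identical candidate ids merge (homozygotes: one call,
counted twice in frequency tables); label-identical distinct candidates
are flagged as a degenerate pair and never completed.

Grouping happens at two granularities: **feature** signatures (ordered
duplicon/inversion modules with orientation, partial modules distinct)
and **label** patterns (one-to-one label correspondence within
`jitter_bp` = 2,000, implemented by exemplar matching so the partition is
well-defined); label groups provably refine feature groups. The ~64 kbp
inversion is called from labels alone by aligning the inversion window
against the reference pattern in both orientations (consensus-level), or
by molecule vote between orientation-differing references.

## NAHR localization

A proband deletion contig is aligned to both parent-of-origin haplotypes.
Labels pair into matched sets; the **prefix** runs through the last label
matching only the LCR22A parent, the **suffix** starts at the first label
matching only the LCR22D parent, and the shared labels in between are the
**ambiguous** recombination region (the partition is always exhaustive
and disjoint). The interval is reported in parent-A coordinates (the
contig frame coincides with it up to the breakpoint) with the homologous
LCR22D span alongside; truth breakpoints fall inside it in 100% of
noise-free and >= 95% of noisy replicates. Unique evidence for only one
parent raises a "no recombinant structure" error; A-unique evidence past
D-unique evidence raises an inconsistency error.

Events are annotated by 1-bp-inclusive overlap against the configured
intervals (FAM230A/B, BCRP2/6/7 at their published coordinates; BCRP2 is
carried with both printed right ends, defaulting to the larger) and
classified as inside reference/inverted 160 kbp modules, module-flanking,
A-SD160-vs-BCRP2, or SD22-3-vs-SD160, with priority
`in_SD160_* > A_SD160_vs_BCRP2 > SD22_3_vs_SD160 > flanking_SD160` and a
multi-overlap flag when an interval spans module types.

Proband contigs in cohort runs carry a consensus-level noise model
(300 bp jitter, 2% missing, 1% extra labels) rather than raw molecule
noise: assembled consensus maps are far cleaner than single molecules,
and localization consumes consensus maps.

## Statistics

The 2x2 Fisher exact test enumerates all tables with the observed margins
and sums hypergeometric point probabilities at most (1+1e-7) times the
observed table's — the convention needed to reproduce the published
0.5248 and 0.1990 exactly. R-by-C tables use Monte-Carlo sampling of
fixed-margin tables (random pairing of row/column category multisets;
default 100,000 draws, `(1+hits)/(n+1)` estimator). Parent-of-origin
assignment requires >= 3 concordant informative microsatellite markers; a
marker is informative when the hemizygous proband's retained allele is
carried by exactly one parent, and the *other* parent — whose allele is
missing — is the origin. Mendelian-inconsistent markers are excluded and
logged.

## Problem sizes and reproducibility

Study-level checks run at 50x coverage with 100 replicates for
haplotype completion, inversion detection, and NAHR containment; the
acceptance script uses 30–100 replicates per quantity, sizes chosen to
hold sampling error well below the decision margins. Every stochastic
path takes a single integer seed (`numpy` `SeedSequence` spawning);
end-to-end reruns with the same seed are hash-identical.

## Known limitations

* Candidate haplotypes are enumerated/validated, not assembled de novo;
  a structure absent from the catalog cannot be discovered.
* Heterozygotes differing by a single paralog label cannot satisfy the
  anchor-to-anchor unique-chain rule when the discriminating label lies
  farther from an anchor than a molecule can span; such pairs surface as
  incomplete with an ambiguity diagnostic, not as calls.
* The LCR22D span of an NAHR interval is projected through the shared
  module, not independently localized.
* Inter- vs intrachromosomal NAHR cannot be distinguished, and LCR22B/C
  structures are out of scope.
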