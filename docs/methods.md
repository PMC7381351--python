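# Methods

## Scope and data model

The package re-implements, as a tested library, the desk-scale inference
chain of a multi-strain comparative-genomics study: one focal strain is
compared against a panel of reference strains through contig binning,
reciprocal-best-hit (RBH) homology labelling, codon-level divergence
estimation, a windowed synonymous-divergence screen for horizontal gene
transfer (HGT), presence/absence class analysis, and plasmid-location
enrichment. Genome-scale results from real assemblies (megabase totals,
thousand-gene ortholog sets) are documentation anchors only; all executable
checks run on synthetic data with known ground truth or on published count
tables, which are treated as inputs.

## Synthetic strain sets (`simdata`)

**Codon model.** Each gene family starts from a uniformly random stop-free
codon sequence and evolves independently down a fixed rooted tree. Branch
lengths are expected *proposed* substitutions per nucleotide site: proposals
arrive as a Poisson count `t × 3 × codons` per branch, each picking a
uniform site and a uniform alternative nucleotide. Proposals creating stop
codons are rejected and redrawn; synonymous proposals are always accepted;
nonsynonymous proposals are accepted with probability ω. Realized
synonymous divergence per synonymous site therefore tracks the patristic
distance (to first order), and Ka/Ks tracks ω. Every accepted substitution
is logged (family, branch, codon, old and new codon states) so tests can
audit divergence with an independent counter over the event log.

**Default tree.** Seven strains on a fixed rooted tree whose patristic
distances span ~0.28–1.8 synonymous substitutions per site, matching the
divergence range typical of a baeocyte-forming cyanobacterial clade (two
closely related sister pairs at the extremes). The first leaf is the focal
strain.

**Defaults and why.** `n_families = 60`, `codon_length = 150` (short but
realistic genes that keep the alignment-heavy RBH stage fast at desk
scale), `omega = 0.2` (strong purifying selection typical of core bacterial
genes), `dup_fraction = 0.20` (focal-lineage duplicates, giving paralog
shares in the ~16–28% range reported for these genomes),
`loss_fraction = 0.15` in one designated lineage, `hgt_fraction = 0.10`
pair-restricted transfers to one recipient at
`hgt_divergence_scale = 0.3`, `plasmid_fraction = 0.15` with a ×5 plasmid
boost for transferred genes, `frameshift_fraction = 0.10`. All stochastic
draws flow from one `numpy` generator seeded by a single integer; identical
config + seed gives byte-identical output.

**HGT model.** A transferred family is present only in the donor (focal)
and recipient strains; the recipient's copy is re-sourced from the donor's
tip sequence and evolved for `scale × d(donor, recipient)` additional
divergence, so the pair's divergence is the vertical expectation scaled by
`hgt_divergence_scale`. This is deliberately simpler than modelling
conjugation; it creates exactly the reduced-Ks window signature the screen
looks for.

**Compartment observation model.** True labels are i.i.d. plasmid with the
configured probability (boosted for transferred genes). Observed classifier
probabilities are confident and correct 85% of the time (top probability
uniform on 0.75–0.99) and ambiguous otherwise (top probability below 0.7,
yielding "unclassified" at the default threshold). Threshold-0.7 recovery
of the plasmid fraction is therefore deflated by the ambiguity rate, which
the recovery test accounts for explicitly.

**Frameshifts** insert one random nucleotide at a uniform position after
evolution, so truth relationships are unaffected; a frameshifted gene is
detectable downstream purely by sequence length modulo three.

**What the generator does not emulate:** GC content and codon-usage bias,
indel-rich alignment error, rate variation across sites and genes,
assembly/annotation artifacts beyond the single-indel frameshift, and real
plasmid replicon structure. Passing tests demonstrate that the estimators
and decision rules recover known truth under this idealized model — not
that they are robust to every property of real genomes.

## Contig binning

"Mostly cyanobacterial hits" is formalized as a strict majority of the
≤ 20 retained hits, and "identity much higher" as a configurable
≥ 10-percentage-point margin between the best cyanobacterial and best
non-cyanobacterial identity; the coverage gate is strict (> 70). A
discarded contig whose best identities on both sides are ≥ 70 with margin
below the cutoff is treated as the ambiguous case: if the second binner
calls it cyanobacterial it is excluded from the final set rather than
rescued. Contigs the hit rules retain against the second binner's vote stay
retained but flagged. The congruence fraction is agreement restricted to
contigs retained by either method.

## RBH homology

The scorer translates both nucleotide sequences in all three forward frames
(CDS inputs are assumed stranded; a flag adds reverse-complement frames)
and takes the best frame-pair local alignment score under BLOSUM62 with
affine gaps (open −11, extend −1). Codons containing ambiguity translate to
X, which scores 0 against everything. A raw score threshold (default 50)
replaces a search-tool E-value, since E-value calibration needs database
statistics that are out of scope; precomputed tabular hits can be
substituted (`rbh_from_tables`). Ties are broken by lexicographically
smallest gene id for reproducibility. At the default gene lengths the score
gap between true homologs and unrelated genes is wide (hundreds vs ≤ ~55),
so recovery is insensitive to the exact threshold; for much longer genes
the threshold should be raised in proportion to the random-score growth.

## Divergence estimation

Ks/Ka uses Nei–Gojobori (1986) counting with Jukes–Cantor correction.
Synonymous sites: per codon position, the fraction of the possible
single-nucleotide changes that are synonymous, with stop-creating changes
excluded from the denominator; each codon contributes sites summing to
exactly 3, giving the exact identity S + N = 3 × comparable codons.
Differences: multi-hit codon pairs are averaged over all minimal
substitution pathways with equal weights, excluding pathways through stop
codons; in the rare pairs where every minimal pathway is blocked, all
pathways are used with stop-involving steps counted as nonsynonymous.
Codons containing gaps, ambiguity, or a stop in either sequence are
skipped. When `p > 3/4` the log correction is undefined and Ks/Ka is
reported as NaN rather than clamped.

**Windows.** Scanning codons in concatenation order, the first codon that
pushes cumulative synonymous sites to ≥ 500 closes a window (windows may
slightly exceed the nominal size); the trailing partial window is
discarded. Site accumulation uses pairwise comparable codons only, i.e.
pairwise deletion within windows.

**Mann–Whitney.** Exact two-sided p (doubled smaller tail) when the pooled
sample is ≤ 20 without ties, otherwise the tie-corrected normal
approximation; both delegated to `scipy.stats.mannwhitneyu` behind the
module's switch.

**Relative rate test.** m1/m2 count sites where exactly one ingroup lineage
differs while the other matches the outgroup; columns (third positions or
translated codons) containing gaps or ambiguity in any of the three
sequences are excluded; `chi² = (m1 − m2)²/(m1 + m2)` with a 1-df upper
tail, and p = 1 when m1 + m2 = 0.

**Alignments.** The module consumes aligned FASTA. For synthetic families a
convenience aligner translates, aligns globally at the amino-acid level,
and back-maps to codons (guaranteeing multiple-of-three output); families
containing a frameshifted member are returned as a padded placeholder whose
length is not a multiple of three, so the frame filter drops exactly the
families the truth table says are corrupted — emulating the
nucleotide-alignment frameshift filter of the original workflow.

## Inventory and plasmid screen

Presence counts paralog labels as present (no-similarity is the complement
of ortholog ∪ paralog). Class 0 (present everywhere) is carried for
bookkeeping alongside classes 1–6. Per-strain absence frequencies satisfy
the identity Σ_strains freq(k) = k × |class k|; the pair-restricted class
is additionally reported in the present-in-pair view. Unclassified
compartment predictions are folded into chromosome before fractions and
contingency tables, following the convention that a below-threshold plasmid
prediction is not evidence of plasmid origin. The Fisher test is two-sided
by the minimum-likelihood rule (scipy); the odds ratio is the sample
cross-product with an explicit infinity flag.

## Seeded study conditions for the calibration checks

* **Ks recovery**: one 10⁴-codon pair at patristic distance 0.3; the
  estimate must land within 10% of target (observed bias is well under 2%
  on average; single-run sampling noise is ~2.5%).
* **Transfer screen power**: 30 families of 600 codons, half transferred at
  scale 0.3 — sized so both the All and Pair concatenations yield ≥ 10
  windows of 500 synonymous sites; two-sided Mann–Whitney p < 0.05 must
  occur in ≥ 80% of 40 seeded replicates.
* **Rate-test calibration**: 500 equal-rate three-taxon replicates
  (300 codons, ingroup tips equidistant from their ancestor); third-position
  rejection frequency at α = 0.05 must stay within [0.02, 0.09].

Problem sizes throughout (tens of families, 10²–10⁴ codons) are chosen so
the full suite and the acceptance script each run in well under a minute on
one CPU while leaving the statistical checks comfortably powered.

## Known limitations

The RBH score threshold is not an E-value and is length-sensitive; NG86
with equal pathway weights underestimates divergence when transition bias
is strong; the JC correction saturates near p = 3/4 and windows in that
regime return NaN; the convenience aligner is reference-free only for
equal-length families and is not a substitute for a real MSA tool on
diverged indel-rich data; the generator's compartment and category labels
are i.i.d., so the inventory and enrichment stages see idealized signal.
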