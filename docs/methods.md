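# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## Conservation scanning (`cne_scan`)

The scanner operates on reference-anchored alignment blocks, column by column.

**Column rule.** A column is conserved iff (i) the reference base is a real
base (not gap/N), (ii) at least `min_species_in_column` (default 3)
non-reference rows are ungapped, and (iii) the fraction of those rows whose
base differs from the reference is strictly below
`column_substitution_threshold` (default 0.12). Gapped rows are excluded from
the denominator; N never counts as identity (it mismatches everything,
including another N). Mismatch is measured against the reference base by
default; a consensus-base mode (`consensus_mode="consensus"`) is available
because either reading is defensible, but the reference mode is the default
and the one all tests pin down.

**Seeds and extension.** Seeds are `seed_length` (10) consecutive
reference-base columns containing at least `ceil(seed_identity × seed_length)`
(9) conserved columns. Each qualifying window is extended outward
independently on each side, tolerating at most `max_nonconserved_per_side`
(3) non-conserved columns on that side, and trimmed so elements start and end
on conserved columns; overlapping extended elements are merged. Extension is
applied per window rather than to pre-merged seed regions: per-window
semantics make the scanner provably equal to the exhaustive enumeration of
all qualifying intervals (the brute-force oracle in
`ohnocne.reference.brute_scan_spans`), which a merged-seed variant would not
be. Reference-gap columns are non-conserved, count against the side budget,
and do not advance reference coordinates.

**Masking and retention.** Exon/UTR/repeat masks split blocks before
scanning, so no element can cross or touch a masked reference position.
After merging, an element is retained only if at least one fish-class row has
ungapped bases over ≥ `fish_presence_min_cover` (0.50) of its columns;
setting the threshold to 0 disables the filter. The same coverage rule
defines per-species support and the tetrapod-shared flag used for vCNE
counting (elements conserved in both fish and tetrapods).

The scanner is deterministic; output is sorted by (sequence, start, end).

## Pairwise paralog search (`cne_pairwise`)

A full Gotoh dynamic program (no heuristic word seeding) with match +1,
mismatch −1 and affine gaps costing `open + k × extend` = 2 + 2k for a
length-k gap — the gap-existence convention, configurable. The DP tracks, per
cell and state, the path's start and length so that ties are broken
deterministically and in a stated order: higher score, then smaller query
start, then smaller subject start, then shorter alignment; '+' strand beats
'−' on equal score. The kernel is compiled with numba; memory is
O(n·m) and the intended scale is gene-neighbourhood windows up to a few tens
of kb (full 800-kb windows would need banding, which is out of scope).

Multiple hits are found by iterative best-hit-and-mask: report the optimal
local alignment, hard-mask its query footprint with N (N matches nothing, so
masked stretches can never seed or extend), repeat while the best score is at
least `min_report_score` (11 — the minimum score an ungapped hit can have and
still pass the retention filter below; gapped hits scoring lower than this
are not pursued, a deliberate greedy approximation). Retention then requires
strictly more than `min_hit_length` (50) alignment columns and identity
≥ `min_identity` (0.60). Identity's denominator excludes gap columns by
default (`identity_denominator="columns"`); a with-gaps variant is provided
since conventions differ between tools.

## Partition of ancestral CNEs (`paralog_partition`)

An ancestral CNE counts as present in a (species, paralog) environment when a
retained hit overlaps ≥ 50% of the CNE's length (`min_overlap_fraction`).
Aggregation across species defaults to `any_species` — a CNE is a-only if
seen near a in at least one species and near b in none — with `all_species`
and `per_species` modes exposed, because per-gene summaries and per-species
detection matrices are both legitimate views of the same table. Percentages
are reported to one decimal.

The count-asymmetry test is Student's *t* on per-unit (gene or species) CNE
counts around a vs b: paired by default (one-sample *t* on differences —
counts come naturally paired per unit), with the two-sample equal-variance
variant available. Zero-variance differences with nonzero mean are reported
as p < machine floor with an explicit flag rather than an exception.

## Branch-partitioned codon models (`codon_evolution`)

Goldman–Yang instantaneous rates over the 61 sense codons of the universal
code: q_ij = 0 for multi-nucleotide changes, ∝ π_j for transversions, κπ_j
for transitions, times ω when the change is nonsynonymous; the matrix is
scaled to one expected substitution per codon per unit branch length. Codon
frequencies are F3x4-style empirical by default (positional nucleotide
frequencies, floored at 1e-10 and renormalised) or equal.

Branch ω classes come from the tree's `#tag` labels (`a`, `b`, `p`, `r`,
untagged = `r`), mapped per model: A collapses everything to one ω; B maps
`a`/`b`/`p` to ω^p and `r` to ω^r; C keeps ω^a, ω^b, ω^r (a bare `p` tag is
ambiguous under C and rejected). Which branches belong to a paralog class —
including clade stems — is entirely the user's tagging; nothing is inferred.

**Unrooted-edge convention.** Likelihood under a reversible model depends
only on the unrooted tree, so a bifurcating root's two branches are one
edge. They are always merged (combined length on one branch, the other fixed
at zero), and the merged edge carries a single ω class: the common class if
the tags agree, the non-background tag if exactly one side is tagged, and an
error if the two sides carry different paralog tags (re-root trifurcating
instead). Without this, the richer model gains a spurious extra dimension —
splitting one physical edge between two ω classes — that is unidentifiable
under the null and visibly inflates likelihood-ratio tests.

**Likelihood and fitting.** Felsenstein pruning over site patterns
(duplicate columns compressed) with per-node rescaling; transition matrices
P(t) = exp(Qt) from the eigendecomposition of the symmetrised reversible
form, clipped at 0. Fitting maximises over log-transformed κ, the ω classes
and (by default) all free branch lengths with L-BFGS-B, bounds ω ∈ [1e-6,
50], κ ∈ [1e-3, 200], t ∈ [1e-9, 25]; `ftol = 5e-10` corresponds to a ΔlnL
stopping scale of ~1e-6 on typical data. Decompositions are cached per
(κ, ω) so the optimiser's branch-length finite differences reuse them. The
default start (κ = 2, ω = 0.3, input-tree branch lengths) is augmented by
jittered restarts (`n_restarts`, default 3, seeded); ω estimates within 1% of
a bound are flagged, not corrected. The LRT statistic 2(lnL_alt − lnL_null)
is clipped at zero and compared to χ² with df equal to the difference in
ω-class counts (A→B: 1, B→C: 1).

The simulator draws root codons from π and evolves them branch by branch with
the branch's class matrix; rows of P(t) are renormalised before sampling.
Everything is reproducible from the seed.

## Retention landscape (`landscape_summary`)

Over the non-salmonid teleost columns: `duplicated_any` = copy number ≥ 2 in
at least one species; `duplicated_all` = in every species;
`lineage_specific` = the difference; WGD retention = fraction of genes whose
origin annotation is WGD-duplicate. Salmonids are excluded from these
denominators (their own younger WGD would conflate two duplication rounds)
and get a separate rate: per salmonid, the fraction of assayed genes (copy
≥ 1) retained at copy ≥ 2. Percentages are carried exact; rendering supports
round-half-up (default) and truncation, because one-decimal percentages in
the literature are formatted inconsistently between the two — the bundled
fixture's 11/19 prints 57.9 rounded and 57.8 truncated, while its 3/11
prints 27.3 rounded and 27.2 truncated.

The bundled 19-gene *sox* fixture encodes the family's published structure:
ten WGD ohnolog pairs (*sox1, 4, 6, 8, 9, 10, 11, 14, 19, 21*), six
all-singleton genes (*sox2, 3, 5, 7, 13, 18*), the single small-scale
duplication pair (*sox17/32*, present in all teleosts), and *sox12*/*sox30*
singletons with lineage losses (*sox12* absent from acanthopterygians,
*sox30* from six genomes, *sox10* from cavefish). Which lineages retain each
lineage-specific duplicate, and the salmonid copy numbers (16/19 genes at ≥ 2
copies), are representative choices consistent with those lists, not
measurements.

## ΔΔCT quantification (`expression_ddct`)

Replicate Cq values are averaged per (sample, gene) — arithmetic mean, the
usual choice when no aggregation rule is stated. Mean Cq ≥ 34 (the
single-molecule detection limit is ~33 cycles) is a non-detect and
propagates. ΔCT = Cq_target − Cq_reference (one reference gene or the mean
of several), ΔΔCT subtracts the calibrator sample's ΔCT, relative expression
is 2^−ΔΔCT. The low-expression bin is relative expression ≤ 0.10: a cutoff
quoted as "ΔΔCT ≤ 0.10" is ambiguous between the raw-ΔΔCT and fold-change
scales, and only the fold-change reading produces a *low* bin, so that is the
default; the literal raw-ΔΔCT rule is available via `threshold_on="ddct"`.
The boundary comparison carries a 1e-12 relative guard so values that are
exactly the cutoff up to floating-point round-trip stay in the low bin.
Samples with undetected reference genes are flagged, never silently dropped.
Primer-efficiency correction and reference-gene stability screening are out
of scope.

## Synthetic data (`synthetic_data`)

The planted-alignment generator draws a uniform-random reference and copies
it per species with per-column mismatch at the background rate (default
identity 0.60, far below every acceptance threshold) or the element rate
(default 0.98, above every threshold); mismatches are uniform over the three
alternative bases; gaps (default 2% per column per species) occur only
outside planted elements, so truth intervals are exact. The paralog
generator retains each ancestral element near paralog a/b independently per
species with probabilities `p_keep_a`/`p_keep_b`, re-emitting retained copies
at 90% identity inside unrelated random backgrounds (~25% identity, so
background can never pass the 60% retention filter). What these generators do
**not** emulate: indels inside conserved elements, rearrangements, local
duplications, phylogenetic correlation between species (each species diverges
independently from the reference), or compositional heterogeneity — so
passing tests demonstrate algorithmic correctness under the intended
signal/noise regime, not robustness to every property of real genomes.

## Problem sizes and calibration checks

The test suite runs the scanner-vs-enumeration oracle on 200 random
alignments of ≤ 60 columns, planted-element recovery on 100 elements
(lengths 20–65 in 12-kb blocks), the aligner against exhaustive path
enumeration on 100 pairs of ≤ 8-mers (plus Bio.Align.PairwiseAligner with the
identical scoring as a second, independent check), the likelihood against a
brute-force sum over internal states on 3-taxon/10-codon instances
(agreement to 1e-8), LRT type-I calibration with 500 replicates of 200
codons on 6 taxa (rejection rate 0.054 at α = 0.05, within the expected
band for a χ²₁ reference), asymmetric-ω recovery (ω^a = 0.5 vs ω^b = 0.1,
300 codons, 50 replicates, ω̂^a > ω̂^b in 100%), and paired-*t* calibration on
500 symmetric retention datasets. Calibration fits use a single start at the
generating values with the alternative warm-started from the null's optimum —
the likelihood surfaces are unimodal at these sizes and this keeps the suite
fast. `scripts/acceptance.py` re-runs the same computations with the
calibration loops at reduced replicate counts (150 LRT replicates, 30
recovery replicates, 120 scanner-oracle cases) so the whole script finishes
in about a minute.

## Known limitations

Quadratic-memory alignment limits pairwise searches to tens of kb; the
codon machinery assumes gap-free alignments (gapped columns must be removed
upstream) and the universal genetic code; branch models cover whole-branch ω
only (no site or branch-site variation); the greedy hit discovery can in
principle miss a heavily gapped retainable hit scoring below the ungapped
floor; and the LRT relies on the asymptotic χ² reference, which is slightly
anti-conservative at a few hundred codons.
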