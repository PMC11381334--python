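# Methods

## Mass model

Peptide monoisotopic masses are residue-mass sums plus one water
(N-terminal H, C-terminal OH). The residue table stores the 20 standard
monoisotopic residue masses to 1 µDa precision alongside the water
(18.010565 Da) and proton (1.007276 Da) constants, so no constant is
hard-coded at a call site. Isoleucine and leucine carry the identical mass
by construction — their exact isobarism is load-bearing for panel
selection, not a rounding artefact. Only the singly protonated b/y series
is generated: the workflow uses MS2 qualitatively (is a confirming
fragment present? do two isobaric barcodes differ in any fragment?), for
which a/x/c/z series, neutral losses and isotope envelopes add nothing.
Cysteine is unmodified by default with a fixed-modification hook
(carbamidomethyl, +57.02146 Da); barcode cores exclude C, so the choice
only matters for carrier peptides.

## Design cascade

The allowed core alphabet is the 20 residues minus {M, W, N, Q, C, R, K,
D, E}: methionine/tryptophan oxidise, asparagine/glutamine deamidate,
cysteine forms disulfides (all of which shift mass and split signal), and
K/R/D/E interact with tryptic cleavage and charging. That leaves 11
residues; 5-mer cores give 11⁵ = 161,051 candidates, and requiring
*exactly one* proline leaves 5·10⁴ = 50,000. "At least one" proline would
leave 61,051; exactly-one is the default because a single proline gives a
single unambiguous diagnostic y-ion, and the filter then has a clean
closed-form count. Both rules are available.

Flanks: the barcode core sits between constant 6-residue flanks inside the
tryptic release peptide, so digestion kinetics at the cleavage sites are
identical for every barcode. The default flanks (`GSGSGA` / `AGSGSG`) are
documented placeholders — K/R-free (a tryptic site inside a flank would
split the barcode), free of the excluded residues, and proline-free (so
the core proline stays the unique diagnostic). Every cascade count is
flank-independent: flanks add a constant mass offset to all candidates.

Panel selection works on the sorted mass line. Exact-mass classes
(sequence permutations of one composition, plus I/L exchanges and
coincidental composition isobars such as G+L = A+V) are first collapsed to
one representative — the lexicographically smallest core — because no
member of such a class can ever be "unique" by mass. `strict_unique` then
keeps representatives at least Δ₁ from both neighbours; `max_separated`
keeps a maximum-cardinality subset with all consecutive gaps ≥ Δ₁ via a
greedy sweep, which is optimal for points on a line (verified against a
DP oracle in the tests). Ties break lexicographically everywhere, so
identical constraints give byte-identical panels.

The MS1 tolerance Δ₁ behind any published panel size is generally not
stated, so `calibrate_separation` inverts the monotone size–tolerance
relation: panel size at tolerance t is the number of classes whose
nearest-neighbour distance is ≥ t, so the largest tolerance yielding ≥ k
members is the k-th largest nearest-neighbour distance. Under the default
constraints a 120-member panel appears at ≈0.050 Da; the default working
tolerance is 0.01 Da (a round, conservative value well above instrument
accuracy at these masses, giving a 268-member strict panel).

Isobaric library: single-linkage clusters at Δ₁ on the mass line; within a
cluster a maximal subset is retained greedily (lexicographic order)
requiring every retained pair to differ by ≥ Δ₂ in at least one b/y ion.
I/L swaps at the same position are invisible to every fragment and
collapse; permutations across a fragment boundary are distinguishable.
`members_total` counts retained candidates in groups that keep ≥ 2 — the
barcode space usable beyond mass-unique panels when MS2 confirmation is
acquired. The isolation-window co-selection check (precursors within 1.2
m/z at a shared charge) is reported as a warning, not a hard filter, since
co-isolated precursors remain separable in MS2.

## Digestion

Classic trypsin rule: cleave C-terminal to K/R except before P, no Keil
exceptions — adequate for design verification, where the question is
whether the barcode's release boundaries are clean, not what the exact
digestion efficiency is. Missed cleavages up to a configurable maximum are
emitted alongside the fully cleaved backbone (default 0 for verification,
2 recommended for carrier-peptide prediction). Coordinates are 0-based
half-open; the fully cleaved products concatenate back to the input, an
invariant property-tested on random sequences.

Release verification treats a product as intact if it equals the panel
peptide exactly (C-terminal barcode) or with one trailing K/R (internal
barcode — the junction residue that directed its release travels with the
tryptic product). Carrier products whose mass falls within Δ₁ of any
barcode are flagged as quantitation interferents. A carrier whose secreted
form undergoes additional C-terminal processing (mature erythropoietin
loses its C-terminal arginine, for example) may shift the barcode's
release context in vivo; this is outside the digestion model and should be
checked per construct.

## Reverse translation

The GC target is met exactly in total GC count where feasible: for the
standard genetic code every residue's synonymous-codon GC counts form a
contiguous integer range, so the achievable ORF totals form the contiguous
range [Σ min, Σ max]. The encoder clamps the desired total into that
envelope (flagging the clamp), then realises it by starting every position
at its minimum-GC codon and raising positions left to right, taking the
lexicographically smallest codon at each chosen GC count. This is
deterministic, achieves |GC − target| ≤ half a base over the whole ORF,
and is provably monotone in the target — a global-allocation variant of
per-position greedy deficit tracking, preferred because the greedy variant
can violate monotonicity at the margin. Known cosmetic limitation: the GC
adjustment concentrates at the 5' end rather than spreading evenly; GC
*content* is the only optimisation target (no codon-adaptation index, no
secondary-structure terms). Uridine chemistry (e.g. 5-moU substitution)
affects synthesis, not sequence, and is not modelled.

## Quantitation and ranking

Normalization is the per-animal ratio to a designated reference barcode
(the standard-LNP barcode), which cancels any animal-level multiplicative
factor exactly — not global median scaling, which would not. Animals
missing the reference (or with it censored) are excluded by name rather
than imputed. Group summaries are arithmetic mean ± SD; ranking is by
descending mean fold change with average ranks for exact ties and
alphabetical ordering within ties for determinism.

LOQ censoring substitutes the LOQ itself for sub-LOQ areas (flagged, raw
value kept in an audit column). Substitution-at-LOQ is conservative for
ranking — a censored barcode can never rank above an uncensored one at the
threshold; LOQ/2 or exclusion are easily applied upstream by the caller if
preferred. Two sensitivity constants are stored independently: the molar
per-barcode LOQ (2 fmol/µl) and the protein-equivalent per-barcode LOQ
(0.6 ng/mL of a ~30 kDa carrier). They are not derivable from one another
by unit conversion alone (the processing chain between serum and injection
intervenes), so the package deliberately does not reconcile them; the
pool-size arithmetic (minimum detectable total = pool size × per-barcode
LOQ) uses whichever the caller supplies.

The exact Wilcoxon matched-pairs signed-rank test drops zero differences,
ranks |d| with average ranks, and builds the full null of W⁺ over all 2ⁿ
sign assignments by shift-convolution (doubled ranks keep tied averages
integral). The two-sided p doubles the smaller tail, capped at 1. n ≤ 20
keeps enumeration exact and instant; beyond that a user should switch to
scipy's asymptotic test (the suite cross-checks against scipy's exact
method on tie-free data). No multiple-testing correction is applied
anywhere by default.

## Simulator

Defaults mirror a realistic pooled screen: groups of 5 animals, a total
pool dose cap of 0.5 mg/kg (so five LNPs at 0.1 or ten at 0.05 mg/kg each),
animal-level CV 0.3 and measurement CV 0.2 — mid-range values for in-vivo
expression and manual XIC integration. Noise is lognormal at both levels
(positive, multiplicative, the natural match for ratio-based
normalization), parameterised by CV with unit mean so the noiseless limit
is exact. All randomness flows from a single integer seed through one
generator. Pools have no LNP–LNP interaction by default — pooling is
assumed (and in this model is exactly) behaviour-preserving — with an
optional exponential competition term to stress-test ranking robustness.

The built-in example models rank MC3 > KC2 > C12-200 > DLin-DMA > DOTAP
with ~2× potency steps; the parameters are illustrative placeholders, not
fits to measured dose–response data. What the simulator does *not*
emulate: PK/biodistribution, saturation of the secretion pathway,
correlated noise between barcodes beyond the shared animal factor,
retention-time or ionisation differences between barcodes (all barcodes
are assumed equally detectable per unit protein). Tests passing on
simulated data therefore establish the pipeline's algebra (cancellation,
ranking, censoring) and its noise robustness, not instrument-level
fidelity.

`group_size_for_effect` is the standard two-sample normal-approximation
size, n = ⌈2(z₁₋α/₂ + z_power)²/d²⌉ per group: d = 2 SD units at α = 0.05
and 80% power gives n = 4, which screens round up to 5 for attrition.

## Problem sizes in the test suite

The full design cascade (161,051 → 50,000 → calibration) runs in seconds
and is exercised at full size. The isobaric library in the acceptance test
runs on the first 5,000 candidates (the full 50,000 takes ~1 s more and is
exercised via the example script). Monte-Carlo checks use 100–400
replicates, enough to bound the binomial error below the margins asserted.
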