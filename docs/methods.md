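# Methods

## Mass and ion calculus

All masses are monoisotopic, assembled from IUPAC atomic masses: hexose
residue 162.052824 Da, pentose 132.042259, deoxyhexose 146.057909, water
18.010565, proton 1.007276, Li⁺ 7.015455 (⁷Li minus one electron), formic
acid 46.005480, oxygen 15.994915.  A structure's neutral mass is the sum
of its residue masses plus one water plus the oxidation shift.  Oxidation
is modelled as a single state per oligosaccharide: C4 forms (keto −2.01565,
gem-diol +15.994915) sit on the backbone glucosyl of the non-reducing
terminal unit, C1 forms (δ-lactone −2.01565, aldonic acid +15.994915) on
the reducing terminal one — the only positions oxidative backbone cleavage
can create.  Deprotonation subtracts proton mass; the lithium adduct adds
the cation mass.  The differences from sloppier bookkeeping (hydrogen vs
proton, electron mass) are below the 0.1 Da reporting precision of the
instruments emulated here but are kept physically correct.

Printed low-resolution values from ion-trap/MALDI instruments typically
sit 0.0–0.3 Da above monoisotopic theory; the package therefore always
reports theory and matches observations with a tolerance (default 0.3 Da
for precursor and fragment matching — ion-trap accuracy — and 0.05 Da when
checking one-decimal reproduction of reference values).  There is no
average-mass mode and no isotope-pattern simulation.

The structure grammar is the Fry one-letter code over G/X/L/F with strings
reading non-reducing → reducing.  The unit table is data-driven, so further
letters (e.g. arabinosylated S units) can be registered, but the shipped
grammar is exactly the set needed for tamarind (TXG) and black-currant
(BCXG) xyloglucan.  ASCII oxidation prefixes `O4k:`, `O4g:`, `O1l:`,
`O1a:` are emitted; the literature-style `_O=G_` marker is accepted on
input as a synonym of `O4k:`.

Isomer enumeration solves the unit-count equations for a residue
composition (F = deoxyhexose; X+L+F = pentose; G+X+2L+2F = hexose) and
generates distinct unit permutations, optionally filtered to substrings of
an (SSSG)ₙ repeat — the XXXG-type architecture of TXG/BCXG — by requiring
a phase in which all and only the G units occupy every fourth position.

## Fragmentation model

B/C and Y/Z pairs are generated for every backbone and side-chain
glycosidic bond: B = Σ residues(non-reducing part) − H⁺, C = B + water,
Y = Σ residues(reducing part) + water − H⁺, Z = Y − water, so the
complementarity identity mz(B) + mz(Y) = mz([M−H]⁻) − 1.008 holds exactly.
The oxidation shift travels with whichever side retains the oxidized unit.
Two cross-ring ion types are generated as *empirical offsets calibrated on
published ion-trap spectra of xyloglucan oligosaccharides, not derived
from atom bookkeeping*: the ⁰'²A ion on the reducing-end residue at
precursor − 60.021, and one ²'⁴X ion per backbone Y at Y + 102.032.  The
exact atom retention of ²'⁴X ions on C4-oxidized rings is not derivable
from the available evidence; the offsets are flagged as empirical here and
validated against the published fragment tables in the test suite.  D ions
(internal double C/Z cleavage) cover contiguous internal backbone spans of
at most three linked residues, at Σ residues − H⁺.  Fragment charge is 1−
by default (published MS/MS annotations are singly charged); 2− variants
are available.

Index bookkeeping: B/C subscripts count the residues contained in the
fragment (this reproduces the published B₃/B₄ labels); Y/Z subscripts give
the backbone position, counted from the reducing end, of the unit lost at
the cleaved bond (reproducing Y₄ for the loss of the oxidized terminus of
a DP-4 product); ²'⁴X reuses its paired Y index.  Published subscripts for
branched-path cross-ring ions can differ by one from this scheme;
subscripts are bookkeeping only — all matching is on m/z.

Of the published fragment list for the −2 H4P3 peak, the implemented ion
types cover 293/453/605/765/899/999/1041; the remaining printed ions
(527, 821, 839) are secondary double-cleavage products outside the model
and are reported as uncovered rather than silently dropped (see
`tests/test_fragments.py`).

## Annotation logic

Precursors are classified against a defined mass list (compositions ×
oxidation forms × ion kinds, deduplicated over isomers): `non-oxidized`,
`minus2` (C4-keto / C1-lactone) or `plus16` (C1-aldonic / C4-gem-diol —
the band where formic acid adducts of non-oxidized species of the
composition one hexose-for-pentose swap away also land, e.g. C1-oxidized
H5P2 and the formate adduct of H4P3 coincide at m/z 1107.35).  A `plus16`
precursor with a clean −46.005 loss in its MS/MS is re-assigned as a
formate adduct and its oxidized interpretation suppressed; without the
loss it is recorded as a C1-oxidized product *at composition level only* —
C1 products co-elute and cannot be structurally localized, so they count
as evidence of activity but are never assigned a terminus.

For `minus2` precursors, all C4-keto isomers of the matching compositions
(XXXG grammar by default) are scored: score = number of distinct matched
theoretical fragment m/z values (peak within 0.3 Da and above an intensity
floor of 0.5 % of the base peak), with candidate-unique ("diagnostic")
fragments weighted ×3.  The published tables mark "informative" fragments
without defining the criterion; here diagnostic = unique among the
co-candidate set, a deliberately auditable divergence.  All co-optimal
candidates are reported (ties broken lexicographically), mirroring how
co-eluting isomers are listed per chromatographic peak.  Intensities are
otherwise ignored: preference statements in this field rest on the number
of identified structures, not abundances, so intensity weighting is left
out of the default scheme.

On a noise-free spectrum containing a candidate's complete theoretical
fragment set, that candidate is provably co-optimal: every competitor can
match only the subset of peaks it shares with the truth, and competitor
diagnostics are by definition absent.  On the published *union* fragment
list of a peak containing two co-eluting isomers, fragment evidence alone
ranks the better-covered isomer first and cannot tie the second (the
instrument separated them by elution time, which this package does not
model); the second isomer is still reported with its distinct supporting
ions.

## Mode-of-action classification

The tolerance index of a digest is the fraction of localized oxidized
termini that are substituted (X/L/F).  Classification: `Inactive` if no
oxidized product at all; `Substitution-intolerant` if index ≤ 0.30;
`Substitution-tolerant` if ≥ 0.50; `Indeterminate` otherwise, including
active digests with no localized terminus.  The low threshold is set at
0.30 so that a digest dominated by oxidized-G termini with a minority of
X termini (the published intolerant product table re-tallies to index
2/7 ≈ 0.286) falls on the intolerant side while anything approaching an
even split does not; the high threshold at 0.50 keeps "tolerant" meaning
"majority substituted" (the published tolerant table re-tallies to
13/15 ≈ 0.87).  Both thresholds are exposed in `RunConfig`.  The index is
scale-invariant, so duplicating a report never changes the label.

## Synthetic data

`simulate_polymer` builds (SSSG)ₙ chains; substituted positions are X,
upgraded to L with probability `p_L` (default 0.35, the galactosylation
level typical of tamarind xyloglucan) and, in black-currant mode, L → F
with probability `p_F`.  `simulate_digest` samples cuts along the
backbone: in intolerant mode only bonds whose reducing-side unit is G are
eligible (cut probability = `cut_density`, default 0.5); in tolerant mode
every bond is eligible with substituted reducing-side units up-weighted
×3; each cut adds one water across the two products and oxidizes the new
terminus — C4-keto on the reducing-side product (probability
`c4_fraction`) or C1-aldonic on the non-reducing-side product.  The
tolerant default mixes C4:C1 at 70:30 (the tolerant enzyme produced both
oxidation types; no ratio was published, so this is a stated default, not
a fit).  A product flanked by a C4 cut on its left and a C1 cut on its
right keeps only the C4 mark — the model holds one oxidation state per
product, a known simplification.  Products outside DP 2–8 are treated as
chromatographically unobservable when spectra are acquired, but all
products are returned so mass bookkeeping (Σ products = polymer + cuts ×
water + shifts) stays checkable.

`simulate_spectrum` degrades the theoretical fragment set with per-peak
dropout (default 0.10), Gaussian m/z jitter (σ = 0.05 Da), Poisson decoy
peaks (rate 3 per spectrum, uniform m/z) and exponential intensities with
a ×3 boost for B/Y ions — an arbitrary but documented intensity model,
since intensities only gate the matching floor.  All generators are pure
functions of their seed.

What passing synthetic tests does **not** show: real digests contain
double oxidations, acetylated galactosyls, in-source fragments,
co-isolated precursors and retention-time information, none of which are
modelled.  The end-to-end recovery experiments (50 seeded replicate
digests per mode on 12-block polymers, classified through the full
annotate → profile → classify chain with ≥ 95 % accuracy) validate the
inference logic, not instrument realism.  The 12-block polymer size and
50-replicate count were chosen as the smallest experiment in which the
per-replicate evidence (≈ 8–12 oxidized products) makes classification
noise-limited rather than sample-limited.

## Segment analysis

Segment boundaries are supplied as 0-based half-open column ranges on the
trimmed alignment (mature sequences, signal peptide / linker / CBM already
removed — trimming is out of scope).  The shipped boundary maps are
synthetic examples from the family generator, not a curated AA9 map, which
lives in the primary literature.  Ungapped lengths per segment feed the
±Seg caller; long/short thresholds default to a data-driven 1-D 2-means
split per segment (no numeric cut-offs are published), with fixed
thresholds accepted.  Signs for Seg1 and Seg2 are always emitted; `+Seg3`
is appended only when Seg3 is long (the extended-Seg3 sub-cluster).

The segments-only tree uses normalized BLOSUM62 score distances,
d(a,b) = 1 − 2·s(a,b)/(s(a,a)+s(b,b)) with a −4 score for residue-vs-gap
columns, followed by neighbor joining (scikit-bio).  This is a deliberate
desk-scale surrogate for ML inference with bootstrapping; it is exact on
additive distances (verified against brute-force bipartition comparison
for n ≤ 8) and deterministic given input order.  Cluster–label concordance
is the fraction of label classes that admit an exact edge bipartition on
the unrooted tree, with `unknown` leaves unconstrained.

The synthetic family generator emits three configuration families
(+Seg1−Seg2, −Seg1+Seg2, −Seg1−Seg2 by default) as mutations of a shared
root consensus (between-family divergence 0.35, within-family 0.05), with
per-sequence segment lengths drawn around the family means.  Real AA9
families differ by indels and domain content as well as substitutions;
the generator only emulates the length signal and a clean three-cluster
substitution structure.

## Numerical and interface choices

Tolerances: 1e−6 Da for exact identities in tests, 0.3 Da for matching,
0.05 Da for one-decimal reproduction.  Ties in candidate ranking break
lexicographically on the structure string; ties in 2-means break toward
the smaller split sum.  Degenerate inputs: empty peak lists raise
(distinct from "no candidate matched"), infeasible compositions return
empty sets, inactive digests return the intact polymer, zero-variance
segment lengths classify everything as short.  Reports are TSV (UTF-8;
tab avoids comma collisions in annotation lists); trees are Newick;
configuration is YAML round-trippable; MGF goes through pyteomics with a
preceding line-numbered structural validation so malformed blocks fail
with the offending line.
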