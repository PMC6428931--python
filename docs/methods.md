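# Methods

## Problem and model

Urine from a tumor-bearing xenograft mouse contains host (mouse) proteins
and graft (human) proteins. Identification is bottom-up: only peptide
sequences are observed, and a peptide shared between the two species'
tryptic digests cannot be attributed to either. The pipeline therefore
formalizes "unambiguously human" as a property of the *in-silico digests*:
a peptide is human-unique iff it appears in the tryptic digest of the human
proteome and is absent from the digest of the mouse proteome, at the same
digestion parameters the identifications were searched under. This is a
deliberately conservative, purely set-theoretic definition — no homology
alignment or locus restriction is applied, so a peptide matching *any*
mouse protein anywhere is disqualified.

## Digestion

Trypsin cleaves C-terminal to K or R; under classical specificity the cut
is suppressed when the next residue is proline (configurable, default on —
matching Sequest-era search behavior; the upstream search settings we
mirror do not state it). Peptides spanning up to `max_missed_cleavages`
internal sites (default 2, the common search-engine allowance) are emitted
and filtered to 6–50 residues, the range LC-MS/MS typically identifies;
both bounds are exposed because no authoritative values exist for the
manual comparison being formalized. Coordinates are 0-based half-open.
Peptides containing X/B/Z/U are dropped: their residue identity is
ambiguous for exact string matching. Correctness is checked against two
independent oracles: a brute-force enumerator of all substrings whose
boundaries are termini or allowed cleavage sites, and pyteomics' cleavage
function.

## Species assignment

The index maps each canonicalized peptide (uppercase; optionally with I
collapsed onto L, since MS cannot distinguish them) to its human and mouse
parent accession sets. Labels follow from the parent sets: `human_unique`,
`mouse_unique`, `shared`, `unmapped`. `equate_il` defaults to off,
mirroring exact-sequence comparison against the protein databases; turning
it on can only merge index keys and therefore never increases the
species-unique counts (a tested monotonicity property). Modification
annotations (oxidation, deamidation, carbamidomethyl, flanking-residue
notation) are stripped by the reader before classification.

## Protein rollup

For one species label, every accession with at least one labeled peptide is
reported; no parsimony grouping is attempted, because the upstream
search-engine grouping being emulated is undocumented and a transparent
rule is testable. A protein's *unique peptide count* counts distinct
labeled peptides whose within-species parent set is exactly that accession;
peptides degenerate within a species accrue their PSMs to every parent but
count as unique for none. A sample detects a protein when its summed PSM
count is ≥ 1; detection ratios are reported per group.

## Differential screen

Counts are depth-normalized by scaling each sample's column so its total
equals the mean total (spectral counts have no stated normalization in the
emulated design; total-count scaling is the minimal choice and is exposed
as its own operation). The three screening criteria are: (1) ≥ 2 unique
peptides; (2) two-sided p < 0.05 and tumor/control fold change > 2 or
< 0.5; (3) detection in all samples of the group(s) in which the protein is
reported — proteins present in every sample of one group and absent from
every sample of the other are reported as group-exclusive without a fold
change or p-value. Reported fold changes are `max(fc, 1/fc)` with an
Up/Down trend. No multiple-testing correction is applied by default,
reproducing a raw-p screen; BH-FDR is available behind a flag.

The default test is Student's (pooled) t on normalized counts. At the
4-vs-4 group sizes this design targets, Welch's t is measurably
conservative on overdispersed counts (empirical type-I ≈ 0.03–0.04 at
nominal 0.05) because its degrees-of-freedom estimate is unstable at n = 4,
while the pooled test holds nominal size across the dispersion range we
simulate; under the null both groups share one distribution, so the pooled
variance assumption is exact where calibration matters. Welch's t and an
exact permutation test (full enumeration of group assignments, two-sided on
the difference in means) remain selectable. The permutation test's smallest
attainable two-sided p at 4 + 4 is 2/70 ≈ 0.029, so it is inherently
conservative at α = 0.05; it is used as the fallback when both groups have
zero variance with unequal means (zero variance with equal means yields
p = 1), which avoids 0/0 without manufacturing significance.

## Synthetic data

The generator emulates the study design: paired proteomes, 4 control + 4
tumor urine samples, tumor-only graft proteins, up-regulated host proteins.
Graft proteins are uniform random sequences over the 20 standard residues
(60–300 aa by default); host orthologs are derived by per-residue
substitution at `ortholog_mutation_rate` (default 0.05, a realistic
human/mouse protein divergence) with every K, R and P fixed and never
introduced, so tryptic frames coincide and species-unique peptides arise
only from substitutions inside aligned peptides — a deliberate
simplification of real homology, which also involves indels and locally
varying conservation. Ground truth is computed by digesting both proteomes
and comparing, so it is definitionally consistent with the classifier's
contract.

Spectral counts are negative-binomial: per protein and sample a total is
drawn with mean `baseline_mean` (default 20 PSMs) and size parameter
`dispersion` (default 5; variance μ + μ²/θ), then spread over the
protein's tryptic peptides by a uniform multinomial. Planted differential
hosts have their tumor mean multiplied by `effect_size` (default 8); spike
(graft) proteins draw counts in tumor samples only. All randomness flows
from one seed via `numpy.random.default_rng`; two deterministic
sub-streams (seed, 0) and (seed, 1) separate proteome from count
generation so the same proteome pair can be reused across count draws.

What the generator does *not* emulate: indels and domain-level homology,
protein-length–dependent peptide yields coupled to abundance, shared-peptide
quantification interference across host proteins, contaminants, and
missingness beyond sampling zeros. Passing tests therefore demonstrate the
pipeline's correctness on its own contract, not identification performance
on real spectra.

## Verification problem sizes

The statistical checks run at sizes chosen to keep Monte-Carlo error small
while remaining desk-scale: digestion-oracle equivalence on 500 random
sequences (length ≤ 60, 0–2 missed cleavages); classification recovery on
200 proteins per species at 5% divergence; screen calibration on 2,000
null negative-binomial proteins at 4 + 4 (the empirical p < 0.05 rate must
fall within 3 Monte-Carlo standard errors of 0.05); power on 20 planted
8-fold proteins among 400 at low dispersion (θ = 50), where sensitivity
must be ≥ 0.9. The planted fraction is kept at 5% because total-count
normalization is compositional: planting a large fraction of up-regulated
proteins shifts every null protein's normalized ratio downward, which is
visible in the worked example's false-positive Down calls and is a known
limitation of spectral-count normalization, not of the screen per se.

## Known limitations

- The species-uniqueness rule is stricter than locus-restricted manual
  comparison; it can only under-call, never over-call, graft peptides.
- Whether a reported "unique peptide count" means within-species-unique or
  merely distinct-per-protein is not decidable from the emulated design;
  the within-species definition is used throughout.
- Exclusive-protein reporting requires full presence in the owning group
  and zero detection in the other; relaxing criterion (3) is available via
  `require_full_presence=False`.
- The packaged concentration table is a static snapshot; the live urinary
  protein database is deliberately not queried, for reproducibility.
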