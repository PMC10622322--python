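# Methods

This note documents the models, parameter choices and numerical details
behind `haplopept`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Search-space model

A protein haplotype is modeled as a reference protein plus a set of
single amino acid substitutions (`posREF>ALT`, 1-based positions) with a
population frequency; indels and stop-gain/loss variation are out of
scope, so every haplotype record has its parent's length and peptide
spans on a haplotype project positionally onto reference coordinates.
Input reference sequences may contain `*` stop symbols (translated
internal stops); these are stripped and the 0-based junction positions
recorded, and any peptide whose span crosses a junction is discarded.
Non-standard residues (X, B, Z, U) are kept in records but peptides
containing them are excluded from digestion output.

The target database is one record per reference, per
(reference × haplotype) and per contaminant. Redundant haplotypes
(empty substitution sets, duplicate sequences) are retained but logged:
classification absorbs redundancy through the occurrence index, and
dropping records would silently change frequency bookkeeping.

## Digestion

Trypsin cleaves after K/R; by default a following proline suppresses
the site (`strict_kr` via `proline_rule=False` disables the exception).
Peptides are concatenations of 1..(max_missed+1) consecutive fully
cleaved fragments, filtered to 8–40 residues inclusive; defaults are 2
missed cleavages and 8–40, the standard settings for this kind of
search. Semi-tryptic peptides are not generated, N-terminal methionine
is never clipped, and I/L are distinct residues. The test suite checks
the enumeration against a brute-force substring oracle (all substrings
with cleavage-consistent boundaries and ≤2 internal sites) and against
an independent trypsin implementation.

## Classification and discoverability

The peptide index maps each unique peptide string to its occurrence set
(one occurrence per distinct (record, span); the same span reached at
different missed-cleavage levels counts once). The variant class is the
minimum substitution burden over occurrences; the downgrade rule means
a substitution is discoverable through a peptide only if the occurrence
containing it is not downgraded (its burden equals the peptide's
class). Specificity uses gene identity; contaminant records have no
gene and each counts as its own, so a peptide shared with a contaminant
is nonspecific. Contaminant occurrences carry no substitutions, and
therefore also downgrade a shared variant peptide to canonical.

Substitutions are keyed per protein isoform (accession, position, ref,
alt) without genomic-variant deduplication. Discoverability categories:
`single_only`, `multi_only`, `either` (typically a substitution whose
fragment merges with a second substitution's fragment at higher missed
cleavage), `not_discoverable`. The frequency stratification flags a
substitution when some haplotype carrying it is strictly more frequent
than the protein's reference haplotype (reference frequency = 1 − sum
of haplotype frequencies); aggregates are reported separately for
substitutions discoverable in single-variant and in multivariant
peptides.

## Coverage

Predicted coverage partitions each reference protein's residues:
variant-mapped ≻ canonical-only ≻ not-discoverable, with precedence to
the variant class; percentages are residue-weighted in the aggregate.
A residue covered only by a *downgraded* variant occurrence counts as
canonical-only: the region is coverable, but no substitution is
discoverable there. Nonspecific peptides contribute coverage to every
gene they map to; this double counting is inherent to shared peptides
and the count of identified nonspecific peptides is reported alongside.

Identified (observed) coverage fixes the residue strata by the
predicted partition and reports the share of each coverable stratum
actually covered: a canonical-only residue counts when any identified
peptide covers it, a variant-mapped residue when an identified
non-downgraded variant peptide does. This "darker shade within lighter
shade" convention makes identified coverage monotone in the identified
set and bounded by predicted coverage per class — recomputing the
partition from scratch on the identified subset would not have either
property, because removing a variant peptide reclassifies residues as
canonical.

Heterozygosity evidence: a gene is flagged in a sample when two
confident peptides in that sample overlap the same variant position
with different residues (reference-allele and alternative-allele
peptides observed together).

## PSM quality control

Peaks are matched greedily one-to-one in order of ascending ppm
difference (ties to the lower predicted m/z), with tolerance 10 ppm
relative to the predicted m/z — the prediction is the hypothesis being
tested. Predicted ions with missing intensity (NaN) yield the
"missing prediction" annotation and are excluded from the matched
vectors. Observed intensities are scaled so the observed median equals
the predicted median before similarity computation; angular similarity
is invariant to positive rescaling, so this affects mirror plots only.
The angle is computed with the numerically stable arctan form
(2·arctan2(|u−v|, |u+v|) for unit vectors u, v), which returns exactly
1 for proportional vectors where a naive arccos loses ~√ε. Similarity
over matched peaks only is the default; an n = 0 match is reported as
missing, never zero. With a single matched peak the similarity is
identically 1 and carries no information — a known limitation of
matched-only similarity for sparse matches.

Retention-time deviation is |z_obs − z_pred| where each series is
centered and scaled (sample SD, ddof = 1) on the calibration set of
confident PSMs; zero calibration variance is an error naming the
series. Target-decoy q-values use the simple competition estimator
(#decoys ≥ s)/(#targets ≥ s) without the +1 correction (switchable via
`plus_one=True`), running-minimum from worst to best score, capped at
1; tied scores share the FDR evaluated after the last tie. Confident
PSMs are targets with q < 0.01; matches to contaminant records are then
removed. Mirror-plot categories follow the matched / missing-prediction
/ unmatched scheme, and a peak matching a predicted ion with intensity
exactly zero is left unannotated.

## Synthetic data

The generator emulates the study conditions: by default 20 reference
proteins of 150–300 residues, residue composition uniform with K and R
boosted to 10% each so tryptic peptides land in the 8–40 window; 3
haplotypes per protein with frequencies drawn from a Dirichlet scaled
to a total non-reference share of 0.25–0.75, each ≥ the 1%
minor-allele-frequency floor (a single worldwide floor; population
structure is not modeled); substitution density 1.5 per 100 residues;
10% of substitutions replace a cleavage-site K/R. Haplotypes are
generated directly as phased substitution sets.

Two construction rules make the ground-truth manifest exact:

* each planted pair of substitutions shares one cleavage-free window
  (12–18 residues, flanked by arginines), in half the windows via an
  internal K whose K>E substitution removes the site;
* all other substitution pairs within a haplotype are separated by ≥3
  cleavage sites on the haplotype sequence, so no peptide with ≤2
  missed cleavages contains two of them.

Multivariant peptides therefore arise from planted windows only, and
the manifest enumerates their expected sequences (window fragment plus
missed-cleavage extensions, 8–40 filter) by a local fragment
enumeration that is independent of the digestion module. Expected
substitution classes are `multi_only` for planted pairs and
`single_only`/`not_discoverable` for the rest. Exactness relies on
unique random sequences; an 8-mer collision between unrelated proteins
(probability ~20⁻⁸ per pair) would downgrade a planted peptide.

Simulated PSMs: each unique peptide yields one true match whose
observed spectrum is the prediction corrupted with log-normal intensity
noise (σ = noise_level), uniform m/z jitter within ±10·noise_level ppm,
and Poisson spurious peaks — the simplest model that exercises the
10 ppm matcher; at noise 0 the observed spectrum equals the prediction
and angular similarity is exactly 1. Ions with missing intensity
predictions are still emitted in the observed spectrum (the molecule is
present even when the predictor is silent), exercising the
missing-prediction path. Planted false matches assign a spectrum the
best-scoring of several shuffled permutations of its source peptide,
mimicking how target-decoy competition selects the decoy sharing the
most fragment masses; naive random decoy pairing leaves ≤1 matched peak
per decoy, where matched-only similarity is degenerate. The score is
angular similarity weighted by the matched share of observed peaks.

The toy predictor computes exact singly charged b/y ion m/z values with
hash-derived deterministic intensities (5% missing by default) and a
position-weighted additive retention model (N-terminal residues count
less), so permuted peptides elute at different times. It is a stand-in
for learned fragment/RT predictors behind the same interface, not an
attempt at fragmentation physics: intensity patterns, isotope
envelopes, charge states >1 and chimeric spectra are not modeled.
Passing tests demonstrate the correctness of the bookkeeping and
statistics on data satisfying the stated assumptions, not
identification performance on real spectra.

## Pipeline

Stages exchange plain files (FASTA with a bit-exact header dialect,
TSV, MGF, JSON) so each can run and be inspected independently; the run
manifest records the configuration hash, seed, output checksums and row
counts, and a fixed seed reproduces every output byte-identically. The
QC stage simulates PSMs for up to 200 sampled peptides by default to
keep runs interactive; all sizes are configuration knobs.

## Known limitations

* Substitutions only: indels and stop-altering variants are excluded,
  and transcript-level processing is out of scope.
* Decoy generation resolves tryptic collisions by seeded reshuffling
  (segment interiors first, then a protein-wide shuffle of non-K/R
  residues); collisions surviving `max_attempts` are warnings, not
  errors, though none occur on the synthetic databases tested.
* Coverage double counting for nonspecific peptides is reported, not
  resolved; protein inference beyond the three specificity classes is
  out of scope.
* Posterior error probabilities are accepted as optional input columns
  and never computed.
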