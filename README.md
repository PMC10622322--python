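# haplopept

Haplotype-aware proteogenomics in Python: build a search space of
**protein haplotypes**, digest it in silico, classify peptides by variant
content and specificity, quantify proteome coverage and substitution
discoverability, generate collision-free decoys, and score
peptide-spectrum matches (PSMs) with spectrum-similarity and
retention-time quality control — all exercisable end-to-end on synthetic
data with a known ground truth.

## Why

Common genomic variants are inherited in linkage: co-occurring sets of
alleles (haplotypes) in protein-coding genes encode protein sequences
that may differ from the reference at several positions at once. After
tryptic digestion, two or more amino acid substitutions can land in the
*same* peptide — a **multivariant peptide** — which is invisible to a
standard proteomic search unless the haplotype sequence is in the
database. Worse, a substitution that removes a lysine or arginine
destroys a cleavage site, so the haplotype produces a peptide the
reference sequence cannot. This package provides the machinery to build
and analyze such haplotype-aware search spaces and to quality-control
the resulting matches.

## Core definitions

For a database of reference proteins, haplotype proteins (reference +
substitution set, length-preserving) and contaminants, digested with
trypsin (cleave after K/R not before P, up to 2 missed cleavages,
peptide length 8–40):

* **Variant class** of a unique peptide = the *minimum* substitution
  burden over all database sequences containing it: canonical (0),
  single-variant (1), multivariant (≥2). A peptide is *downgraded* by
  its least-variant occurrence, and substitutions inside a downgraded
  occurrence are not discoverable through that peptide.
* **Specificity class**: nonspecific (products of >1 gene),
  protein-specific (1 gene, >1 sequence), proteoform-specific (exactly
  1 sequence).
* **Coverage partition** on reference coordinates: a residue is
  *variant-mapped* if it lies in ≥1 discoverable non-downgraded peptide
  containing a substitution, *canonical-only* if covered only by
  substitution-free peptides, otherwise *not discoverable*.
* **Spectrum agreement**: observed and predicted peaks are matched
  one-to-one within 10 ppm; with matched intensity vectors
  M = (m₁…mₙ), P = (p₁…pₙ),

      C(M,P) = Σ mᵢpᵢ / (√Σ mᵢ² · √Σ pᵢ²)        (cosine similarity)
      A(M,P) = 1 − arccos(C(M,P)) / π            (angular similarity)

  so A ∈ [0.5, 1] for nonnegative intensities.
* **Confidence**: target-decoy competition; FDR(s) = #decoys ≥ s /
  #targets ≥ s, q-value = running minimum of FDR from worst to best
  score; confident PSMs have q < 0.01, contaminant matches removed.

## Worked example: a cleavage-site-destroying haplotype

Two linked substitutions on one protein region — `13D>E` and `18K>E`,
the second removing a tryptic site — merge two reference fragments into
a single fully tryptic multivariant peptide:

```python
from haplopept import digestion
from haplopept.haplotype_db import apply_substitutions
from haplopept.records import Haplotype, ProteinRecord, Substitution

ref = ProteinRecord(accession="REGION", sequence="VLWLDEIQQAVDDANVDKDR", gene_id="G")
hap = Haplotype("h1", "REGION",
                (Substitution(13, "D", "E"), Substitution(18, "K", "E")), 0.849)
hap_rec = apply_substitutions(ref, hap)
print("haplotype sequence:", hap_rec.sequence)
print("reference fragments:",
      [ref.sequence[a:b] for a, b in digestion.tryptic_fragments(ref.sequence)])
for occ in digestion.digest(hap_rec, max_missed=0):
    print(f"haplotype peptide: {occ.sequence}  substitutions: "
          + ";".join(s.notation() for s in occ.substitutions))
```

prints

```
haplotype sequence: VLWLDEIQQAVDEANVDEDR
reference fragments: ['VLWLDEIQQAVDDANVDK', 'DR']
haplotype peptide: VLWLDEIQQAVDEANVDEDR  substitutions: 13D>E;18K>E
```

The reference region digests into two fragments (one below the 8-residue
floor), while the haplotype yields a single 20-mer carrying both
substitutions — identifiable only with the haplotype in the database.

## Pipeline

```bash
haplopept run-all --outdir run --seed 7
```

runs synthetic-proteome generation → database + decoy construction →
digestion → classification → coverage → PSM simulation + QC, writing
plain FASTA/TSV/MGF/JSON files and a run manifest with checksums.
On the demo run above, the QC table separates true from planted-false
matches on every metric:

```
        score  angular_similarity  rt_deviation  q_value
decoy   0.143               0.845         0.226    0.218
target  0.786               0.940         0.050    0.000
```

Stages are also exposed individually (`simulate`, `build-db`, `digest`,
`classify`, `coverage`, `qc`) with a YAML config; see
`haplopept --help`.

## Layout

```
src/haplopept/
  records.py         core types (ProteinRecord, Substitution, Haplotype, ...)
  haplotype_db.py    haplotype sequences, target database, decoys, FASTA dialect
  digestion.py       tryptic cleavage, missed cleavages, length filters
  classification.py  variant/specificity classes, discoverability, frequencies
  coverage.py        residue-level coverage, identified substitutions, heterozygosity
  psm_qc.py          peak matching, angular similarity, RT calibration, q-values
  predictors.py      fragment/RT predictor interface + deterministic toy predictor
  synthetic_data.py  proteome/haplotype/PSM simulation with ground-truth manifest
  workflow.py, cli.py  stage orchestration and command-line interface
```

See `docs/methods.md` for the model, parameter choices, numerical
details and known limitations.
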