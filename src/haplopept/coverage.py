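"""Residue-level proteome coverage and identification summaries.

Coverage is computed on reference coordinates. Haplotypes preserve
length, so a peptide span on a haplotype record projects positionally
onto the parent reference. Each reference residue is:

* ``variant_mapped`` if it lies in at least one non-downgraded
  discoverable peptide whose occurrence contains a substitution;
* ``canonical_only`` if it is covered only by substitution-free (or
  downgraded) peptide occurrences;
* ``not_discoverable`` otherwise (the tryptic context is too short or
  too long to yield an identifiable peptide).

Nonspecific peptides contribute coverage to every gene they map to;
this double counting is inherent to shared peptides and is reported as
such. Aggregate percentages are residue-weighted over all reference
proteins.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import (
    PeptideClassification,
    SpecificityClass,
    VariantClass,
    occurrence_is_downgraded,
    substitution_key,
)
from .records import Haplotype, ProteinRecord

logger = logging.getLogger(__name__)

_NOT, _CANONICAL, _VARIANT = 0, 1, 2


class CoveragePartition:
    """Per-protein and aggregate coverage percentages.

    The three classes partition each protein: they sum to 100% within
    numerical tolerance.
    """

    def __init__(self, per_protein: pd.DataFrame):
        self.per_protein = per_protein

    @property
    def aggregate(self) -> dict[str, float]:
        total = float(self.per_protein["length"].sum())
        out = {}
        for col in ("canonical_only", "variant_mapped", "not_discoverable"):
            residues = (
                self.per_protein[col] / 100.0 * self.per_protein["length"]
            ).sum()
            out[col] = 100.0 * float(residues) / total if total else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        agg = self.aggregate
        agg_row = pd.DataFrame(
            [
                {
                    "accession": "AGGREGATE",
                    "length": int(self.per_protein["length"].sum()),
                    **agg,
                }
            ]
        )
        return pd.concat([self.per_protein, agg_row], ignore_index=True)


def _residue_status(
    references: Sequence[ProteinRecord],
    classifications: Mapping[str, PeptideClassification],
    peptide_filter: Iterable[str] | None = None,
) -> dict[str, np.ndarray]:
    """Status code per reference residue (0 not, 1 canonical, 2 variant)."""
    status = {
        rec.accession: np.zeros(len(rec.sequence), dtype=np.int8)
        for rec in references
    }
    keep = None if peptide_filter is None else set(peptide_filter)
    if keep is not None:
        missing = keep.difference(classifications)
        for pep in sorted(missing):
            logger.warning("identified peptide %r absent from index; skipped", pep)
    for pep, cls in classifications.items():
        if keep is not None and pep not in keep:
            continue
        for occ in cls.occurrences:
            arr = status.get(occ.reference_accession)
            if arr is None:  # contaminant (or unknown) parent: no projection
                continue
            is_variant = occ.substitutions and not occurrence_is_downgraded(
                occ, cls.variant_class
            )
            code = _VARIANT if is_variant else _CANONICAL
            np.maximum(
                arr[occ.start : occ.end], code, out=arr[occ.start : occ.end]
            )
    return status


def residue_coverage(
    references: Sequence[ProteinRecord],
    classifications: Mapping[str, PeptideClassification],
    peptide_filter: Iterable[str] | None = None,
) -> CoveragePartition:
    """Partition each reference protein's residues into coverage classes."""
    status = _residue_status(references, classifications, peptide_filter)
    rows = []
    for rec in references:
        arr = status[rec.accession]
        n = len(arr)
        rows.append(
            {
                "accession": rec.accession,
                "length": n,
                "canonical_only": 100.0 * float((arr == _CANONICAL).sum()) / n,
                "variant_mapped": 100.0 * float((arr == _VARIANT).sum()) / n,
                "not_discoverable": 100.0 * float((arr == _NOT).sum()) / n,
            }
        )
    return CoveragePartition(pd.DataFrame(rows))


def identified_coverage(
    identified_peptides: Iterable[str],
    references: Sequence[ProteinRecord],
    classifications: Mapping[str, PeptideClassification],
) -> dict[str, object]:
    """Observed-vs-predicted coverage report.

    Residue strata are fixed by the *predicted* partition; identified
    coverage is the share of each coverable stratum actually covered:
    a canonical_only residue counts when any identified peptide covers
    it, a variant_mapped residue when an identified non-downgraded
    variant peptide does. Identified coverage therefore never exceeds
    predicted coverage in any class, and grows monotonically with the
    identified set. Identified nonspecific peptides (mapping to several
    genes) are counted separately because they inflate per-gene
    coverage.
    """
    identified = set(identified_peptides)
    predicted_status = _residue_status(references, classifications)
    observed_status = _residue_status(references, classifications, identified)
    rows = []
    for rec in references:
        pred = predicted_status[rec.accession]
        obs = observed_status[rec.accession]
        n = len(pred)
        rows.append(
            {
                "accession": rec.accession,
                "length": n,
                "canonical_only": 100.0
                * float(((pred == _CANONICAL) & (obs >= _CANONICAL)).sum())
                / n,
                "variant_mapped": 100.0
                * float(((pred == _VARIANT) & (obs == _VARIANT)).sum())
                / n,
            }
        )
    observed_frame = pd.DataFrame(rows)
    total = float(observed_frame["length"].sum())
    aggregate = {
        col: 100.0
        * float((observed_frame[col] / 100.0 * observed_frame["length"]).sum())
        / total
        for col in ("canonical_only", "variant_mapped")
    }
    n_nonspecific = sum(
        1
        for pep in identified
        if pep in classifications
        and classifications[pep].specificity_class is SpecificityClass.NONSPECIFIC
    )
    return {
        "predicted": residue_coverage(references, classifications),
        "identified_per_protein": observed_frame,
        "identified_aggregate": aggregate,
        "n_identified_peptides": len(identified & classifications.keys()),
        "n_identified_nonspecific": n_nonspecific,
    }


def summarize_identified_substitutions(
    confident_psms: pd.DataFrame,
    classifications: Mapping[str, PeptideClassification],
) -> pd.DataFrame:
    """Per-sample identification status of substitutions.

    A substitution is identified in a sample iff at least one confident
    PSM in that sample maps to a non-downgraded peptide occurrence
    containing its alternative allele. The ``category`` column gives the
    kind of peptide evidence: single_variant, multivariant, or either.
    ``confident_psms`` needs ``peptide`` and ``sample_id`` columns.
    """
    seen: dict[tuple[str, tuple], set[VariantClass]] = {}
    for sample_id, group in confident_psms.groupby("sample_id"):
        for pep in set(group["peptide"]):
            cls = classifications.get(pep)
            if cls is None or cls.variant_class is VariantClass.CANONICAL:
                continue
            for occ in cls.occurrences:
                if not occ.substitutions or occurrence_is_downgraded(
                    occ, cls.variant_class
                ):
                    continue
                for sub in occ.substitutions:
                    key = (
                        str(sample_id),
                        substitution_key(occ.reference_accession, sub),
                    )
                    seen.setdefault(key, set()).add(cls.variant_class)
    rows = []
    for (sample_id, key), kinds in sorted(seen.items()):
        if kinds == {VariantClass.SINGLE_VARIANT}:
            category = "single_variant"
        elif kinds == {VariantClass.MULTIVARIANT}:
            category = "multivariant"
        else:
            category = "either"
        acc, pos, ref, alt = key
        rows.append(
            {
                "sample_id": sample_id,
                "protein_id": acc,
                "substitution": f"{pos}{ref}>{alt}",
                "category": category,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "protein_id", "substitution", "category"]
    )


def heterozygosity_evidence(
    confident_psms: pd.DataFrame,
    classifications: Mapping[str, PeptideClassification],
    haplotypes: Sequence[Haplotype],
) -> pd.DataFrame:
    """Genes with both alleles of a variant observed in one sample.

    A gene is flagged in a sample iff two confident peptides identified
    in that sample overlap the same variant position with different
    residues (e.g. a reference-allele and an alternative-allele
    peptide), the proteomic signature of heterozygosity.
    """
    var_positions: dict[str, set[int]] = {}
    for hap in haplotypes:
        pos = var_positions.setdefault(hap.parent_accession, set())
        pos.update(s.position for s in hap.substitutions)
    alleles: dict[tuple[str, str, str, int], dict[str, set[str]]] = {}
    for sample_id, group in confident_psms.groupby("sample_id"):
        for pep in set(group["peptide"]):
            cls = classifications.get(pep)
            if cls is None:
                continue
            for occ in cls.occurrences:
                positions = var_positions.get(occ.reference_accession)
                if not positions:
                    continue
                for pos in positions:
                    if occ.start <= pos - 1 < occ.end:
                        residue = pep[pos - 1 - occ.start]
                        entry = alleles.setdefault(
                            (str(sample_id), occ.gene_id, occ.reference_accession, pos),
                            {},
                        )
                        entry.setdefault(residue, set()).add(pep)
    rows = []
    for (sample_id, gene, acc, pos), by_res in sorted(alleles.items()):
        if len(by_res) < 2:
            continue
        rows.append(
            {
                "gene_id": gene,
                "sample_id": sample_id,
                "protein_id": acc,
                "position": pos,
                "alleles": "/".join(sorted(by_res)),
                "n_supporting_peptides": sum(len(v) for v in by_res.values()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "sample_id",
            "protein_id",
            "position",
            "alleles",
            "n_supporting_peptides",
        ],
    )
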