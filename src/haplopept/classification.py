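"""Peptide classification and substitution discoverability.

Each unique peptide string is assigned a variant class and a specificity
class from the full set of database sequences it occurs in:

* variant class - canonical (no substitutions), single-variant (exactly
  one) or multivariant (two or more). A peptide occurring with a lower
  substitution burden on another sequence is *downgraded* to that lower
  class, and substitutions sitting in a downgraded occurrence are not
  considered discoverable through it.
* specificity class - nonspecific (maps to products of several genes),
  protein-specific (one gene, several sequences) or proteoform-specific
  (exactly one sequence).

Substitutions are then stratified by the kind of peptide through which
they can be identified (single-variant only, multivariant only, either,
or not discoverable at all) and by whether a haplotype carrying them is
more frequent than the reference haplotype of the protein.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .records import Haplotype, PeptideOccurrence, Substitution

logger = logging.getLogger(__name__)

SubKey = tuple[str, int, str, str]  # (protein accession, position, ref, alt)


class VariantClass(str, Enum):
    CANONICAL = "canonical"
    SINGLE_VARIANT = "single_variant"
    MULTIVARIANT = "multivariant"

    @property
    def level(self) -> int:
        return _LEVELS[self]


_LEVELS = {
    VariantClass.CANONICAL: 0,
    VariantClass.SINGLE_VARIANT: 1,
    VariantClass.MULTIVARIANT: 2,
}


class SpecificityClass(str, Enum):
    NONSPECIFIC = "nonspecific"
    PROTEIN_SPECIFIC = "protein_specific"
    PROTEOFORM_SPECIFIC = "proteoform_specific"


class DiscoverabilityCategory(str, Enum):
    SINGLE_ONLY = "single_only"
    MULTI_ONLY = "multi_only"
    EITHER = "either"
    NOT_DISCOVERABLE = "not_discoverable"


@dataclass(frozen=True)
class PeptideClassification:
    peptide: str
    variant_class: VariantClass
    specificity_class: SpecificityClass
    occurrences: tuple[PeptideOccurrence, ...]
    genes: frozenset[str]


@dataclass(frozen=True)
class SubstitutionDiscoverability:
    substitution: Substitution
    parent_accession: str
    category: DiscoverabilityCategory
    in_haplotype_more_frequent_than_reference: bool | None = None


def variant_class_for_count(n: int) -> VariantClass:
    if n == 0:
        return VariantClass.CANONICAL
    if n == 1:
        return VariantClass.SINGLE_VARIANT
    return VariantClass.MULTIVARIANT


def build_peptide_index(
    occurrences: Iterable[PeptideOccurrence],
) -> dict[str, list[PeptideOccurrence]]:
    """Map each unique peptide string to its occurrence set.

    An occurrence is one distinct (record, span) pair: the same span
    reached at different missed-cleavage enumerations is kept once.
    Contaminant occurrences stay in the index (their ``kind`` marks
    them) so specificity can see them; they never carry substitutions.
    """
    index: dict[str, dict[tuple[str, int, int], PeptideOccurrence]] = {}
    for occ in occurrences:
        key = (occ.accession, occ.start, occ.end)
        index.setdefault(occ.sequence, {}).setdefault(key, occ)
    return {pep: list(occs.values()) for pep, occs in index.items()}


def classify_variant_status(
    occurrences: Sequence[PeptideOccurrence],
) -> VariantClass:
    """Minimum substitution burden over all occurrences (downgrade rule)."""
    if not occurrences:
        raise ValueError("cannot classify an empty occurrence set")
    return variant_class_for_count(min(o.n_substitutions for o in occurrences))


def _gene_key(occ: PeptideOccurrence) -> str:
    # contaminants have no gene annotation; each counts as its own gene so
    # a peptide shared with a contaminant is nonspecific
    return occ.gene_id if occ.gene_id else f"contaminant:{occ.accession}"


def classify_specificity(
    occurrences: Sequence[PeptideOccurrence],
) -> SpecificityClass:
    if not occurrences:
        raise ValueError("cannot classify an empty occurrence set")
    genes = {_gene_key(o) for o in occurrences}
    if len(genes) > 1:
        return SpecificityClass.NONSPECIFIC
    if len({o.accession for o in occurrences}) > 1:
        return SpecificityClass.PROTEIN_SPECIFIC
    return SpecificityClass.PROTEOFORM_SPECIFIC


def classify_peptides(
    index: Mapping[str, Sequence[PeptideOccurrence]],
) -> dict[str, PeptideClassification]:
    out: dict[str, PeptideClassification] = {}
    for pep, occs in index.items():
        out[pep] = PeptideClassification(
            peptide=pep,
            variant_class=classify_variant_status(occs),
            specificity_class=classify_specificity(occs),
            occurrences=tuple(occs),
            genes=frozenset(_gene_key(o) for o in occs),
        )
    return out


def occurrence_is_downgraded(
    occ: PeptideOccurrence, variant_class: VariantClass
) -> bool:
    """True if this occurrence's burden exceeds the peptide's class.

    Substitutions in a downgraded occurrence are not discoverable
    through that peptide.
    """
    return variant_class_for_count(occ.n_substitutions).level > variant_class.level


def substitution_key(parent_accession: str, sub: Substitution) -> SubKey:
    return (parent_accession, sub.position, sub.ref_residue, sub.alt_residue)


def substitution_discoverability(
    classifications: Mapping[str, PeptideClassification],
    haplotypes: Sequence[Haplotype],
    reference_frequencies: Mapping[str, float] | None = None,
) -> dict[SubKey, SubstitutionDiscoverability]:
    """Stratify every substitution by its discoverable peptide kinds.

    ``single_only``: every non-downgraded in-range peptide containing
    the substitution is single-variant; ``multi_only``: all are
    multivariant; ``either``: both kinds exist (typically depending on
    the number of missed cleavages); ``not_discoverable``: no such
    peptide. When ``reference_frequencies`` is given the
    more-frequent-than-reference flag is filled in.
    """
    universe: dict[SubKey, Substitution] = {}
    for hap in haplotypes:
        for sub in hap.substitutions:
            universe.setdefault(substitution_key(hap.parent_accession, sub), sub)
    kinds: dict[SubKey, set[VariantClass]] = {}
    for cls in classifications.values():
        if cls.variant_class is VariantClass.CANONICAL:
            continue
        for occ in cls.occurrences:
            if not occ.substitutions or occurrence_is_downgraded(occ, cls.variant_class):
                continue
            for sub in occ.substitutions:
                key = substitution_key(occ.reference_accession, sub)
                universe.setdefault(key, sub)
                kinds.setdefault(key, set()).add(cls.variant_class)
    flags = (
        frequency_stratify(haplotypes, reference_frequencies)
        if reference_frequencies is not None
        else {}
    )
    out: dict[SubKey, SubstitutionDiscoverability] = {}
    for key, sub in universe.items():
        seen = kinds.get(key, set())
        if not seen:
            category = DiscoverabilityCategory.NOT_DISCOVERABLE
        elif seen == {VariantClass.SINGLE_VARIANT}:
            category = DiscoverabilityCategory.SINGLE_ONLY
        elif seen == {VariantClass.MULTIVARIANT}:
            category = DiscoverabilityCategory.MULTI_ONLY
        else:
            category = DiscoverabilityCategory.EITHER
        out[key] = SubstitutionDiscoverability(
            substitution=sub,
            parent_accession=key[0],
            category=category,
            in_haplotype_more_frequent_than_reference=flags.get(key),
        )
    return out


def frequency_stratify(
    haplotypes: Sequence[Haplotype],
    reference_frequencies: Mapping[str, float],
) -> dict[SubKey, bool]:
    """Flag substitutions carried by a haplotype more frequent than reference.

    The flag is true iff some haplotype carrying the substitution has a
    frequency strictly greater than the reference haplotype's frequency
    for that protein. Substitutions on proteins with no known reference
    frequency are skipped (logged).
    """
    flags: dict[SubKey, bool] = {}
    for hap in haplotypes:
        ref_freq = reference_frequencies.get(hap.parent_accession)
        if ref_freq is None:
            if hap.substitutions:
                logger.warning(
                    "no reference frequency for %s; %d substitution(s) "
                    "excluded from frequency stratification",
                    hap.parent_accession,
                    len(hap.substitutions),
                )
            continue
        beats_ref = hap.frequency > ref_freq
        for sub in hap.substitutions:
            key = substitution_key(hap.parent_accession, sub)
            flags[key] = flags.get(key, False) or beats_ref
    return flags


def frequency_stratification_summary(
    discoverability: Mapping[SubKey, SubstitutionDiscoverability],
) -> dict[str, float]:
    """Fraction of discoverable substitutions beating the reference frequency.

    Reported separately for substitutions discoverable in single-variant
    peptides (single_only or either) and in multivariant peptides
    (multi_only or either), as percentages.
    """
    out: dict[str, float] = {}
    groups = {
        "single_variant_discoverable": {
            DiscoverabilityCategory.SINGLE_ONLY,
            DiscoverabilityCategory.EITHER,
        },
        "multivariant_discoverable": {
            DiscoverabilityCategory.MULTI_ONLY,
            DiscoverabilityCategory.EITHER,
        },
    }
    for name, cats in groups.items():
        pool = [
            d
            for d in discoverability.values()
            if d.category in cats
            and d.in_haplotype_more_frequent_than_reference is not None
        ]
        flagged = sum(
            1 for d in pool if d.in_haplotype_more_frequent_than_reference
        )
        out[name] = 100.0 * flagged / len(pool) if pool else float("nan")
    return out


# ---------------------------------------------------------------------------
# tabular export


def classification_table(
    classifications: Mapping[str, PeptideClassification],
) -> pd.DataFrame:
    rows = []
    for cls in classifications.values():
        subs = sorted(
            {
                s.notation()
                for o in cls.occurrences
                for s in o.substitutions
            }
        )
        rows.append(
            {
                "peptide": cls.peptide,
                "variant_class": cls.variant_class.value,
                "specificity_class": cls.specificity_class.value,
                "n_genes": len(cls.genes),
                "n_records": len({o.accession for o in cls.occurrences}),
                "substitutions": ";".join(subs),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "variant_class",
            "specificity_class",
            "n_genes",
            "n_records",
            "substitutions",
        ],
    ).sort_values("peptide", ignore_index=True)


def discoverability_table(
    discoverability: Mapping[SubKey, SubstitutionDiscoverability],
) -> pd.DataFrame:
    rows = []
    for key, d in sorted(discoverability.items()):
        rows.append(
            {
                "protein_id": d.parent_accession,
                "variant_id": d.substitution.variant_id,
                "position": d.substitution.position,
                "substitution": d.substitution.notation(),
                "category": d.category.value,
                "more_frequent_than_reference": d.in_haplotype_more_frequent_than_reference,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "variant_id",
            "position",
            "substitution",
            "category",
            "more_frequent_than_reference",
        ],
    )
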