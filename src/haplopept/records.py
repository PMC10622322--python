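"""Core domain types shared across the pipeline.

Coordinate conventions: substitution positions are 1-based (``527D>E``
notation), every span stored on a record or peptide is a 0-based
half-open interval. Sequences use the 20 standard one-letter amino acid
codes; non-standard residues (X, B, Z, U) may appear in input references
but peptides containing them are excluded during digestion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
NONSTANDARD_AA = "XBZUJO"

_SUB_RE = re.compile(r"^(\d+)([A-Z*])>([A-Z*])$")


class DataIntegrityError(ValueError):
    """Raised when input data contradicts itself (e.g. ref-residue mismatch)."""


class ConfigurationError(ValueError):
    """Raised for impossible or inconsistent configuration values."""


@dataclass(frozen=True, order=True)
class Substitution:
    """A single amino acid substitution on a protein.

    ``position`` is 1-based, as in the conventional ``527D>E`` notation.
    ``allele_frequency`` is the population frequency of the alternative
    allele (may be ``None`` when unknown).
    """

    position: int
    ref_residue: str
    alt_residue: str
    variant_id: str = field(default="", compare=False)
    allele_frequency: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"substitution position must be >= 1, got {self.position}")
        if self.ref_residue == self.alt_residue:
            raise ValueError(
                f"substitution at {self.position} has identical ref and alt "
                f"residue {self.ref_residue!r}"
            )
        for res in (self.ref_residue, self.alt_residue):
            if len(res) != 1 or not res.isalpha() or not res.isupper():
                raise ValueError(f"invalid residue {res!r}")

    @classmethod
    def parse(
        cls,
        text: str,
        variant_id: str = "",
        allele_frequency: float | None = None,
    ) -> "Substitution":
        """Parse ``posREF>ALT`` notation, e.g. ``527D>E``."""
        m = _SUB_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse substitution notation {text!r}")
        return cls(
            position=int(m.group(1)),
            ref_residue=m.group(2),
            alt_residue=m.group(3),
            variant_id=variant_id,
            allele_frequency=allele_frequency,
        )

    def notation(self) -> str:
        return f"{self.position}{self.ref_residue}>{self.alt_residue}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation()


@dataclass(frozen=True)
class Haplotype:
    """A set of co-occurring substitutions on one protein, with a frequency.

    The frequency is the population frequency of the haplotype; per
    protein the haplotype frequencies plus the reference-haplotype
    frequency sum to 1.
    """

    haplotype_id: str
    parent_accession: str
    substitutions: tuple[Substitution, ...]
    frequency: float

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.substitutions))
        object.__setattr__(self, "substitutions", subs)
        positions = [s.position for s in subs]
        if len(set(positions)) != len(positions):
            raise ValueError(
                f"haplotype {self.haplotype_id} has duplicate substitution positions"
            )
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(
                f"haplotype frequency must be in [0, 1], got {self.frequency}"
            )

    def subs_notation(self) -> str:
        return ";".join(s.notation() for s in self.substitutions)


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: reference, haplotype, contaminant or decoy.

    ``stop_junctions`` are 0-based indices in the cleaned sequence
    immediately after a removed stop symbol; peptides spanning a junction
    are excluded downstream. Haplotype records carry their substitutions
    so digestion can annotate peptides, and ``parent_accession`` names
    the reference record they derive from.
    """

    accession: str
    sequence: str
    gene_id: str = ""
    kind: str = "reference"  # reference | haplotype | contaminant | decoy
    parent_accession: str = ""
    stop_junctions: frozenset[int] = frozenset()
    substitutions: tuple[Substitution, ...] = ()
    haplotype_id: str = ""
    frequency: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"reference", "haplotype", "contaminant", "decoy"}:
            raise ValueError(f"unknown record kind {self.kind!r}")
        if "*" in self.sequence:
            raise ValueError(
                f"{self.accession}: sequence still contains '*'; "
                "strip stop symbols first"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def reference_accession(self) -> str:
        """Accession of the reference this record projects onto."""
        return self.parent_accession if self.kind == "haplotype" else self.accession


@dataclass(frozen=True)
class PeptideOccurrence:
    """A peptide located on one database entry.

    ``span`` fields (``start``, ``end``) are 0-based half-open
    coordinates on the parent record. Because haplotypes preserve length,
    the same span projects positionally onto the parent reference.
    """

    sequence: str
    accession: str
    start: int
    end: int
    missed_cleavages: int
    substitutions: tuple[Substitution, ...] = ()
    gene_id: str = ""
    kind: str = "reference"
    parent_accession: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"span [{self.start}, {self.end}) does not match peptide "
                f"length {len(self.sequence)}"
            )
        for sub in self.substitutions:
            if not (self.start <= sub.position - 1 < self.end):
                raise ValueError(
                    f"substitution {sub.notation()} outside span "
                    f"[{self.start}, {self.end})"
                )

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def reference_accession(self) -> str:
        return self.parent_accession if self.kind == "haplotype" else self.accession
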