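"""In silico tryptic digestion.

Trypsin cleaves C-terminal to lysine (K) or arginine (R); by default the
canonical exception applies and a site followed by proline (P) is not
cleaved. Peptides are formed by merging up to ``max_missed + 1``
consecutive fully cleaved fragments and filtered to a length window
(default 8-40 residues). Peptides that cross a stop-codon junction or
contain a non-standard residue are removed.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

from .records import NONSTANDARD_AA, PeptideOccurrence, ProteinRecord

DEFAULT_LENGTH_RANGE = (8, 40)
DEFAULT_MAX_MISSED = 2

_NONSTANDARD = set(NONSTANDARD_AA)


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based positions after which trypsin cleaves.

    Position ``i`` is a site iff residue ``i`` is K or R and residue
    ``i + 1`` exists and (under the default proline rule) is not P. The
    C-terminus is not a site: it terminates the last fragment anyway.
    With ``proline_rule=False`` cleavage occurs after every internal K/R.
    """
    sites: list[int] = []
    last = len(sequence) - 1
    for i, res in enumerate(sequence):
        if res in "KR" and i < last:
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def tryptic_fragments(
    sequence: str, proline_rule: bool = True
) -> list[tuple[int, int]]:
    """Spans of the fully cleaved (0 missed cleavages) fragments."""
    bounds = [0] + [s + 1 for s in cleavage_sites(sequence, proline_rule)]
    bounds.append(len(sequence))
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _spans(
    sequence: str, max_missed: int, proline_rule: bool
) -> Iterator[tuple[int, int, int]]:
    frags = tryptic_fragments(sequence, proline_rule)
    n = len(frags)
    for i in range(n):
        for k in range(min(max_missed + 1, n - i)):
            yield frags[i][0], frags[i + k][1], k


def digest(
    record: ProteinRecord,
    max_missed: int = DEFAULT_MAX_MISSED,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    proline_rule: bool = True,
) -> list[PeptideOccurrence]:
    """Enumerate fully tryptic peptides of a record.

    Output covers every concatenation of 1..``max_missed + 1``
    consecutive fragments whose length falls inside ``length_range``
    (inclusive), excluding peptides that span a stop junction or contain
    a non-standard residue. ``contained_substitutions`` are taken from
    the record (haplotype records carry them; reference and contaminant
    records have none).
    """
    if not record.sequence:
        raise ValueError(f"{record.accession}: cannot digest empty sequence")
    lo, hi = length_range
    out: list[PeptideOccurrence] = []
    seq = record.sequence
    junctions = record.stop_junctions
    for start, end, k in _spans(seq, max_missed, proline_rule):
        length = end - start
        if length < lo or length > hi:
            continue
        if any(start < j < end for j in junctions):
            continue
        pep = seq[start:end]
        if _NONSTANDARD.intersection(pep):
            continue
        subs = tuple(
            s for s in record.substitutions if start <= s.position - 1 < end
        )
        out.append(
            PeptideOccurrence(
                sequence=pep,
                accession=record.accession,
                start=start,
                end=end,
                missed_cleavages=k,
                substitutions=subs,
                gene_id=record.gene_id,
                kind=record.kind,
                parent_accession=record.parent_accession,
            )
        )
    return out


def digest_sequence(
    sequence: str,
    max_missed: int = DEFAULT_MAX_MISSED,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    proline_rule: bool = True,
) -> set[str]:
    """In-range tryptic peptide strings of a bare sequence (no annotation)."""
    lo, hi = length_range
    return {
        sequence[s:e]
        for s, e, _ in _spans(sequence, max_missed, proline_rule)
        if lo <= e - s <= hi and not _NONSTANDARD.intersection(sequence[s:e])
    }


def digest_all(
    records: Iterable[ProteinRecord],
    max_missed: int = DEFAULT_MAX_MISSED,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    proline_rule: bool = True,
) -> list[PeptideOccurrence]:
    """Digest every record, concatenating the occurrence lists."""
    out: list[PeptideOccurrence] = []
    for rec in records:
        out.extend(digest(rec, max_missed, length_range, proline_rule))
    return out
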