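"""Protein haplotype database construction.

Builds haplotype sequences by applying substitution sets to reference
proteins, assembles the target database (references + haplotypes +
contaminants) and generates collision-free decoys by per-segment
sequence reversal with seeded reshuffling (the DecoyPyrat strategy).

FASTA header dialect (bit-exact, round-trippable):

* reference    ``>ref|{accession}|gene={gene_id}``
* haplotype    ``>hap|{parent}-{hap_id}|gene={gene} subs={pos}{R}>{A}[;...] freq={f:.6f}``
* contaminant  ``>cont|{accession}``
* decoy        ``>decoy_{original header}``
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import digestion
from .records import (
    DataIntegrityError,
    Haplotype,
    ProteinRecord,
    Substitution,
)

logger = logging.getLogger(__name__)

DECOY_PREFIX = "decoy_"


def strip_stop_symbols(raw_sequence: str) -> tuple[str, frozenset[int]]:
    """Remove ``*`` stop symbols, recording junction positions.

    Returns the cleaned sequence and the set of 0-based indices in the
    cleaned sequence immediately after each removal. Peptides whose span
    crosses a junction are excluded during digestion, because the
    translated protein would contain a stop codon there.
    """
    clean: list[str] = []
    junctions: set[int] = set()
    for res in raw_sequence:
        if res == "*":
            junctions.add(len(clean))
        else:
            clean.append(res)
    return "".join(clean), frozenset(junctions)


def apply_substitutions(reference: ProteinRecord, haplotype: Haplotype) -> ProteinRecord:
    """Construct the haplotype protein sequence from a reference.

    Substitutions only (no indels), so the output has the reference
    length and differs exactly at the substituted positions. Raises
    :class:`DataIntegrityError` if a substitution's stated reference
    residue does not match the sequence.
    """
    seq = list(reference.sequence)
    for sub in haplotype.substitutions:
        idx = sub.position - 1
        if idx >= len(seq):
            raise DataIntegrityError(
                f"{reference.accession}: substitution position {sub.position} "
                f"beyond sequence length {len(seq)}"
            )
        if seq[idx] != sub.ref_residue:
            raise DataIntegrityError(
                f"{reference.accession}: substitution {sub.notation()} claims "
                f"reference residue {sub.ref_residue!r} at position "
                f"{sub.position} but sequence has {seq[idx]!r}"
            )
        seq[idx] = sub.alt_residue
    return ProteinRecord(
        accession=f"{reference.accession}-{haplotype.haplotype_id}",
        sequence="".join(seq),
        gene_id=reference.gene_id,
        kind="haplotype",
        parent_accession=reference.accession,
        stop_junctions=reference.stop_junctions,
        substitutions=haplotype.substitutions,
        haplotype_id=haplotype.haplotype_id,
        frequency=haplotype.frequency,
    )


def build_target_database(
    references: Sequence[ProteinRecord],
    haplotypes: Sequence[Haplotype],
    contaminants: Sequence[ProteinRecord] = (),
) -> list[ProteinRecord]:
    """Assemble the target search space.

    One record per reference, per (reference x haplotype) and per
    contaminant. Redundant haplotypes (no substitutions, or sequence
    identical to another record of the same parent) are kept but logged,
    mirroring how the classification stage absorbs redundancy.
    """
    by_acc = {r.accession: r for r in references}
    if len(by_acc) != len(references):
        raise DataIntegrityError("duplicate reference accessions")
    records: list[ProteinRecord] = list(references)
    seen_seqs: dict[str, set[str]] = {}
    for hap in haplotypes:
        parent = by_acc.get(hap.parent_accession)
        if parent is None:
            raise DataIntegrityError(
                f"haplotype {hap.haplotype_id} references unknown protein "
                f"{hap.parent_accession}"
            )
        rec = apply_substitutions(parent, hap)
        pool = seen_seqs.setdefault(parent.accession, {parent.sequence})
        if not hap.substitutions:
            logger.warning(
                "haplotype %s of %s is redundant: no substitutions",
                hap.haplotype_id,
                parent.accession,
            )
        elif rec.sequence in pool:
            logger.warning(
                "haplotype %s of %s is redundant: duplicate sequence",
                hap.haplotype_id,
                parent.accession,
            )
        pool.add(rec.sequence)
        records.append(rec)
    records.extend(contaminants)
    accs = [r.accession for r in records]
    if len(set(accs)) != len(accs):
        raise DataIntegrityError("duplicate accessions in target database")
    return records


# ---------------------------------------------------------------------------
# decoys


def _reverse_segments(sequence: str, proline_rule: bool) -> str:
    """Reverse each cleavage-delimited segment, keeping terminal K/R in place."""
    sites = digestion.cleavage_sites(sequence, proline_rule)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    parts: list[str] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = sequence[a:b]
        if seg and seg[-1] in "KR":
            parts.append(seg[:-1][::-1] + seg[-1])
        else:
            parts.append(seg[::-1])
    return "".join(parts)


def _shuffle_segments(
    sequence: str, rng: np.random.Generator, proline_rule: bool
) -> str:
    """Shuffle segment interiors (terminal K/R stays), preserving composition."""
    sites = digestion.cleavage_sites(sequence, proline_rule)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    parts: list[str] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = sequence[a:b]
        if seg and seg[-1] in "KR":
            interior, tail = list(seg[:-1]), seg[-1]
        else:
            interior, tail = list(seg), ""
        rng.shuffle(interior)
        parts.append("".join(interior) + tail)
    return "".join(parts)


def _shuffle_global(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle all non-K/R residues across the protein; K/R stay in place.

    Escalation for stubborn collisions: segment-interior shuffles are
    fixed points on segments of length <= 2, so peptides built from
    short segments can never move. Keeping every K/R in place preserves
    the cleavage structure and the residue composition.
    """
    chars = list(sequence)
    idx = [i for i, c in enumerate(chars) if c not in "KR"]
    pool = [chars[i] for i in idx]
    rng.shuffle(pool)
    for i, c in zip(idx, pool):
        chars[i] = c
    return "".join(chars)


def generate_decoys(
    targets: Sequence[ProteinRecord],
    max_attempts: int = 10,
    seed: int = 0,
    proline_rule: bool = True,
    max_missed: int = digestion.DEFAULT_MAX_MISSED,
    length_range: tuple[int, int] = digestion.DEFAULT_LENGTH_RANGE,
) -> list[ProteinRecord]:
    """One decoy per target by segment reversal, reshuffled on collision.

    A decoy tryptic peptide (in ``length_range``, up to ``max_missed``
    missed cleavages) colliding with any target peptide triggers a
    seeded reshuffle of that decoy, up to ``max_attempts``; residue
    composition per protein is preserved throughout. Collisions that
    survive all attempts are reported as warnings, never errors.
    """
    if not targets:
        raise ValueError("cannot generate decoys for an empty target set")
    target_peptides: set[str] = set()
    for rec in targets:
        target_peptides |= digestion.digest_sequence(
            rec.sequence, max_missed, length_range, proline_rule
        )
    rng = np.random.default_rng(seed)
    decoys: list[ProteinRecord] = []
    n_colliding = 0
    for rec in targets:
        decoy_seq = _reverse_segments(rec.sequence, proline_rule)
        attempts = 0
        while (
            digestion.digest_sequence(decoy_seq, max_missed, length_range, proline_rule)
            & target_peptides
            and attempts < max_attempts
        ):
            if attempts < max_attempts // 2:
                decoy_seq = _shuffle_segments(rec.sequence, rng, proline_rule)
            else:
                decoy_seq = _shuffle_global(rec.sequence, rng)
            attempts += 1
        remaining = (
            digestion.digest_sequence(decoy_seq, max_missed, length_range, proline_rule)
            & target_peptides
        )
        if remaining:
            n_colliding += 1
            logger.warning(
                "decoy of %s still shares %d peptide(s) with targets after "
                "%d attempts",
                rec.accession,
                len(remaining),
                max_attempts,
            )
        decoys.append(
            ProteinRecord(
                accession=DECOY_PREFIX + rec.accession,
                sequence=decoy_seq,
                gene_id=rec.gene_id,
                kind="decoy",
                parent_accession=rec.accession,
            )
        )
    if n_colliding:
        logger.warning("%d/%d decoys retain target collisions", n_colliding, len(targets))
    return decoys


# ---------------------------------------------------------------------------
# FASTA I/O


def fasta_header(record: ProteinRecord) -> str:
    """Header line (without '>') in the database dialect."""
    if record.kind == "reference":
        return f"ref|{record.accession}|gene={record.gene_id}"
    if record.kind == "haplotype":
        subs = ";".join(s.notation() for s in record.substitutions)
        freq = 0.0 if record.frequency is None else record.frequency
        return (
            f"hap|{record.accession}|gene={record.gene_id} "
            f"subs={subs} freq={freq:.6f}"
        )
    if record.kind == "contaminant":
        return f"cont|{record.accession}"
    # decoy: the original header with a prefix
    original = ProteinRecord(
        accession=record.parent_accession or record.accession[len(DECOY_PREFIX):],
        sequence=record.sequence,
        gene_id=record.gene_id,
        kind="reference",
    )
    return DECOY_PREFIX + fasta_header(original)


def parse_fasta_header(header: str, sequence: str) -> ProteinRecord:
    """Reconstruct a :class:`ProteinRecord` from a header in the dialect."""
    kind_map = {"ref": "reference", "hap": "haplotype", "cont": "contaminant"}
    if header.startswith(DECOY_PREFIX):
        inner = parse_fasta_header(header[len(DECOY_PREFIX):], sequence)
        return ProteinRecord(
            accession=DECOY_PREFIX + inner.accession,
            sequence=sequence,
            gene_id=inner.gene_id,
            kind="decoy",
            parent_accession=inner.accession,
        )
    head, _, attrs = header.partition(" ")
    fields = head.split("|")
    kind = kind_map.get(fields[0])
    if kind is None:
        raise ValueError(f"unrecognized FASTA header {header!r}")
    accession = fields[1]
    gene_id = ""
    if len(fields) > 2 and fields[2].startswith("gene="):
        gene_id = fields[2][len("gene="):]
    if kind != "haplotype":
        return ProteinRecord(accession=accession, sequence=sequence, gene_id=gene_id, kind=kind)
    subs: tuple[Substitution, ...] = ()
    freq = 0.0
    for token in attrs.split():
        key, _, value = token.partition("=")
        if key == "subs" and value:
            subs = tuple(Substitution.parse(t) for t in value.split(";"))
        elif key == "freq":
            freq = float(value)
    parent, _, hap_id = accession.rpartition("-")
    return ProteinRecord(
        accession=accession,
        sequence=sequence,
        gene_id=gene_id,
        kind="haplotype",
        parent_accession=parent,
        substitutions=subs,
        haplotype_id=hap_id,
        frequency=freq,
    )


def haplotype_from_record(record: ProteinRecord) -> Haplotype:
    """Recover the :class:`Haplotype` encoded on a haplotype record."""
    if record.kind != "haplotype":
        raise ValueError(f"{record.accession} is not a haplotype record")
    return Haplotype(
        haplotype_id=record.haplotype_id,
        parent_accession=record.parent_accession,
        substitutions=record.substitutions,
        frequency=record.frequency or 0.0,
    )


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqs = []
    for rec in records:
        header = fasta_header(rec)
        rec_id, _, desc = header.partition(" ")
        seqs.append(SeqRecord(Seq(rec.sequence), id=rec_id, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[ProteinRecord]:
    out = []
    for sr in SeqIO.parse(str(path), "fasta"):
        header = sr.description if sr.description else sr.id
        out.append(parse_fasta_header(header, str(sr.seq)))
    return out


# ---------------------------------------------------------------------------
# haplotype table TSV


def write_haplotype_table(haplotypes: Iterable[Haplotype], path) -> None:
    """TSV: protein_id, haplotype_id, substitutions (``;``-joined), frequency."""
    with open(path, "w") as fh:
        fh.write("protein_id\thaplotype_id\tsubstitutions\tfrequency\n")
        for hap in haplotypes:
            fh.write(
                f"{hap.parent_accession}\t{hap.haplotype_id}\t"
                f"{hap.subs_notation()}\t{hap.frequency:.6f}\n"
            )


def read_haplotype_table(path) -> list[Haplotype]:
    out: list[Haplotype] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            subs_field = row[idx["substitutions"]]
            subs = tuple(
                Substitution.parse(t) for t in subs_field.split(";") if t
            )
            out.append(
                Haplotype(
                    haplotype_id=row[idx["haplotype_id"]],
                    parent_accession=row[idx["protein_id"]],
                    substitutions=subs,
                    frequency=float(row[idx["frequency"]]),
                )
            )
    return out
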