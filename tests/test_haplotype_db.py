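"""Haplotype sequence construction, database assembly and decoy generation."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from haplopept import digestion
from haplopept.haplotype_db import (
    apply_substitutions,
    build_target_database,
    fasta_header,
    generate_decoys,
    haplotype_from_record,
    parse_fasta_header,
    read_fasta,
    read_haplotype_table,
    strip_stop_symbols,
    write_fasta,
    write_haplotype_table,
)
from haplopept.records import (
    DataIntegrityError,
    Haplotype,
    ProteinRecord,
    Substitution,
)


class TestStripStopSymbols:
    @pytest.mark.parametrize(
        "raw, clean, junctions",
        [
            ("AAAAK*CCCCK", "AAAAKCCCCK", {5}),
            ("ACDEF", "ACDEF", set()),
            ("**AB", "AB", {0}),
            ("AB*CD*EF", "ABCDEF", {2, 4}),
            ("ABC*", "ABC", {3}),
        ],
    )
    def test_examples(self, raw, clean, junctions):
        seq, j = strip_stop_symbols(raw)
        assert seq == clean
        assert j == frozenset(junctions)

    def test_junction_blocks_spanning_peptides(self):
        seq, junctions = strip_stop_symbols("AAAAK*CCCCKDDDDDDDD")
        rec = ProteinRecord(accession="X", sequence=seq, stop_junctions=junctions)
        peps = digestion.digest(rec)
        assert all(not (occ.start < 5 < occ.end) for occ in peps)
        assert {p.sequence for p in peps} == {"DDDDDDDD", "CCCCKDDDDDDDD"}


class TestApplySubstitutions:
    def test_double_substitution_removes_cleavage_site(self):
        # two linked substitutions, the second destroying a tryptic site
        region = "VLWLDEIQQAVDDANVDKDR"
        hap = Haplotype(
            haplotype_id="h1",
            parent_accession="Q",
            substitutions=(
                Substitution(13, "D", "E", variant_id="rs2431352"),
                Substitution(18, "K", "E", variant_id="rs2909888"),
            ),
            frequency=0.849,
        )
        ref = ProteinRecord(accession="Q", sequence=region, gene_id="QG")
        out = apply_substitutions(ref, hap)
        assert out.sequence == "VLWLDEIQQAVDEANVDEDR"
        assert out.kind == "haplotype"
        assert len(out) == len(ref)

    def test_empty_substitution_set_is_identity(self):
        ref = ProteinRecord(accession="A", sequence="ACDEFGHIK")
        hap = Haplotype("h1", "A", (), 0.1)
        assert apply_substitutions(ref, hap).sequence == ref.sequence

    def test_ref_residue_mismatch_raises_with_position(self):
        ref = ProteinRecord(accession="A", sequence="ACDEFGHIK")
        hap = Haplotype("h1", "A", (Substitution(3, "K", "E"),), 0.1)
        with pytest.raises(DataIntegrityError, match="position 3"):
            apply_substitutions(ref, hap)

    def test_position_beyond_length_raises(self):
        ref = ProteinRecord(accession="A", sequence="ACDEF")
        hap = Haplotype("h1", "A", (Substitution(9, "K", "E"),), 0.1)
        with pytest.raises(DataIntegrityError):
            apply_substitutions(ref, hap)

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_apply_then_revert_roundtrip(self, data):
        seq = data.draw(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=60)
        )
        n = data.draw(st.integers(0, min(3, len(seq))))
        positions = data.draw(
            st.lists(
                st.integers(1, len(seq)), min_size=n, max_size=n, unique=True
            )
        )
        subs = []
        for pos in positions:
            ref_res = seq[pos - 1]
            alt = data.draw(
                st.sampled_from(
                    [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != ref_res]
                )
            )
            subs.append(Substitution(pos, ref_res, alt))
        ref = ProteinRecord(accession="A", sequence=seq)
        hap = Haplotype("h1", "A", tuple(subs), 0.5)
        applied = apply_substitutions(ref, hap)
        reverted = Haplotype(
            "r",
            "A-h1",
            tuple(
                Substitution(s.position, s.alt_residue, s.ref_residue)
                for s in subs
            ),
            0.5,
        )
        back = apply_substitutions(
            ProteinRecord(accession="A-h1", sequence=applied.sequence), reverted
        )
        assert back.sequence == seq


class TestBuildTargetDatabase:
    def test_record_counting(self):
        refs = [
            ProteinRecord(accession="A", sequence="ACDEFGHIK", gene_id="G1"),
            ProteinRecord(accession="B", sequence="LMNPQRSTV", gene_id="G2"),
        ]
        haps = [
            Haplotype(f"h{i}", "A", (Substitution(1, "A", alt),), 0.1)
            for i, alt in enumerate("CDE", start=1)
        ]
        conts = [ProteinRecord(accession="C1", sequence="WYWYWYWYW", kind="contaminant")]
        db = build_target_database(refs, haps, conts)
        assert len(db) == 6
        kinds = [r.kind for r in db]
        assert kinds.count("haplotype") == 3

    def test_redundant_haplotype_logged_but_kept(self, caplog):
        refs = [ProteinRecord(accession="A", sequence="ACDEFGHIK", gene_id="G1")]
        haps = [Haplotype("h1", "A", (), 0.2)]
        with caplog.at_level(logging.WARNING, logger="haplopept.haplotype_db"):
            db = build_target_database(refs, haps)
        assert len(db) == 2
        assert any("redundant" in r.message for r in caplog.records)

    def test_duplicate_accession_raises(self):
        refs = [
            ProteinRecord(accession="A", sequence="ACDEFGHIK"),
            ProteinRecord(accession="A", sequence="LMNPQRSTV"),
        ]
        with pytest.raises(DataIntegrityError):
            build_target_database(refs, [])

    def test_unknown_parent_raises(self):
        refs = [ProteinRecord(accession="A", sequence="ACDEFGHIK")]
        haps = [Haplotype("h1", "Z", (Substitution(1, "A", "C"),), 0.1)]
        with pytest.raises(DataIntegrityError):
            build_target_database(refs, haps)


class TestFastaDialect:
    def test_haplotype_header_roundtrip(self):
        rec = ProteinRecord(
            accession="P0001-h2",
            sequence="ACDEFGHIK",
            gene_id="G0001",
            kind="haplotype",
            parent_accession="P0001",
            substitutions=(
                Substitution(2, "C", "W", allele_frequency=0.25),
                Substitution(5, "F", "L", allele_frequency=0.25),
            ),
            haplotype_id="h2",
            frequency=0.25,
        )
        header = fasta_header(rec)
        assert header == "hap|P0001-h2|gene=G0001 subs=2C>W;5F>L freq=0.250000"
        parsed = parse_fasta_header(header, rec.sequence)
        assert haplotype_from_record(parsed) == haplotype_from_record(rec)

    def test_fasta_file_roundtrip(self, tmp_path, small_proteome):
        _, refs, haps, _ = small_proteome
        db = build_target_database(refs, haps)
        path = tmp_path / "db.fasta"
        write_fasta(db, path)
        back = read_fasta(path)
        assert [r.accession for r in back] == [r.accession for r in db]
        assert [r.sequence for r in back] == [r.sequence for r in db]
        assert [r.kind for r in back] == [r.kind for r in db]

    def test_decoy_header_prefixes_original(self):
        ref = ProteinRecord(accession="A", sequence="ACDEKFGHIR", gene_id="G1")
        decoy = generate_decoys([ref], seed=0)[0]
        assert fasta_header(decoy).startswith("decoy_ref|A|")

    def test_haplotype_table_roundtrip(self, tmp_path, small_proteome):
        _, _, haps, _ = small_proteome
        path = tmp_path / "haps.tsv"
        write_haplotype_table(haps, path)
        back = read_haplotype_table(path)
        assert len(back) == len(haps)
        for a, b in zip(back, haps):
            assert a.parent_accession == b.parent_accession
            assert a.substitutions == b.substitutions
            assert a.frequency == pytest.approx(b.frequency, abs=1e-6)


class TestGenerateDecoys:
    def test_segment_reversal_keeps_terminal_kr(self):
        rec = ProteinRecord(accession="A", sequence="ACDEKFGHIR")
        decoy = generate_decoys([rec], seed=0)[0]
        assert decoy.sequence == "EDCAKIHGFR"
        assert decoy.accession == "decoy_A"

    def test_all_k_sequence_is_fixed_point(self):
        rec = ProteinRecord(accession="A", sequence="KKKK")
        assert generate_decoys([rec], seed=0)[0].sequence == "KKKK"

    def test_length_and_composition_preserved(self, small_proteome):
        _, refs, haps, _ = small_proteome
        targets = build_target_database(refs, haps)
        decoys = generate_decoys(targets, seed=4)
        for t, d in zip(targets, decoys):
            assert len(d.sequence) == len(t.sequence)
            assert sorted(d.sequence) == sorted(t.sequence)

    def test_no_shared_tryptic_peptides_with_targets(self, small_proteome):
        _, refs, haps, _ = small_proteome
        targets = build_target_database(refs, haps)
        decoys = generate_decoys(targets, seed=4)
        target_peps: set[str] = set()
        decoy_peps: set[str] = set()
        for rec in targets:
            target_peps |= digestion.digest_sequence(rec.sequence)
        for rec in decoys:
            decoy_peps |= digestion.digest_sequence(rec.sequence)
        assert not target_peps & decoy_peps

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError):
            generate_decoys([], seed=0)
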