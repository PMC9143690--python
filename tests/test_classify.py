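"""Family assignment, catalytic triads, anchored regions, TAG-activity calls."""

import numpy as np
import pytest

from figlipase.classify import (
    RegionReport,
    RegionSpec,
    ReferenceSpec,
    TriadSite,
    assign_family,
    call_tag_activity,
    check_cap,
    check_triad,
    extract_region,
)
from figlipase.formats import ProteinRecord
from figlipase.synth import EXEMPLARS, fixture_table3, random_protein

pytestmark = []


def _mutate_at(sequence: str, pos1: int, residue: str) -> str:
    return sequence[: pos1 - 1] + residue + sequence[pos1:]


def _delete_at(sequence: str, pos1: int) -> str:
    return sequence[: pos1 - 1] + sequence[pos1:]


class TestAssignFamily:
    def test_identical_to_reference_wins(self, panel):
        for ref in panel:
            rec = ProteinRecord(f"q_{ref.family}", ref.sequence)
            result = assign_family(rec, panel)
            assert result.family == ref.family
            assert result.reference_id == ref.ref_id

    def test_random_sequence_unassigned(self, panel, rng):
        rec = ProteinRecord("decoy", random_protein(rng, 50))
        assert assign_family(rec, panel).family == "unassigned"

    def test_mutated_exemplar_keeps_family(self, panel, neutral_ref, rng):
        seq = list(neutral_ref.sequence)
        sites = rng.choice(len(seq), size=len(seq) // 10, replace=False)
        for i in sites:
            seq[i] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
        rec = ProteinRecord("mut", "".join(seq))
        assert assign_family(rec, panel).family == "neutral"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            assign_family(ProteinRecord("q", "MKV"), [])


class TestCheckTriad:
    def test_identity_is_complete(self, neutral_ref):
        rec = ProteinRecord("q", neutral_ref.sequence)
        report = check_triad(rec, neutral_ref)
        assert report.complete
        assert report.description == "complete"

    def test_ser_to_glu_substitution_described(self, neutral_ref):
        ser = next(t for t in neutral_ref.triad if t.name == "Ser")
        rec = ProteinRecord("q", _mutate_at(neutral_ref.sequence, ser.position, "E"))
        report = check_triad(rec, neutral_ref)
        assert not report.complete
        assert "Glu in place of Ser" in report.description

    def test_deleted_his_reported_missing(self, neutral_ref):
        his = next(t for t in neutral_ref.triad if t.name == "His")
        rec = ProteinRecord("q", _delete_at(neutral_ref.sequence, his.position))
        report = check_triad(rec, neutral_ref)
        assert not report.complete
        assert "lacked His" in report.description

    def test_ambiguity_letter_never_matches(self, neutral_ref):
        ser = next(t for t in neutral_ref.triad if t.name == "Ser")
        rec = ProteinRecord("q", _mutate_at(neutral_ref.sequence, ser.position, "X"))
        assert not check_triad(rec, neutral_ref).complete

    def test_mutations_outside_triad_columns_irrelevant(self, neutral_ref, rng):
        triad_positions = {t.position for t in neutral_ref.triad}
        seq = list(neutral_ref.sequence)
        candidates = [i for i in range(len(seq)) if i + 1 not in triad_positions]
        for i in rng.choice(candidates, size=10, replace=False):
            seq[i] = "W"
        report = check_triad(ProteinRecord("q", "".join(seq)), neutral_ref)
        assert report.complete


class TestExtractRegion:
    def test_identity_region_spans_anchor_columns(self, neutral_ref):
        rec = ProteinRecord("q", neutral_ref.sequence)
        loop = extract_region(rec, neutral_ref, "beta9")
        spec = neutral_ref.region("beta9")
        assert loop.length == spec.end_position - spec.start_position + 1 == 21
        assert loop.sequence == neutral_ref.sequence[
            spec.start_position - 1 : spec.end_position
        ]

    def test_internal_deletion_shortens_by_exactly_that_much(self, neutral_ref):
        lid = neutral_ref.region("lid")
        mid = (lid.start_position + lid.end_position) // 2
        seq = neutral_ref.sequence[: mid - 1] + neutral_ref.sequence[mid + 2 :]
        report = extract_region(ProteinRecord("q", seq), neutral_ref, "lid")
        identity_len = lid.end_position - lid.start_position + 1
        assert report.length == identity_len - 3

    def test_anchor_substitution_recorded_not_fatal(self, acid_ref):
        cap = acid_ref.region("cap")
        seq = _mutate_at(acid_ref.sequence, cap.start_position, "F")
        report = check_cap(ProteinRecord("q", seq), acid_ref)
        assert report.passes
        assert report.start_residue == "F"

    def test_published_strings_extracted_verbatim(self):
        """Embedding each printed loop/lid into an exemplar carrier and
        re-extracting through the alignment recovers the exact string."""
        # trimmed neutral exemplar: same anchors, shorter flanks, faster DP
        offset = 150
        ref_seq = EXEMPLARS["neutral"][offset:]
        ref = ReferenceSpec(
            "neutral",
            "trimmed",
            ref_seq,
            regions=(
                RegionSpec("beta9", 204 - offset, "H", 224 - offset, "H"),
                RegionSpec("lid", 238 - offset, "C", 262 - offset, "C"),
            ),
        )
        loop_spec, lid_spec = ref.regions
        entries = fixture_table3()
        for entry in entries:
            carrier = (
                ref_seq[: loop_spec.start_position - 1]
                + entry.loop
                + ref_seq[loop_spec.end_position : lid_spec.start_position - 1]
                + entry.lid
                + ref_seq[lid_spec.end_position :]
            )
            rec = ProteinRecord(entry.gene_id, carrier)
            loop = extract_region(rec, ref, "beta9")
            lid = extract_region(rec, ref, "lid")
            assert loop.sequence == entry.loop, entry.gene_id
            assert lid.sequence == entry.lid, entry.gene_id
            assert loop.length == entry.loop_length
            assert lid.length == entry.lid_length


class TestActivityCall:
    @pytest.mark.parametrize(
        "loop_len,lid_len,expected",
        [
            (20, 24, True),  # the published Abak_neutral_11 lengths
            (15, 24, False),  # loop at exactly 15 fails the strict rule
            (16, 17, False),
            (16, 18, True),  # lid threshold is inclusive
        ],
    )
    def test_threshold_rules(self, loop_len, lid_len, expected):
        loop = RegionReport("beta9", "H" * loop_len, loop_len, "H", "H", True)
        lid = RegionReport("lid", "C" * lid_len, lid_len, "C", "C", True)
        call = call_tag_activity(loop, lid, "q")
        assert call.putative_tag_hydrolase is expected

    def test_kind_mismatch_rejected(self):
        loop = RegionReport("beta9", "HH", 2, "H", "H", True)
        with pytest.raises(ValueError):
            call_tag_activity(loop, loop, "q")


class TestCheckCap:
    def test_identity_cap_present(self, acid_ref):
        rec = ProteinRecord("q", acid_ref.sequence)
        report = check_cap(rec, acid_ref)
        spec = acid_ref.region("cap")
        assert report.passes
        assert report.length == spec.end_position - spec.start_position + 1

    def test_whole_span_deleted_fails(self, acid_ref):
        spec = acid_ref.region("cap")
        seq = acid_ref.sequence[: spec.start_position - 1] + acid_ref.sequence[spec.end_position :]
        report = check_cap(ProteinRecord("q", seq), acid_ref)
        assert not report.passes
        assert report.length == 0


class TestReferenceSpecValidation:
    def test_anchor_residue_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSpec(
                "neutral",
                "bad",
                "MKVHW",
                regions=(RegionSpec("beta9", 1, "H", 4, "H"),),
            )

    def test_duplicate_triad_positions_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSpec(
                "neutral",
                "bad",
                "MSVHW",
                triad=(TriadSite("Ser", 2, "S"), TriadSite("Asp", 2, "S")),
            )
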