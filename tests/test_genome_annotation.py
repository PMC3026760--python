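"""ORF scanning, overlapping-ORF detection and genome organization."""

import numpy as np
import pytest

from virna.errors import AlphabetError, InputError
from virna.genome_annotation import (
    OrfCall,
    ViralSegment,
    classify_organization,
    find_overlapping_plus1_orf,
    scan_orfs,
    translate,
)
from virna.synthetic_data import SimConfig, simulate_viral_genome

from conftest import CODON_ORACLE, orf_oracle, random_nt


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,aa", [("ATG", "M"), ("ATGTAA", "M*"), ("atgugg", "MW")]
    )
    def test_codon_table(self, nt, aa):
        assert translate(nt) == aa

    def test_matches_independent_codon_lookup(self, rng):
        nt = random_nt(rng, 60)
        expected = "".join(
            CODON_ORACLE[nt[i : i + 3]] for i in range(0, 60, 3)
        )
        assert translate(nt) == expected

    def test_non_triplet_rejected_unless_allowed(self):
        with pytest.raises(InputError):
            translate("ATGA")
        assert translate("ATGA", require_triplet=False) == "M"

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(AlphabetError):
            translate("ATN")


class TestScanOrfs:
    def test_minimal_orf(self, toy_segment):
        calls = scan_orfs(toy_segment, min_aa=1)
        plus = [c for c in calls if c.strand == "+"]
        assert plus == [
            OrfCall(
                segment_id="toy", strand="+", frame=0, start=0, end=9,
                aa_length=2, protein="MK",
            )
        ]

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            ViralSegment(id="x", sequence="")

    @pytest.mark.parametrize("allow_partial", [False, True])
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_oracle(self, trial, allow_partial):
        rng = np.random.default_rng(500 + trial)
        seq = random_nt(rng, int(rng.integers(30, 800)))
        seg = ViralSegment(id="r", sequence=seq)
        calls = scan_orfs(seg, min_aa=0, allow_partial=allow_partial)
        got = {
            (c.strand, c.frame, c.start, c.end, c.aa_length, c.partial_3prime)
            for c in calls
        }
        assert got == orf_oracle(seq, 0, allow_partial, True)

    def test_protein_consistent_with_coordinates(self, sim_genomes):
        segments, _ = sim_genomes
        for seg in segments:
            for c in scan_orfs(seg, min_aa=10):
                if c.strand == "+":
                    nt = seg.sequence[c.start : c.end]
                else:
                    nt = seg.reverse_complement().sequence[
                        len(seg) - c.end : len(seg) - c.start
                    ]
                expected = c.protein if c.partial_3prime else c.protein + "*"
                assert translate(nt) == expected
                if not c.partial_3prime:
                    assert c.protein.startswith("M")

    def test_reverse_complement_mirrors_coordinates(self, sim_genomes):
        segments, _ = sim_genomes
        seg = segments[0]
        fwd = scan_orfs(seg, min_aa=5)
        rev = scan_orfs(seg.reverse_complement(), min_aa=5)
        n = len(seg)
        mirrored = {
            (("-" if c.strand == "+" else "+"), n - c.end, n - c.start)
            for c in rev
        }
        assert {(c.strand, c.start, c.end) for c in fwd} == mirrored


class TestOverlappingPlus1Orf:
    def test_planted_overlapping_orf_found(self):
        # Frame-0 anchor over [0, 300) with stop TAA at [297, 300); a
        # frame-1 ORF planted at [250, 313): its ATG and G-rich body
        # keep every overlapping frame-0 codon stop-free.
        seq = list("ATG" + "GGA" * 98 + "TAA" + "G" * 100)
        seq[250:253] = "ATG"
        seq[253:297] = "G" * 44
        seq[300:310] = "G" * 10
        seq[310:313] = "TGA"
        seq[313:] = "C" * (400 - 313)
        seg = ViralSegment(id="c", sequence="".join(seq))
        orfs = scan_orfs(seg, min_aa=0, allow_partial=False)
        anchors = [o for o in orfs if o.strand == "+" and o.frame == 0]
        anchor = max(anchors, key=lambda o: o.aa_length)
        assert (anchor.start, anchor.end) == (0, 300)
        hit = find_overlapping_plus1_orf(orfs, anchor, min_aa=5, cterm_window=100)
        assert hit is not None
        assert hit.frame == 1 and hit.start == 250 and hit.end == 313
        assert hit.aa_length == 20

    def test_anchor_must_be_plus_strand(self, toy_segment):
        calls = scan_orfs(toy_segment, min_aa=1)
        minus = OrfCall(
            segment_id="toy", strand="-", frame=0, start=0, end=9,
            aa_length=2, protein="MK",
        )
        with pytest.raises(InputError):
            find_overlapping_plus1_orf(calls, minus)


class TestClassifyOrganization:
    def test_conventional_rna2_has_no_delta_and_no_oversize(self):
        cfg = SimConfig(
            seed=9, rna2_length=1400, plant_delta=False, capsid_aa=380
        )
        segments, _ = simulate_viral_genome(cfg)
        rep = classify_organization(segments)
        assert rep.orf_delta_candidate is None
        assert not rep.rna2_oversize
        assert rep.capsid_candidate is not None

    @pytest.mark.parametrize("plant_b2,plant_delta", [(False, True), (True, False)])
    def test_flags_follow_generator_truth(self, plant_b2, plant_delta):
        for seed in range(10):
            cfg = SimConfig(seed=seed, plant_b2=plant_b2, plant_delta=plant_delta)
            segments, truth = simulate_viral_genome(cfg)
            rep = classify_organization(segments)
            assert rep.segments == {"RNA1_sim": "RNA1", "RNA2_sim": "RNA2"}
            assert (rep.b2_like is not None) == plant_b2
            assert (rep.orf_delta_candidate is not None) == plant_delta
            assert (rep.rdrp_candidate.start, rep.rdrp_candidate.end) == (
                truth.rdrp.start, truth.rdrp.end,
            )
            if plant_delta:
                assert (
                    rep.orf_delta_candidate.start,
                    rep.orf_delta_candidate.end,
                ) == (truth.delta.start, truth.delta.end)
            if plant_b2:
                assert (rep.b2_like.start, rep.b2_like.end) == (
                    truth.b2.start, truth.b2.end,
                )

    def test_too_many_segments_rejected(self, toy_segment):
        with pytest.raises(InputError):
            classify_organization([toy_segment] * 3)

    def test_no_orf_yields_warning_not_error(self):
        seg = ViralSegment(id="tiny", sequence="ACGTACGTACGT")
        rep = classify_organization([seg], min_aa=50)
        assert rep.warnings and rep.rdrp_candidate is None
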