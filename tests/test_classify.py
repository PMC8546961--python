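"""Residue-anchored classification, marker-gene genotyping and taxon rollups."""

import numpy as np
import pandas as pd
import pytest

from g6pdhkit.classify import (AnchorReference, Call, CofactorCall,
                               ConservedReference, GenomeMarkers, Glycolysis,
                               ProteinRecord, align_to_reference,
                               anchor_window, build_species_profiles,
                               call_cofactor, check_conserved_residues,
                               classify_glycolysis, classify_records,
                               detect_fingerprint, position_frequency_matrix,
                               summarize_taxon)
from g6pdhkit.errors import InputError, UsageError
from g6pdhkit.synth import SynthSequenceSpec, gen_protein_set


@pytest.fixture(scope="module")
def clean_bundle():
    return gen_protein_set(SynthSequenceSpec(n_species=30, seed=17))


@pytest.fixture(scope="module")
def reference(clean_bundle):
    return AnchorReference(name="scaffold", sequence=clean_bundle.reference,
                           anchor_pos=50)


def record(seq, rid="q1", **kwargs):
    return ProteinRecord(record_id=rid, sequence=seq, **kwargs)


class TestAlignToReference:
    def test_identity_maps_anchor_onto_itself(self, reference):
        q = record(reference.sequence)
        assert align_to_reference(q, reference) == reference.anchor_pos

    def test_deletion_before_anchor_shifts_mapping(self, reference):
        seq = reference.sequence
        q = record(seq[:30] + seq[33:])  # drop 3 residues upstream of the anchor
        assert align_to_reference(q, reference) == reference.anchor_pos - 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            ProteinRecord(record_id="x", sequence="")

    def test_planted_anchor_recovered_under_mutation(self):
        # 2% substitutions plus one indel outside the anchor window
        hits = total = 0
        for seed in range(5):
            bundle = gen_protein_set(SynthSequenceSpec(
                n_species=20, substitution_rate=0.02, indel_rate=1 / 500,
                seed=100 + seed))
            ref = AnchorReference(name="r", sequence=bundle.reference,
                                  anchor_pos=50)
            for (rid, seq), row in zip(bundle.records,
                                       bundle.truth.itertuples()):
                mapped = align_to_reference(record(seq, rid), ref)
                hits += (mapped == row.anchor_pos)
                total += 1
        assert hits / total >= 0.99


class TestCallCofactor:
    def test_arginine_is_nadp_specific(self, reference):
        call = call_cofactor(record(reference.sequence), reference)
        assert call.call is Call.NADP_SPECIFIC
        assert call.residue == "R"
        assert call.mapped_pos == reference.anchor_pos

    def test_histidine_is_relaxed(self, reference):
        seq = list(reference.sequence)
        seq[reference.anchor_pos - 1] = "H"
        call = call_cofactor(record("".join(seq)), reference)
        assert call.call is Call.RELAXED
        assert call.residue == "H"

    def test_anchor_region_deleted_is_unresolved(self, reference):
        # remove a 9-residue block centred on the anchor so the alignment
        # places a query gap in the anchor column
        seq = reference.sequence
        a0 = reference.anchor_pos - 1
        q = record(seq[:a0 - 4] + seq[a0 + 5:])
        call = call_cofactor(q, reference)
        assert call.call is Call.UNRESOLVED
        assert call.mapped_pos is None

    def test_x_at_anchor_is_unresolved(self, reference):
        seq = list(reference.sequence)
        seq[reference.anchor_pos - 1] = "X"
        call = call_cofactor(record("".join(seq)), reference)
        assert call.call is Call.UNRESOLVED

    def test_call_bijection_with_anchor_residue(self, clean_bundle, reference):
        calls, table = classify_records(
            [record(seq, rid) for rid, seq in clean_bundle.records], reference)
        for call, row in zip(calls, clean_bundle.truth.itertuples()):
            assert call.mapped_pos == row.anchor_pos
            assert (call.call is Call.NADP_SPECIFIC) == (row.anchor_residue == "R")


class TestFingerprint:
    def test_motif_found_at_reported_offset(self):
        seq = "MAAAAAAAAA" + "GATGDLAK" + "W" * 30
        found, offset = detect_fingerprint(record(seq))
        assert found and offset == 11

    def test_seventh_position_must_be_a_or_v(self):
        seq = "MAAAAAAAAA" + "GATGDLTK" + "W" * 30
        found, offset = detect_fingerprint(record(seq))
        assert not found and offset is None

    def test_planted_motif_in_generator_output(self, clean_bundle):
        for rid, seq in clean_bundle.records[:10]:
            found, offset = detect_fingerprint(record(seq, rid))
            assert found and offset == 12

    def test_outside_window_not_reported(self):
        seq = "W" * 100 + "GATGDLAK" + "W" * 10
        found, _ = detect_fingerprint(record(seq), window=60)
        assert not found


class TestConservedResidues:
    def make_ref(self):
        rng = np.random.default_rng(5)
        seq = list(rng.choice(list("ACDEFGHIKLMNPQRSTVW"), size=450))
        sites = {"R176": (176, "R"), "E146": (146, "E"),
                 "Y415": (415, "Y"), "H240": (240, "H")}
        for _, (pos, res) in sites.items():
            seq[pos - 1] = res
        return ConservedReference(name="lm", sequence="".join(seq), sites=sites)

    def test_identity_hits_every_site(self):
        ref = self.make_ref()
        hits = check_conserved_residues(record(ref.sequence), ref)
        assert all(hits[s] is True for s in ref.sites)

    def test_planted_substitution_detected(self):
        ref = self.make_ref()
        seq = list(ref.sequence)
        seq[414] = "F"  # Y415F
        hits = check_conserved_residues(record("".join(seq)), ref)
        assert hits["Y415"] is False
        assert hits["R176"] is True and hits["E146"] is True and hits["H240"] is True

    def test_truncated_query_reports_unresolved_sites(self):
        ref = self.make_ref()
        hits = check_conserved_residues(record(ref.sequence[:300]), ref)
        assert hits["Y415"] is None
        assert hits["R176"] is True


class TestPositionFrequencyMatrix:
    def test_single_sequence_is_one_hot(self):
        pfm = position_frequency_matrix(["ARN"])
        assert pfm.loc["A", 1] == 1.0 and pfm.loc["R", 2] == 1.0
        np.testing.assert_allclose(pfm.sum(axis=0), 1.0)

    def test_two_sequences_split_a_column(self):
        pfm = position_frequency_matrix(["ARN", "AHN"])
        assert pfm.loc["R", 2] == 0.5 and pfm.loc["H", 2] == 0.5

    def test_planted_anchor_mixture_recovered(self):
        rng = np.random.default_rng(23)
        spec = SynthSequenceSpec(
            n_species=100, isoform_count_distribution={1: 1.0},
            anchor_residue_distribution={"R": 0.8, "H": 0.2}, seed=23)
        bundle = gen_protein_set(spec)
        ref = AnchorReference(name="r", sequence=bundle.reference, anchor_pos=50)
        segments = [anchor_window(record(seq, rid), 50)
                    for rid, seq in bundle.records]
        pfm = position_frequency_matrix(segments)
        anchor_col = 8  # centre of the +/-7 window
        freq_r = pfm.loc["R", anchor_col]
        truth_r = (bundle.truth["anchor_residue"] == "R").mean()
        assert freq_r == pytest.approx(truth_r, abs=1e-12)
        assert abs(freq_r - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 100)

    def test_ragged_segments_rejected(self):
        with pytest.raises(InputError):
            position_frequency_matrix(["ARN", "AR"])


class TestGlycolysis:
    @pytest.mark.parametrize("pfk, edd, eda, rule, expected", [
        (False, False, True, "eda_only", Glycolysis.ED),
        (True, False, True, "eda_only", Glycolysis.ED_EMP),
        (True, False, False, "eda_only", Glycolysis.EMP),
        (False, False, False, "eda_only", Glycolysis.OTHER),
        (False, True, False, "eda_only", Glycolysis.OTHER),
        (False, True, False, "edd_or_eda", Glycolysis.ED),
    ])
    def test_marker_rules(self, pfk, edd, eda, rule, expected):
        m = GenomeMarkers(species="s", has_pfk=pfk, has_edd=edd, has_eda=eda)
        assert classify_glycolysis(m, ed_rule=rule) is expected

    def test_unknown_rule_rejected(self):
        m = GenomeMarkers(species="s", has_pfk=False, has_edd=False,
                          has_eda=False)
        with pytest.raises(UsageError):
            classify_glycolysis(m, ed_rule="whatever")


def make_profile_inputs(calls_per_species, markers=None):
    """calls_per_species: {species: [Call, ...]}"""
    records, calls = [], []
    for species, call_list in calls_per_species.items():
        for i, c in enumerate(call_list):
            rid = f"{species}_i{i}"
            records.append(ProteinRecord(record_id=rid, sequence="MAR",
                                         species=species, taxon="T"))
            calls.append(CofactorCall(record_id=rid, call=c))
    return records, calls, markers or []


class TestSpeciesProfiles:
    def test_kt2440_like_trio(self):
        records, calls, markers = make_profile_inputs(
            {"Pp": [Call.NADP_SPECIFIC, Call.RELAXED, Call.NADP_SPECIFIC]},
            [GenomeMarkers(species="Pp", has_pfk=False, has_edd=True,
                           has_eda=True)])
        (profile,) = build_species_profiles(records, calls, markers)
        assert profile.n_isoforms == 3 and profile.bin == "3"
        assert profile.has_relaxed
        assert profile.glycolysis is Glycolysis.ED

    def test_single_nadp_specific_species(self):
        records, calls, markers = make_profile_inputs(
            {"Ec": [Call.NADP_SPECIFIC]},
            [GenomeMarkers(species="Ec", has_pfk=True, has_edd=True,
                           has_eda=True)])
        (profile,) = build_species_profiles(records, calls, markers)
        assert profile.bin == "1" and not profile.has_relaxed

    def test_five_isoforms_fall_in_4plus_bin(self):
        records, calls, markers = make_profile_inputs(
            {"Sp": [Call.NADP_SPECIFIC] * 5},
            [GenomeMarkers(species="Sp", has_pfk=True, has_edd=False,
                           has_eda=False)])
        (profile,) = build_species_profiles(records, calls, markers)
        assert profile.bin == "4plus"

    def test_unresolved_counts_isoforms_not_relaxed(self):
        records, calls, markers = make_profile_inputs(
            {"Sp": [Call.NADP_SPECIFIC, Call.UNRESOLVED]},
            [GenomeMarkers(species="Sp", has_pfk=False, has_edd=False,
                           has_eda=True)])
        (profile,) = build_species_profiles(records, calls, markers)
        assert profile.n_isoforms == 2 and not profile.has_relaxed

    def test_missing_marker_row_warns_and_defaults_to_other(self):
        records, calls, _ = make_profile_inputs({"Sp": [Call.RELAXED]})
        with pytest.warns(UserWarning, match="marker"):
            (profile,) = build_species_profiles(records, calls, [])
        assert profile.glycolysis is Glycolysis.OTHER


class TestSummarizeTaxon:
    def test_multiple_isoform_fraction_on_fixture(self):
        # 50 species, 44 of them with 2 or 3 isozymes -> 88% multi-isoform
        counts = [2] * 30 + [3] * 14 + [1] * 6
        records, calls, markers = [], [], []
        for i, n in enumerate(counts):
            sp = f"S{i:02d}"
            r, c, _ = make_profile_inputs({sp: [Call.NADP_SPECIFIC] * n})
            records += r
            calls += c
            markers.append(GenomeMarkers(species=sp, has_pfk=False,
                                         has_edd=False, has_eda=True))
        profiles = build_species_profiles(records, calls, markers)
        (summary,) = summarize_taxon(profiles)
        multi = sum(summary.bin_fractions[b] for b in ("2", "3", "4plus"))
        assert multi == pytest.approx(0.88)
        assert summary.species_count == 50

    def test_single_profile_concentrates_all_mass(self):
        records, calls, markers = make_profile_inputs(
            {"Sp": [Call.RELAXED]},
            [GenomeMarkers(species="Sp", has_pfk=True, has_edd=False,
                           has_eda=False)])
        (summary,) = summarize_taxon(build_species_profiles(records, calls,
                                                            markers))
        assert summary.bin_fractions["1"] == 1.0
        assert summary.glycolysis_fractions["EMP"] == 1.0
        assert summary.crosstab.loc["EMP", "1"] == 1.0

    def test_partitions_sum_to_one_and_margins_agree(self):
        bundle = gen_protein_set(SynthSequenceSpec(n_species=60, seed=31))
        ref = AnchorReference(name="r", sequence=bundle.reference, anchor_pos=50)
        records = [ProteinRecord(record_id=rid, sequence=seq,
                                 species=row.species, taxon=row.taxon)
                   for (rid, seq), row in zip(bundle.records,
                                              bundle.mapping.itertuples())]
        calls, _ = classify_records(records, ref)
        markers = [GenomeMarkers(species=r.species, has_pfk=bool(r.pfk),
                                 has_edd=bool(r.edd), has_eda=bool(r.eda))
                   for r in bundle.markers.itertuples()]
        profiles = build_species_profiles(records, calls, markers)
        for summary in summarize_taxon(profiles):
            assert sum(summary.bin_fractions.values()) == pytest.approx(1, abs=1e-12)
            assert sum(summary.glycolysis_fractions.values()) == pytest.approx(
                1, abs=1e-12)
            assert summary.crosstab.values.sum() == pytest.approx(1, abs=1e-12)
            # cross-tab margins equal the marginal partitions
            for b in summary.crosstab.columns:
                assert summary.crosstab[b].sum() == pytest.approx(
                    summary.bin_fractions[b], abs=1e-12)
            for g in summary.crosstab.index:
                assert summary.crosstab.loc[g].sum() == pytest.approx(
                    summary.glycolysis_fractions[g], abs=1e-12)

    def test_permutation_invariance(self):
        bundle = gen_protein_set(SynthSequenceSpec(n_species=20, seed=37))
        ref = AnchorReference(name="r", sequence=bundle.reference, anchor_pos=50)
        records = [ProteinRecord(record_id=rid, sequence=seq,
                                 species=row.species, taxon=row.taxon)
                   for (rid, seq), row in zip(bundle.records,
                                              bundle.mapping.itertuples())]
        markers = [GenomeMarkers(species=r.species, has_pfk=bool(r.pfk),
                                 has_edd=bool(r.edd), has_eda=bool(r.eda))
                   for r in bundle.markers.itertuples()]
        calls, _ = classify_records(records, ref)
        forward = summarize_taxon(build_species_profiles(records, calls, markers))
        backward = summarize_taxon(build_species_profiles(
            records[::-1], calls[::-1], markers[::-1]))
        for f, b in zip(forward, backward):
            assert f.taxon == b.taxon
            assert f.bin_fractions == b.bin_fractions
            assert f.glycolysis_fractions == b.glycolysis_fractions


class TestCallsFromAlignment:
    ALN = {
        "ref":  "MK-RDEAR",
        "q_r":  "MKARDEAR",
        "q_h":  "MKARDEAH",
        "q_gap": "MKARDEA-",
    }

    def test_precomputed_alignment_calls(self):
        from g6pdhkit.classify import calls_from_alignment
        calls = {c.record_id: c
                 for c in calls_from_alignment(self.ALN, "ref", anchor_pos=7)}
        assert calls["q_r"].call is Call.NADP_SPECIFIC
        assert calls["q_r"].mapped_pos == 8
        assert calls["q_h"].call is Call.RELAXED
        assert calls["q_gap"].call is Call.UNRESOLVED
        assert calls["q_gap"].mapped_pos is None

    def test_ragged_alignment_rejected(self):
        from g6pdhkit.classify import calls_from_alignment
        with pytest.raises(InputError):
            calls_from_alignment({"ref": "MKR", "q": "MK"}, "ref", anchor_pos=3)
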