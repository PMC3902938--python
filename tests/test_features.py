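"""Sequence features: codon indices, composition, motifs, folding, schema."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from translatomics.features import (
    CodonWeightTable,
    FAMILIES,
    SequenceFeaturizer,
    StartContextTable,
    TranscriptRecord,
    aa_composition,
    assemble_transcript,
    cai,
    composition_features,
    default_schema,
    fold_energy,
    fop,
    scan_motif,
    start_context_features,
    tai,
)
from translatomics.io import IUPAC_RNA, MotifModel, SequenceRecord

rna = st.text(alphabet="ACGU", min_size=0, max_size=60)


def _record(utr5="ACGUACGUACGU", orf="AUGGCCUAA", utr3="ACGUACGUACGUACGU"):
    return TranscriptRecord("t1", utr5, orf, utr3)


class TestAssembly:
    def test_valid_split(self):
        seq = SequenceRecord("t1", "A" * 30 + "AUG" + "GCC" * 9 + "UAA" + "C" * 12)
        rec = assemble_transcript(seq, (30, 33, 12))
        assert (len(rec.utr5), len(rec.orf), len(rec.utr3)) == (30, 33, 12)
        assert rec.utr5 + rec.orf + rec.utr3 == seq.sequence

    def test_missing_utr_rejected_when_required(self):
        seq = SequenceRecord("t1", "AUGGCCUAA" + "C" * 4)
        with pytest.raises(ValueError, match="UTR"):
            assemble_transcript(seq, (0, 9, 4), require_utrs=True)
        rec = assemble_transcript(seq, (0, 9, 4), require_utrs=False)
        assert rec.utr5 == ""

    @pytest.mark.parametrize(
        "orf,msg",
        [
            ("GUGGCCUAA", "start with AUG"),
            ("AUGGCCGCC", "stop"),
            ("AUGUAAGCCUAA", "internal stop"),
        ],
    )
    def test_invalid_orf_rejected(self, orf, msg):
        seq = SequenceRecord("t1", "AC" + orf + "GU")
        with pytest.raises(ValueError, match=msg):
            assemble_transcript(seq, (2, len(orf), 2))

    def test_length_mismatch_rejected(self):
        seq = SequenceRecord("t1", "ACAUGGCCUAAGU")
        with pytest.raises(ValueError, match="length"):
            assemble_transcript(seq, (2, 9, 5))


class TestComposition:
    def test_hand_counted_orf(self):
        rec = _record(orf="AUGGCCUAA")
        out = composition_features(rec)
        assert out["orf_frac_A"] == pytest.approx(3 / 9)
        assert out["orf_frac_U"] == pytest.approx(2 / 9)
        assert out["orf_frac_G"] == pytest.approx(2 / 9)
        assert out["orf_frac_C"] == pytest.approx(2 / 9)
        assert out["orf_len"] == 9

    def test_homopolymer_utr(self):
        out = composition_features(_record(utr5="AAAA"))
        assert out["utr5_frac_A"] == 1.0
        assert out["utr5_frac_C"] == out["utr5_frac_G"] == out["utr5_frac_U"] == 0.0

    @given(seq=st.text(alphabet="ACGU", min_size=1, max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, seq):
        out = composition_features(_record(utr3=seq))
        total = sum(out[f"utr3_frac_{b}"] for b in "ACGU")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_region_zeroed(self):
        out = composition_features(
            TranscriptRecord("t", "", "AUGGCCUAA", "ACGU")
        )
        assert out["utr5_len"] == 0
        assert all(out[f"utr5_frac_{b}"] == 0.0 for b in "ACGU")


class TestCodonIndices:
    def toy_weights(self):
        # Gln CAA=1.0, CAG=0.25; everything else neutral
        w = {c: 1.0 for fam in FAMILIES.values() for c in fam}
        w["CAG"] = 0.25
        return CodonWeightTable(cai_weights=w)

    def test_cai_all_optimal_is_one(self):
        assert cai("CAACAACAA", self.toy_weights()) == pytest.approx(1.0)

    def test_cai_two_codon_geometric_mean(self):
        # w = 0.25 and 1.0 -> sqrt(0.25) = 0.5
        assert cai("CAGCAA", self.toy_weights()) == pytest.approx(0.5)

    def test_cai_order_invariant(self):
        w = self.toy_weights()
        assert cai("CAGCAACAA", w) == pytest.approx(cai("CAACAGCAA", w))

    def test_cai_excludes_met_trp_and_stop(self):
        w = self.toy_weights()
        assert cai("AUGCAGCAAUGGUAA", w) == pytest.approx(0.5)

    def test_fop_all_optimal(self):
        assert fop("CAACAA", self.toy_weights()) == 1.0

    def test_fop_half_optimal(self):
        assert fop("CAACAG", self.toy_weights()) == 0.5

    def test_fop_counting_oracle(self):
        """fop equals a direct count of optimal codons over codons with a
        synonymous choice, on random ORFs."""
        rng = np.random.default_rng(31)
        ref_orfs = [
            "".join(rng.choice(list(FAMILIES), size=30).tolist()) for _ in range(5)
        ]
        # build weights from random reference usage
        orfs = []
        sense = [c for fam in FAMILIES.values() for c in fam]
        for _ in range(100):
            orfs.append("".join(rng.choice(sense, size=40)))
        weights = CodonWeightTable(
            cai_weights=CodonWeightTable.cai_from_reference(orfs[:10])
        )
        optimal = weights.optimal_codons
        for orf in orfs[10:40]:
            codons = [orf[i: i + 3] for i in range(0, len(orf), 3)]
            eligible = [
                c for c in codons
                if c in weights.cai_weights
                and len(FAMILIES[[aa for aa, fam in FAMILIES.items() if c in fam][0]]) > 1
            ]
            expected = (
                sum(c in optimal for c in eligible) / len(eligible)
                if eligible else None
            )
            if expected is not None:
                assert fop(orf, weights) == pytest.approx(expected)

    def test_tai_max_weight_codon_is_one(self):
        w = CodonWeightTable(tai_weights={"CAA": 1.0, "GAA": 0.5})
        assert tai("CAA", w) == pytest.approx(1.0)

    def test_tai_toy_two_anticodon_system(self):
        """Two anticodons with s=0 and gene copies 2:1 give weights 1.0 and
        0.5; an ORF with one codon of each scores sqrt(0.5)."""
        weights = CodonWeightTable.tai_from_tgcn(
            {"UUG": 2, "UUC": 1},  # read CAA (Gln) and GAA (Glu)
            s={"G:U": 0.0, "I:C": 0.0, "I:A": 1.0, "U:G": 1.0},
        )
        assert weights["CAA"] == pytest.approx(1.0)
        assert weights["GAA"] == pytest.approx(0.5)
        table = CodonWeightTable(tai_weights=weights)
        assert tai("CAAGAA", table) == pytest.approx(math.sqrt(0.5))

    def test_tai_order_invariant(self):
        w = CodonWeightTable(tai_weights={"CAA": 1.0, "GAA": 0.5, "GCU": 0.7})
        assert tai("CAAGAAGCU", w) == pytest.approx(tai("GCUCAAGAA", w))

    def test_default_tgcn_weights_in_unit_interval(self):
        weights = CodonWeightTable.tai_from_tgcn(CodonWeightTable.default_tgcn())
        vals = np.array(list(weights.values()))
        assert np.all((vals > 0) & (vals <= 1))
        assert np.isclose(vals.max(), 1.0)


class TestAminoAcidComposition:
    def test_two_codon_orf(self):
        out = aa_composition("AUGUCUUAA")
        assert out["aa_frac_M"] == 0.5
        assert out["aa_frac_S"] == 0.5

    def test_poly_met(self):
        out = aa_composition("AUGAUGAUG")
        assert out["aa_frac_M"] == 1.0

    @given(st.lists(st.sampled_from(sorted(FAMILIES)), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, aas):
        orf = "".join(FAMILIES[aa][0] for aa in aas)
        out = aa_composition(orf)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_internal_stop_errors(self):
        with pytest.raises(ValueError, match="internal stop"):
            aa_composition("AUGUAAGCCUAA")


class TestStartContext:
    def test_no_upstream_aug(self):
        out = start_context_features(_record(utr5="CCCCCCCCCC"))
        assert out["uaug_count"] == 0
        assert out["uorf_present"] == 0

    def test_contained_uorf_detected(self):
        out = start_context_features(_record(utr5="CCAUGUAACC"))
        assert out["uaug_count"] == 1
        assert out["uorf_present"] == 1

    def test_uaug_without_stop_is_not_uorf(self):
        out = start_context_features(_record(utr5="CCAUGCCCCC"))
        assert out["uaug_count"] == 1
        assert out["uorf_present"] == 0

    def test_stop_presence_any_frame(self):
        assert start_context_features(_record(utr5="CCCUAACCC"))[
            "utr5_stop_present"
        ] == 1
        assert start_context_features(_record(utr5="CCCCCCCC"))[
            "utr5_stop_present"
        ] == 0

    def test_consensus_context_scores_one(self):
        """A transcript whose -6..-1 context is the positionwise consensus
        of the reference set scores AUG-CAI(r) = 1 by construction."""
        recs = [
            TranscriptRecord(f"r{i}", "AAAAAA", "AUGGCCUAA", "ACGU")
            for i in range(20)
        ]
        table = StartContextTable.from_records(recs)
        out = start_context_features(_record(utr5="AAAAAA"), context_table=table)
        assert out["aug_cai_r"] == pytest.approx(1.0)

    def test_gc_windows(self):
        rec = _record(utr5="GGGG", orf="AUG" + "GC" * 15 + "UAA")
        out = start_context_features(rec, gc_window=30)
        assert out["gc_before_start"] == 1.0
        assert out["gc_after_start"] == 1.0


class TestMotifScan:
    PUF3 = MotifModel("Puf3", consensus="CYUGUAAAUA", target_region="utr3")

    def test_y_matches_c(self):
        assert scan_motif("CCUGUAAAUA", self.PUF3) == 1

    def test_a_not_in_y(self):
        assert scan_motif("CAUGUAAAUA", self.PUF3) == 0

    def test_overlapping_windows_counted(self):
        m = MotifModel("aa", consensus="AAAA")
        assert scan_motif("AAAAAA", m) == 3

    def test_short_sequence_scores_zero(self):
        assert scan_motif("CCU", self.PUF3) == 0.0

    def test_count_matches_window_enumeration(self):
        """Counts on random 200-mers equal an independent window-by-window
        IUPAC enumeration."""
        rng = np.random.default_rng(77)
        motifs = [
            MotifModel("m1", consensus="CYUGUAAAUA"),
            MotifModel("m2", consensus="UGUAHAUA"),
            MotifModel("m3", consensus="RRACW"),
        ]
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGU"), size=200))
            for motif in motifs:
                L = len(motif.consensus)
                expected = sum(
                    all(
                        seq[i + j] in IUPAC_RNA[code]
                        for j, code in enumerate(motif.consensus)
                    )
                    for i in range(len(seq) - L + 1)
                )
                assert scan_motif(seq, motif) == expected

    def test_pwm_max_log_odds(self):
        pwm = np.full((4, 4), 1e-9)
        for j, base in enumerate("ACGU"):
            pwm["ACGU".index(base), j] = 1.0
        pwm = pwm / pwm.sum(axis=0, keepdims=True)
        m = MotifModel("pwm", pwm=pwm, scoring="max_log_odds")
        score = scan_motif("GGACGUGG", m)
        assert score == pytest.approx(4 * np.log2(1 / 0.25), abs=1e-3)


class TestFoldEnergy:
    def test_unpairable_sequence_scores_zero(self):
        assert fold_energy("AAAAAAAA") == 0.0

    def test_hand_traced_hairpin(self):
        # GGGAAACCC folds into one 3-pair helix: 3 pairs + 2 stacks
        assert fold_energy("GGGAAACCC") == -(3 * 1.0 + 2 * 1.0)

    def test_short_region_flagged_zero(self):
        assert fold_energy("GGGCCC") == 0.0

    def test_extension_with_complement_never_raises_energy(self):
        """Appending the reverse complement of a prefix can only add
        structure: energy is monotone non-increasing (checked on 12-mers)."""
        rng = np.random.default_rng(13)
        comp = str.maketrans("ACGU", "UGCA")
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGU"), size=12))
            base = fold_energy(seq)
            for k in (3, 5, 8):
                ext = seq + seq[:k].translate(comp)[::-1]
                assert fold_energy(ext) <= base + 1e-9

    def test_window_cap_applies(self):
        seq = "GGGAAACCC" + "A" * 100 + "GGGGCCCC"
        assert fold_energy(seq, max_window=9) == fold_energy("GGGAAACCC")


class TestSchemaAndFeaturizer:
    def test_default_schema_has_77_unique_names(self):
        schema = default_schema()
        assert len(schema) == 77
        assert "Puf3_3utr" in schema.names

    def test_single_transcript_vector_length(self):
        rec = _record()
        X = SequenceFeaturizer().fit_transform([rec])
        assert X.shape == (1, 77)
        assert not X.isna().any().any()

    def test_column_order_matches_schema_on_shuffled_input(self, small_features):
        records = small_features["records"][:40]
        fz = small_features["featurizer"]
        a = fz.transform(records)
        b = fz.transform(records[::-1])
        assert list(a.columns) == list(fz.schema_.names)
        assert np.allclose(
            a.sort_index().to_numpy(), b.sort_index().to_numpy()
        )

    def test_compositional_columns_in_unit_interval(self, small_features):
        X = small_features["X"]
        cols = [c for c in X.columns if "frac" in c] + [
            "cai", "fop", "tai", "aug_cai_r"
        ]
        assert ((X[cols] >= 0) & (X[cols] <= 1)).all().all()

    def test_transform_is_deterministic(self, small_features):
        fz = small_features["featurizer"]
        records = small_features["records"][:20]
        a = fz.transform(records)
        b = fz.transform(records)
        assert a.equals(b)
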