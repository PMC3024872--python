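"""Decoy generation, PSM parsing, FDR machinery and the homology filter."""

import random

import numpy as np
import pytest

from jxpepdb.junctiondb import TranslatedJunctionEntry
from jxpepdb.search_postprocess import (
    PSM,
    ProteinDB,
    ProteinEntry,
    assemble_combined_db,
    clean_peptide,
    estimate_fdr_curve,
    filter_at_fdr,
    generate_decoys,
    homology_filter,
    min_mismatch_distance,
    quality_filter,
    read_protein_fasta,
    read_psm_table,
    subset_fdr_filter,
    threshold_at_fdr,
    write_protein_fasta,
)


def _ref_db(n=3, seed=0, length=40):
    rng = random.Random(seed)
    return ProteinDB(
        [
            ProteinEntry(
                f"REF{i}",
                "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                        for _ in range(length)),
                "reference",
            )
            for i in range(n)
        ]
    )


class TestGenerateDecoys:
    def test_sequences_are_reversed_with_prefix(self):
        db = generate_decoys(
            ProteinDB([ProteinEntry("P1", "PEPTIDER", "reference")])
        )
        decoy = db.decoys()[0]
        assert (decoy.accession, decoy.sequence) == ("DECOY_P1", "REDITPEP")

    def test_output_count_doubles_and_lengths_match(self):
        db = generate_decoys(_ref_db(5))
        assert len(db) == 10
        assert sorted(len(e.sequence) for e in db.targets()) == sorted(
            len(e.sequence) for e in db.decoys()
        )

    def test_palindromic_sequence_allowed(self):
        db = generate_decoys(ProteinDB([ProteinEntry("P", "ABCBA", "reference")]))
        assert db.decoys()[0].sequence == "ABCBA"

    def test_existing_decoys_are_error(self):
        db = generate_decoys(_ref_db(2))
        with pytest.raises(ValueError):
            generate_decoys(db)

    def test_accession_collision_is_error(self):
        db = ProteinDB(
            [
                ProteinEntry("P1", "AAAA", "reference"),
                ProteinEntry("DECOY_P1", "CCCC", "reference"),
            ]
        )
        with pytest.raises(ValueError, match="collision"):
            generate_decoys(db)


def _jxn_entries(n=5, seed=1, length=35):
    rng = random.Random(seed)
    return [
        TranslatedJunctionEntry(
            f"e{i}", f"j{i}", "+0",
            "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length)),
            length // 2, "novel",
        )
        for i in range(n)
    ]


class TestAssembleCombinedDb:
    def test_counts(self):
        db = assemble_combined_db(_ref_db(10), _jxn_entries(5))
        assert len(db) == 30
        assert len(db.decoys()) == 15

    def test_junction_sequence_equal_to_reference_is_retained(self):
        ref = ProteinDB([ProteinEntry("R", "A" * 35, "reference")])
        e = TranslatedJunctionEntry("e", "j", "+0", "A" * 35, 10, "novel")
        db = assemble_combined_db(ref, [e])
        assert sum(1 for x in db.targets() if x.sequence == "A" * 35) == 2

    def test_fasta_round_trip(self, tmp_path):
        db = assemble_combined_db(_ref_db(4), _jxn_entries(3))
        path = tmp_path / "combined.fa"
        write_protein_fasta(db, path)
        reread = read_protein_fasta(path)
        assert [(e.accession, e.sequence, e.origin) for e in reread.entries] \
            == [(e.accession, e.sequence, e.origin) for e in db.entries]


@pytest.fixture
def tiny_combined():
    ref = _ref_db(2)
    return assemble_combined_db(ref, _jxn_entries(2))


def _psm_file(tmp_path, rows):
    header = "spectrum_id\tpeptide\tprobability\tproteins\tquality\n"
    path = tmp_path / "psms.tsv"
    path.write_text(header + "".join(rows))
    return path


class TestReadPsmTable:
    def test_origin_derivations(self, tmp_path, tiny_combined):
        jxn_acc = next(
            e.accession for e in tiny_combined.entries if e.origin == "junction"
        )
        rows = [
            f"s1\tPEPK\t0.95\tDECOY_REF0\t2.0\n",
            f"s2\tPEPK\t0.95\t{jxn_acc}\t2.0\n",
            f"s3\tPEPK\t0.95\t{jxn_acc};REF0\t2.0\n",
        ]
        psms = read_psm_table(_psm_file(tmp_path, rows), tiny_combined)
        by_id = {p.spectrum_id: p for p in psms}
        assert by_id["s1"].is_decoy and by_id["s1"].novelty == "decoy"
        assert by_id["s2"].novelty == "novel_candidate"
        assert by_id["s2"].junction_only
        assert by_id["s3"].novelty == "known"  # reference hit wins

    def test_bad_probability_and_unknown_accession_rejected(
        self, tmp_path, tiny_combined
    ):
        rows = [
            "s1\tPEPK\t1.5\tREF0\t2.0\n",
            "s2\tPEPK\t0.9\tNOSUCH\t2.0\n",
            "s3\tPEPK\t0.9\tREF0\t2.0\n",
        ]
        psms = read_psm_table(_psm_file(tmp_path, rows), tiny_combined)
        assert [p.spectrum_id for p in psms] == ["s3"]

    def test_modification_stripping(self):
        assert clean_peptide("PEPT[80.0]IDEk") == "PEPTIDEK"
        assert clean_peptide("M[15.99]AAK") == "MAAK"

    def test_quality_filter(self):
        p_hi = PSM("a", "PEP", 0.9, ("x",), False, "known", quality=2.0)
        p_lo = PSM("b", "PEP", 0.9, ("x",), False, "known", quality=0.5)
        p_none = PSM("c", "PEP", 0.9, ("x",), False, "known", quality=None)
        assert quality_filter([p_hi, p_lo, p_none]) == [p_hi, p_none]


def _mk_psms(target_scores, decoy_scores, junction_only=False):
    psms = []
    for i, s in enumerate(target_scores):
        psms.append(PSM(f"t{i}", "PEP", s, ("T",), False, "known",
                        junction_only=junction_only))
    for i, s in enumerate(decoy_scores):
        psms.append(PSM(f"d{i}", "PEP", s, ("DECOY_T",), True, "decoy",
                        junction_only=junction_only))
    return psms


class TestFdrCurve:
    def test_fdr_formula(self):
        psms = _mk_psms([0.9] * 98, [0.9] * 2 + [0.1] * 10)
        curve = estimate_fdr_curve(psms)
        i = list(curve.thresholds).index(0.9)
        assert curve.fdr[i] == pytest.approx(2 / 98)

    def test_zero_decoys_above_threshold(self):
        psms = _mk_psms([0.9, 0.8], [0.1])
        curve = estimate_fdr_curve(psms)
        assert curve.fdr[0] == 0.0

    def test_all_decoy_input_is_error(self):
        with pytest.raises(ValueError):
            estimate_fdr_curve(_mk_psms([], [0.9, 0.8]))

    def test_q_values_monotone_as_threshold_decreases(self):
        rng = np.random.default_rng(5)
        psms = _mk_psms(rng.beta(4, 1, 200), rng.beta(1, 4, 200))
        curve = estimate_fdr_curve(psms)
        assert (np.diff(curve.q) >= 0).all()
        assert (np.diff(curve.n_target) >= 0).all()
        assert (np.diff(curve.n_decoy) >= 0).all()

    def test_passing_set_never_violates_alpha(self):
        # at the q<=alpha threshold, decoys above never exceed alpha*targets
        rng = np.random.default_rng(7)
        psms = _mk_psms(rng.beta(6, 1, 500), rng.beta(1, 6, 500))
        for alpha in (0.01, 0.05, 0.2):
            curve = estimate_fdr_curve(psms)
            thr = threshold_at_fdr(curve, alpha)
            if thr is None:
                continue
            n_t = sum(1 for p in psms if not p.is_decoy and p.probability >= thr)
            n_d = sum(1 for p in psms if p.is_decoy and p.probability >= thr)
            assert n_d <= alpha * max(1, n_t)


class TestThresholdAtFdr:
    def test_constructed_crossing_at_probability_cut(self):
        psms = _mk_psms([0.95] * 99 + [0.5] * 50, [0.95] + [0.5] * 20)
        curve = estimate_fdr_curve(psms)
        assert threshold_at_fdr(curve, 0.02) == 0.95

    def test_target_fdr_one_passes_everything(self):
        psms = _mk_psms([0.9, 0.3], [0.5])
        curve = estimate_fdr_curve(psms)
        assert threshold_at_fdr(curve, 1.0) == 0.3

    def test_threshold_monotone_in_target_fdr(self):
        rng = np.random.default_rng(11)
        psms = _mk_psms(rng.beta(6, 1, 300), rng.beta(1, 6, 300))
        curve = estimate_fdr_curve(psms)
        thresholds = [
            threshold_at_fdr(curve, a) for a in (0.005, 0.02, 0.1, 0.5)
        ]
        known = [t for t in thresholds if t is not None]
        assert known == sorted(known, reverse=True)

    def test_nonpositive_target_is_error(self):
        curve = estimate_fdr_curve(_mk_psms([0.9], [0.1]))
        with pytest.raises(ValueError):
            threshold_at_fdr(curve, 0.0)


class TestSubsetFdr:
    def test_subset_identical_to_full_set_gives_same_threshold(self):
        rng = np.random.default_rng(3)
        psms = _mk_psms(rng.beta(6, 1, 300), rng.beta(1, 6, 300),
                        junction_only=True)
        _, global_thr = filter_at_fdr(psms, 0.02)
        _, subset_thr = subset_fdr_filter(psms, 0.02)
        assert subset_thr == global_thr

    def test_subset_without_decoys_returns_none(self):
        psms = [PSM("t", "PEP", 0.9, ("J",), False, "novel_candidate",
                    junction_only=True)]
        psms += _mk_psms([0.8], [0.5])
        passing, thr = subset_fdr_filter(psms, 0.02)
        assert (passing, thr) == ([], None)

    def test_unreachable_target_returns_empty(self):
        psms = _mk_psms([0.9] * 3, [0.9] * 3, junction_only=True)
        passing, thr = subset_fdr_filter(psms, 0.02)
        assert passing == [] and thr is None


class TestMinMismatchDistance:
    def test_verbatim_match_is_zero(self):
        db = _ref_db(1)
        pep = db.entries[0].sequence[5:15]
        assert min_mismatch_distance(pep, db) == 0

    def test_empty_reference_gives_peptide_length(self):
        assert min_mismatch_distance("PEPTIDEK", ProteinDB([])) == 8

    def test_il_equivalence(self):
        db = ProteinDB([ProteinEntry("R", "AAALVAAA", "reference")])
        assert min_mismatch_distance("AAIVA", db, il_equivalent=True) == 0
        assert min_mismatch_distance("AAIVA", db, il_equivalent=False) == 1

    def test_agrees_with_naive_double_loop_oracle(self):
        rng = random.Random(13)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            seqs = ["".join(rng.choice(aa) for _ in range(60))
                    for _ in range(4)]
            pep = "".join(rng.choice(aa) for _ in range(rng.randrange(6, 13)))
            naive = min(
                (
                    sum(
                        a != b
                        for a, b in zip(
                            pep.replace("L", "I"),
                            s.replace("L", "I")[i:i + len(pep)],
                        )
                    )
                    for s in seqs
                    for i in range(len(s) - len(pep) + 1)
                ),
                default=len(pep),
            )
            db = ProteinDB(
                [ProteinEntry(f"R{i}", s, "reference")
                 for i, s in enumerate(seqs)]
            )
            assert min_mismatch_distance(pep, db) == naive


class TestHomologyFilter:
    def _psm(self, pep):
        return PSM("s", pep, 0.95, ("J",), False, "novel_candidate",
                   junction_only=True)

    def test_distance_threshold_boundary(self):
        ref = ProteinDB([ProteinEntry("R", "GGGGAAAAAAAAGGGG", "reference")])
        two_off = self._psm("AAAAAACC")    # distance 2 from AAAAAAAA
        three_off = self._psm("AAAAACCC")  # distance 3
        kept = homology_filter([two_off, three_off], ref, min_mismatches=3)
        assert kept == [three_off]

    def test_il_substitution_counts_as_match(self):
        ref = ProteinDB([ProteinEntry("R", "GGGPELTIDKGGG", "reference")])
        psm = self._psm("PEITIDK")  # differs from PELTIDK only by I/L
        assert homology_filter([psm], ref, min_mismatches=1) == []
        assert homology_filter([psm], ref, min_mismatches=1,
                               il_equivalent=False) == [psm]

    def test_zero_min_mismatches_is_identity(self):
        ref = _ref_db(2)
        psms = [self._psm("AAAAAA"), self._psm("CCCCCC")]
        assert homology_filter(psms, ref, min_mismatches=0) == psms
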