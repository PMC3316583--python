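import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consegment import motifs
from consegment.alignment import AlignmentColumn
from consegment.motifs import (
    PROTEIN_PATTERNS,
    ProteinPattern,
    annotate_flanks,
    conserved_hits,
    find_g_runs,
    find_tandem_repeats,
    scan_iupac,
    scan_protein_pattern,
)

# the human sequence of conserved feature B, as printed
FEATURE_B = "GCAAAGGGATCCAGCTCTCCCTGGGGGCCTTCGTGACAC"


def brute_force_iupac(seq, motif):
    """Window-by-window oracle for IUPAC matching."""
    seq = seq.upper().replace("U", "T")
    out = []
    for i in range(len(seq) - len(motif) + 1):
        ok = all(seq[i + j] in motifs.IUPAC[ch.upper()]
                 for j, ch in enumerate(motif))
        if ok:
            out.append(i)
    return out


class TestScanIupac:
    def test_polya_signal(self):
        hits = scan_iupac("GGAATAAAC", "AATAAA")
        assert [h.start for h in hits] == [2]

    def test_ycay(self):
        hits = scan_iupac("ACCATT", "YCAY")
        assert [(h.start, h.matched) for h in hits] == [(1, "CCAT")]
        assert scan_iupac("AAAA", "YCAY") == []

    def test_rna_motif_scanned_as_dna(self):
        assert len(scan_iupac("GCTCTCTG", "CUCUCU")) == 1

    def test_overlapping_matches_reported(self):
        assert [h.start for h in scan_iupac("ACACAC", "ACA")] == [0, 2]

    def test_invalid_code(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_iupac("ACGT", "AZ")

    def test_antisense(self):
        # AATAAA on the reverse strand reads TTTATT on the sense strand
        hits = scan_iupac("GTTTATTC", "AATAAA", antisense=True)
        anti = [h for h in hits if h.strand == "antisense"]
        assert len(anti) == 1 and anti[0].start == 1

    @given(st.text(alphabet="ACGT", min_size=20, max_size=200),
           st.sampled_from(["YCAY", "CTCTCT", "TCTTC", "AATAAA", "RRACH"]))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, seq, motif):
        assert [h.start for h in scan_iupac(seq, motif)] == \
            brute_force_iupac(seq, motif)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=100))
    @settings(max_examples=50, deadline=None)
    def test_hits_rematch(self, seq):
        for h in scan_iupac(seq, "YCAY"):
            assert seq[h.start:h.end] == h.matched


class TestGRuns:
    def test_printed_feature_b_sequence(self):
        runs = find_g_runs(FEATURE_B, min_run=3)
        assert [(h.start, h.length) for h in runs] == [(5, 3), (22, 5)]

    def test_maximal_run_reported_once(self):
        runs = find_g_runs("GGGGGG", min_run=3)
        assert [(h.start, h.length) for h in runs] == [(0, 6)]

    def test_short_runs_ignored(self):
        assert find_g_runs("GGAGG") == []


class TestTandemRepeats:
    def test_ca_triplet(self):
        runs = find_tandem_repeats("TCACACAG", min_units=3)
        assert [(h.start, h.length) for h in runs] == [(1, 6)]

    def test_below_min_units(self):
        assert find_tandem_repeats("CACA", min_units=3) == []

    def test_planted_repeat_recovered(self):
        from consegment.simulate import plant_motifs
        seq, planted = plant_motifs(500, [(100, "CA" * 8)], seed=4)
        runs = find_tandem_repeats(seq, min_units=8)
        assert [(h.start, h.length) for h in runs] == [(100, 16)]


def _conserved_cols(text, mouse=None, rat=None):
    mouse = mouse or text
    rat = rat or text
    return [AlignmentColumn(a, (b, c), i)
            for i, (a, b, c) in enumerate(zip(text, mouse, rat))]


class TestConservedHits:
    def scan(self, s):
        return scan_iupac(s, "CUCUCU")

    def test_three_species_conserved(self):
        cols = _conserved_cols("ACTCTCTG")
        hits = conserved_hits(cols, self.scan)
        assert len(hits) == 1
        assert hits[0].conserved_in == 3

    def test_substitution_breaks_conservation(self):
        cols = _conserved_cols("ACTCTCTG", rat="ACTCTATG")
        assert conserved_hits(cols, self.scan) == []

    def test_gap_breaks_conservation(self):
        cols = _conserved_cols("ACTCTCTG", mouse="ACTC-CTG")
        assert conserved_hits(cols, self.scan) == []

    def test_subset_of_reference_hits(self):
        rng = np.random.default_rng(0)
        text = "".join(rng.choice(list("ACGT"), 300))
        mouse = "".join(rng.choice(list("ACGT"), 300))
        cols = _conserved_cols(text, mouse=mouse)
        scanner = lambda s: scan_iupac(s, "YCAY")
        ref_starts = {h.start for h in scanner(text)}
        for h in conserved_hits(cols, scanner):
            assert h.start in ref_starts


class TestProteinPatterns:
    @pytest.mark.parametrize("peptide,kinase", [
        ("TSLD", "CKII"),
        ("STKE", "CKII"),
        ("SVSE", "CKII"),
        ("SKQE", "CKII"),
        ("KRLT", "cAMP_cGMP_PK"),
    ])
    def test_quoted_acceptor_peptides_match(self, peptide, kinase):
        hits = scan_protein_pattern(peptide, PROTEIN_PATTERNS[kinase])
        assert any(h.start == 0 for h in hits)

    def test_pkc_match_within_stke(self):
        # the PKC acceptor in STKE is the STK prefix ([ST]X[RK])
        hits = scan_protein_pattern("STKE", PROTEIN_PATTERNS["PKC"])
        assert [(h.start, h.matched) for h in hits] == [(0, "STK")]

    def test_no_pattern_matches_polyalanine(self):
        for pat in PROTEIN_PATTERNS.values():
            assert scan_protein_pattern("AAAA", pat) == []

    def test_overlapping_protein_hits(self):
        # STSD: CKII matches at 0 (STSD); T-S-x-x fails; one hit only
        hits = scan_protein_pattern("STSDD", PROTEIN_PATTERNS["CKII"])
        assert [h.start for h in hits] == [0, 1]

    def test_invalid_residue(self):
        with pytest.raises(ValueError, match="residue"):
            scan_protein_pattern("ASB1", PROTEIN_PATTERNS["CKII"])

    def test_from_string_parser(self):
        pat = ProteinPattern.from_string("x", "[ST]XX[DE]")
        assert len(pat) == 4
        assert pat.elements[1] is None
        assert pat.elements[3] == frozenset("DE")


class TestAnnotateFlanks:
    def test_acidic_n_terminal(self):
        seq = "AAESKQEA"
        hit = scan_protein_pattern(seq, PROTEIN_PATTERNS["CKII"])[0]
        fl = annotate_flanks(seq, hit, PROTEIN_PATTERNS["CKII"])
        assert fl.n_terminal_residue == "E"
        assert fl.n_terminal_class == "acidic"

    def test_basic_n_terminal(self):
        seq = "AAKSVSEA"
        hit = scan_protein_pattern(seq, PROTEIN_PATTERNS["CKII"])[0]
        fl = annotate_flanks(seq, hit, PROTEIN_PATTERNS["CKII"])
        assert fl.n_terminal_class == "basic"

    def test_match_at_start_has_no_flank(self):
        seq = "TSLDAAA"
        hit = scan_protein_pattern(seq, PROTEIN_PATTERNS["CKII"])[0]
        fl = annotate_flanks(seq, hit, PROTEIN_PATTERNS["CKII"])
        assert fl.n_terminal_residue is None
        assert fl.n_terminal_class is None

    def test_plus_five_from_acceptor(self):
        # CKII acceptor at position 2; +5 lands on the E
        seq = "AKSTKEAE"
        hit = scan_protein_pattern(seq, PROTEIN_PATTERNS["CKII"])[0]
        fl = annotate_flanks(seq, hit, PROTEIN_PATTERNS["CKII"])
        assert fl.acceptor_position == 2
        assert fl.plus_five_residue == "E"

    def test_acceptor_index_for_rk_pattern(self):
        seq = "AKRLTAA"
        hit = scan_protein_pattern(seq, PROTEIN_PATTERNS["cAMP_cGMP_PK"])[0]
        fl = annotate_flanks(seq, hit, PROTEIN_PATTERNS["cAMP_cGMP_PK"])
        assert seq[fl.acceptor_position] == "T"


class TestPlantedRecovery:
    def test_planted_motifs_found_with_no_spurious_excess(self):
        """Planted polyA signals are all recovered, and the extra hit count
        stays within 3 sigma of the analytic chance expectation."""
        from consegment.simulate import plant_motifs
        length, motif = 20_000, "AATAAA"
        positions = [1000, 5000, 9000, 13000, 17000]
        seq, _ = plant_motifs(length, [(p, motif) for p in positions],
                              seed=9)
        found = {h.start for h in scan_iupac(seq, motif)}
        assert set(positions) <= found
        n_windows = length - len(motif) + 1
        p_match = 0.25 ** 6
        expect = n_windows * p_match
        sigma = np.sqrt(expect)
        assert len(found) - len(positions) <= expect + 3 * sigma

    def test_zero_planted_chance_rate(self):
        from consegment.simulate import plant_motifs
        seq, _ = plant_motifs(50_000, [], seed=10)
        hits = scan_iupac(seq, "YCAY")
        n_windows = 50_000 - 3
        expect = n_windows * (0.5 * 0.25 * 0.25 * 0.5)
        sigma = np.sqrt(expect)
        assert abs(len(hits) - expect) < 3 * sigma


class TestRegistryAndDensity:
    def test_registry_covers_all_motif_families(self):
        seq = "GGGTTCACACATTCTCTCTTTAATAAATTTCTTCTTCCAT"
        hits = motifs.scan_dna_registry(seq)
        found = {h.motif for h in hits}
        assert "G_run>=3" in found
        assert "CA_repeat>=3" in found
        assert "polyA_AAUAAA" in found
        assert "PTB_CUCUCU" in found
        assert "PTB_UCUUC" in found
        assert "YCAY" in found

    def test_hit_density_sliding_window(self):
        hits = [motifs.MotifHit("s", p, 4, "YCAY", "YCAY")
                for p in (0, 10, 60)]
        dens = motifs.hit_density(hits, length=100, window=50)
        assert len(dens) == 51
        assert dens[0] == 2          # starts 0 and 10 fall in [0, 50)
        assert dens[50] == 1         # only the start at 60 in [50, 100)
        assert dens.max() == 2
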