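import numpy as np
import pytest

from wrkyfam import synthetic
from wrkyfam.domain_scan import (
    DEFAULT_CONFIG,
    find_heptapeptides,
    find_zinc_finger,
    is_degenerate_heptapeptide,
    scan_protein,
    scan_proteome,
)

BG = synthetic.BACKGROUND_AA  # no C, H or W -> no accidental motifs


class TestHeptapeptides:
    def test_planted_canonical(self):
        assert find_heptapeptides("AAWRKYGQKAA") == [(2, "WRKYGQK", "canonical")]

    def test_planted_variant(self):
        hits = find_heptapeptides("AAWRKYGKKAA")
        assert hits == [(2, "WRKYGKK", "variant")]

    def test_no_tryptophan_no_hits(self):
        assert find_heptapeptides("MAAAAAA") == []

    def test_degenerate_tier_needs_w_k_g(self):
        assert is_degenerate_heptapeptide("WAKAGAA")
        assert not is_degenerate_heptapeptide("XAKAGAA")  # X never matches W
        hits = find_heptapeptides("AAWAKAGAAAA")
        assert hits == [(2, "WAKAGAA", "degenerate")]

    def test_degenerate_count_matches_sliding_window_oracle(self, rng):
        # exhaustive O(n) oracle over all windows of random 500-mers
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            seq = "".join(rng.choice(alphabet, size=500))
            oracle = 0
            for i in range(len(seq) - 6):
                w = seq[i : i + 7]
                if w in DEFAULT_CONFIG.allow_list or (
                    w[0] == "W" and w[2] == "K" and w[4] == "G"
                ):
                    oracle += 1
            assert len(find_heptapeptides(seq)) == oracle


class TestZincFinger:
    def test_c2h2_pattern(self):
        seq = "C" + "A" * 4 + "C" + "A" * 22 + "H" + "A" + "H"
        assert find_zinc_finger(seq, 0) == ("C2H2", (4, 22, 1), (0, 30))

    def test_c2hc_pattern(self):
        seq = "C" + "A" * 7 + "C" + "A" * 24 + "H" + "A" + "C"
        assert find_zinc_finger(seq, 0) == ("C2HC", (7, 24, 1), (0, 35))

    def test_no_cysteine_is_incomplete(self):
        assert find_zinc_finger("A" * 80, 0) == ("incomplete", None, None)

    def test_search_respects_window(self):
        finger = "C" + "A" * 4 + "C" + "A" * 22 + "H" + "A" + "H"
        seq = "A" * 150 + finger
        assert find_zinc_finger(seq, 0)[0] == "incomplete"
        assert find_zinc_finger(seq, 40)[0] == "C2H2"

    @pytest.mark.parametrize("g1, g2", [(4, 21), (4, 24), (5, 23)])
    def test_c2h2_spacing_window_union(self, g1, g2):
        seq = "C" + "A" * g1 + "C" + "A" * g2 + "H" + "A" + "H"
        assert find_zinc_finger(seq, 0) == ("C2H2", (g1, g2, 1), (0, len(seq) - 1))


class TestScanProtein:
    def test_two_planted_domains_get_n_c_termini(self, rng):
        seq, manifest = synthetic.make_protein(
            [synthetic.DomainSpec(), synthetic.DomainSpec()], rng
        )
        hits = scan_protein("x", seq)
        assert [h.terminus for h in hits] == ["N", "C"]
        assert [h.start for h in hits] == [m["start"] for m in manifest]
        assert all(h.finger_type == "C2H2" for h in hits)

    def test_allow_list_variant_without_degenerate_demotion(self, rng):
        # WKKHGSN is on the allow-list, so it is a variant even though it
        # also satisfies the weak positional pattern
        seq, _ = synthetic.make_protein(
            [synthetic.DomainSpec(heptapeptide="WKKHGSN")], rng
        )
        (hit,) = scan_protein("x", seq)
        assert hit.hepta_class == "variant"
        assert hit.heptapeptide == "WKKHGSN"

    def test_missing_finger_reported_incomplete(self, rng):
        seq, _ = synthetic.make_protein(
            [synthetic.DomainSpec(finger_type="incomplete")], rng
        )
        (hit,) = scan_protein("x", seq)
        assert hit.finger_type == "incomplete"
        assert hit.finger_span is None

    def test_degenerate_without_finger_dropped(self):
        # degenerate heptapeptide, no downstream finger
        seq = "AA" + "WAKAGAA" + "AAAAAAAA"
        assert scan_protein("x", seq) == []

    def test_degenerate_with_finger_retained(self):
        finger = "C" + "A" * 4 + "C" + "A" * 22 + "H" + "A" + "H"
        seq = "AA" + "WAKAGAA" + "AAA" + finger
        (hit,) = scan_protein("x", seq)
        assert hit.hepta_class == "degenerate"
        assert hit.finger_type == "C2H2"


class TestScanProteome:
    def test_decoys_without_heptapeptide_excluded(self, rng):
        records, truth = synthetic.make_proteome(10, 10, rng)
        hit_map = scan_proteome(records)
        assert set(hit_map) == set(truth)

    def test_exact_recovery_on_zero_decoy_proteome(self, rng):
        records, truth = synthetic.make_proteome(15, 0, rng)
        hit_map = scan_proteome(records)
        for gid, hits in hit_map.items():
            assert [h.start for h in hits] == [m["start"] for m in truth[gid]]
            assert [h.finger_type for h in hits] == [
                m["finger_type"] for m in truth[gid]
            ]

    def test_empty_proteome(self):
        assert scan_proteome([]) == {}

    def test_deterministic(self, rng):
        records, _ = synthetic.make_proteome(5, 5, rng)
        assert scan_proteome(records) == scan_proteome(records)


class TestInvariants:
    def test_hits_satisfy_configured_constraints_on_random_proteomes(self):
        rng = np.random.default_rng(7)
        records, _ = synthetic.make_proteome(30, 0, rng)
        for gid, hits in scan_proteome(records).items():
            for h in hits:
                assert h.heptapeptide in DEFAULT_CONFIG.allow_list or (
                    is_degenerate_heptapeptide(h.heptapeptide)
                )
                if h.finger_type == "C2H2":
                    g1, g2, g3 = h.finger_spacing
                    assert DEFAULT_CONFIG.c2h2_gap1[0] <= g1 <= DEFAULT_CONFIG.c2h2_gap1[1]
                    assert DEFAULT_CONFIG.c2h2_gap2[0] <= g2 <= DEFAULT_CONFIG.c2h2_gap2[1]
                    assert g3 == 1

    def test_position_equivariance_under_prefix(self, rng):
        seq, _ = synthetic.make_protein([synthetic.DomainSpec()], rng)
        base = scan_protein("x", seq)
        for k in (1, 5, 17):
            prefix = "".join(rng.choice(list(BG), size=k))
            shifted = scan_protein("x", prefix + seq)
            assert [h.start for h in shifted] == [h.start + k for h in base]
            assert [h.finger_span for h in shifted] == [
                (a + k, b + k) for a, b in (h.finger_span for h in base)
            ]
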