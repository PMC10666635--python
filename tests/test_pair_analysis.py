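"""Pair extraction, orientation, distance, phase and overlap feasibility."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overlapscan import (
    UNCONSTRAINED,
    CodonSets,
    GenePair,
    classify_orientation,
    drop_truncated_pairs,
    extract_adjacent_pairs,
    filter_protein_coding,
    intergenic_distance,
    overlap_feasibility,
    overlap_phase,
    remove_transposase_insertions,
    serial_pairs,
)
from overlapscan.pair_analysis import _constrained_layout, reverse_complement_records

from conftest import make_gene

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


class TestCleanup:
    def test_stable_rna_genes_are_excluded(self):
        records = [
            make_gene(1, 900, locus="cds1"),
            make_gene(1000, 1100, locus="trna", is_protein_coding=False),
            make_gene(1200, 2000, locus="cds2"),
        ]
        assert [r.locus_tag for r in filter_protein_coding(records)] == ["cds1", "cds2"]

    def test_filter_is_identity_on_all_coding_and_empty_input(self):
        records = [make_gene(1, 900, locus="x"), make_gene(1000, 1900, locus="y")]
        assert filter_protein_coding(records) == records
        assert filter_protein_coding([]) == []

    def test_gene_internal_transposase_removed_fragments_kept(self):
        records = [
            make_gene(1, 600, locus="geneA_frag1"),
            make_gene(700, 2200, locus="transposase", transposase_internal=True),
            make_gene(2300, 2900, locus="geneA_frag2"),
        ]
        survivors = remove_transposase_insertions(records)
        assert [r.locus_tag for r in survivors] == ["geneA_frag1", "geneA_frag2"]
        # surviving records are unaltered
        assert survivors[0] == records[0] and survivors[1] == records[2]

    def test_transposase_removal_identity_and_empty_cases(self):
        clean = [make_gene(1, 900, locus="x")]
        assert remove_transposase_insertions(clean) == clean
        flagged = [make_gene(1, 900, locus="t", transposase_internal=True)]
        assert remove_transposase_insertions(flagged) == []


class TestAdjacentPairs:
    def test_n_minus_one_pairs_per_replicon(self, forward_operon):
        assert len(extract_adjacent_pairs(forward_operon)) == 2

    def test_pairs_never_span_replicons(self):
        records = [
            make_gene(1, 900, locus="a1", replicon="chr1"),
            make_gene(1000, 1900, locus="a2", replicon="chr1"),
            make_gene(1, 900, locus="b1", replicon="plasmid"),
            make_gene(1000, 1900, locus="b2", replicon="plasmid"),
        ]
        pairs = extract_adjacent_pairs(records)
        assert len(pairs) == 2
        assert all(p.first.replicon_id == p.second.replicon_id for p in pairs)

    def test_duplicate_records_rejected(self):
        g = make_gene(1, 900, locus="a")
        with pytest.raises(ValueError, match="duplicate"):
            extract_adjacent_pairs([g, g])

    def test_equal_start_tiebreak_matches_sort_oracle(self):
        records = [
            make_gene(500, 2000, locus="zz"),
            make_gene(500, 1400, locus="aa"),
            make_gene(100, 400, locus="mm"),
        ]
        pairs = extract_adjacent_pairs(records)
        oracle = sorted(records, key=lambda r: (r.replicon_id, r.start, r.stop, r.locus_tag))
        assert [p.first.locus_tag for p in pairs] == [r.locus_tag for r in oracle[:-1]]
        assert [p.second.locus_tag for p in pairs] == [r.locus_tag for r in oracle[1:]]


class TestOrientation:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            ("+", "+", "serial"),
            ("-", "-", "serial"),
            ("+", "-", "convergent"),
            ("-", "+", "divergent"),
        ],
    )
    def test_orientation_classes(self, s1, s2, expected):
        pair = GenePair(
            replicon_id="chr1",
            first=make_gene(1, 900, strand=s1, locus="a"),
            second=make_gene(1000, 1900, strand=s2, locus="b"),
        )
        assert classify_orientation(pair).orientation == expected

    @pytest.mark.parametrize(
        "strand, upstream, downstream",
        [("+", "a", "b"), ("-", "b", "a")],
    )
    def test_serial_transcription_order(self, strand, upstream, downstream):
        pair = GenePair(
            replicon_id="chr1",
            first=make_gene(1, 900, strand=strand, locus="a"),
            second=make_gene(1000, 1900, strand=strand, locus="b"),
        )
        classified = classify_orientation(pair)
        assert classified.upstream_locus == upstream
        assert classified.downstream_locus == downstream

    def test_orientation_counts_partition_pairs(self):
        rng = random.Random(7)
        records = []
        pos = 1
        for i in range(40):
            length = rng.randrange(300, 900, 3)
            records.append(
                make_gene(pos, pos + length - 1, strand=rng.choice("+-"), locus=f"g{i}")
            )
            pos += length + rng.randrange(0, 50)
        pairs = [classify_orientation(p) for p in extract_adjacent_pairs(records)]
        counts = {o: sum(1 for p in pairs if p.orientation == o)
                  for o in ("serial", "convergent", "divergent")}
        assert sum(counts.values()) == len(records) - 1


class TestTruncatedPairs:
    def _serial(self, **up_down_flags):
        up = make_gene(1, 900, locus="up", **up_down_flags.get("up", {}))
        down = make_gene(1000, 1900, locus="down", **up_down_flags.get("down", {}))
        return classify_orientation(GenePair(replicon_id="chr1", first=up, second=down))

    def test_upstream_truncated_stop_removes_pair(self):
        pair = self._serial(up={"truncated_stop": True})
        assert drop_truncated_pairs([pair]) == []

    def test_downstream_truncated_start_removes_pair(self):
        pair = self._serial(down={"truncated_start": True})
        assert drop_truncated_pairs([pair]) == []

    def test_non_distance_defining_truncation_kept(self):
        # termini away from the shared boundary do not define the distance
        pair = self._serial(up={"truncated_start": True}, down={"truncated_stop": True})
        assert drop_truncated_pairs([pair]) == [pair]

    def test_no_flags_identity(self):
        pair = self._serial()
        assert drop_truncated_pairs([pair]) == [pair]


class TestIntergenicDistance:
    def _distance(self, first, second):
        return intergenic_distance(
            classify_orientation(GenePair(replicon_id="chr1", first=first, second=second))
        )

    def test_atga_boundary_motif_gives_minus_4(self):
        # upstream stop codon TGA at 2996-2998, downstream start codon ATG at 2995-2997
        up = make_gene(2000, 2998, locus="up")
        down = make_gene(2995, 3999, locus="down")
        assert self._distance(up, down) == -4

    def test_taatg_boundary_motif_gives_minus_1(self):
        # stop TAA at 2996-2998, start ATG at 2998-3000: share one base
        up = make_gene(2000, 2998, locus="up")
        down = make_gene(2998, 3999, locus="down")
        assert self._distance(up, down) == -1

    def test_abutting_genes_give_zero(self):
        up = make_gene(1, 300, locus="up")
        down = make_gene(301, 900, locus="down")
        assert self._distance(up, down) == 0

    def test_one_spacer_nucleotide_gives_plus_1(self):
        up = make_gene(1, 300, locus="up")
        down = make_gene(302, 900, locus="down")
        assert self._distance(up, down) == 1

    def test_reverse_strand_pair_same_formula(self):
        # reverse pair: upstream gene is the right-hand one
        left = make_gene(2995, 3999, strand="-", locus="down")
        right = make_gene(4996, 5999, strand="-", locus="up")
        # distance = 4996 - 3999 - 1
        assert self._distance(left, right) == 996

    def test_non_serial_pair_rejected(self):
        pair = classify_orientation(
            GenePair(
                replicon_id="chr1",
                first=make_gene(1, 900, strand="+", locus="a"),
                second=make_gene(1000, 1900, strand="-", locus="b"),
            )
        )
        with pytest.raises(ValueError, match="serial"):
            intergenic_distance(pair)

    def test_strand_symmetry_under_replicon_mirror(self):
        rng = random.Random(11)
        records = []
        pos = 100
        for i in range(30):
            length = rng.randrange(300, 1200, 3)
            records.append(
                make_gene(pos, pos + length - 1, strand=rng.choice("+-"), locus=f"g{i}")
            )
            pos += length + rng.randrange(-8, 120)
        mirrored = reverse_complement_records(records, replicon_length=pos + 1000)

        def serial_distances(recs):
            return sorted(
                intergenic_distance(p)
                for p in map(classify_orientation, extract_adjacent_pairs(recs))
                if p.orientation == "serial"
            )

        assert serial_distances(records) == serial_distances(mirrored)


class TestOverlapPhase:
    @pytest.mark.parametrize(
        "k, expected",
        [(-8, 1), (-11, 1), (-14, 1), (-7, 2), (-10, 2), (-13, 2), (-4, 2), (-1, 2),
         (0, 0), (7, 1), (-3, 0)],
    )
    def test_phase_memberships(self, k, expected):
        assert overlap_phase(k) == expected

    @given(st.integers(min_value=-1000, max_value=1000))
    @settings(max_examples=500, derandomize=True)
    def test_two_branch_formula_equals_nonnegative_mod(self, k):
        assert overlap_phase(k) == ((k % 3) + 3) % 3


def brute_force_motifs(k, starts, stops):
    """Independent oracle: enumerate all 4^L strings at the boundary layout."""
    length, stop_off, start_off = _constrained_layout(k)
    motifs = set()
    for bases in itertools.product("ACGT", repeat=length):
        s = "".join(bases)
        if s[stop_off : stop_off + 3] in stops and s[start_off : start_off + 3] in starts:
            motifs.add(s)
    return motifs


class TestOverlapFeasibility:
    @pytest.mark.parametrize("k", [-5, -4, -3, -2, -1])
    def test_matches_brute_force_enumeration(self, k):
        assert overlap_feasibility(k) == brute_force_motifs(k, START_CODONS, STOP_CODONS)

    @pytest.mark.parametrize("k", [-5, -4, -3, -2, -1])
    def test_matches_brute_force_with_att_extension(self, k):
        codons = CodonSets(extended_start_codons=frozenset({"ATT"}))
        assert overlap_feasibility(k, codons) == brute_force_motifs(
            k, START_CODONS | {"ATT"}, STOP_CODONS
        )

    def test_minus_4_includes_printed_motifs(self):
        assert {"ATGA", "GTGA"} <= overlap_feasibility(-4)

    def test_minus_1_printed_motif_set(self):
        assert overlap_feasibility(-1) == {"TAATG", "TGATG", "TAGTG"}

    @pytest.mark.parametrize("k", [-2, -5])
    def test_canonical_impossible_overlaps(self, k):
        assert overlap_feasibility(k) == frozenset()

    def test_att_start_enables_minus_5(self):
        codons = CodonSets(extended_start_codons=frozenset({"ATT"}))
        assert overlap_feasibility(-5, codons) == {"ATTGA", "ATTAG", "ATTAA"}

    @pytest.mark.parametrize("k", [-8, -6, 0, 3, 100])
    def test_disjoint_codons_are_unconstrained(self, k):
        assert overlap_feasibility(k) == UNCONSTRAINED


class TestSerialPipeline:
    def test_distances_and_phases_attached(self, forward_operon):
        pairs = serial_pairs(forward_operon)
        assert [(p.distance, p.phase) for p in pairs] == [(-4, 2), (1, 1)]

    def test_anomalous_deep_overlap_flagged_not_dropped(self):
        up = make_gene(1, 999, locus="up")
        down = make_gene(900, 1998, locus="down")  # 100 nt overlap
        pairs = serial_pairs([up, down])
        assert len(pairs) == 1
        assert pairs[0].distance == -100
        assert pairs[0].anomalous_overlap
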