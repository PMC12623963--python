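import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldrank import msa as M
from foldrank.containers import (
    DisorderTrack,
    DomainSegmentation,
    Msa,
    SequenceRecord,
    TemplateHit,
)
from foldrank.errors import ArgumentError
from foldrank.synthetic import make_msa


def _msa(query: str, rows: list[str]) -> Msa:
    return Msa(
        query=SequenceRecord("q", query),
        rows=[SequenceRecord(f"r{i}", r) for i, r in enumerate(rows)],
        insertions=[{} for _ in rows],
    )


def _hit(start, end, evalue=1e-5, coverage=0.9, template_length=None):
    return TemplateHit("t", start, end, evalue,
                       template_length or (end - start + 1), coverage)


class TestDepth:
    def test_query_only_all_ones(self):
        assert M.column_depth(_msa("ACDE", [])).tolist() == [1, 1, 1, 1]

    def test_direct_count(self):
        msa = _msa("AAAA", ["A--A"])
        assert M.column_depth(msa).tolist() == [2, 1, 1, 2]
        assert M.window_mean_depth(msa, 2, 3) == 1.0

    def test_binomial_sampling_bound(self):
        n_rows, p = 1000, 0.3
        msa = make_msa(length=50, n_rows=n_rows, coverage_profile=p, rng_seed=5)
        depth = M.column_depth(msa) - 1  # exclude the always-present query
        bound = 3 * np.sqrt(n_rows * p * (1 - p))
        assert np.all(np.abs(depth - n_rows * p) <= bound)

    def test_window_outside_alignment_rejected(self):
        with pytest.raises(ArgumentError):
            M.window_mean_depth(_msa("ACDE", []), 2, 9)


class TestFilterHits:
    @pytest.mark.parametrize(
        "hit,kept",
        [
            (_hit(1, 100, evalue=2.0), False),  # e-value above 1
            (_hit(1, 100, evalue=1.0), True),   # boundary e-value kept
            (_hit(1, 40), False),               # 40 aligned residues: removed
            (_hit(1, 41), True),                # 41 residues: kept
            (_hit(1, 100, coverage=0.5), False),  # coverage at 0.5: removed
            (_hit(1, 100, coverage=0.51), True),
        ],
    )
    def test_thresholds(self, hit, kept):
        assert (M.filter_hits([hit]) == [hit]) is kept

    def test_empty_and_order_and_idempotence(self):
        assert M.filter_hits([]) == []
        hits = [_hit(1, 100), _hit(5, 60, evalue=9), _hit(10, 200)]
        once = M.filter_hits(hits)
        assert once == [hits[0], hits[2]]
        assert M.filter_hits(once) == once


class TestSegmentDomains:
    def test_no_hits_single_domain(self):
        seg = M.segment_domains([], 200)
        assert seg.domains == [(1, 200)]

    def test_short_gap_split_at_midpoint(self):
        seg = M.segment_domains([_hit(1, 120), _hit(161, 320)], 320)
        assert seg.domains == [(1, 140), (141, 320)]

    def test_long_gap_becomes_domain(self):
        seg = M.segment_domains([_hit(1, 100), _hit(160, 320)], 320)
        assert seg.domains == [(1, 100), (101, 159), (160, 320)]

    def test_long_leading_and_trailing_gaps(self):
        seg = M.segment_domains([_hit(60, 160)], 220)
        assert seg.domains == [(1, 59), (60, 160), (161, 220)]

    def test_short_edge_gaps_absorbed(self):
        seg = M.segment_domains([_hit(20, 200)], 230)
        assert seg.domains == [(1, 230)]

    def test_bad_target_length(self):
        with pytest.raises(ArgumentError):
            M.segment_domains([], 0)

    def test_disorder_moves_boundary_to_run_midpoint(self):
        # boundary at 140 falls inside disordered run 131..150 -> moved to 140?
        # run midpoint (131+150)//2 = 140 stays; use an off-centre run instead
        labels = np.zeros(320, dtype=bool)
        labels[135:155] = True  # run 136..155, midpoint 145
        seg = M.segment_domains(
            [_hit(1, 120), _hit(161, 320)], 320, disorder=DisorderTrack(labels)
        )
        assert seg.domains == [(1, 145), (146, 320)]

    def test_boundary_outside_disorder_untouched(self):
        labels = np.zeros(320, dtype=bool)
        labels[10:30] = True
        seg = M.segment_domains(
            [_hit(1, 120), _hit(161, 320)], 320, disorder=DisorderTrack(labels)
        )
        assert seg.domains == [(1, 140), (141, 320)]

    @settings(deadline=None, max_examples=200)
    @given(st.data())
    def test_always_partitions_target(self, data):
        length = data.draw(st.integers(50, 500))
        n_hits = data.draw(st.integers(0, 6))
        hits = []
        for _ in range(n_hits):
            start = data.draw(st.integers(1, length))
            end = data.draw(st.integers(start, length))
            hits.append(_hit(start, end))
        seg = M.segment_domains(hits, length)
        seg.validate()  # raises if not a sorted exact partition


class TestPairingAndPadding:
    def test_shared_identifier_paired(self):
        a = _msa("ACDE", [])
        a.rows = [SequenceRecord("U1/1-4", "ACDE")]
        a.insertions = [{}]
        b = _msa("FGHI", [])
        b.rows = [SequenceRecord("U1/7-10", "FG-I")]
        b.insertions = [{}]
        out = M.pair_domain_alignments([a, b])
        assert len(out.paired) == 1
        assert out.paired[0].identifier == "U1"
        assert out.paired[0].residues == "ACDEFG-I"
        assert out.unpaired == [[], []]

    def test_unshared_identifier_listed_unpaired(self):
        a = _msa("AC", ["AC"])
        b = _msa("DE", ["DE"])
        b.rows[0] = SequenceRecord("other", "DE")
        out = M.pair_domain_alignments([a, b])
        assert out.paired == []
        assert [r.identifier for r in out.unpaired[0]] == ["r0"]
        assert [r.identifier for r in out.unpaired[1]] == ["other"]

    def test_counts_match_set_intersection_oracle(self, rng):
        for _ in range(50):
            ids_a = [f"U{i}" for i in rng.choice(50, size=rng.integers(1, 15),
                                                 replace=False)]
            ids_b = [f"U{i}" for i in rng.choice(50, size=rng.integers(1, 15),
                                                 replace=False)]
            a = _msa("ACDE", ["ACDE"] * len(ids_a))
            b = _msa("FG", ["FG"] * len(ids_b))
            for row, ident in zip(a.rows, ids_a):
                row.identifier = ident
            for row, ident in zip(b.rows, ids_b):
                row.identifier = ident
            out = M.pair_domain_alignments([a, b])
            expected = len(set(ids_a) & set(ids_b))
            assert len(out.paired) == expected
            assert len(out.unpaired[0]) == len(ids_a) - expected
            assert len(out.unpaired[1]) == len(ids_b) - expected

    def test_pad_examples(self):
        row = SequenceRecord("r", "WYCA")
        padded = M.pad_unpaired(row, (3, 6), 8)
        assert padded.residues == "--WYCA--"
        same = M.pad_unpaired(SequenceRecord("r", "WYCA"), (1, 4), 4)
        assert same.residues == "WYCA"
        with pytest.raises(ArgumentError):
            M.pad_unpaired(row, (3, 7), 8)

    def test_pad_gap_arithmetic(self):
        row = SequenceRecord("r", "W-C-")
        padded = M.pad_unpaired(row, (5, 8), 20)
        internal_gaps = row.residues.count("-")
        assert padded.residues.count("-") == 20 - 4 + internal_gaps


class TestBuildDomainMsa:
    def _setup(self):
        seg = DomainSegmentation(8, [(1, 4), (5, 8)])
        full = _msa("ACDEFGHI", ["ACDEFGHI"] * 10)
        for i, row in enumerate(full.rows):
            row.identifier = f"full{i}"
        shared = [f"S{i}" for i in range(3)]
        a = _msa("ACDE", ["ACDE"] * 5)
        for row, ident in zip(a.rows, shared + ["onlyA1", "onlyA2"]):
            row.identifier = ident
        b = _msa("FGHI", ["FGHI"] * 4)
        for row, ident in zip(b.rows, shared + ["onlyB1"]):
            row.identifier = ident
        return full, [a, b], seg

    def test_row_count_arithmetic(self):
        full, domain_msas, seg = self._setup()
        out = M.build_domain_msa(full, domain_msas, seg)
        # 1 query + 10 full + 3 paired + (2 + 1) padded unpaired
        assert out.n_rows == 1 + 10 + 3 + 3
        out.validate()
        assert all(len(r.residues) == 8 for r in out.rows)

    def test_empty_domain_msas_gives_query_plus_full(self):
        full, _, seg = self._setup()
        empty = [_msa("ACDE", []), _msa("FGHI", [])]
        out = M.build_domain_msa(full, empty, seg)
        assert out.n_rows == 11

    def test_duplicates_dropped(self):
        full, domain_msas, seg = self._setup()
        # make a paired row collide with a full row (same id, same residues)
        domain_msas[0].rows[0].identifier = "full0"
        domain_msas[1].rows[0].identifier = "full0"
        out = M.build_domain_msa(full, domain_msas, seg)
        assert out.n_rows == 1 + 10 + 2 + 3

    def test_four_by_two_combination_yields_eight(self):
        full, domain_msas, seg = self._setup()
        full2 = _msa("ACDEFGHI", [])
        combos = M.combine_domain_msas(
            [full, full2], [(seg, domain_msas)] * 4
        )
        assert len(combos) == 8

    def test_inconsistent_lengths_rejected(self):
        full, domain_msas, seg = self._setup()
        with pytest.raises(ArgumentError):
            M.build_domain_msa(full, domain_msas[:1], seg)
        bad_seg = DomainSegmentation(9, [(1, 4), (5, 9)])
        with pytest.raises(ArgumentError):
            M.build_domain_msa(full, domain_msas, bad_seg)


class TestAugment:
    def test_query_only_copies_query(self):
        out = M.augment_with_profile(_msa("ACDE", []))
        assert out.n_rows == 3
        assert all(r.residues == "ACDE" for r in out.rows)

    def test_dominant_substitution_adopted(self):
        # column 0: 9 of 10 rows carry L over query V -> freq 0.9 > 0.3
        rows = ["LCDE"] * 9 + ["VCDE"]
        out = M.augment_with_profile(_msa("VCDE", rows))
        synth = [r for r in out.rows if r.identifier.startswith("synthetic")]
        assert synth[0].residues[0] == "L"
        # second synthetic row: next candidate is below threshold -> query kept
        assert synth[1].residues[0] == "V"

    def test_default_appends_two_rows(self):
        msa = _msa("ACDE", ["ACDE", "AC-E"])
        out = M.augment_with_profile(msa)
        assert out.n_rows == msa.n_rows + 2

    def test_bad_n_sequences(self):
        with pytest.raises(ArgumentError):
            M.augment_with_profile(_msa("ACDE", []), n_sequences=0)
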