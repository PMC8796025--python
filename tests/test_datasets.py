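import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lrrscan.datasets import (
    SplitSpec,
    UnitRecord,
    filter_positive_units,
    greedy_identity_cluster,
    make_splits,
    pairwise_identity,
    read_units_tsv,
    sample_negative_units,
    write_units_tsv,
)
from lrrscan.hcsp import HCSPattern, contains_hcsp
from lrrscan.synthetic import GeneratorConfig, gen_non_lrr

AA = "ACDEFGHIKLMNPQRSTVWY"


def _protein(unit_lengths, gap=5):
    """Build (id, seq, intervals) with units of the given lengths."""
    rng = np.random.default_rng(0)
    seq, intervals, pos = [], [], 0
    for length in unit_lengths:
        seq.append("".join(rng.choice(list("GPE"), gap)))
        pos += gap
        seq.append("".join(rng.choice(list(AA), length)))
        intervals.append((pos + 1, pos + length))
        pos += length
    return "P1", "".join(seq), intervals


class TestFilterPositiveUnits:
    def test_short_unit_drops_protein_below_three(self):
        assert filter_positive_units([_protein([18, 22, 25])]) == []

    def test_all_in_range_kept(self):
        records = filter_positive_units([_protein([20, 24, 30])])
        assert len(records) == 3
        assert {len(r.sequence) for r in records} == {20, 24, 30}

    def test_all_out_of_range(self):
        assert filter_positive_units([_protein([19, 19, 19, 19])]) == []

    def test_unit_sequences_match_intervals(self):
        pid, seq, intervals = _protein([21, 26, 28])
        records = filter_positive_units([(pid, seq, intervals)])
        for r, (s, e) in zip(records, intervals):
            assert r.sequence == seq[s - 1 : e]

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            filter_positive_units([("P1", "ACDEF", [(1, 9)])])


class TestIdentityClustering:
    def test_duplicates_collapse(self):
        units = ["LRELDLSGNKLSGSIPSELGNLKN"] * 3
        assert len(greedy_identity_cluster(units)) == 1

    def test_below_threshold_stays_separate(self):
        a = "LRELDLSGNKLSGSIPSELG"
        b = "ARECDVSGNKTSGSIPSEAG"  # 5 differences on 20 -> identity 0.75
        assert sum(x != y for x, y in zip(a, b)) == 5
        assert len(greedy_identity_cluster([a, b], 0.8)) == 2

    def test_above_threshold_merges(self):
        a = "LRELDLSGNKLSGSIPSELG"
        b = "ARECDVSGNKLSGSIPSELG"  # 3 differences on 20 -> identity 0.85
        assert sum(x != y for x, y in zip(a, b)) == 3
        assert len(greedy_identity_cluster([a, b], 0.8)) == 1

    def test_offset_identity_uses_shorter_length(self):
        # the 20-mer appears verbatim inside the 24-mer -> identity 1.0
        long = "GPGP" + "LRELDLSGNKLSGSIPSELG"
        assert pairwise_identity(long, "LRELDLSGNKLSGSIPSELG") == 1.0

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="LRES", min_size=20, max_size=24),
            min_size=1,
            max_size=8,
        )
    )
    def test_representatives_pairwise_below_threshold(self, units):
        reps = greedy_identity_cluster(units, 0.8)
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                assert pairwise_identity(a, b) < 0.8

    def test_empty_input(self):
        assert greedy_identity_cluster([]) == []


class TestNegativeSampling:
    def _background(self, seed=3, n=30, length=120):
        cfg = GeneratorConfig(seed=seed)
        rng = cfg.rng()
        out = []
        for _ in range(n):
            seq = ""
            while len(seq) < length:
                seq += gen_non_lrr(cfg, 30, rng)
            out.append(seq[:length])
        return out

    def test_histogram_satisfied(self):
        records = sample_negative_units(
            self._background(), {20: 5, 24: 5}, seed=1
        )
        lengths = [len(r.sequence) for r in records]
        assert sorted(lengths) == [20] * 5 + [24] * 5
        assert all(not contains_hcsp(r.sequence) for r in records)

    def test_seed_reproducible(self):
        bg = self._background()
        a = sample_negative_units(bg, {22: 8}, seed=7)
        b = sample_negative_units(bg, {22: 8}, seed=7)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_infeasible_length_reported(self):
        with pytest.raises(RuntimeError, match="25"):
            sample_negative_units(["ACDEFGHIKL"], {25: 1}, seed=0)

    def test_saturated_background_exhausts(self):
        # a pattern with no constrained positions matches everywhere, so no
        # HCSP-free segment of length >= 11 exists
        pattern = HCSPattern(allowed={})
        with pytest.raises(RuntimeError, match="20"):
            sample_negative_units(
                self._background(n=3), {20: 1}, pattern=pattern, seed=0
            )


class TestMakeSplits:
    def _records(self, n_per_length, lengths=(20, 22, 24, 26)):
        pos, neg = [], []
        rng = np.random.default_rng(5)
        for L in lengths:
            for i in range(n_per_length):
                pos.append(
                    UnitRecord("".join(rng.choice(list(AA), L)), "positive", f"p{L}_{i}")
                )
                neg.append(
                    UnitRecord("".join(rng.choice(list(AA), L)), "negative", f"n{L}_{i}")
                )
        return pos, neg

    def test_eighty_twenty_and_fold_sizes(self):
        pos, neg = self._records(25)  # 100 pos + 100 neg
        split = make_splits(pos, neg, SplitSpec(seed=0))
        assert len(split.train) == 160
        assert len(split.test) == 40
        assert [len(f) for f in split.folds] == [32] * 5

    def test_partitions_disjoint_and_cover(self):
        pos, neg = self._records(25)
        split = make_splits(pos, neg, SplitSpec(seed=0))
        ids = [r.source_id for fold in split.folds for r in fold]
        assert len(ids) == len(set(ids))
        test_ids = {r.source_id for r in split.test}
        assert not test_ids & set(ids)
        assert len(test_ids | set(ids)) == 200

    def test_per_length_balance(self):
        pos, neg = self._records(25)
        split = make_splits(pos, neg, SplitSpec(seed=0))
        for part in [split.test, *split.folds]:
            by_length = {}
            for r in part:
                key = len(r.sequence)
                by_length.setdefault(key, []).append(r.label)
            for labels in by_length.values():
                n_pos = labels.count("positive")
                assert abs(n_pos - (len(labels) - n_pos)) <= 1

    def test_unbalanced_rejected(self):
        pos, neg = self._records(10)
        with pytest.raises(ValueError):
            make_splits(pos, neg[:-1], SplitSpec(seed=0))


def test_units_tsv_round_trip(tmp_path):
    records = [
        UnitRecord("LRELDLSGNKLSGSIPSELG", "positive", "a"),
        UnitRecord("GPGPGPGPGPGPGPGPGPGP", "negative", "b"),
    ]
    path = tmp_path / "units.tsv"
    write_units_tsv(records, path)
    assert read_units_tsv(path) == records
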