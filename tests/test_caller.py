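import numpy as np
import pytest

from lrrscan.caller import (
    AssemblyParams,
    CandidateWindow,
    assemble,
    filter_groups,
    group_by_distance,
    local_filter,
    predict_protein,
    resolve_units,
    scan_windows,
    segment_select,
)

# ---------------------------------------------------------------------------
# independent transcription of the five assembly steps, written as literal
# per-step loops; used as the oracle for equivalence testing


def oracle_assemble(windows, params):
    thr, lscp, ldcp, lncp = (
        params.lps_threshold,
        params.lscp,
        params.ldcp,
        params.lncp,
    )
    by_start = {}
    for w in windows:
        by_start.setdefault(w.start, []).append(w)

    # step 1: score control — keep starts predicting >= lscp units
    step1 = []
    for start in by_start:
        if len([w for w in by_start[start] if w.lps >= thr]) >= lscp:
            step1.append(start)

    # step 2: per 20-aa segment keep the start with the best 20-mer LPS
    lps20 = {w.start: w.lps for w in windows if w.length == 20}
    winners = {}
    for start in sorted(step1):
        seg = (start - 1) // 20
        if seg not in winners:
            winners[seg] = start
        elif lps20[start] > lps20[winners[seg]]:
            winners[seg] = start
    step2 = sorted(winners.values())

    # step 3: distance control
    groups = []
    for start in step2:
        if groups and (start - groups[-1][-1] - 20) <= ldcp:
            groups[-1].append(start)
        else:
            groups.append([start])

    # step 4: number control
    groups = [g for g in groups if len(g) >= lncp]

    # step 5: best window per start, greedy non-overlap by LPS
    domains = []
    for g in groups:
        cands = []
        for start in g:
            for w in by_start[start]:
                if w.lps >= thr:
                    cands.append(w)
        cands.sort(key=lambda w: (-w.lps, w.start, w.length))
        taken, done = [], set()
        for w in cands:
            if w.start in done:
                continue
            if not any(
                w.start <= u.end and u.start <= w.end for u in taken
            ):
                taken.append(w)
                done.add(w.start)
        taken.sort(key=lambda w: w.start)
        if len(taken) >= lncp:
            domains.append([(w.start, w.end, w.lps) for w in taken])
    return domains


def as_tuples(domains):
    return [[(u.start, u.end, u.lps) for u in d.units] for d in domains]


def random_windows(rng, n_protein):
    windows = []
    for start in range(1, n_protein - 19):
        for length in range(20, 31):
            if start + length - 1 <= n_protein:
                lps = round(float(rng.random()), 3)
                windows.append(CandidateWindow(start, length, lps))
    return windows


# ---------------------------------------------------------------------------


class TestScanWindows:
    def test_window_counts(self):
        counter = lambda seqs: [0.0] * len(seqs)
        assert scan_windows("A" * 19, score_fn=counter) == []
        assert len(scan_windows("A" * 20, score_fn=counter)) == 1
        assert len(scan_windows("A" * 49, score_fn=counter)) == 275

    def test_windows_cover_all_lengths(self):
        windows = scan_windows("A" * 35, score_fn=lambda s: [0.5] * len(s))
        assert {w.length for w in windows} == set(range(20, 31))
        assert all(w.start + w.length - 1 <= 35 for w in windows)


class TestLocalFilter:
    def _windows(self, start, lps_values):
        return [
            CandidateWindow(start, 20 + i, v) for i, v in enumerate(lps_values)
        ]

    def test_kept_when_k_meets_lscp(self):
        ws = self._windows(5, [0.9, 0.8, 0.7, 0.6, 0.55, 0.1])
        assert local_filter(ws, AssemblyParams(lscp=4)) == [5]

    def test_removed_when_k_below_lscp(self):
        ws = self._windows(5, [0.9, 0.8, 0.7, 0.6, 0.55, 0.1])
        assert local_filter(ws, AssemblyParams(lscp=6)) == []

    def test_lscp_one_keeps_any_predicted(self):
        ws = self._windows(3, [0.51])
        assert local_filter(ws, AssemblyParams(lscp=1)) == [3]


class TestSegmentSelect:
    def test_max_lps_wins(self):
        ws = [CandidateWindow(3, 20, 0.90), CandidateWindow(15, 20, 0.95)]
        assert segment_select([3, 15], ws, AssemblyParams()) == [15]

    def test_single_start_kept(self):
        ws = [CandidateWindow(7, 20, 0.6)]
        assert segment_select([7], ws, AssemblyParams()) == [7]

    def test_tie_keeps_smaller_start(self):
        ws = [CandidateWindow(7, 20, 0.8), CandidateWindow(12, 20, 0.8)]
        assert segment_select([7, 12], ws, AssemblyParams()) == [7]


class TestGrouping:
    def test_gap_splits_groups(self):
        groups = group_by_distance([10, 32, 80], AssemblyParams(ldcp=9))
        assert groups == [[10, 32], [80]]  # gaps: 2 and 28

    def test_ldcp_zero_groups_only_abutting(self):
        groups = group_by_distance([10, 30, 51], AssemblyParams(ldcp=0))
        assert groups == [[10, 30], [51]]

    def test_single_start(self):
        assert group_by_distance([4], AssemblyParams()) == [[4]]

    def test_filter_groups_by_size(self):
        params3 = AssemblyParams(lncp=3)
        params4 = AssemblyParams(lncp=4)
        groups = [[1, 25, 49]]
        assert filter_groups(groups, params3) == groups
        assert filter_groups(groups, params4) == []


class TestResolveUnits:
    def test_isolated_start_takes_best_length(self):
        ws = [CandidateWindow(10, L, 0.5 + 0.01 * L) for L in range(20, 31)]
        ws[4] = CandidateWindow(10, 24, 0.97)  # best at length 24
        units = resolve_units([10], ws, AssemblyParams())
        assert len(units) == 1
        assert (units[0].start, units[0].end) == (10, 33)

    def test_overlapping_starts_resolved_disjoint(self):
        ws = [
            CandidateWindow(19, 20, 0.8),
            CandidateWindow(21, 20, 0.9),
            CandidateWindow(21, 22, 0.85),
        ]
        units = resolve_units([19, 21], ws, AssemblyParams())
        for i, a in enumerate(units):
            for b in units[i + 1 :]:
                assert a.end < b.start or b.end < a.start
        # higher-LPS window from start 21 must have been emitted first
        assert any(u.start == 21 and u.lps == 0.9 for u in units)


class TestPredictProtein:
    def test_no_confident_windows_no_domains(self):
        assert predict_protein("A" * 80, score_fn=lambda s: [0.1] * len(s)) == []

    def test_planted_units_recovered_with_oracle_scores(self):
        # five units of 20 aa separated by 5-aa spacers; the oracle scores a
        # window 1.0 iff it is exactly a planted unit
        truth = []
        pos = 1
        for _ in range(5):
            truth.append((pos, pos + 19))
            pos += 25
        protein_len = pos - 6
        windows = []
        for start in range(1, protein_len - 18):
            for length in range(20, 31):
                if start + length - 1 <= protein_len:
                    lps = 1.0 if (start, start + length - 1) in truth else 0.0
                    windows.append(CandidateWindow(start, length, lps))
        domains = assemble(windows, AssemblyParams(lscp=1, ldcp=9, lncp=3))
        called = [(u.start, u.end) for d in domains for u in d.units]
        assert called == truth

    def test_unit_count_nonincreasing_in_lncp(self):
        rng = np.random.default_rng(11)
        windows = random_windows(rng, 100)
        counts = []
        for lncp in range(1, 6):
            domains = assemble(windows, AssemblyParams(lscp=2, lncp=lncp))
            counts.append(sum(len(d.units) for d in domains))
        assert counts == sorted(counts, reverse=True)

    def test_survivors_nonincreasing_in_lscp(self):
        rng = np.random.default_rng(12)
        windows = random_windows(rng, 100)
        prev = None
        for lscp in range(1, 12):
            kept = set(local_filter(windows, AssemblyParams(lscp=lscp)))
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestOracleEquivalence:
    def test_random_proteins_match_transcription(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            n = int(rng.integers(20, 121))
            windows = random_windows(rng, n)
            params = AssemblyParams(
                lscp=int(rng.integers(1, 7)),
                ldcp=int(rng.integers(0, 13)),
                lncp=int(rng.integers(1, 5)),
            )
            assert as_tuples(assemble(windows, params)) == oracle_assemble(
                windows, params
            )

    def test_emitted_units_satisfy_contracts(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(40, 121))
            windows = random_windows(rng, n)
            params = AssemblyParams(lscp=2, ldcp=9, lncp=2)
            for domain in assemble(windows, params):
                units = domain.units
                assert len(units) >= params.lncp
                assert all(u.lps >= params.lps_threshold for u in units)
                for a, b in zip(units, units[1:]):
                    assert a.end < b.start  # pairwise disjoint, sorted
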