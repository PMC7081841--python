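"""Peak-table I/O, filtering, and fragment-size binning."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from msaptools import peaks
from msaptools.errors import FormatError, UsageError
from msaptools.peaks import FragmentBinner, PeakRecord, bin_fragments, filter_peaks


def _rec(size, sample="s1", digest="EH", height=100.0):
    return PeakRecord(sample_id=sample, digest=digest, size_bp=size, height=height)


class TestReadPeakTable:
    def test_write_read_round_trip(self, tmp_path, noise_free_cohort):
        _, records = noise_free_cohort
        path = tmp_path / "t.csv"
        peaks.write_peak_table(records, path)
        assert peaks.read_peak_table(path) == records

    def test_well_formed_rows_parse(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,digest,size_bp,height,area\n"
            "a,EH,100.5,120,10\na,EM,100.4,80,5\nb,EH,250,60,4\n"
        )
        assert len(peaks.read_peak_table(path)) == 3

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,size_bp,height\na,100,50\n")
        with pytest.raises(FormatError, match="digest"):
            peaks.read_peak_table(path)

    def test_unknown_digest_label_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,digest,size_bp,height\na,XY,100,50\n")
        with pytest.raises(FormatError):
            peaks.read_peak_table(path)

    def test_non_numeric_size_reports_line_number(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,digest,size_bp,height\na,EH,100,50\na,EM,oops,50\n")
        with pytest.raises(FormatError, match=":3:"):
            peaks.read_peak_table(path)

    def test_size_window_drops_out_of_range_rows(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,digest,size_bp,height\na,EH,40,50\na,EH,100,50\na,EM,600,50\n"
        )
        records = peaks.read_peak_table(path, size_window=(50, 500))
        assert [r.size_bp for r in records] == [100.0]


class TestFilterPeaks:
    def test_identity_filter(self, noise_free_cohort):
        _, records = noise_free_cohort
        assert filter_peaks(records, 0.0, (0.0, float("inf"))) == records

    def test_all_below_threshold_empty(self):
        records = [_rec(100, height=10), _rec(200, height=20)]
        assert filter_peaks(records, min_height=30) == []

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1, max_value=1000),
                st.floats(min_value=0, max_value=5000),
            ),
            max_size=50,
        ),
        st.floats(min_value=0, max_value=5000),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_exhaustive_predicate(self, rows, min_height):
        records = [_rec(s, height=h) for s, h in rows]
        lo, hi = 50.0, 500.0
        expected = [r for r in records if r.height >= min_height and lo <= r.size_bp <= hi]
        assert filter_peaks(records, min_height, (lo, hi)) == expected


def brute_force_partition(sizes, half_width):
    """All-pairs transitive-closure clustering at gap threshold 2*half_width."""
    n = len(sizes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(sizes[i] - sizes[j]) <= 2 * half_width:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(sizes[i])
    return sorted(sorted(g) for g in groups.values())


class TestBinFragments:
    def test_gap_rule_example(self):
        records = [_rec(120.1), _rec(120.4, sample="s2"), _rec(200.0)]
        bins, _ = bin_fragments(records, half_width_bp=0.5)
        assert len(bins) == 2
        assert bins[0].nominal_size_bp == pytest.approx((120.1 + 120.4) / 2)
        assert bins[1].nominal_size_bp == 200.0

    @given(
        st.lists(st.floats(min_value=50, max_value=500), min_size=1, max_size=60),
        st.floats(min_value=0.05, max_value=5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_all_pairs_clustering_oracle(self, sizes, half_width):
        records = [_rec(s) for s in sizes]
        binner = FragmentBinner(half_width_bp=half_width).fit(records)
        got = []
        for lo, hi in zip(binner.bin_lower_, binner.bin_upper_):
            got.append(sorted(s for s in sizes if lo <= s < hi))
        assert got == brute_force_partition(sizes, half_width)

    @given(rnd=st.randoms(use_true_random=False))
    @settings(
        max_examples=20,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_permutation_invariance(self, rnd, noise_free_cohort):
        _, records = noise_free_cohort
        shuffled = list(records)
        rnd.shuffle(shuffled)
        bins_a, mat_a = bin_fragments(records)
        bins_b, mat_b = bin_fragments(shuffled)
        assert bins_a == bins_b
        assert mat_a.samples == mat_b.samples
        assert np.array_equal(mat_a.presence, mat_b.presence)

    def test_every_peak_maps_to_exactly_one_bin(self, noise_free_cohort):
        _, records = noise_free_cohort
        binner = FragmentBinner().fit(records)
        hits = [
            sum(lo <= r.size_bp < hi for lo, hi in zip(binner.bin_lower_, binner.bin_upper_))
            for r in records
        ]
        assert hits == [1] * len(records)

    def test_round_trip_bins_match_truth(self, noise_free_cohort):
        truth, records = noise_free_cohort
        bins, _ = bin_fragments(records)
        informative = np.any(truth.states != 3, axis=0)  # locus has >=1 band
        expected = truth.locus_sizes[informative]
        assert np.allclose([b.nominal_size_bp for b in bins], expected)

    def test_min_samples_per_locus_discards_rare_bins(self):
        records = [
            _rec(100.0, sample="s1"), _rec(100.1, sample="s2"),
            _rec(300.0, sample="s1"),
        ] + [_rec(1.0, sample=s, digest="EM") for s in ("s1", "s2")]
        bins, _ = bin_fragments(records, min_samples_per_locus=2)
        assert [b.nominal_size_bp for b in bins] == [1.0, pytest.approx(100.05)]

    def test_sample_missing_one_digest_excluded(self, caplog):
        records = [
            _rec(100, sample="both", digest="EH"),
            _rec(200, sample="both", digest="EM"),
            _rec(100, sample="ehonly", digest="EH"),
        ]
        _, matrix = bin_fragments(records)
        assert matrix.samples == ["both"]

    def test_duplicate_peaks_collapse_to_single_call(self):
        records = [
            _rec(100.0), _rec(100.2),  # same sample, same digest, same bin
            _rec(100.1, digest="EM"),
        ]
        _, matrix = bin_fragments(records)
        assert matrix.presence.shape == (1, 1, 2)
        assert matrix.presence.all()

    def test_empty_input_gives_empty_matrix(self):
        bins, matrix = bin_fragments([])
        assert bins == [] and matrix.presence.size == 0

    def test_presence_monotone_in_min_height(self, noise_free_cohort):
        _, records = noise_free_cohort
        low = bin_fragments(filter_peaks(records, min_height=0))[1]
        high_records = filter_peaks(records, min_height=np.median([r.height for r in records]))
        binner = FragmentBinner().fit(records)  # same bin layout
        high = binner.transform(high_records)
        sub = low.presence[:, [low.samples.index(s) for s in high.samples], :]
        assert not np.any(high.presence & ~sub)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(UsageError):
            bin_fragments([_rec(100)], half_width_bp=0)
        with pytest.raises(UsageError):
            filter_peaks([], min_height=-1)
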