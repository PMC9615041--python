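import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atacdyn import (
    CountMatrix,
    GenomicInterval,
    count_fragments,
    merge_intervals,
    read_bed,
    write_bed,
)
from atacdyn.intervals import BedFormatError


class TestBedIO:
    def test_basic_record(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tp1\n")
        (iv,) = read_bed(p)
        assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr1", 100, 200, "p1")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_inverted_coordinates_name_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(BedFormatError, match="line 1"):
            read_bed(p)

    def test_round_trip_identity(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 0, 50, "a", "+"),
            GenomicInterval("chr2", 10, 11, "b", "-"),
            GenomicInterval("chr2", 5, 500, "c"),
        ]
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        back = read_bed(p)
        assert [(i.chrom, i.start, i.end, i.name, i.strand) for i in back] == [
            (i.chrom, i.start, i.end, i.name, i.strand) for i in ivs
        ]

    def test_invalid_interval_construction(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)


class TestMerge:
    def test_overlapping(self):
        merged, prov = merge_intervals(
            [GenomicInterval("chr1", 100, 200, "a"), GenomicInterval("chr1", 150, 250, "b")]
        )
        assert [(m.chrom, m.start, m.end) for m in merged] == [("chr1", 100, 250)]
        assert prov["a"] == prov["b"] == merged[0].name

    def test_bookended_merge_at_gap_zero(self):
        merged, _ = merge_intervals(
            [GenomicInterval("chr1", 100, 200, "a"), GenomicInterval("chr1", 200, 300, "b")]
        )
        assert [(m.start, m.end) for m in merged] == [(100, 300)]

    def test_different_chromosomes_untouched(self):
        merged, _ = merge_intervals(
            [GenomicInterval("chr1", 100, 200, "a"), GenomicInterval("chr2", 100, 200, "b")]
        )
        assert len(merged) == 2

    def test_max_gap(self):
        ivs = [GenomicInterval("chr1", 0, 10, "a"), GenomicInterval("chr1", 15, 20, "b")]
        assert len(merge_intervals(ivs, max_gap=0)[0]) == 2
        assert len(merge_intervals(ivs, max_gap=5)[0]) == 1

    def test_provenance_covers_every_input(self):
        rng = np.random.default_rng(0)
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(w), f"p{i}")
            for i, (s, w) in enumerate(zip(rng.integers(0, 5000, 60), rng.integers(1, 400, 60)))
        ]
        merged, prov = merge_intervals(ivs)
        assert set(prov) == {iv.name for iv in ivs}
        assert set(prov.values()) == {m.name for m in merged}

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 60)), min_size=1, max_size=30
        )
    )
    def test_idempotent_and_disjoint(self, raw):
        ivs = [GenomicInterval("chr1", s, s + w, f"p{i}") for i, (s, w) in enumerate(raw)]
        once, _ = merge_intervals(ivs)
        twice, _ = merge_intervals(once)
        assert [(m.start, m.end) for m in once] == [(m.start, m.end) for m in twice]
        for a, b in zip(once, once[1:]):
            assert a.end < b.start  # disjoint and sorted, gaps strictly positive


class TestCounting:
    def _samples(self, ids):
        return pd.DataFrame(
            {"sample_id": ids, "day": range(len(ids)), "replicate": [1] * len(ids)}
        )

    def test_single_overlap_counts(self):
        peaks = [GenomicInterval("chr1", 100, 200, "pk1")]
        frags = {"s1": [GenomicInterval("chr1", 120, 180, "f")]}
        cm = count_fragments(frags, peaks, self._samples(["s1"]))
        assert cm.counts.loc["pk1", "s1"] == 1

    def test_no_overlap_no_increment(self):
        peaks = [GenomicInterval("chr1", 100, 200, "pk1")]
        frags = {"s1": [GenomicInterval("chr1", 300, 400, "f")]}
        cm = count_fragments(frags, peaks, self._samples(["s1"]))
        assert cm.counts.to_numpy().sum() == 0

    def test_multi_overlap_discarded_by_default(self):
        peaks = [GenomicInterval("chr1", 100, 200, "a"), GenomicInterval("chr1", 300, 400, "b")]
        frags = {"s1": [GenomicInterval("chr1", 150, 350, "f")]}
        cm = count_fragments(frags, peaks, self._samples(["s1"]))
        assert cm.counts.to_numpy().sum() == 0
        cm2 = count_fragments(frags, peaks, self._samples(["s1"]), count_multi_overlap=True)
        assert cm2.counts.to_numpy().sum() == 2

    def test_overlapping_peaks_rejected(self):
        peaks = [GenomicInterval("chr1", 100, 200, "a"), GenomicInterval("chr1", 150, 250, "b")]
        with pytest.raises(ValueError, match="disjoint"):
            count_fragments({}, peaks, self._samples(["s1"]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        raw = [
            GenomicInterval("chr1", int(s), int(s + w), f"p{i}")
            for i, (s, w) in enumerate(zip(rng.integers(0, 20000, 100), rng.integers(50, 500, 100)))
        ]
        peaks, _ = merge_intervals(raw)
        frags = [
            GenomicInterval(rng.choice(["chr1", "chr2"]), int(s), int(s + w), f"f{i}")
            for i, (s, w) in enumerate(zip(rng.integers(0, 22000, 1000), rng.integers(20, 600, 1000)))
        ]
        cm = count_fragments({"s1": frags}, peaks, self._samples(["s1"]))
        # brute force all-pairs oracle
        expected = {p.name: 0 for p in peaks}
        for f in frags:
            hits = [p for p in peaks if f.overlaps(p)]
            if len(hits) == 1:
                expected[hits[0].name] += 1
        assert {p: int(cm.counts.loc[p, "s1"]) for p in expected} == expected
        assert cm.counts["s1"].sum() <= len(frags)


class TestCountMatrix:
    def test_round_trip(self, tmp_path, two_day_samples, make_cm):
        cm = make_cm(np.arange(8).reshape(2, 4), two_day_samples)
        cm.write(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountMatrix.read(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert (back.counts.to_numpy() == cm.counts.to_numpy()).all()
        assert back.days == [0.0, 3.0]

    def test_negative_counts_rejected(self, two_day_samples, make_cm):
        with pytest.raises(ValueError):
            make_cm(np.array([[1, -1, 0, 0]]), two_day_samples)


class TestBedtoolsCrossCheck:
    def test_merge_matches_bedtools(self, tmp_path):
        """Our merge (bookended intervals join at max_gap=0) agrees with
        `bedtools merge` on random intervals."""
        import subprocess

        rng = np.random.default_rng(9)
        intervals = []
        for i in range(300):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 5000))
            end = start + int(rng.integers(1, 400))
            intervals.append(GenomicInterval(chrom, start, end, f"iv{i}"))
        merged, _ = merge_intervals(intervals)

        bed_in = tmp_path / "in.bed"
        write_bed(sorted(intervals, key=lambda p: (p.chrom, p.start, p.end)), bed_in)
        res = subprocess.run(
            ["bedtools", "merge", "-i", str(bed_in)],
            capture_output=True, text=True, check=True,
        )
        ref = [
            (f[0], int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in res.stdout.strip().splitlines())
        ]
        ours = [(p.chrom, p.start, p.end) for p in merged]
        assert sorted(ours) == sorted(ref)
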