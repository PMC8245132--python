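"""Tract segmentation, merging, shared exclusion, coordinates, classification."""

import numpy as np
import pandas as pd
import pytest

from lohscape.loh_caller import (
    INTERSTITIAL,
    TERMINAL,
    LohConfig,
    LohTract,
    call_loh,
    classify_tract,
    exclude_shared,
    filter_and_merge,
    resolve_coordinates,
    segment_tracts,
)
from lohscape.markers import HET, HOM_P1, HOM_P2, MISSING
from lohscape.simulate import Genome

from conftest import calls_from_string


# --- independent brute-force rule enumerator (the oracle) -------------------

def brute_force_call(states: list[int]) -> list[tuple[str, int, int, int]]:
    """Direct enumeration of the calling rules on a marker-state vector.

    Returns (origin, first_idx, last_idx, n_converted_markers) tuples.
    Written independently of the production implementation: runs are built
    from the non-missing subsequence, sub-two-marker runs dropped, and
    same-origin neighbours merged to a fixed point whenever fewer than two
    heterozygous calls separate them.
    """
    runs: list[list] = []  # [state, [indices]]
    for i, s in enumerate(states):
        if s == MISSING:
            continue
        if runs and runs[-1][0] == s:
            runs[-1][1].append(i)
        else:
            runs.append([s, [i]])
    tracts = [[s, idx] for s, idx in runs if s in (HOM_P1, HOM_P2) and len(idx) >= 2]
    while True:
        merged: list[list] = []
        changed = False
        for s, idx in tracts:
            if merged and merged[-1][0] == s:
                between = [
                    k
                    for k in range(merged[-1][1][-1] + 1, idx[0])
                    if states[k] == HET
                ]
                if len(between) < 2:
                    merged[-1][1] = merged[-1][1] + idx
                    changed = True
                    continue
            merged.append([s, list(idx)])
        tracts = merged
        if not changed:
            break
    label = {HOM_P1: "P1", HOM_P2: "P2"}
    return [(label[s], idx[0], idx[-1], len(idx)) for s, idx in tracts]


def production_call(states: list[int]) -> list[tuple[str, int, int, int]]:
    calls = calls_from_string("H" * len(states))
    calls["state"] = np.array(states, dtype=np.int8)
    tracts = filter_and_merge(segment_tracts(calls), calls)
    return [(t.origin, t.first_idx, t.last_idx, t.n_markers) for t in tracts]


class TestSegmentTracts:
    def test_single_run_between_het(self):
        tracts = segment_tracts(calls_from_string("HH11H"))
        assert len(tracts) == 1
        assert (tracts[0].origin, tracts[0].n_markers) == ("P1", 2)

    def test_missing_is_transparent(self):
        tracts = segment_tracts(calls_from_string("1M1"))
        assert len(tracts) == 1
        assert tracts[0].n_markers == 2
        assert (tracts[0].first_idx, tracts[0].last_idx) == (0, 2)

    def test_origin_switch_breaks_run(self):
        tracts = segment_tracts(calls_from_string("H12H"))
        assert [(t.origin, t.n_markers) for t in tracts] == [("P1", 1), ("P2", 1)]

    def test_multiple_chromosomes_rejected(self):
        calls = pd.concat(
            [calls_from_string("11", chrom="chr1"), calls_from_string("11", chrom="chr2")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="single chromosome"):
            segment_tracts(calls)


class TestFilterAndMerge:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ("111H11", [("P1", 5)]),  # one HET cannot support the disruption
            ("111HH11", [("P1", 3), ("P1", 2)]),  # two HETs keep them apart
            ("11H22", [("P1", 2), ("P2", 2)]),  # origins never merge
            ("H1H", []),  # single-marker tract filtered
            ("11M11", [("P1", 4)]),  # missing never blocks a merge
            ("112H11", [("P1", 4)]),  # a dropped single P2 does not block
            ("11H11H11", [("P1", 6)]),  # chained merging reaches a fixed point
            ("11H1H11", [("P1", 2), ("P1", 2)]),  # dropped single leaves 2 HETs
        ],
    )
    def test_merge_rules(self, pattern, expected):
        calls = calls_from_string(pattern)
        tracts = filter_and_merge(segment_tracts(calls), calls)
        assert [(t.origin, t.n_markers) for t in tracts] == expected

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            states = rng.choice(
                [HET, HOM_P1, HOM_P2, MISSING], size=n, p=[0.4, 0.25, 0.25, 0.1]
            ).tolist()
            assert production_call(states) == brute_force_call(states)

    def test_every_tract_has_at_least_two_markers(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            states = rng.choice([HET, HOM_P1, HOM_P2, MISSING], size=30).tolist()
            for origin, first, last, n in production_call(states):
                assert n >= 2
                assert first < last


def make_tract(start, end, chrom="chr1", origin="P1", n=5):
    return LohTract(chrom, origin, start, end, n, 0, 0)


class TestExcludeShared:
    def test_tract_in_half_the_lines_removed_everywhere(self):
        shared = {f"L{i}": [make_tract(10_000, 20_000)] for i in range(10)}
        private = {f"L{i}": [] for i in range(10, 20)}
        result = exclude_shared({**shared, **private})
        assert all(len(ts) == 0 for ts in result.values())

    def test_tract_below_line_fraction_kept(self):
        shared = {f"L{i}": [make_tract(10_000, 20_000)] for i in range(9)}
        private = {f"L{i}": [] for i in range(9, 20)}
        result = exclude_shared({**shared, **private})
        assert sum(len(ts) for ts in result.values()) == 9

    def test_reciprocal_rule_ignores_asymmetric_overlap(self):
        # 10 kb inside 100 kb: only 10% of the long span, so not "shared"
        lines = {f"L{i}": [make_tract(50_000, 60_000)] for i in range(10)}
        lines["L10"] = [make_tract(1, 100_000)]
        for i in range(11, 20):
            lines[f"L{i}"] = []
        result = exclude_shared(lines)
        assert len(result["L10"]) == 1  # the long tract survives
        assert all(len(result[f"L{i}"]) == 0 for i in range(10))

    def test_origin_must_match(self):
        lines = {f"L{i}": [make_tract(10_000, 20_000, origin="P1")] for i in range(10)}
        for i in range(10, 20):
            lines[f"L{i}"] = [make_tract(10_000, 20_000, origin="P2")]
        result = exclude_shared(lines)
        # each origin is present in only half the lines
        assert all(len(ts) == 0 for ts in result.values())

    def test_single_line_returned_unchanged(self, caplog):
        lines = {"L1": [make_tract(10, 20)]}
        result = exclude_shared(lines)
        assert len(result["L1"]) == 1

    def test_lowering_thresholds_never_increases_survivors(self):
        rng = np.random.default_rng(3)
        lines = {}
        for i in range(12):
            tracts = []
            for _ in range(rng.integers(1, 5)):
                s = int(rng.integers(1, 80_000))
                tracts.append(make_tract(s, s + int(rng.integers(500, 20_000))))
            lines[f"L{i}"] = tracts
        total = lambda r: sum(len(ts) for ts in r.values())
        for of_low, of_high in [(0.5, 0.8), (0.3, 0.9)]:
            assert total(exclude_shared(lines, overlap_frac=of_low)) <= total(
                exclude_shared(lines, overlap_frac=of_high)
            )
        for lf_low, lf_high in [(0.25, 0.5), (0.1, 0.9)]:
            assert total(exclude_shared(lines, line_frac=lf_low)) <= total(
                exclude_shared(lines, line_frac=lf_high)
            )


class TestResolveCoordinates:
    def test_midpoints_between_flanking_markers(self):
        calls = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [1000, 2000, 3000, 4000],
                "state": np.array([HET, HOM_P1, HOM_P1, HET], dtype=np.int8),
            }
        )
        tract = LohTract("chr1", "P1", 2000, 3000, 2, 1, 2)
        resolve_coordinates(tract, calls, 200_000)
        assert (tract.avg_start, tract.avg_end, tract.size) == (1500, 3500, 2000)

    def test_no_upstream_marker_extends_to_position_one(self):
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": [500, 600, 700],
             "state": np.array([HOM_P1, HOM_P1, HET], dtype=np.int8)}
        )
        tract = LohTract("chr1", "P1", 500, 600, 2, 0, 1)
        resolve_coordinates(tract, calls, 10_000)
        assert tract.avg_start == 1
        assert tract.avg_end == 650

    def test_no_downstream_marker_extends_to_chrom_end(self):
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": [500, 600, 700],
             "state": np.array([HET, HOM_P2, HOM_P2], dtype=np.int8)}
        )
        tract = LohTract("chr1", "P2", 600, 700, 2, 1, 2)
        resolve_coordinates(tract, calls, 10_000)
        assert tract.avg_end == 10_000

    def test_missing_flank_is_skipped(self):
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 300, 400, 500],
             "state": np.array([HET, MISSING, HOM_P1, HOM_P1], dtype=np.int8)}
        )
        tract = LohTract("chr1", "P1", 400, 500, 2, 2, 3)
        resolve_coordinates(tract, calls, 10_000)
        assert tract.avg_start == (100 + 400) // 2

    def test_odd_sum_midpoint_floors(self):
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 201, 301, 401],
             "state": np.array([HET, HOM_P1, HOM_P1, HET], dtype=np.int8)}
        )
        tract = LohTract("chr1", "P1", 201, 301, 2, 1, 2)
        resolve_coordinates(tract, calls, 10_000)
        assert tract.avg_start == 150  # floor((100 + 201) / 2)

    def test_marker_beyond_chromosome_raises(self):
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 200],
             "state": np.array([HOM_P1, HOM_P1], dtype=np.int8)}
        )
        tract = LohTract("chr1", "P1", 100, 200, 2, 0, 1)
        with pytest.raises(ValueError, match="length"):
            resolve_coordinates(tract, calls, 150)


class TestClassifyTract:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (5_000, 15_000, TERMINAL),  # intersects first 20 kb
            (20_001, 30_000, INTERSTITIAL),  # window boundary is exclusive
            (190_000, 195_000, TERMINAL),  # intersects last 20 kb
            (100_000, 181_000, TERMINAL),  # reaches into the right window
            (20_000, 30_000, TERMINAL),  # touches the boundary base
        ],
    )
    def test_window_intersection(self, start, end, expected):
        tract = make_tract(start, end)
        tract.avg_start, tract.avg_end = start, end
        assert classify_tract(tract, 200_000, terminal_window=20_000) == expected


class TestCallLoh:
    def test_all_het_line_yields_nothing(self, small_genome):
        calls = {"L1": calls_from_string("H" * 50), "L2": calls_from_string("H" * 50)}
        results = call_loh(calls, small_genome)
        assert all(r.n_events == 0 and r.bp_under_loh == 0 for r in results.values())

    def test_fully_homozygous_line_is_one_terminal_tract_per_chromosome(self, small_genome):
        per_chrom = []
        for chrom, length in small_genome.chromosomes:
            per_chrom.append(calls_from_string("1" * 40, chrom=chrom, spacing=length // 50))
        line = pd.concat(per_chrom, ignore_index=True)
        lines = {"L1": line}
        for i in range(2, 5):  # heterozygous companions keep the tract private
            hetline = line.copy()
            hetline["state"] = np.int8(HET)
            lines[f"L{i}"] = hetline
        results = call_loh(lines, small_genome)
        tracts = results["L1"].tracts
        assert len(tracts) == len(small_genome.chromosomes)
        for t in tracts:
            assert t.type == TERMINAL
            assert t.avg_start == 1
            assert t.avg_end == small_genome.lengths[t.chrom]

    def test_tracts_are_disjoint_per_chromosome(self, small_genome):
        rng = np.random.default_rng(12)
        lines = {}
        for li in range(4):
            states = rng.choice([HET, HOM_P1, HOM_P2, MISSING], size=120,
                                p=[0.5, 0.2, 0.2, 0.1])
            calls = calls_from_string("H" * 120, spacing=1500)
            calls["state"] = states.astype(np.int8)
            lines[f"L{li}"] = calls
        results = call_loh(lines, small_genome)
        for lc in results.values():
            spans = sorted((t.avg_start, t.avg_end) for t in lc.tracts)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
            for t in lc.tracts:
                assert t.n_markers >= 2
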