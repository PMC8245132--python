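"""Simulation benchmarks: planted-event and mutation recovery, study replica.

These are the package's validation workloads.  The recovery benchmarks
simulate noise-free lines on a scaled-down 16-chromosome toy karyotype,
run the real calling pipeline, and score it against the ground-truth log.

Scoring conventions (documented in the methods note):

* The oracle is the ground truth's *realized final state* — later planted
  events overwrite earlier ones, so the recoverable objects are the maximal
  final-state segments, restricted to segments spanning at least two markers
  (the caller's support threshold; a segment spanning fewer markers is
  undetectable by construction).  Adjacent same-origin truth segments whose
  separating gap contains fewer than two markers are likewise fused before
  scoring: a disruption unsupported by two heterozygous sites is invisible
  at the given marker density, by the calling rules themselves.
* A truth segment counts as recovered when a called tract of the same line,
  chromosome and parental origin matches it with reciprocal overlap >= 0.9.
  Truth segments are compared on their marker-resolvable span (midpoints to
  the flanking markers, exactly the boundary convention the caller reports),
  since marker density bounds the attainable boundary resolution.
* Mutation recovery feeds the homozygous-in-LOH filter with the ground-truth
  tract set, isolating the mutation pipeline from caller boundary rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .loh_caller import INTERSTITIAL, TERMINAL, LohConfig, call_loh, tracts_frame
from .mutations import call_mutations
from .rates_stats import LineResult, line_results_frame
from .reference import R64_CHROMOSOMES, STUDY_DESIGN, marker_density_per_kb
from .simulate import Genome, SimConfig, place_markers, simulate_lineage

#: 1 Mb toy karyotype: 16 chromosomes of 62.5 kb (yeast karyotype at 1/12 scale).
TOY_GENOME = Genome(tuple((f"chr{i + 1}", 62_500) for i in range(16)))

#: Terminal window scaled with the toy chromosomes (20 kb is meaningful only
#: relative to full-length chromosomes).
TOY_TERMINAL_WINDOW = 2_000


def toy_loh_config(seed: int = 0, n_lines: int = 20) -> SimConfig:
    """Noise-free toy conditions for planted-LOH recovery."""
    return SimConfig(
        seed=seed,
        n_lines=n_lines,
        n_bottlenecks=100,
        divisions_per_bottleneck=20.0,  # D = 2000
        marker_density=5.0,
        i_loh_rate=5e-2,
        t_loh_rate=5e-3,
        i_loh_mean_len=2000.0,
        snm_rate=0.0,
        missing_rate=0.0,
        gq_range=(99, 99),
        dp_range=(50, 50),
    )


def toy_mutation_config(seed: int = 0, n_lines: int = 10) -> SimConfig:
    """Noise-free toy conditions for mutation recovery (planted Ts/Tv 2:1)."""
    return replace(
        toy_loh_config(seed=seed, n_lines=n_lines),
        snm_rate=1e-7,
        ts_tv_bias=2.0,
    )


def _resolvable_span(
    positions: np.ndarray, start: int, end: int, chrom_length: int
) -> tuple[int, int, int] | None:
    """Marker-resolvable span of a truth segment, or None if < 2 markers.

    Returns (resolved_start, resolved_end, n_markers) using the same midpoint
    and chromosome-end conventions as the caller.
    """
    lo = int(np.searchsorted(positions, start, side="left"))
    hi = int(np.searchsorted(positions, end, side="right")) - 1
    n = hi - lo + 1
    if n < 2:
        return None
    first_in, last_in = int(positions[lo]), int(positions[hi])
    res_start = 1 if lo == 0 else (int(positions[lo - 1]) + first_in) // 2
    res_end = chrom_length if hi == len(positions) - 1 else (last_in + int(positions[hi + 1])) // 2
    return res_start, res_end, n


def _detectable_truth_segments(
    segments: pd.DataFrame, positions: np.ndarray, chrom_length: int
) -> list[tuple[int, int, str, tuple[int, int]]]:
    """Fuse marker-invisible disruptions, drop sub-2-marker segments.

    Returns (start, end, origin, resolvable_span) per detectable truth
    segment of one chromosome, in positional order.
    """
    fused: list[list] = []
    for seg in segments.itertuples(index=False):
        if fused and fused[-1][2] == seg.origin:
            gap_markers = int(
                np.searchsorted(positions, seg.start, side="left")
                - np.searchsorted(positions, fused[-1][1], side="right")
            )
            if gap_markers < 2:
                fused[-1][1] = seg.end
                continue
        fused.append([seg.start, seg.end, seg.origin])
    out = []
    for start, end, origin in fused:
        span = _resolvable_span(positions, start, end, chrom_length)
        if span is None:
            continue
        out.append((start, end, origin, span[:2]))
    return out


def _reciprocal(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


@dataclass
class LohRecoveryReport:
    n_truth_segments: int  # detectable (>= 2 markers) realized segments
    n_recovered: int
    recovery_frac: float
    n_truth_terminal: int
    n_terminal_matched: int  # terminal truth segments with a matched call
    n_terminal_correct: int
    terminal_accuracy: float  # correct / matched (classification accuracy)
    called_event_rate: float  # events per division, mean over lines
    truth_event_rate: float  # detectable realized segments per division
    called_i_rate: float
    truth_i_rate: float
    called_t_rate: float
    truth_t_rate: float
    mean_called_i_size: float
    mean_truth_i_size: float  # true bp size of detectable interstitial segments
    planted_event_rate: float  # configured i+t intensity, for reference
    results: dict


def loh_recovery_benchmark(
    seed: int = 0,
    n_lines: int = 20,
    genome: Genome = TOY_GENOME,
    terminal_window: int = TOY_TERMINAL_WINDOW,
) -> LohRecoveryReport:
    """Plant LOH events, run the caller, and score recovery against the truth."""
    config = toy_loh_config(seed=seed, n_lines=n_lines)
    markers = place_markers(genome, config.marker_density, config.seed)
    sim = simulate_lineage(genome, markers, config)
    loh_cfg = LohConfig(terminal_window=terminal_window)
    results = call_loh(sim.calls, genome, loh_cfg)

    lengths = genome.lengths
    pos_by_chrom = {
        chrom: sub["pos"].to_numpy()
        for chrom, sub in markers.groupby("chrom", sort=False)
    }
    D = config.divisions

    n_truth = n_rec = n_term = n_term_matched = n_term_ok = 0
    truth_i = truth_t = called_i = called_t = 0
    truth_i_sizes: list[int] = []
    called_i_sizes: list[float] = []
    for line, lc in results.items():
        all_segs = sim.truth.realized_segments(line)
        called = [
            ((t.avg_start, t.avg_end), t.origin, t.chrom, t.type) for t in lc.tracts
        ]
        called_i += lc.n_interstitial
        called_t += lc.n_terminal
        called_i_sizes.extend(t.size for t in lc.tracts if t.type == INTERSTITIAL)
        for chrom, segs in all_segs.groupby("chrom", sort=False):
            positions = pos_by_chrom.get(chrom, np.array([], dtype=np.int64))
            L = lengths[chrom]
            for start, end, origin, span in _detectable_truth_segments(segs, positions, L):
                n_truth += 1
                is_terminal = start <= terminal_window or end >= L - terminal_window + 1
                if is_terminal:
                    n_term += 1
                    truth_t += 1
                else:
                    truth_i += 1
                    truth_i_sizes.append(end - start + 1)
                best = None
                for c_span, c_origin, c_chrom, c_type in called:
                    if c_chrom != chrom or c_origin != origin:
                        continue
                    if _reciprocal(span, c_span) >= 0.9:
                        best = c_type
                        break
                if best is not None:
                    n_rec += 1
                    if is_terminal:
                        n_term_matched += 1
                        n_term_ok += best == TERMINAL

    total_D = D * len(results)
    return LohRecoveryReport(
        n_truth_segments=n_truth,
        n_recovered=n_rec,
        recovery_frac=n_rec / n_truth if n_truth else float("nan"),
        n_truth_terminal=n_term,
        n_terminal_matched=n_term_matched,
        n_terminal_correct=n_term_ok,
        terminal_accuracy=n_term_ok / n_term_matched if n_term_matched else float("nan"),
        called_event_rate=(called_i + called_t) / total_D,
        truth_event_rate=n_truth / total_D,
        called_i_rate=called_i / total_D,
        truth_i_rate=truth_i / total_D,
        called_t_rate=called_t / total_D,
        truth_t_rate=truth_t / total_D,
        mean_called_i_size=float(np.mean(called_i_sizes)) if called_i_sizes else float("nan"),
        mean_truth_i_size=float(np.mean(truth_i_sizes)) if truth_i_sizes else float("nan"),
        planted_event_rate=config.i_loh_rate + config.t_loh_rate,
        results=results,
    )


@dataclass
class MutationRecoveryReport:
    n_truth: int  # detectable truth mutations (line-private survivors, het)
    n_called: int
    precision: float
    recall: float
    estimated_rate: float  # homozygous-doubled, per haploid site per division
    planted_rate: float
    ts_tv: float
    planted_ts_tv: float
    n_spectrum: int


def mutation_recovery_benchmark(
    seed: int = 0,
    n_lines: int = 10,
    genome: Genome = TOY_GENOME,
) -> MutationRecoveryReport:
    """Plant mutations, run detection with ground-truth LOH tracts, score it."""
    from .mutations import mutation_spectrum

    config = toy_mutation_config(seed=seed, n_lines=n_lines)
    markers = place_markers(genome, config.marker_density, config.seed)
    sim = simulate_lineage(genome, markers, config)

    # ground-truth tract spans stand in for called LOH in the overlap filter
    truth_tracts = {
        line: sim.truth.realized_segments(line).rename(
            columns={"start": "avg_start", "end": "avg_end"}
        )
        for line in sim.calls
    }
    called = call_mutations(sim.variants, markers, truth_tracts, min_depth=10)

    private = sim.truth.private_mutations()
    truth_keys = set()
    for line, muts in private.items():
        for m in muts:
            if m.zygosity == "HOM":
                continue  # homozygous mutations sit inside LOH and are filtered
            truth_keys.add((line, m.chrom, m.pos))
    called_keys = set(zip(called["line"], called["chrom"], called["pos"]))

    tp = len(called_keys & truth_keys)
    precision = tp / len(called_keys) if called_keys else float("nan")
    recall = tp / len(truth_keys) if truth_keys else float("nan")

    D = config.divisions
    G = genome.total_length
    snms = called[called["mnm_id"].isna()]
    n_het = int(snms["zygosity"].eq("HET").sum())
    n_hom = int(snms["zygosity"].eq("HOM").sum())
    est_rate = (n_het + 2 * n_hom) / (D * 2 * G * n_lines)

    spectrum = mutation_spectrum(called)
    return MutationRecoveryReport(
        n_truth=len(truth_keys),
        n_called=len(called_keys),
        precision=precision,
        recall=recall,
        estimated_rate=est_rate,
        planted_rate=config.snm_rate,
        ts_tv=spectrum.ts_tv,
        planted_ts_tv=config.ts_tv_bias,
        n_spectrum=spectrum.n_snm,
    )


def study_replica(
    seed: int = 0,
    scale: int = 8,
    lines_cap: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the nine-hybrid MA design at 1/``scale`` genome size.

    Each hybrid keeps its own marker density (ancestral heterozygous sites /
    genome), line count, and division total from the study design.  The
    genome-wide event intensities are extensive in DNA content, so they are
    divided by ``scale`` to preserve the study's areal event density; the
    aggregate event rates are also reported rescaled back to full-genome
    equivalents.  Returns the per-line summary frame and a dict of aggregate
    quantities.
    """
    genome = Genome(
        tuple((name, max(length // scale, 1)) for name, length in R64_CHROMOSOMES)
    )
    window = max(20_000 // scale, 1)
    all_results: list[LineResult] = []
    for idx, row in STUDY_DESIGN.iterrows():
        n_lines = int(row["n_lines"] if lines_cap is None else min(lines_cap, row["n_lines"]))
        config = SimConfig(
            seed=seed + idx,
            n_lines=n_lines,
            n_bottlenecks=int(row["n_bottlenecks"]),
            divisions_per_bottleneck=row["divisions"] / row["n_bottlenecks"],
            marker_density=marker_density_per_kb(int(row["het_positions"])),
        )
        config.i_loh_rate /= scale
        config.t_loh_rate /= scale
        markers = place_markers(genome, config.marker_density, config.seed)
        sim = simulate_lineage(genome, markers, config)
        results = call_loh(sim.calls, genome, LohConfig(terminal_window=window))
        for line, lc in sorted(results.items()):
            all_results.append(
                LineResult(
                    line=f"{row['hybrid']}-{line}",
                    hybrid=row["hybrid"],
                    divisions=float(config.divisions),
                    genome_size=genome.total_length,
                    call=lc,
                )
            )
    summary = line_results_frame(all_results)
    aggregates = {
        "n_lines": len(summary),
        "n_events": int(summary["n_events"].sum()),
        "pct_interstitial": 100.0 * summary["n_interstitial"].sum() / summary["n_events"].sum(),
        "pct_terminal": 100.0 * summary["n_terminal"].sum() / summary["n_events"].sum(),
        "mean_pct_genome_under_loh": 100.0 * summary["genome_fraction"].mean(),
        "site_rate": summary["site_rate"].mean(),
        "event_rate": summary["event_rate"].mean(),
        "i_event_rate": summary["i_event_rate"].mean(),
        "t_event_rate": summary["t_event_rate"].mean(),
        "event_rate_genome_equiv": summary["event_rate"].mean() * scale,
        "i_event_rate_genome_equiv": summary["i_event_rate"].mean() * scale,
        "t_event_rate_genome_equiv": summary["t_event_rate"].mean() * scale,
    }
    return summary, aggregates
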