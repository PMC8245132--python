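"""LOH tract calling from tagged marker sequences.

The caller walks each line's ordered marker calls per chromosome and

1. segments maximal runs of identically-tagged markers (MISSING calls are
   transparent: they neither extend nor interrupt a run);
2. drops single-marker runs and merges consecutive same-origin tracts whose
   interruption is supported by fewer than two heterozygous calls, iterating
   to a fixed point;
3. removes tracts shared across lines of one hybrid (reciprocal overlap >= 80%
   of both spans in >= 50% of lines) — these are ancestral homozygous blocks,
   not de novo events;
4. resolves base-pair boundaries as the floor of the midpoint between the
   tract's outermost converted marker and the nearest flanking non-missing
   marker (chromosome ends when no flanking marker exists), so tract size is
   the distance between the midpoints of the closest unconverted sites;
5. tags a tract terminal when its resolved span intersects the first or last
   ``terminal_window`` (default 20 kb) of its chromosome, interstitial
   otherwise.

Every emitted tract is supported by at least two converted markers.
Coordinates are 1-based inclusive throughout; only BED export converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import HET, HOM_P1, HOM_P2, MISSING
from .simulate import Genome

logger = logging.getLogger(__name__)

INTERSTITIAL = "INTERSTITIAL"
TERMINAL = "TERMINAL"

_ORIGIN_LABEL = {HOM_P1: "P1", HOM_P2: "P2"}


@dataclass
class LohTract:
    chrom: str
    origin: str  # "P1" | "P2"
    first_marker_pos: int
    last_marker_pos: int
    n_markers: int
    first_idx: int = -1  # indices into the per-chromosome call table
    last_idx: int = -1
    avg_start: int | None = None
    avg_end: int | None = None
    type: str | None = None

    @property
    def size(self) -> int | None:
        if self.avg_start is None or self.avg_end is None:
            return None
        return self.avg_end - self.avg_start


@dataclass
class LohConfig:
    min_gq: int = 20
    min_markers: int = 2
    terminal_window: int = 20_000
    shared_overlap: float = 0.8
    shared_lines: float = 0.5
    reciprocal_shared_overlap: bool = True

    def validate(self) -> None:
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2 (two-site support threshold)")
        if not (0 < self.shared_overlap <= 1) or not (0 < self.shared_lines <= 1):
            raise ValueError("shared_overlap and shared_lines must be in (0, 1]")
        if self.terminal_window < 0:
            raise ValueError("terminal_window must be >= 0")


@dataclass
class LineCall:
    """Called tracts and summary metrics for one line."""

    line: str
    tracts: list[LohTract] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.tracts)

    @property
    def n_interstitial(self) -> int:
        return sum(1 for t in self.tracts if t.type == INTERSTITIAL)

    @property
    def n_terminal(self) -> int:
        return sum(1 for t in self.tracts if t.type == TERMINAL)

    @property
    def bp_under_loh(self) -> int:
        return int(sum(t.size for t in self.tracts))

    def bp_by_type(self, kind: str) -> int:
        return int(sum(t.size for t in self.tracts if t.type == kind))

    def bp_by_origin(self, origin: str) -> int:
        return int(sum(t.size for t in self.tracts if t.origin == origin))

    def mean_size(self, kind: str | None = None) -> float:
        sizes = [t.size for t in self.tracts if kind is None or t.type == kind]
        return float(np.mean(sizes)) if sizes else float("nan")


def segment_tracts(calls: pd.DataFrame) -> list[LohTract]:
    """Maximal runs of consecutive same-tag non-missing markers, one chromosome.

    MISSING markers are transparent.  Only homozygous (HOM_P1/HOM_P2) runs are
    returned, as raw tracts with marker counts and positions.
    """
    states = calls["state"].to_numpy()
    pos = calls["pos"].to_numpy()
    if len(calls) and calls["chrom"].nunique() > 1:
        raise ValueError("segment_tracts expects calls from a single chromosome")
    chrom = str(calls["chrom"].iloc[0]) if len(calls) else ""

    tracts: list[LohTract] = []
    cur_state = None
    cur: LohTract | None = None
    for i in range(len(states)):
        s = states[i]
        if s == MISSING:
            continue
        if s == cur_state and cur is not None:
            cur.last_marker_pos = int(pos[i])
            cur.last_idx = i
            cur.n_markers += 1
            continue
        if cur is not None and cur_state in _ORIGIN_LABEL:
            tracts.append(cur)
        cur_state = s
        if s in _ORIGIN_LABEL:
            cur = LohTract(chrom, _ORIGIN_LABEL[s], int(pos[i]), int(pos[i]), 1, i, i)
        else:
            cur = None
    if cur is not None and cur_state in _ORIGIN_LABEL:
        tracts.append(cur)
    return tracts


def filter_and_merge(
    raw_tracts: list[LohTract],
    calls: pd.DataFrame,
    min_markers: int = 2,
) -> list[LohTract]:
    """Drop sub-threshold tracts, then merge weakly-interrupted same-origin pairs.

    Single-marker (more generally < ``min_markers``) tracts are removed first.
    Consecutive surviving tracts of the same origin separated by fewer than
    two intervening HET calls are merged — a disruption not supported by two
    heterozygous sites is not believed.  Merging repeats until stable.  The
    merged tract spans both parts plus the interruption, but only converted
    markers count toward ``n_markers``.
    """
    states = calls["state"].to_numpy()
    het_cum = np.concatenate([[0], np.cumsum(states == HET)])

    def hets_between(a: LohTract, b: LohTract) -> int:
        return int(het_cum[b.first_idx] - het_cum[a.last_idx + 1])

    tracts = [replace(t) for t in raw_tracts if t.n_markers >= min_markers]
    changed = True
    while changed:
        changed = False
        merged: list[LohTract] = []
        for t in tracts:
            prev = merged[-1] if merged else None
            if (
                prev is not None
                and prev.origin == t.origin
                and hets_between(prev, t) < 2
            ):
                prev.last_marker_pos = t.last_marker_pos
                prev.last_idx = t.last_idx
                prev.n_markers += t.n_markers
                changed = True
            else:
                merged.append(t)
        tracts = merged
    return tracts


def _reciprocal_overlap(a: LohTract, b: LohTract, reciprocal: bool = True) -> float:
    """Overlap fraction between two marker spans.

    Spans are taken inclusive on marker coordinates.  With ``reciprocal`` the
    returned fraction is the smaller of the two per-span fractions; otherwise
    the larger (one-sided reading).
    """
    lo = max(a.first_marker_pos, b.first_marker_pos)
    hi = min(a.last_marker_pos, b.last_marker_pos)
    ov = max(0, hi - lo + 1)
    fa = ov / (a.last_marker_pos - a.first_marker_pos + 1)
    fb = ov / (b.last_marker_pos - b.first_marker_pos + 1)
    return min(fa, fb) if reciprocal else max(fa, fb)


def exclude_shared(
    tracts_by_line: dict[str, list[LohTract]],
    overlap_frac: float = 0.8,
    line_frac: float = 0.5,
    reciprocal: bool = True,
) -> dict[str, list[LohTract]]:
    """Remove tracts shared across lines of one hybrid (ancestral homozygosity).

    A tract is removed when tracts of the same chromosome and origin with
    reciprocal overlap >= ``overlap_frac`` exist in >= ``line_frac`` of the
    hybrid's lines (the tract's own line included).  Decisions are taken on
    the pre-removal tract sets.
    """
    n_lines = len(tracts_by_line)
    if n_lines < 2:
        logger.warning("shared-tract exclusion skipped: fewer than two lines")
        return {line: list(ts) for line, ts in tracts_by_line.items()}

    lines = list(tracts_by_line)
    out: dict[str, list[LohTract]] = {}
    for line in lines:
        kept = []
        for t in tracts_by_line[line]:
            support = 0
            for other in lines:
                hit = any(
                    o.chrom == t.chrom
                    and o.origin == t.origin
                    and _reciprocal_overlap(t, o, reciprocal) >= overlap_frac
                    for o in tracts_by_line[other]
                )
                support += hit
            if support / n_lines < line_frac:
                kept.append(t)
        out[line] = kept
    return out


def resolve_coordinates(
    tract: LohTract,
    calls: pd.DataFrame,
    chrom_length: int,
) -> LohTract:
    """Resolve base-pair boundaries from flanking non-missing markers.

    ``avg_start`` is the floored midpoint between the nearest non-missing
    marker upstream of the tract and the tract's first marker (1 when no such
    marker exists); ``avg_end`` symmetrically downstream (``chrom_length`` at
    the chromosome end).
    """
    states = calls["state"].to_numpy()
    pos = calls["pos"].to_numpy()
    if len(pos) and pos[-1] > chrom_length:
        raise ValueError(
            f"marker at {pos[-1]} beyond chromosome length {chrom_length}"
        )
    if tract.last_marker_pos > chrom_length:
        raise ValueError("tract extends beyond chromosome length")

    prev = None
    for i in range(tract.first_idx - 1, -1, -1):
        if states[i] != MISSING:
            prev = int(pos[i])
            break
    nxt = None
    for i in range(tract.last_idx + 1, len(states)):
        if states[i] != MISSING:
            nxt = int(pos[i])
            break

    tract.avg_start = 1 if prev is None else (prev + tract.first_marker_pos) // 2
    tract.avg_end = chrom_length if nxt is None else (tract.last_marker_pos + nxt) // 2
    return tract


def classify_tract(tract: LohTract, chrom_length: int, terminal_window: int = 20_000) -> str:
    """TERMINAL if the resolved span intersects either ``terminal_window`` end."""
    if tract.avg_start is None or tract.avg_end is None:
        raise ValueError("resolve coordinates before classification")
    left_end = terminal_window
    right_start = chrom_length - terminal_window + 1
    if tract.avg_start <= left_end or tract.avg_end >= right_start:
        tract.type = TERMINAL
    else:
        tract.type = INTERSTITIAL
    return tract.type


def call_chromosome(
    calls: pd.DataFrame,
    chrom_length: int,
    config: LohConfig,
) -> list[LohTract]:
    """Segment + filter/merge for one line and chromosome (no shared exclusion)."""
    raw = segment_tracts(calls)
    return filter_and_merge(raw, calls, config.min_markers)


def call_loh(
    calls_by_line: dict[str, pd.DataFrame],
    genome: Genome,
    config: LohConfig | None = None,
) -> dict[str, LineCall]:
    """Full LOH calling across the lines of one hybrid.

    ``calls_by_line`` maps line id to a tagged call table (columns chrom, pos,
    state, gq, ...).  The GQ filter is applied, tracts are segmented, merged,
    cross-line shared tracts removed, coordinates resolved and types assigned.
    """
    from .markers import apply_gq_filter

    config = config or LohConfig()
    config.validate()
    lengths = genome.lengths

    per_line_chrom: dict[str, dict[str, pd.DataFrame]] = {}
    tracts_by_line: dict[str, list[LohTract]] = {}
    for line, calls in calls_by_line.items():
        calls = apply_gq_filter(calls, config.min_gq)
        per_chrom = {
            str(chrom): sub.reset_index(drop=True)
            for chrom, sub in calls.groupby("chrom", sort=False)
        }
        per_line_chrom[line] = per_chrom
        tracts: list[LohTract] = []
        for chrom in genome.names:
            sub = per_chrom.get(chrom)
            if sub is None or not len(sub):
                continue
            tracts.extend(call_chromosome(sub, lengths[chrom], config))
        tracts_by_line[line] = tracts

    tracts_by_line = exclude_shared(
        tracts_by_line,
        config.shared_overlap,
        config.shared_lines,
        config.reciprocal_shared_overlap,
    )

    results: dict[str, LineCall] = {}
    for line, tracts in tracts_by_line.items():
        for t in tracts:
            sub = per_line_chrom[line][t.chrom]
            resolve_coordinates(t, sub, lengths[t.chrom])
            classify_tract(t, lengths[t.chrom], config.terminal_window)
        results[line] = LineCall(line=line, tracts=tracts)
    return results


def tracts_frame(results: dict[str, LineCall]) -> pd.DataFrame:
    """Flatten called tracts into a tidy frame (1-based inclusive coordinates)."""
    rows = [
        {
            "line": lc.line,
            "chrom": t.chrom,
            "avg_start": t.avg_start,
            "avg_end": t.avg_end,
            "size": t.size,
            "origin": t.origin,
            "type": t.type,
            "n_markers": t.n_markers,
            "first_marker_pos": t.first_marker_pos,
            "last_marker_pos": t.last_marker_pos,
        }
        for lc in results.values()
        for t in lc.tracts
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "line", "chrom", "avg_start", "avg_end", "size", "origin",
            "type", "n_markers", "first_marker_pos", "last_marker_pos",
        ],
    )
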