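"""Division accounting, LOH and mutation rates, and cross-line statistics.

Rates follow the MA-experiment conventions: with N_sites the base pairs under
LOH, D the total mitotic divisions of a line and G the genome size,

* LOH site rate  = N_sites / (D x G)    per site per division,
* LOH event rate = n_events / D         events per division,

each also restricted to the interstitial/terminal subsets.  Mutation rates
use the diploid genome (2G) and double homozygous mutations, so

* SNM rate = (n_het + 2 x n_hom) / (D x 2G)  per site per division,

with the analogous MNM event rate; unweighted variants are reported too.
Divisions derive from exponential growth, N = e^(r t): generation time
g = ln2 / r, hence (hours per bottleneck) x r / ln2 divisions per bottleneck.

The identity site_rate x D = genome_fraction holds exactly for every line
(both sides are N_sites / G) and is asserted in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .loh_caller import INTERSTITIAL, TERMINAL, LineCall
from .simulate import Genome

logger = logging.getLogger(__name__)

LOW = "LOW"
MID = "MID"
NEARLY_HOMOZYGOUS = "NEARLY_HOMOZYGOUS"


@dataclass
class GrowthRecord:
    """Per-line exponential growth: rate r per hour, generation time g = ln2/r."""

    line: str
    r: float  # growth rate per hour
    hours_per_bottleneck: float = 48.0

    @property
    def g(self) -> float:
        return math.log(2) / self.r


def estimate_divisions(growth: GrowthRecord, n_bottlenecks: int) -> tuple[float, float]:
    """(divisions per bottleneck, total divisions D) from a growth record."""
    if growth.r <= 0:
        raise ValueError("growth rate r must be > 0")
    per_bottleneck = growth.hours_per_bottleneck * growth.r / math.log(2)
    return per_bottleneck, n_bottlenecks * per_bottleneck


@dataclass
class LohRates:
    site_rate: float
    event_rate: float
    i_site_rate: float
    i_event_rate: float
    t_site_rate: float
    t_event_rate: float


def loh_rates(line_call: LineCall, divisions: float, genome_size: float) -> LohRates:
    """Per-line LOH rates; N/(D x G) for sites, N/D for events."""
    if divisions <= 0:
        raise ValueError("divisions must be > 0")
    if genome_size <= 0:
        raise ValueError("genome size must be > 0")
    D, G = float(divisions), float(genome_size)
    return LohRates(
        site_rate=line_call.bp_under_loh / (D * G),
        event_rate=line_call.n_events / D,
        i_site_rate=line_call.bp_by_type(INTERSTITIAL) / (D * G),
        i_event_rate=line_call.n_interstitial / D,
        t_site_rate=line_call.bp_by_type(TERMINAL) / (D * G),
        t_event_rate=line_call.n_terminal / D,
    )


@dataclass
class MutationRates:
    snm_rate: float  # homozygous-doubled, per site per division
    mnm_rate: float
    snm_rate_unweighted: float
    mnm_rate_unweighted: float


def mutation_rates(
    n_het_snm: int,
    n_hom_snm: int,
    divisions: float,
    genome_size: float,
    n_het_mnm: int = 0,
    n_hom_mnm: int = 0,
) -> MutationRates:
    """Mutation rates over the diploid genome, homozygous events doubled."""
    if divisions <= 0 or genome_size <= 0:
        raise ValueError("divisions and genome size must be > 0")
    denom = divisions * 2.0 * genome_size
    return MutationRates(
        snm_rate=(n_het_snm + 2 * n_hom_snm) / denom,
        mnm_rate=(n_het_mnm + 2 * n_hom_mnm) / denom,
        snm_rate_unweighted=(n_het_snm + n_hom_snm) / denom,
        mnm_rate_unweighted=(n_het_mnm + n_hom_mnm) / denom,
    )


def classify_line(genome_fraction: float, thresholds: tuple[float, float] = (0.10, 0.85)) -> str:
    """Group a line by its genome fraction under LOH."""
    if not (0 <= genome_fraction <= 1):
        raise ValueError("genome_fraction must be in [0, 1]")
    low, high = thresholds
    if genome_fraction > high:
        return NEARLY_HOMOZYGOUS
    if genome_fraction < low:
        return LOW
    return MID


def parental_bias_test(bp_p1: float, bp_p2: float) -> float:
    """Two-sided exact binomial test of equal fixation of the two parents.

    Operates on base pairs under LOH by default; pass event counts for the
    event-level variant.  Returns NaN when there is nothing under LOH.
    """
    k1, k2 = int(round(bp_p1)), int(round(bp_p2))
    if k1 + k2 == 0:
        return float("nan")
    return float(stats.binomtest(k1, k1 + k2, 0.5, alternative="two-sided").pvalue)


@dataclass
class LineResult:
    """Per-line summary joining tracts, mutations and division accounting."""

    line: str
    hybrid: str
    divisions: float
    genome_size: float
    call: LineCall
    n_het_snm: int = 0
    n_hom_snm: int = 0
    n_het_mnm: int = 0
    n_hom_mnm: int = 0
    group: str = field(init=False)

    def __post_init__(self) -> None:
        if self.call.bp_under_loh > self.genome_size:
            raise ValueError("bp under LOH exceeds genome size")
        self.group = classify_line(self.genome_fraction)

    @property
    def bp_under_loh(self) -> int:
        return self.call.bp_under_loh

    @property
    def genome_fraction(self) -> float:
        return self.bp_under_loh / self.genome_size

    @property
    def loh(self) -> LohRates:
        return loh_rates(self.call, self.divisions, self.genome_size)

    @property
    def snm(self) -> MutationRates:
        return mutation_rates(
            self.n_het_snm, self.n_hom_snm, self.divisions, self.genome_size,
            self.n_het_mnm, self.n_hom_mnm,
        )


def line_results_frame(results: list[LineResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        loh = r.loh
        snm = r.snm
        rows.append(
            {
                "line": r.line,
                "hybrid": r.hybrid,
                "divisions": r.divisions,
                "n_events": r.call.n_events,
                "n_interstitial": r.call.n_interstitial,
                "n_terminal": r.call.n_terminal,
                "bp_under_loh": r.bp_under_loh,
                "genome_fraction": r.genome_fraction,
                "group": r.group,
                "site_rate": loh.site_rate,
                "event_rate": loh.event_rate,
                "i_event_rate": loh.i_event_rate,
                "t_event_rate": loh.t_event_rate,
                "mean_i_size": r.call.mean_size(INTERSTITIAL),
                "mean_t_size": r.call.mean_size(TERMINAL),
                "snm_rate": snm.snm_rate,
                "mnm_rate": snm.mnm_rate,
            }
        )
    return pd.DataFrame(rows)


def cross_line_stats(
    summary: pd.DataFrame,
    het_positions: dict[str, int] | None = None,
    fertility_group: dict[str, str] | None = None,
) -> dict:
    """Cross-line statistics over per-line summaries.

    ``summary`` is a ``line_results_frame`` output.  When ``het_positions``
    maps hybrid to its ancestral heterozygous-site count, Pearson correlations
    of heterozygosity against per-line terminal / interstitial / total event
    counts are computed.  Hybrids are compared with Kruskal-Wallis tests and,
    when ``fertility_group`` maps hybrid to a two-level grouping, the groups
    with two-sided Mann-Whitney U tests.  Degenerate inputs yield NaN entries
    with a warning.
    """
    out: dict[str, dict] = {}

    if het_positions is not None:
        het = summary["hybrid"].map(het_positions)
        for col, key in (
            ("n_terminal", "pearson_het_vs_t_loh"),
            ("n_interstitial", "pearson_het_vs_i_loh"),
            ("n_events", "pearson_het_vs_total"),
        ):
            x, y = het.to_numpy(float), summary[col].to_numpy(float)
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                logger.warning("degenerate input for %s", key)
                out[key] = {"r": float("nan"), "p": float("nan"), "n": len(x)}
            else:
                r, p = stats.pearsonr(x, y)
                out[key] = {"r": float(r), "p": float(p), "n": len(x)}

    for col, key in (
        ("n_events", "kruskal_events_by_hybrid"),
        ("genome_fraction", "kruskal_fraction_by_hybrid"),
    ):
        groups = [g[col].to_numpy(float) for _, g in summary.groupby("hybrid")]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            logger.warning("degenerate groups for %s", key)
            out[key] = {"stat": float("nan"), "p": float("nan"), "n": len(summary)}
        else:
            h, p = stats.kruskal(*groups)
            out[key] = {"stat": float(h), "p": float(p), "n": len(summary)}

    if fertility_group is not None:
        grp = summary["hybrid"].map(fertility_group)
        levels = sorted(set(grp.dropna()))
        for col, key in (
            ("n_events", "mannwhitney_events_by_fertility"),
            ("mean_i_size", "mannwhitney_i_size_by_fertility"),
        ):
            if len(levels) != 2:
                logger.warning("fertility grouping is not two-level")
                out[key] = {"stat": float("nan"), "p": float("nan"), "n": 0}
                continue
            a = summary.loc[grp == levels[0], col].dropna().to_numpy(float)
            b = summary.loc[grp == levels[1], col].dropna().to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                out[key] = {"stat": float("nan"), "p": float("nan"), "n": len(a) + len(b)}
                continue
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            out[key] = {"stat": float(u), "p": float(p), "n": len(a) + len(b)}

    return out
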