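"""Forward-in-time simulator of heterozygous diploid mutation-accumulation lines.

Each MA line is a single cell lineage: single-cell bottlenecks make exactly one
lineage ancestral to the sequenced clone, so a line reduces to one genome
undergoing ``D`` mitotic divisions.  Per division the lineage draws

* interstitial LOH events (gene-conversion proxy): Poisson with rate
  ``i_loh_rate`` per division; the chromosome is chosen proportionally to its
  length, the start uniformly, and the tract length from a geometric
  distribution with mean ``i_loh_mean_len``;
* terminal LOH events (crossover / break-induced-replication proxy): Poisson
  with rate ``t_loh_rate``; a breakpoint is placed uniformly on a
  length-weighted chromosome and the tract runs from the breakpoint to the
  nearer chromosome end;
* single-nucleotide mutations: Poisson with rate ``snm_rate`` per *haploid*
  site per division (2 x genome size sites), placed on one of the two
  homologues with a fair coin, transitions favoured over transversions with
  odds ``ts_tv_bias``.

Events overwrite earlier state: a heterozygous marker inside a tract becomes
homozygous for the tract's parental origin; a later tract over the same region
re-writes it.  A heterozygous mutation overwritten by a later LOH event either
fixes (homozygous) or is erased, depending on which homologue the conversion
copied.  The :class:`GroundTruth` log records every planted event and mutation
and can replay the exact final state, which is the oracle used by the recovery
tests.

Randomness: one root seed; stream ``i`` of ``numpy``'s ``default_rng([seed, i])``
drives line ``i`` (stream 0 places markers), so individual lines are
reproducible independently of how many are simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import HET, HOM_P1, HOM_P2, MISSING

BASES = np.array(["A", "C", "G", "T"])
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

INTERSTITIAL = "I"
TERMINAL = "T"


@dataclass(frozen=True)
class Genome:
    """An ordered set of named chromosomes with 1-based inclusive coordinates."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.chromosomes, columns=["chrom", "length"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Genome":
        return cls(tuple(zip(frame["chrom"].astype(str), frame["length"].astype(int))))


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults reproduce the conditions of the nine-hybrid MA experiment: 20
    lines per background, 75 bottlenecks of 24.2 divisions, and the observed
    genome-wide event rates (interstitial 5.6e-2 and terminal 9.2e-3 events
    per division, mutations 1.1e-10 per haploid site per division, Ts/Tv
    odds 1.35).  ``i_loh_mean_len`` defaults to 2 kb, the kb-scale of mitotic
    gene-conversion tracts.
    """

    seed: int = 0
    n_lines: int = 20
    n_bottlenecks: int = 75
    divisions_per_bottleneck: float = 24.2
    marker_density: float = 5.0  # markers per kb
    i_loh_rate: float = 5.6e-2  # events per division
    t_loh_rate: float = 9.2e-3  # events per division
    i_loh_mean_len: float = 2000.0  # bp
    snm_rate: float = 1.1e-10  # per haploid site per division
    ts_tv_bias: float = 1.35  # transition:transversion odds
    missing_rate: float = 0.02  # probability a marker call is dropped
    gq_range: tuple[int, int] = (10, 99)
    dp_range: tuple[int, int] = (30, 80)
    mutate_marker_sites: bool = False

    def validate(self) -> None:
        for name in ("i_loh_rate", "t_loh_rate", "snm_rate", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.marker_density <= 50):
            raise ValueError("marker_density must be in (0, 50] markers/kb")
        if self.divisions_per_bottleneck <= 0:
            raise ValueError("divisions_per_bottleneck must be > 0")
        if self.n_lines < 1 or self.n_bottlenecks < 1:
            raise ValueError("n_lines and n_bottlenecks must be >= 1")
        if self.i_loh_mean_len < 1:
            raise ValueError("i_loh_mean_len must be >= 1 bp")
        if self.ts_tv_bias < 0:
            raise ValueError("ts_tv_bias must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.gq_range
        if lo > hi or lo < 0:
            raise ValueError("gq_range must be (lo, hi) with 0 <= lo <= hi")

    @property
    def divisions(self) -> int:
        """Total divisions per line, D = bottlenecks x divisions/bottleneck."""
        return int(round(self.n_bottlenecks * self.divisions_per_bottleneck))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gq_range"] = list(self.gq_range)
        d["dp_range"] = list(self.dp_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("gq_range", "dp_range"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PlantedEvent:
    """One planted LOH event, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    origin: str  # "P1" | "P2"
    type: str  # INTERSTITIAL ("I") | TERMINAL ("T")
    division: float  # time of occurrence in (0, D)


@dataclass
class PlantedMutation:
    chrom: str
    pos: int
    ref: str
    alt: str
    haplotype: str  # homologue carrying the new allele, "P1" | "P2"
    division: float
    zygosity: str  # final state: "HET" | "HOM" | "LOST"


@dataclass
class LineTruth:
    line: str
    divisions: int
    events: list[PlantedEvent] = field(default_factory=list)
    mutations: list[PlantedMutation] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Planted-event log with replay helpers; the oracle for recovery tests."""

    genome: Genome
    lines: dict[str, LineTruth] = field(default_factory=dict)

    def realized_segments(self, line: str) -> pd.DataFrame:
        """Final homozygous segments after overwrite resolution.

        Returns one row per maximal run of constant parental origin in the
        final genome state (columns chrom, start, end, origin), i.e. what the
        planted events actually left behind once later events overwrote
        earlier ones.
        """
        truth = self.lines[line]
        rows: list[tuple[str, int, int, str]] = []
        lengths = self.genome.lengths
        for chrom in self.genome.names:
            events = [e for e in truth.events if e.chrom == chrom]
            if not events:
                continue
            bounds = sorted({1, lengths[chrom] + 1}
                            | {e.start for e in events}
                            | {e.end + 1 for e in events})
            order = sorted(range(len(events)), key=lambda i: events[i].division)
            seg: list[tuple[int, int, str | None]] = []
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                owner = None
                for i in order:  # later events overwrite earlier ones
                    e = events[i]
                    if e.start <= lo and e.end >= hi - 1:
                        owner = e.origin
                seg.append((lo, hi - 1, owner))
            # merge adjacent intervals of identical final origin
            for lo, hi, owner in seg:
                if owner is None:
                    continue
                if rows and rows[-1][0] == chrom and rows[-1][3] == owner and rows[-1][2] == lo - 1:
                    rows[-1] = (chrom, rows[-1][1], hi, owner)
                else:
                    rows.append((chrom, lo, hi, owner))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])

    def replay_states(self, line: str, markers: pd.DataFrame) -> np.ndarray:
        """Expected final marker states (HET / HOM_P1 / HOM_P2), ignoring noise."""
        states = np.full(len(markers), HET, dtype=np.int8)
        segments = self.realized_segments(line)
        pos = markers["pos"].to_numpy()
        for _, s in segments.iterrows():
            in_chrom = (markers["chrom"] == s["chrom"]).to_numpy()
            inside = in_chrom & (pos >= s["start"]) & (pos <= s["end"])
            states[inside] = HOM_P1 if s["origin"] == "P1" else HOM_P2
        return states

    def surviving_mutations(self, line: str) -> list[PlantedMutation]:
        return [m for m in self.lines[line].mutations if m.zygosity != "LOST"]

    def private_mutations(self) -> dict[str, list[PlantedMutation]]:
        """Surviving mutations unique to one line at their position.

        A site mutated in two lines is not line-exclusive and no private-
        variant caller can report it; such collisions are excluded from the
        detectable truth.
        """
        counts: dict[tuple[str, int], int] = {}
        for line, truth in self.lines.items():
            for m in truth.mutations:
                if m.zygosity == "LOST":
                    continue
                counts[(m.chrom, m.pos)] = counts.get((m.chrom, m.pos), 0) + 1
        out: dict[str, list[PlantedMutation]] = {}
        for line in self.lines:
            out[line] = [
                m
                for m in self.surviving_mutations(line)
                if counts[(m.chrom, m.pos)] == 1
            ]
        return out


@dataclass
class SimResult:
    genome: Genome
    markers: pd.DataFrame
    calls: dict[str, pd.DataFrame]  # per line, aligned to markers
    variants: dict[str, pd.DataFrame]  # per line, non-marker variant calls
    truth: GroundTruth
    config: SimConfig


def place_markers(genome: Genome, density: float, seed: int | np.random.Generator) -> pd.DataFrame:
    """Scatter heterozygous markers uniformly over the genome.

    Per chromosome the marker count is Poisson(length_kb x density) and
    positions are drawn uniformly without replacement; each marker gets two
    distinct parental alleles.  Returns a frame sorted by (chrom, pos) with
    columns chrom, pos, p1, p2.
    """
    if density <= 0:
        raise ValueError("marker density must be > 0")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng([seed, 0])
    frames = []
    for chrom, length in genome.chromosomes:
        n = rng.poisson(density / 1000.0 * length)
        if n > length:
            raise ValueError(
                f"density {density}/kb asks for {n} distinct positions on "
                f"{chrom} (length {length})"
            )
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        p1 = BASES[rng.integers(0, 4, size=n)]
        shift = rng.integers(1, 4, size=n)  # a different base, uniformly
        p2 = BASES[(np.searchsorted(BASES, p1) + shift) % 4]
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "p1": p1, "p2": p2}))
    markers = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "p1", "p2"]
    )
    markers["pos"] = markers["pos"].astype(np.int64)
    return markers


def _draw_events(rng: np.random.Generator, genome: Genome, config: SimConfig) -> list[PlantedEvent]:
    D = config.divisions
    names = genome.names
    lengths = np.array([genome.lengths[n] for n in names], dtype=float)
    weights = lengths / lengths.sum()
    events: list[PlantedEvent] = []

    n_i = rng.poisson(config.i_loh_rate * D)
    for _ in range(n_i):
        ci = rng.choice(len(names), p=weights)
        L = int(lengths[ci])
        start = int(rng.integers(1, L + 1))
        length = int(rng.geometric(min(1.0, 1.0 / config.i_loh_mean_len)))
        end = min(start + length - 1, L)
        events.append(
            PlantedEvent(names[ci], start, end, "P1" if rng.random() < 0.5 else "P2",
                         INTERSTITIAL, float(rng.uniform(0, D)))
        )
    n_t = rng.poisson(config.t_loh_rate * D)
    for _ in range(n_t):
        ci = rng.choice(len(names), p=weights)
        L = int(lengths[ci])
        b = int(rng.integers(1, L + 1))
        if b - 1 <= L - b:  # nearer the left end (ties break left)
            start, end = 1, b
        else:
            start, end = b, L
        events.append(
            PlantedEvent(names[ci], start, end, "P1" if rng.random() < 0.5 else "P2",
                         TERMINAL, float(rng.uniform(0, D)))
        )
    events.sort(key=lambda e: e.division)
    return events


def _draw_mutations(
    rng: np.random.Generator,
    genome: Genome,
    markers: pd.DataFrame,
    events: list[PlantedEvent],
    config: SimConfig,
) -> list[PlantedMutation]:
    D = config.divisions
    G = genome.total_length
    n_m = rng.poisson(config.snm_rate * 2 * G * D)
    if n_m == 0:
        return []
    # global 1-based coordinates over concatenated chromosomes
    names = genome.names
    lengths = np.array([genome.lengths[n] for n in names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    if config.mutate_marker_sites:
        taken = np.array([], dtype=np.int64)
    else:
        chrom_index = pd.Series(range(len(names)), index=names)
        taken = (offsets[chrom_index[markers["chrom"]].to_numpy()]
                 + markers["pos"].to_numpy())
    available = G - len(taken)
    if n_m > available:
        raise ValueError("more mutations requested than available sites")
    # rejection sampling of distinct non-marker global positions
    chosen: set[int] = set()
    taken_set = set(int(t) for t in taken)
    while len(chosen) < n_m:
        draw = rng.integers(1, G + 1, size=2 * (n_m - len(chosen)) + 8)
        for g in draw:
            g = int(g)
            if g in taken_set or g in chosen:
                continue
            chosen.add(g)
            if len(chosen) == n_m:
                break
    positions = sorted(chosen)

    p_ts = config.ts_tv_bias / (1.0 + config.ts_tv_bias)
    mutations: list[PlantedMutation] = []
    for g in positions:
        ci = int(np.searchsorted(offsets[1:], g, side="left"))
        pos = int(g - offsets[ci])
        chrom = names[ci]
        ref = str(BASES[rng.integers(0, 4)])
        if rng.random() < p_ts:
            alt = TRANSITION[ref]
        else:
            alt = TRANSVERSIONS[ref][rng.integers(0, 2)]
        hap = "P1" if rng.random() < 0.5 else "P2"
        t = float(rng.uniform(0, D))
        # first LOH event covering the site after the mutation decides its fate
        zyg = "HET"
        for e in sorted((e for e in events
                         if e.chrom == chrom and e.start <= pos <= e.end
                         and e.division > t),
                        key=lambda e: e.division)[:1]:
            zyg = "HOM" if e.origin == hap else "LOST"
        mutations.append(PlantedMutation(chrom, pos, ref, alt, hap, t, zyg))
    return mutations


def simulate_lineage(genome: Genome, markers: pd.DataFrame, config: SimConfig) -> SimResult:
    """Simulate all lines of one hybrid background.

    Returns per-line marker calls (aligned to ``markers``, with simulated GQ /
    DP and missingness), per-line non-marker variant calls carrying the new
    mutations, and the ground-truth log.
    """
    config.validate()
    D = config.divisions
    width = max(2, len(str(config.n_lines)))
    truth = GroundTruth(genome=genome)
    calls: dict[str, pd.DataFrame] = {}
    variants: dict[str, pd.DataFrame] = {}
    mpos = markers["pos"].to_numpy()
    mchrom = markers["chrom"].to_numpy()

    for i in range(config.n_lines):
        line = f"L{i + 1:0{width}d}"
        rng = np.random.default_rng([config.seed, i + 1])
        events = _draw_events(rng, genome, config)
        mutations = _draw_mutations(rng, genome, markers, events, config)
        truth.lines[line] = LineTruth(line, D, events, mutations)

        states = np.full(len(markers), HET, dtype=np.int8)
        for e in events:  # chronological; later events overwrite
            inside = (mchrom == e.chrom) & (mpos >= e.start) & (mpos <= e.end)
            states[inside] = HOM_P1 if e.origin == "P1" else HOM_P2

        gq = rng.integers(config.gq_range[0], config.gq_range[1] + 1,
                          size=len(markers)).astype(np.int16)
        dp = rng.integers(config.dp_range[0], config.dp_range[1] + 1,
                          size=len(markers)).astype(np.int16)
        if config.missing_rate > 0:
            drop = rng.random(len(markers)) < config.missing_rate
            states = states.copy()
            states[drop] = MISSING
        calls[line] = pd.DataFrame(
            {
                "chrom": mchrom,
                "pos": mpos,
                "p1": markers["p1"].to_numpy(),
                "p2": markers["p2"].to_numpy(),
                "state": states,
                "gq": gq,
                "dp": dp,
            }
        )

        surv = [m for m in mutations if m.zygosity != "LOST"]
        variants[line] = pd.DataFrame(
            {
                "chrom": [m.chrom for m in surv],
                "pos": np.array([m.pos for m in surv], dtype=np.int64),
                "ref": [m.ref for m in surv],
                "alt": [m.alt for m in surv],
                "zygosity": [m.zygosity for m in surv],
                "gq": rng.integers(config.gq_range[0], config.gq_range[1] + 1,
                                   size=len(surv)).astype(np.int16),
                "dp": rng.integers(config.dp_range[0], config.dp_range[1] + 1,
                                   size=len(surv)).astype(np.int16),
            }
        ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    return SimResult(genome, markers, calls, variants, truth, config)


def simulate(config: SimConfig, genome: Genome | None = None) -> SimResult:
    """Convenience wrapper: place markers then simulate every line."""
    if genome is None:
        from .reference import R64_CHROMOSOMES

        genome = Genome(R64_CHROMOSOMES)
    markers = place_markers(genome, config.marker_density, config.seed)
    return simulate_lineage(genome, markers, config)
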