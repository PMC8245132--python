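"""Line-private de novo mutation calling and spectrum analysis.

A candidate single-nucleotide mutation is a biallelic position covered by more
than ``min_depth`` reads in every line of the background where exactly one
line deviates from the ancestral state.  Positions that are parental markers
are LOH substrate, never mutations, and are excluded up front.  Homozygous
candidates lying inside a called LOH tract of their own line represent the
conversion of a sub-threshold parental polymorphism (the LOH itself), not a
new mutation, and are filtered; heterozygous candidates are kept regardless.

Consecutive SNMs separated by at most one base pair are grouped into
multi-nucleotide mutations (MNMs); an MNM counts as a single event and its
members leave the SNM tally.  Spectra are reported on the six strand-collapsed
substitution classes (pyrimidine reference), with transition/transversion and
GC>AT / AT>GC ratios, optional genic/intergenic split from a GFF3 annotation,
and optional 5'-3' triplet context from a reference FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITION_CLASSES = frozenset({"C>T", "T>C"})

MUTATION_COLUMNS = [
    "line", "chrom", "pos", "ref", "alt", "zygosity", "mnm_id", "subst_class",
]


def collapse_class(ref: str, alt: str) -> str:
    """Strand-collapsed substitution class with pyrimidine (C/T) reference."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def detect_private_snvs(
    joint_calls: pd.DataFrame,
    markers: pd.DataFrame,
    lines: list[str],
    min_depth: int = 10,
) -> pd.DataFrame:
    """Identify line-exclusive substitutions from joint per-line calls.

    ``joint_calls`` is long-form with columns ``line, chrom, pos, ref, alt,
    n_alt, dp`` — one row per line per candidate position (``n_alt`` the
    number of alternate alleles in the genotype: 0, 1 or 2).  Every line must
    have a row at every candidate position (a joint caller emits reference
    calls); lines absent from the table entirely raise an error.

    Keeps positions with a single alternate allele, depth strictly greater
    than ``min_depth`` in all lines, and exactly one line deviating from the
    ancestral (shared) state; marker positions are excluded.
    """
    if not len(joint_calls):
        return pd.DataFrame(columns=MUTATION_COLUMNS)
    absent = set(lines) - set(joint_calls["line"].unique())
    if absent:
        raise ValueError(f"lines missing from joint calls: {sorted(absent)}")

    marker_keys = set(zip(markers["chrom"], markers["pos"]))
    records = []
    for (chrom, pos), grp in joint_calls.groupby(["chrom", "pos"], sort=True):
        if (chrom, pos) in marker_keys:
            continue
        alts = {a for a in grp["alt"] if isinstance(a, str) and a and a != "."}
        if len(alts) != 1:
            continue
        alt = alts.pop()
        if set(grp["line"]) != set(lines):
            continue  # position not genotyped in every line
        if (grp["dp"] <= min_depth).any():
            continue
        carriers = grp[grp["n_alt"] > 0]
        if len(carriers) != 1:
            continue  # not exclusive to one line
        row = carriers.iloc[0]
        records.append(
            {
                "line": row["line"],
                "chrom": chrom,
                "pos": int(pos),
                "ref": row["ref"],
                "alt": alt,
                "zygosity": "HOM" if row["n_alt"] == 2 else "HET",
                "mnm_id": pd.NA,
                "subst_class": collapse_class(row["ref"], alt),
            }
        )
    out = pd.DataFrame(records, columns=MUTATION_COLUMNS)
    return out.sort_values(["line", "chrom", "pos"], kind="stable").reset_index(drop=True)


def build_joint_calls(
    variants_by_line: dict[str, pd.DataFrame],
    default_dp: int = 50,
) -> pd.DataFrame:
    """Assemble a long-form joint call table from per-line variant tables.

    Per-line frames carry columns ``chrom, pos, ref, alt, zygosity, dp``.
    Lines without a record at a position are filled in as homozygous
    reference with ``default_dp`` (standing in for the reference depth a
    joint caller would report).
    """
    lines = list(variants_by_line)
    pieces = []
    for line, tab in variants_by_line.items():
        t = tab.copy()
        t["line"] = line
        t["n_alt"] = np.where(t["zygosity"].eq("HOM"), 2, 1)
        pieces.append(t[["line", "chrom", "pos", "ref", "alt", "n_alt", "dp"]])
    if not pieces:
        return pd.DataFrame(columns=["line", "chrom", "pos", "ref", "alt", "n_alt", "dp"])
    observed = pd.concat(pieces, ignore_index=True)
    sites = observed[["chrom", "pos", "ref", "alt"]].drop_duplicates(["chrom", "pos"])
    full = sites.merge(pd.DataFrame({"line": lines}), how="cross")
    joint = full.merge(observed, on=["line", "chrom", "pos"], how="left", suffixes=("", "_obs"))
    joint["n_alt"] = pd.to_numeric(joint["n_alt"], errors="coerce").fillna(0).astype(int)
    joint["dp"] = pd.to_numeric(joint["dp"], errors="coerce").fillna(default_dp).astype(int)
    return joint[["line", "chrom", "pos", "ref", "alt", "n_alt", "dp"]]


def filter_loh_overlap(
    candidates: pd.DataFrame,
    tracts_by_line: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Drop homozygous candidates inside a called LOH tract of their line.

    ``tracts_by_line`` maps line id to a frame with columns ``chrom,
    avg_start, avg_end`` (1-based inclusive resolved spans).  Heterozygous
    candidates are retained regardless of position.
    """
    keep = np.ones(len(candidates), dtype=bool)
    for i, row in enumerate(candidates.itertuples(index=False)):
        if row.zygosity != "HOM":
            continue
        tracts = tracts_by_line.get(row.line)
        if tracts is None or not len(tracts):
            continue
        sub = tracts[tracts["chrom"] == row.chrom]
        if ((sub["avg_start"] <= row.pos) & (row.pos <= sub["avg_end"])).any():
            keep[i] = False
    return candidates[keep].reset_index(drop=True)


def group_mnm(snms: pd.DataFrame, max_gap: int = 1) -> pd.DataFrame:
    """Assign MNM ids to chains of SNMs separated by <= ``max_gap`` bases.

    Input must be one line's records sorted by (chrom, pos); chains of length
    >= 2 share an ``mnm_id``, singletons keep ``mnm_id`` NA.
    """
    out = snms.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True).copy()
    out["mnm_id"] = pd.NA
    group_no = 0
    i = 0
    while i < len(out):
        j = i
        while (
            j + 1 < len(out)
            and out.at[j + 1, "chrom"] == out.at[j, "chrom"]
            and out.at[j + 1, "pos"] - out.at[j, "pos"] - 1 <= max_gap
        ):
            j += 1
        if j > i:
            group_no += 1
            line = out.at[i, "line"] if "line" in out.columns else "mnm"
            out.loc[i:j, "mnm_id"] = f"{line}_{out.at[i, 'chrom']}_{group_no}"
        i = j + 1
    return out


@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]
    n_snm: int
    n_mnm: int
    ts: int
    tv: int
    ts_tv: float  # NaN when undefined
    gc_to_at: int  # C>T class (C:G -> T:A)
    at_to_gc: int  # T>C class (T:A -> C:G)
    gc_at_bias: float  # NaN when undefined
    n_genic: int | None = None
    n_intergenic: int | None = None
    triplet_counts: dict[str, int] | None = None


def _genic_lookup(annotation: pd.DataFrame):
    """Build per-chromosome interval trees from a gene-interval frame."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annotation.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e) + 1) for s, e in zip(sub["start"], sub["end"])
        )
    return trees


def read_gene_intervals(gff3_path) -> pd.DataFrame:
    """Gene intervals (chrom, start, end; 1-based inclusive) from a GFF3 file."""
    gff = pd.read_csv(
        gff3_path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "feature", "start", "end", "score", "strand",
               "frame", "attributes"],
    )
    genes = gff[gff["feature"] == "gene"]
    return genes[["chrom", "start", "end"]].reset_index(drop=True)


def mutation_spectrum(
    records: pd.DataFrame,
    reference=None,
    annotation: pd.DataFrame | None = None,
) -> SpectrumSummary:
    """Summarise the substitution spectrum of retained mutation records.

    MNM members are excluded from class counts and ratios (an MNM is one
    event, not independent substitutions).  ``reference`` may be a
    ``pyfaidx.Fasta`` (or any mapping of chromosome to sequence) for triplet
    context; ``annotation`` a gene-interval frame for the genic split.
    """
    snms = records[records["mnm_id"].isna()] if len(records) else records
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for cls in snms["subst_class"] if len(snms) else []:
        counts[cls] += 1
    ts = sum(counts[c] for c in TRANSITION_CLASSES)
    tv = sum(v for c, v in counts.items() if c not in TRANSITION_CLASSES)
    n_mnm = records["mnm_id"].nunique(dropna=True) if len(records) else 0

    summary = SpectrumSummary(
        class_counts=counts,
        n_snm=len(snms),
        n_mnm=int(n_mnm),
        ts=ts,
        tv=tv,
        ts_tv=ts / tv if tv else float("nan"),
        gc_to_at=counts["C>T"],
        at_to_gc=counts["T>C"],
        gc_at_bias=counts["C>T"] / counts["T>C"] if counts["T>C"] else float("nan"),
    )

    if annotation is not None:
        trees = _genic_lookup(annotation)
        genic = 0
        for row in snms.itertuples(index=False):
            tree = trees.get(row.chrom)
            genic += bool(tree is not None and tree.overlaps(row.pos))
        summary.n_genic = genic
        summary.n_intergenic = len(snms) - genic

    if reference is not None:
        triplets: dict[str, int] = {}
        for row in snms.itertuples(index=False):
            seq = reference[row.chrom]
            try:
                context = str(seq[row.pos - 2 : row.pos + 1]).upper()
            except (IndexError, KeyError) as exc:
                raise ValueError(
                    f"reference mismatch at {row.chrom}:{row.pos}"
                ) from exc
            if len(context) != 3:
                continue  # chromosome edge
            if context[1] != row.ref:
                raise ValueError(
                    f"reference base {context[1]} != record ref {row.ref} "
                    f"at {row.chrom}:{row.pos}"
                )
            triplets[context] = triplets.get(context, 0) + 1
        summary.triplet_counts = triplets

    return summary


def call_mutations(
    variants_by_line: dict[str, pd.DataFrame],
    markers: pd.DataFrame,
    tracts_by_line: dict[str, pd.DataFrame] | None = None,
    min_depth: int = 10,
    default_dp: int = 50,
    max_mnm_gap: int = 1,
) -> pd.DataFrame:
    """End-to-end mutation calling: joint assembly, exclusivity and depth
    filters, LOH-overlap filter, MNM grouping."""
    joint = build_joint_calls(variants_by_line, default_dp=default_dp)
    lines = list(variants_by_line)
    cands = detect_private_snvs(joint, markers, lines, min_depth=min_depth)
    if tracts_by_line is not None:
        cands = filter_loh_overlap(cands, tracts_by_line)
    grouped = [
        group_mnm(sub, max_gap=max_mnm_gap)
        for _, sub in cands.groupby("line", sort=True)
    ]
    if not grouped:
        return cands
    return pd.concat(grouped, ignore_index=True)
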