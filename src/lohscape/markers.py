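"""Marker definition and per-line genotype tagging.

A *marker* is a confidently-called site where the two parental haploids carry
different alleles, so the hybrid ancestor is heterozygous there.  LOH is read
out as conversion of marker genotypes: at every marker a line is tagged
heterozygous (HET), homozygous for parent 1 (HOM_P1), homozygous for parent 2
(HOM_P2), or MISSING when the call is absent or fails the genotype-quality
threshold.

Filters follow the upstream variant-calling conventions: markers require a
single alternate allele and >= 50 reads summed over both parents; per-line
genotypes with GQ < 20 are discarded.  A homozygous call matching neither
parental allele is set to MISSING (and counted) rather than silently dropped —
it is a candidate de novo variant and belongs to the mutation caller, not the
LOH caller.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# marker-call states (int8 codes)
HET: int = 0
HOM_P1: int = 1
HOM_P2: int = 2
MISSING: int = 3

STATE_LABELS = {HET: "HET", HOM_P1: "HOM_P1", HOM_P2: "HOM_P2", MISSING: "MISSING"}
STATE_CODES = {v: k for k, v in STATE_LABELS.items()}


def _parent_allele(row_gt, ref: str, alt: str):
    """Resolve a haploid parent's allele from a diploid genotype call.

    Returns the base, or None when the call is itself heterozygous (a haploid-
    derived parent should be homozygous; ambiguous calls are excluded).
    """
    alleles = {ref if a == 0 else alt for a in row_gt}
    if len(alleles) != 1:
        return None
    return alleles.pop()


def define_markers(
    parent1_calls: pd.DataFrame,
    parent2_calls: pd.DataFrame,
    min_combined_depth: int = 50,
) -> pd.DataFrame:
    """Derive the confident heterozygous marker set from parental variant calls.

    Each input frame needs columns ``chrom, pos, ref, alt, gt, dp`` where
    ``alt`` is the comma-joined alternate allele string and ``gt`` a tuple of
    allele indices.  A position is kept when, across the pair, there is exactly
    one alternate allele, the parents resolve to different alleles, and the
    summed parental depth reaches ``min_combined_depth``.  A parent absent at a
    position counts as homozygous reference with zero depth.

    Returns a sorted frame with columns ``chrom, pos, p1, p2``.
    """
    for name, table in (("parent1", parent1_calls), ("parent2", parent2_calls)):
        missing = {"chrom", "pos", "ref", "alt", "gt", "dp"} - set(table.columns)
        if missing:
            raise ValueError(f"{name} table is missing columns {sorted(missing)}")
        bad = table["pos"].isna() | table["ref"].isna()
        if bad.any():
            loc = table.index[bad][0]
            raise ValueError(f"malformed record in {name} table at row {loc}")

    merged = parent1_calls.merge(
        parent2_calls,
        on=["chrom", "pos"],
        how="outer",
        suffixes=("_1", "_2"),
        sort=False,
    )

    rows = []
    for row in merged.itertuples(index=False):
        refs = {r for r in (getattr(row, "ref_1", None), getattr(row, "ref_2", None)) if isinstance(r, str)}
        if len(refs) != 1:
            continue  # inconsistent reference context
        ref = refs.pop()
        alts = set()
        for a in (getattr(row, "alt_1", None), getattr(row, "alt_2", None)):
            if isinstance(a, str) and a and a != ".":
                alts.update(a.split(","))
        if len(alts) != 1:
            continue  # multi-allelic (or no alternate at all): excluded
        alt = alts.pop()

        gt1, gt2 = getattr(row, "gt_1", None), getattr(row, "gt_2", None)
        a1 = _parent_allele(gt1, ref, alt) if isinstance(gt1, tuple) else ref
        a2 = _parent_allele(gt2, ref, alt) if isinstance(gt2, tuple) else ref
        if a1 is None or a2 is None or a1 == a2:
            continue
        dp1 = getattr(row, "dp_1", np.nan)
        dp2 = getattr(row, "dp_2", np.nan)
        depth = (0 if pd.isna(dp1) else dp1) + (0 if pd.isna(dp2) else dp2)
        if depth < min_combined_depth:
            continue
        rows.append((row.chrom, int(row.pos), a1, a2))

    out = pd.DataFrame(rows, columns=["chrom", "pos", "p1", "p2"])
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def tag_genotypes(
    line_calls: pd.DataFrame,
    markers: pd.DataFrame,
    min_gq: int = 20,
) -> pd.DataFrame:
    """Tag a line's genotype at every marker.

    ``line_calls`` needs columns ``chrom, pos, a1, a2, gq, dp`` (observed
    alleles as bases).  Output is aligned to ``markers`` one row per marker
    with columns ``chrom, pos, p1, p2, state, gq, dp``; markers absent from
    the calls, below ``min_gq``, or carrying non-parental alleles are MISSING.
    """
    merged = markers.merge(line_calls, on=["chrom", "pos"], how="left", sort=False)
    n = len(merged)
    state = np.full(n, MISSING, dtype=np.int8)
    gq = pd.to_numeric(merged["gq"], errors="coerce").fillna(-1).astype(np.int32).to_numpy()
    dp = pd.to_numeric(merged["dp"], errors="coerce").fillna(0).astype(np.int32).to_numpy()

    present = merged["a1"].notna().to_numpy() & (gq >= min_gq)
    a1 = merged["a1"].to_numpy(dtype=object)
    a2 = merged["a2"].to_numpy(dtype=object)
    p1 = merged["p1"].to_numpy(dtype=object)
    p2 = merged["p2"].to_numpy(dtype=object)

    is_het = present & (
        ((a1 == p1) & (a2 == p2)) | ((a1 == p2) & (a2 == p1))
    )
    is_hom1 = present & (a1 == p1) & (a2 == p1)
    is_hom2 = present & (a1 == p2) & (a2 == p2)
    state[is_het] = HET
    state[is_hom1] = HOM_P1
    state[is_hom2] = HOM_P2

    foreign = present & ~(is_het | is_hom1 | is_hom2)
    if foreign.any():
        logger.warning(
            "%d marker call(s) carry non-parental alleles; set to MISSING "
            "(candidate de novo variants)", int(foreign.sum())
        )

    absent_chroms = set(markers["chrom"]) - set(line_calls["chrom"])
    if absent_chroms:
        logger.warning("chromosomes absent from line calls: %s", sorted(absent_chroms))

    out = markers.copy()
    out["state"] = state
    out["gq"] = np.where(merged["a1"].notna(), gq, -1).astype(np.int16)
    out["dp"] = dp.astype(np.int16)
    return out


def apply_gq_filter(calls: pd.DataFrame, min_gq: int = 20) -> pd.DataFrame:
    """Set calls below the GQ threshold to MISSING (used for pre-tagged tables)."""
    out = calls.copy()
    low = (out["gq"] < min_gq) & (out["state"] != MISSING)
    out.loc[low, "state"] = MISSING
    return out


def state_counts(calls: pd.DataFrame) -> dict[str, int]:
    counts = calls["state"].value_counts()
    return {label: int(counts.get(code, 0)) for code, label in STATE_LABELS.items()}
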