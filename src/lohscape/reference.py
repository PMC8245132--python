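"""Reference constants: the S. cerevisiae R64 karyotype and the MA study design.

The nuclear chromosome lengths are those of the R64 (sacCer3) assembly; the
mitochondrial genome is excluded because marker-based LOH genotyping only
applies to the nuclear heterozygous sites.

``STUDY_DESIGN`` holds the propagation design of the nine-hybrid mutation
accumulation experiment the pipeline was built around: ancestral heterozygous
position counts, number of sequenced lines, single-cell bottlenecks, and total
mitotic divisions per line.  These are experiment-design inputs (not results)
and are used to parameterise realistic simulations and the divisions-per-
bottleneck arithmetic.
"""

from __future__ import annotations

import pandas as pd

#: R64 / sacCer3 nuclear chromosome lengths in bp.
R64_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chrI", 230218),
    ("chrII", 813184),
    ("chrIII", 316620),
    ("chrIV", 1531933),
    ("chrV", 576874),
    ("chrVI", 270161),
    ("chrVII", 1090940),
    ("chrVIII", 562643),
    ("chrIX", 439888),
    ("chrX", 745751),
    ("chrXI", 666816),
    ("chrXII", 1078177),
    ("chrXIII", 924431),
    ("chrXIV", 784333),
    ("chrXV", 1091291),
    ("chrXVI", 948066),
)

R64_GENOME_SIZE: int = sum(length for _, length in R64_CHROMOSOMES)

#: Design of the nine-hybrid MA experiment: one row per hybrid background.
#: ``het_positions`` is the ancestral heterozygous marker count, ``divisions``
#: the total number of mitotic divisions each line underwent.
STUDY_DESIGN: pd.DataFrame = pd.DataFrame(
    {
        "hybrid": ["H1", "H2", "H3", "H4", "H5", "H6", "H7", "H8", "H9"],
        "het_positions": [9972, 18789, 20875, 49412, 52223, 55570, 69456, 113241, 116475],
        "n_lines": [20, 12, 20, 20, 20, 20, 19, 19, 19],
        "n_bottlenecks": [100, 75, 75, 75, 75, 100, 75, 75, 100],
        "divisions": [2446, 1842, 1863, 1772, 1777, 2392, 1844, 1769, 2452],
    }
)


def marker_density_per_kb(het_positions: int, genome_size: int = R64_GENOME_SIZE) -> float:
    """Genome-wide heterozygous marker density in markers per kb."""
    return het_positions / (genome_size / 1000.0)


def divisions_per_bottleneck(design: pd.DataFrame = STUDY_DESIGN) -> pd.Series:
    """Per-hybrid mean divisions per single-cell bottleneck (total / bottlenecks)."""
    return design["divisions"] / design["n_bottlenecks"]
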