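"""Chromosome-arm catalogues and chromosome-name handling.

Copy-number summaries in this package are aggregated over chromosome arms.
Two catalogues are provided: an hg19-like table of arm boundaries shipped
as a package asset (used when emulating real genomes) and a small toy
genome (a handful of metacentric chromosomes) for fast tests.

All intervals are 0-based half-open. Chromosome names are normalized to
carry a ``chr`` prefix; acrocentric detail is ignored (every chromosome has
a p and a q arm split at the catalogued centromere point).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CANONICAL_CHROMS = AUTOSOMES + ("chrX", "chrY")


def normalize_chrom(name: str) -> str:
    """Return the canonical ``chr``-prefixed chromosome name, or raise ValueError."""
    s = str(name).strip()
    if not s.lower().startswith("chr"):
        s = "chr" + s
    else:
        s = "chr" + s[3:]
    if s not in CANONICAL_CHROMS:
        raise ValueError(f"unknown chromosome: {name!r}")
    return s


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


def load_hg19_arms() -> pd.DataFrame:
    """Arm table with columns ``arm, chrom, start, end`` (hg19-like boundaries)."""
    with resources.files("occultclone.data").joinpath("hg19_arms.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    rows = []
    for _, r in tab.iterrows():
        rows.append((f"{r.chrom[3:]}p", r.chrom, 0, int(r.centromere)))
        rows.append((f"{r.chrom[3:]}q", r.chrom, int(r.centromere), int(r.length)))
    return pd.DataFrame(rows, columns=["arm", "chrom", "start", "end"])


def toy_arms(n_chrom: int = 4, arm_length: int = 20_000_000) -> pd.DataFrame:
    """Toy genome: ``n_chrom`` autosomes, each with equal-length p and q arms."""
    if not 1 <= n_chrom <= 22:
        raise ValueError("toy genome supports 1-22 autosomes")
    rows = []
    for i in range(1, n_chrom + 1):
        chrom = f"chr{i}"
        rows.append((f"{i}p", chrom, 0, arm_length))
        rows.append((f"{i}q", chrom, arm_length, 2 * arm_length))
    return pd.DataFrame(rows, columns=["arm", "chrom", "start", "end"])


def arm_of(arm_table: pd.DataFrame, chrom: str, pos: int) -> str | None:
    """Arm containing position ``pos`` on ``chrom``, or None if outside the table."""
    hit = arm_table[
        (arm_table.chrom == chrom) & (arm_table.start <= pos) & (pos < arm_table.end)
    ]
    if hit.empty:
        return None
    return hit.iloc[0]["arm"]
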