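"""TCR V(D)J rearrangement classification from per-cell clone tables.

Clone tables (MiXCR-export style: one row per predicted clone with cell id,
chain, CDR3 nucleotide/amino-acid sequence and read count) are filtered for
clones with read count strictly greater than 5 to suppress false positives;
within each cell and chain only the dominant (highest-count) clone is kept.
A cell's rearrangement category summarizes which chain loci survive:

    none        no chain rearranged
    TRA_B       only TRA and/or TRB
    TRG_D       only TRG and/or TRD
    TRA_B_G_D   at least one of {TRA, TRB} and one of {TRG, TRD}

Clone identity for frequency and overlap reports is (chain, CDR3 nucleotide
sequence); amino-acid identity is available as an option.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CHAINS",
    "CATEGORIES",
    "filter_clones",
    "dominant_clone_per_chain",
    "classify_rearrangement",
    "classify_cells",
    "clone_frequency_table",
    "clonal_overlap",
]

CHAINS = ("TRA", "TRB", "TRG", "TRD")
CATEGORIES = ("none", "TRA_B", "TRG_D", "TRA_B_G_D")
CLONE_COLUMNS = ["cell_id", "chain", "cdr3_nt", "cdr3_aa", "read_count"]

_AB = {"TRA", "TRB"}
_GD = {"TRG", "TRD"}


def _check_clone_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLONE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"clone table lacks columns: {missing}")
    bad = set(records["chain"]) - set(CHAINS)
    if bad:
        raise ValueError(f"unknown chain symbols: {sorted(bad)}")
    if (records["read_count"] < 1).any():
        raise ValueError("read counts must be >= 1")
    return records


def filter_clones(records: pd.DataFrame, min_count_exclusive: int = 5) -> pd.DataFrame:
    """Keep clones with read_count strictly greater than ``min_count_exclusive``."""
    if len(records) == 0:
        return records.copy()
    _check_clone_table(records)
    return records[records["read_count"] > min_count_exclusive].reset_index(drop=True)


def dominant_clone_per_chain(records: pd.DataFrame) -> pd.DataFrame:
    """For each (cell, chain), keep the highest-read-count clone.

    Ties are broken by lexicographically smallest CDR3 nucleotide sequence so
    the result never depends on input row order.
    """
    if len(records) == 0:
        return records.copy()
    _check_clone_table(records)
    ordered = records.sort_values(
        ["cell_id", "chain", "read_count", "cdr3_nt"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    return ordered.drop_duplicates(["cell_id", "chain"]).reset_index(drop=True)


def classify_rearrangement(chains) -> str:
    """Map a cell's surviving chain set to its rearrangement category."""
    chains = set(chains)
    bad = chains - set(CHAINS)
    if bad:
        raise ValueError(f"unknown chain symbols: {sorted(bad)}")
    has_ab = bool(chains & _AB)
    has_gd = bool(chains & _GD)
    if has_ab and has_gd:
        return "TRA_B_G_D"
    if has_ab:
        return "TRA_B"
    if has_gd:
        return "TRG_D"
    return "none"


def classify_cells(
    records: pd.DataFrame, all_cells=None, min_count_exclusive: int = 5
) -> tuple[pd.Series, pd.DataFrame]:
    """Full post-processing: filter, pick dominant clones, classify each cell.

    ``all_cells`` optionally names the complete cohort so cells without any
    surviving clone are reported as "none".  Returns ``(calls, dominant)``
    where calls is a cell -> category series and dominant the surviving
    clone table.
    """
    dominant = dominant_clone_per_chain(filter_clones(records, min_count_exclusive))
    per_cell = (
        dominant.groupby("cell_id")["chain"].apply(set) if len(dominant) else pd.Series(dtype=object)
    )
    cells = pd.Index(all_cells) if all_cells is not None else per_cell.index
    calls = pd.Series(
        [classify_rearrangement(per_cell.get(c, set())) for c in cells],
        index=cells,
        name="category",
    )
    return calls, dominant


def clone_frequency_table(
    dominant: pd.DataFrame, groups: pd.Series, by: str = "cdr3_nt"
) -> pd.DataFrame:
    """Cells per distinct dominant clone, split by chain and cell group.

    Returns (group, chain, clone id, n_cells, expanded) where ``expanded``
    marks clones carried by at least 2 cells.
    """
    if by not in ("cdr3_nt", "cdr3_aa"):
        raise ValueError("clone identity must be cdr3_nt or cdr3_aa")
    if len(dominant) == 0:
        return pd.DataFrame(columns=["group", "chain", by, "n_cells", "expanded"])
    missing = set(dominant["cell_id"]) - set(groups.index)
    if missing:
        raise ValueError(f"group labels missing for cells: {sorted(missing)}")
    d = dominant.assign(group=dominant["cell_id"].map(groups).to_numpy())
    freq = (
        d.groupby(["group", "chain", by])["cell_id"]
        .nunique()
        .rename("n_cells")
        .reset_index()
    )
    freq["expanded"] = freq["n_cells"] >= 2
    return freq.sort_values(["group", "chain", "n_cells"], ascending=[True, True, False]).reset_index(
        drop=True
    )


def clonal_overlap(
    group_a, group_b, dominant: pd.DataFrame, by: str = "cdr3_nt"
) -> pd.DataFrame:
    """Clones (chain + CDR3) dominant in at least one cell of each group."""
    if by not in ("cdr3_nt", "cdr3_aa"):
        raise ValueError("clone identity must be cdr3_nt or cdr3_aa")
    a = dominant[dominant["cell_id"].isin(set(group_a))]
    b = dominant[dominant["cell_id"].isin(set(group_b))]
    ka = set(map(tuple, a[["chain", by]].to_numpy()))
    kb = set(map(tuple, b[["chain", by]].to_numpy()))
    shared = sorted(ka & kb)
    return pd.DataFrame(shared, columns=["chain", by])
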