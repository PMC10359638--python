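"""ChIP-MS peptide-count aggregation, candidate filtering and enrichment.

Inputs are protein (or isoform) x sample PSM tables with a role per sample
(chip or input).  Candidate selection follows the rule: total ChIP PSMs at
least ``ratio`` times the total input PSMs (proteins seen only in ChIP
qualify).  The displayed enrichment is log2((chip + pc) / (input + pc)) with
a pseudocount so the value is finite for every protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "PsmTable",
    "read_psm_table",
    "write_psm_table",
    "aggregate_psm",
    "candidate_filter",
    "relative_enrichment",
    "shared_sets",
]


@dataclass
class PsmTable:
    """Protein x sample PSM counts with per-sample roles ('chip' | 'input')."""

    counts: pd.DataFrame            # index = protein id, columns = sample names
    roles: dict = field(default_factory=dict)  # sample -> role

    def __post_init__(self):
        bad_roles = set(self.roles.values()) - {"chip", "input"}
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        missing = set(self.counts.columns) - set(self.roles)
        if missing:
            raise ValueError(f"samples without a role: {sorted(missing)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative PSM counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("PSM counts must be integers")

    def _role_cols(self, role: str):
        cols = [c for c in self.counts.columns if self.roles[c] == role]
        if not cols:
            raise ValueError(f"no samples with role {role!r}")
        return cols

    def chip_total(self) -> pd.Series:
        return self.counts[self._role_cols("chip")].sum(axis=1)

    def input_total(self) -> pd.Series:
        return self.counts[self._role_cols("input")].sum(axis=1)


def read_psm_table(path) -> PsmTable:
    """Read a tab-separated protein x sample table whose second header line
    gives the sample roles (``#roles<TAB>chip<TAB>input...``)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        roles_line = fh.readline().rstrip("\n").split("\t")
        if not roles_line or roles_line[0] != "#roles":
            raise ValueError("second line must be the '#roles' row")
        df = pd.read_csv(fh, sep="\t", header=None, names=header, index_col=0)
    df.index.name = None
    roles = dict(zip(header[1:], roles_line[1:]))
    return PsmTable(df, roles)


def write_psm_table(table: PsmTable, path) -> None:
    with open(path, "w") as fh:
        cols = list(table.counts.columns)
        fh.write("\t".join(["protein"] + cols) + "\n")
        fh.write("\t".join(["#roles"] + [table.roles[c] for c in cols]) + "\n")
        for pid, row in table.counts.iterrows():
            fh.write("\t".join([str(pid)] + [str(int(v)) for v in row]) + "\n")


def aggregate_psm(raw: PsmTable, isoform_map: dict) -> PsmTable:
    """Combine isoform rows into per-protein rows by summing counts.

    ``isoform_map`` maps every isoform id to its protein id; unmapped
    isoforms are an error listing the offenders.
    """
    unmapped = [i for i in raw.counts.index if i not in isoform_map]
    if unmapped:
        raise ValueError(f"unmapped isoforms: {sorted(map(str, unmapped))}")
    grouped = raw.counts.groupby([isoform_map[i] for i in raw.counts.index]).sum()
    return PsmTable(grouped, dict(raw.roles))


def candidate_filter(table: PsmTable, ratio: float = 2.0):
    """Proteins whose total ChIP PSMs are >= ``ratio`` x total input PSMs.

    Zero-input proteins with any ChIP signal qualify.  Returns the sorted
    list of candidate protein ids.
    """
    chip = table.chip_total()
    inp = table.input_total()
    mask = (chip >= ratio * inp) & (chip > 0)
    return sorted(table.counts.index[mask])


def relative_enrichment(table: PsmTable, pseudocount: float = 1.0) -> pd.Series:
    """log2((chip + pc) / (input + pc)) per protein; finite everywhere."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    chip = table.chip_total().astype(float)
    inp = table.input_total().astype(float)
    return np.log2((chip + pseudocount) / (inp + pseudocount)).rename("log2_enrichment")


def shared_sets(named_sets: dict) -> dict:
    """Counts of every region of the Venn partition of >=2 named sets.

    Keys are frozensets of names; each item is counted in the region of
    exactly the sets containing it.  Region counts sum to the union size.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(named_sets)
    union = set().union(*named_sets.values())
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = 0
    for item in union:
        membership = frozenset(n for n in names if item in named_sets[n])
        regions[membership] += 1
    return regions
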