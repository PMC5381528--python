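"""Expression-group association of edited genes.

Genes are grouped by editing status — any putative editing site, A-to-I
editing specific to the focal (sexual) condition, and focal-specific
A-to-I editing that changes the protein at ≥10% penetrance — and each
group's distribution of between-condition expression ratios is
summarised (n, median, quartiles).  Groups are nested by construction
(aa ⊆ condition-specific ⊆ any).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionTable", "GroupAssignment", "assign_groups", "group_ratio_summary"]


class ExpressionTable:
    """Per-gene normalized expression values per condition.

    Backed by a tidy DataFrame with columns gene_id / condition / value;
    values are abundance units as provided upstream (quantification is
    out of scope).
    """

    def __init__(self, df: pd.DataFrame):
        required = {"gene_id", "condition", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"expression table needs columns {sorted(required)}")
        if (df["value"] < 0).any():
            raise ValueError("expression values must be ≥ 0")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def conditions(self) -> set[str]:
        return set(self.df["condition"].unique())

    def wide(self) -> pd.DataFrame:
        return self.df.pivot_table(
            index="gene_id", columns="condition", values="value", aggfunc="first"
        )


@dataclass
class GroupAssignment:
    """The three nested edited-gene groups used for expression comparison."""

    any_edited: set[str]
    condition_specific_ag: set[str]
    aa_changing: set[str]

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "any": self.any_edited,
            "specific": self.condition_specific_ag,
            "aa": self.aa_changing,
        }


def assign_groups(
    records: Sequence,
    focal_condition: str,
    min_edit_fraction: float = 0.10,
) -> GroupAssignment:
    """Group genes by editing status.

    any
        genes carrying any reproducible site in any condition;
    specific
        genes with an A→G site specific to the focal condition;
    aa
        genes where such a site changes the protein (nonsynonymous or
        stop-loss) and is edited in ≥ ``min_edit_fraction`` of pooled
        replicate reads.
    """
    any_edited: set[str] = set()
    specific: set[str] = set()
    aa: set[str] = set()
    for rec in records:
        any_edited.add(rec.gene_id)
        if rec.substitution_type != "AG" or rec.specific_to != focal_condition:
            continue
        specific.add(rec.gene_id)
        cons = rec.consequence
        if (
            cons is not None
            and cons.changes_product
            and rec.pooled_fraction() >= min_edit_fraction
        ):
            aa.add(rec.gene_id)
    return GroupAssignment(any_edited, specific, aa)


def group_ratio_summary(
    expr: ExpressionTable,
    groups: Mapping[str, set[str]],
    comparison: tuple[str, str],
    pseudocount: float = 1.0,
    log2: bool = False,
) -> pd.DataFrame:
    """Per-group expression-ratio distribution statistics.

    Ratios are ``(numerator + pseudocount) / (denominator + pseudocount)``
    per gene for ``comparison = (numerator_condition, denominator_condition)``;
    the pseudocount tolerates zero denominators.  Quartiles use linear
    interpolation between order statistics (numpy default, type 7).
    Empty groups come back with n = 0 and missing statistics.
    """
    num_cond, den_cond = comparison
    missing = {num_cond, den_cond} - expr.conditions
    if missing:
        raise ValueError(f"conditions not in expression table: {sorted(missing)}")
    wide = expr.wide()
    rows = []
    for name, genes in groups.items():
        sub = wide.loc[wide.index.intersection(sorted(genes))].dropna(
            subset=[num_cond, den_cond]
        )
        ratios = (sub[num_cond] + pseudocount) / (sub[den_cond] + pseudocount)
        if log2:
            ratios = np.log2(ratios)
        if len(ratios) == 0:
            rows.append(
                {"group": name, "n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan}
            )
            continue
        rows.append(
            {
                "group": name,
                "n": len(ratios),
                "median": float(np.median(ratios)),
                "q1": float(np.percentile(ratios, 25)),
                "q3": float(np.percentile(ratios, 75)),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3"])
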