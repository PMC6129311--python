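"""Ranked tissue-characterization reports.

Sorting a tissue's column of the set weight matrix puts the gene sets
that are most specifically active in that tissue at the top, which is a
direct functional read-out of the tissue.  Ranking instead by the minimum
weight across a group of tissues highlights processes with at least basic
activity in all of them (e.g. the tissues affected by a systemic disease).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .weights import MultiTissueWeights, SetWeightMatrix, multi_tissue_weight


@dataclass
class RankedReport:
    """Top-k gene sets for a tissue or tissue group.

    ``rows`` holds (rank, set, weight) plus, for multi-tissue reports,
    one audit column per component tissue.  Weights are non-increasing
    down the ranking; ties break lexicographically by set name.
    """

    tissue: str
    rows: pd.DataFrame

    @property
    def k(self) -> int:
        return len(self.rows)

    def write(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.17g")

    def render(self) -> str:
        """Fixed-width human-readable rendering."""
        return self.rows.to_string(index=False, float_format=lambda v: f"{v:.4g}")


def _ranked(weights: pd.Series, k: int) -> pd.DataFrame:
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = weights.dropna().sort_index().sort_values(
        ascending=False, kind="stable"
    )
    top = ordered.iloc[:k]
    return pd.DataFrame(
        {
            "rank": range(1, len(top) + 1),
            "set": top.index,
            "weight": top.to_numpy(),
        }
    )


def rank_sets_for_tissue(sw: SetWeightMatrix, tissue: str, k: int) -> RankedReport:
    """Top-k sets by weight for one tissue; undefined weights excluded."""
    if tissue not in sw.w.columns:
        raise ValueError(f"tissue {tissue!r} not in set weight matrix")
    return RankedReport(tissue=tissue, rows=_ranked(sw.w[tissue], k))


def multi_tissue_report(
    sw: SetWeightMatrix,
    tissues: Sequence[str],
    k: int,
    aggregator: str = "min",
) -> RankedReport:
    """Top-k sets by aggregate (default minimum) weight over a tissue group.

    The per-tissue component weights are included alongside the aggregate
    so a ranking can be audited; sets undefined in any component tissue
    are excluded (see :func:`~tissuesets.weights.multi_tissue_weight`).
    """
    mtw: MultiTissueWeights = multi_tissue_weight(sw, tissues, aggregator=aggregator)
    rows = _ranked(mtw.w, k)
    for t in mtw.tissues:
        rows[t] = sw.w.loc[rows["set"], t].to_numpy()
    return RankedReport(tissue="+".join(mtw.tissues), rows=rows)
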