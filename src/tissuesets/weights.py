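"""Tissue-specific gene and gene set weights.

The gene weight for gene *i* in tissue *t* is

    w_g[i,t] = e[i,t] * a[i,t]

where ``e`` is the RNA fold-change of the gene in that tissue relative to
its mean expression across all tissues, and ``a`` is a 0/1 protein-activity
indicator from IHC (1 when the protein was detected at "Low" or stronger,
or when no IHC record exists; 0 when it was called "Not detected").  A
missing RNA measurement forces e = 0, so a non-zero weight requires
evidence at both the RNA and the protein level.

The set weight for gene set *j* in tissue *t* is the -log p-value of a
one-sided two-sample t-test comparing the mean gene weight of the set's
members against the mean over the rest of the gene universe (a competitive
test in the style of limma's geneSetTest):

    w_s[j,t] = -log Pr(T > t_obs)

The tail probability is evaluated in log space (Student-t log survival
function), so very tissue-specific sets get large finite weights instead
of overflowing to infinity.  The multi-tissue weight of a set over a
tissue group is the minimum of its per-tissue weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionTable, GeneSetCollection, IHCTable

logger = logging.getLogger(__name__)

#: Minimum member count for the competitive t-test.
DEFAULT_MIN_SET_SIZE = 2


def _log_divisor(log_base: str | float) -> float:
    """ln(base); weights are -log_base(p). Natural log by default."""
    if log_base in ("e", "ln", None):
        return 1.0
    base = float(log_base)
    if base <= 1.0:
        raise ValueError(f"log base must be > 1, got {base}")
    return math.log(base)


@dataclass
class GeneWeightMatrix:
    """Per-gene per-tissue weights with their two evidence components.

    ``e`` holds the RNA fold-change component, ``a`` the 0/1 IHC activity
    indicator, and ``w = e * a`` elementwise; all three share the same
    gene index and tissue columns and are non-negative.
    """

    e: pd.DataFrame
    a: pd.DataFrame
    w: pd.DataFrame

    def __post_init__(self) -> None:
        for other in (self.a, self.w):
            if not (self.e.index.equals(other.index) and self.e.columns.equals(other.columns)):
                raise ValueError("e, a and w must share genes and tissues")
        a = self.a.to_numpy()
        if not np.isin(a, (0, 1)).all():
            raise ValueError("activity indicator must be 0/1")
        if (self.e.to_numpy() < 0).any():
            raise ValueError("fold-change component must be non-negative")
        if not np.allclose(self.w.to_numpy(), self.e.to_numpy() * a, atol=0, rtol=0):
            raise ValueError("w must equal e * a elementwise")

    @property
    def genes(self) -> list[str]:
        return list(self.w.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.w.columns)


@dataclass
class SetWeightMatrix:
    """Per-set per-tissue weights w_s = -log p.

    NaN marks an undefined weight (too few testable members, or a
    degenerate t-test); ``n_used`` is the member count that entered the
    test after intersection with the gene universe, and ``flags`` records
    why a cell is undefined.
    """

    w: pd.DataFrame
    n_used: pd.Series
    flags: pd.DataFrame | None = None
    log_base: str | float = "e"

    @property
    def set_names(self) -> list[str]:
        return list(self.w.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.w.columns)


@dataclass
class MultiTissueWeights:
    """Aggregate (default: minimum) of a set's weights over a tissue group."""

    w: pd.Series
    tissues: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)
    aggregator: str = "min"


class SetWeightResult(NamedTuple):
    weight: float
    log_p: float
    degenerate: bool


def expression_fold_change(expr: ExpressionTable) -> pd.DataFrame:
    """RNA fold-change of each gene in each tissue vs its all-tissue mean.

    Missing cells count as 0 both in the numerator (the gene is assumed
    unexpressed there) and in the denominator mean, which is taken over
    all tissues in the table.  A gene with zero mean gets e = 0 everywhere.
    Requires at least two tissues, otherwise the fold-change is undefined.
    """
    if len(expr.tissues) < 2:
        raise ValueError("fold-change undefined for a single-tissue table")
    vals = expr.values.fillna(0.0)
    mean = vals.mean(axis=1)
    e = vals.div(mean.where(mean > 0), axis=0).fillna(0.0)
    return e


def ihc_activity(
    ihc: IHCTable,
    genes: Sequence[str],
    tissues: Sequence[str],
    drop_reliability: Iterable[str] = (),
) -> pd.DataFrame:
    """0/1 protein-activity indicator over the requested gene x tissue grid.

    Multiple records for a (gene, tissue) pair (e.g. one per cell type)
    collapse by maximum: detection at "Low" or stronger in any cell type
    gives a = 1, while a = 0 requires every record to be "Not detected".
    Pairs with no record default to a = 1, leaving the weight to the RNA
    evidence alone.  ``drop_reliability`` discards records whose
    reliability label is in the given collection before aggregation.
    """
    genes = list(genes)
    tissues = list(tissues)
    rec = ihc.records
    if drop_reliability:
        rec = rec[~rec["reliability"].isin(set(drop_reliability))]
    if len(rec) == 0:
        return pd.DataFrame(1, index=genes, columns=tissues, dtype=np.int8)
    best = (
        pd.DataFrame(
            {
                "gene": rec["gene"],
                "tissue": rec["tissue"],
                "det": (rec["level"] != "Not detected").astype(np.int8),
            }
        )
        .groupby(["gene", "tissue"], sort=False)["det"]
        .max()
        .unstack("tissue")
    )
    # Pairs without a record default to active (a = 1).
    a = best.reindex(index=genes, columns=tissues).fillna(1).astype(np.int8)
    a.index.name = None
    a.columns.name = None
    return a


def gene_weights(
    expr: ExpressionTable,
    ihc: IHCTable,
    drop_reliability: Iterable[str] = (),
) -> GeneWeightMatrix:
    """Combine RNA fold-change and IHC activity into gene weights.

    Tissues are reconciled by intersection of the expression table's
    tissues with those named in the IHC records (IHC-only tissues are
    dropped with a log message; expression-only tissues are kept, since
    absent IHC means a = 1).
    """
    expr_tissues = list(expr.tissues)
    ihc_tissues = set(ihc.records["tissue"]) if len(ihc.records) else set()
    extra = ihc_tissues - set(expr_tissues)
    if extra:
        logger.info("IHC tissues absent from expression table ignored: %s", sorted(extra))
    if not expr_tissues:
        raise ValueError("no tissues in common between RNA and IHC inputs")
    e = expression_fold_change(expr)
    a = ihc_activity(ihc, expr.genes, expr_tissues, drop_reliability=drop_reliability)
    w = e * a.astype(float)
    return GeneWeightMatrix(e=e, a=a, w=w)


def _welch_from_moments(mean1, var1, n1, mean2, var2, n2):
    """Welch t statistic and Welch-Satterthwaite df from group moments."""
    se1 = var1 / n1
    se2 = var2 / n2
    denom = np.sqrt(se1 + se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / denom
        df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    return t, df


def _pooled_from_moments(mean1, var1, n1, mean2, var2, n2):
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
        t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, np.broadcast_to(np.asarray(df, dtype=float), np.shape(t))


def _one_sided_log_p(t, df):
    """log Pr(T_df > t), finite for any finite t.

    Uses the t log-survival function where it is representable and falls
    back to the log of the regularized incomplete beta in hypergeometric
    form,

        Pr(T > t) = I_x(df/2, 1/2) / 2,  x = df / (df + t^2)
        I_x(a, b) = x^a (1-x)^b / (a B(a, b)) * 2F1(1, a+b; a+1; x),

    evaluated term-by-term in log space when the survival probability
    itself underflows double precision (extreme t at large df).
    """
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    out = stats.t.logsf(t, df)
    under = np.isneginf(out) & (t > 0)
    if np.any(under):
        tu = t[under] if t.ndim else t
        dfu = df[under] if df.ndim else df
        a = dfu / 2.0
        b = 0.5
        x = dfu / (dfu + tu**2)
        log_tail = (
            a * np.log(x)
            + b * np.log1p(-x)
            - np.log(a)
            - special.betaln(a, b)
            + np.log(special.hyp2f1(1.0, a + b, a + 1.0, x))
            - math.log(2.0)
        )
        if out.ndim:
            out[under] = log_tail
        else:
            out = np.asarray(log_tail)
    return out


def set_weight(
    member_weights: Sequence[float],
    complement_weights: Sequence[float],
    variance: str = "welch",
    log_base: str | float = "e",
) -> SetWeightResult:
    """Competitive one-sided t-test of mean(member) > mean(complement).

    Returns the set weight ``-log p`` (log base configurable, natural by
    default), the natural-log p-value, and a degeneracy flag.  The weight
    is computed from the t distribution's log survival function, so
    arbitrarily small tail probabilities give large finite weights.
    Degenerate inputs (either group smaller than 2, or both groups with
    zero variance) yield ``SetWeightResult(nan, nan, True)``.
    """
    m = np.asarray(member_weights, dtype=float)
    c = np.asarray(complement_weights, dtype=float)
    if m.size < 2 or c.size < 2:
        return SetWeightResult(math.nan, math.nan, True)
    var_m = m.var(ddof=1)
    var_c = c.var(ddof=1)
    if var_m <= 0 and var_c <= 0:
        return SetWeightResult(math.nan, math.nan, True)
    if variance == "welch":
        t, df = _welch_from_moments(m.mean(), var_m, m.size, c.mean(), var_c, c.size)
    elif variance == "pooled":
        t, df = _pooled_from_moments(m.mean(), var_m, m.size, c.mean(), var_c, c.size)
    else:
        raise ValueError(f"variance must be 'welch' or 'pooled', got {variance!r}")
    t = float(np.asarray(t))
    df = float(np.asarray(df))
    if not np.isfinite(t) or not np.isfinite(df) or df <= 0:
        return SetWeightResult(math.nan, math.nan, True)
    log_p = float(_one_sided_log_p(t, df))
    weight = -log_p / _log_divisor(log_base)
    return SetWeightResult(weight, log_p, False)


def collection_weights(
    gw: GeneWeightMatrix,
    gsc: GeneSetCollection,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    variance: str = "welch",
    log_base: str | float = "e",
    restrict_to_measured: bool = False,
) -> SetWeightMatrix:
    """Set weights for every set in a collection, all tissues at once.

    The gene universe is the collection's universe; genes absent from the
    weight matrix receive weight 0 (unmeasured genes are treated as
    inactive, the same rule applied to missing RNA cells).  With
    ``restrict_to_measured`` the universe is instead intersected with the
    measured genes.  Sets whose usable member count falls below
    ``min_set_size`` (or whose test is degenerate in a tissue) get NaN
    and an explanatory flag.

    The tests are vectorized: per tissue, member sums and sums of squares
    for all sets come from one indicator-matrix product, and complement
    moments follow from the universe totals.
    """
    universe = gsc.universe
    if restrict_to_measured:
        measured = set(gw.genes)
        universe = [g for g in universe if g in measured]
    if not universe:
        raise ValueError("empty gene universe after intersection with measured genes")
    if variance not in ("welch", "pooled"):
        raise ValueError(f"variance must be 'welch' or 'pooled', got {variance!r}")

    tissues = gw.tissues
    # p x T weight matrix over the universe; unmeasured genes weigh 0.
    W = gw.w.reindex(index=universe).fillna(0.0).to_numpy(dtype=float)
    G = gsc.to_indicator(universe).to_numpy(dtype=float)  # g x p
    n1 = G.sum(axis=1)  # |m| per set
    p = float(len(universe))
    n2 = p - n1

    tot = W.sum(axis=0)  # per-tissue totals over the universe
    tot2 = (W**2).sum(axis=0)
    s1 = G @ W  # g x T member sums
    q1 = G @ (W**2)
    s2 = tot[None, :] - s1
    q2 = tot2[None, :] - q1

    n1c = n1[:, None]
    n2c = n2[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = s1 / n1c
        mean2 = s2 / n2c
        var1 = np.clip((q1 - n1c * mean1**2) / (n1c - 1), 0.0, None)
        var2 = np.clip((q2 - n2c * mean2**2) / (n2c - 1), 0.0, None)

    if variance == "welch":
        t, df = _welch_from_moments(mean1, var1, n1c, mean2, var2, n2c)
    else:
        t, df = _pooled_from_moments(mean1, var1, n1c, mean2, var2, n2c)

    too_small = (n1c < max(min_set_size, 2)) | (n2c < 2)
    zero_var = (var1 <= 0) & (var2 <= 0)
    bad_stat = ~np.isfinite(t) | ~np.isfinite(df) | (df <= 0)
    undefined = too_small | zero_var | bad_stat

    log_p = np.full(t.shape, np.nan)
    ok = ~undefined
    if ok.any():
        log_p[ok] = _one_sided_log_p(t[ok], np.asarray(df)[ok])
    w = -log_p / _log_divisor(log_base)

    flags = np.where(
        too_small, "too_few_members", np.where(zero_var, "zero_variance", np.where(bad_stat, "degenerate", ""))
    )
    w_df = pd.DataFrame(w, index=gsc.names, columns=tissues)
    flags_df = pd.DataFrame(flags, index=gsc.names, columns=tissues)
    n_used = pd.Series(n1.astype(int), index=gsc.names)
    n_undef = int(undefined.sum())
    if n_undef:
        logger.info("collection_weights: %d undefined set/tissue cells", n_undef)
    return SetWeightMatrix(w=w_df, n_used=n_used, flags=flags_df, log_base=log_base)


_AGGREGATORS = {"min": np.min, "mean": np.mean, "median": np.median}


def multi_tissue_weight(
    sw: SetWeightMatrix,
    tissues: Sequence[str],
    aggregator: str = "min",
) -> MultiTissueWeights:
    """Aggregate per-tissue set weights over a tissue group.

    The default aggregator is the minimum, which favors sets with at
    least a basic level of activity in every analyzed tissue; mean and
    median are available alternatives.  Sets with an undefined weight in
    any requested tissue are excluded, with the reason recorded.
    """
    tissues = list(tissues)
    if not tissues:
        raise ValueError("at least one tissue required")
    missing = [t for t in tissues if t not in sw.w.columns]
    if missing:
        raise ValueError(f"tissue(s) not in set weight matrix: {missing}")
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    sub = sw.w[tissues]
    defined = sub.notna().all(axis=1)
    excluded: dict[str, str] = {}
    for name in sub.index[~defined]:
        bad = [t for t in tissues if pd.isna(sub.at[name, t])]
        excluded[name] = f"undefined weight in {', '.join(bad)}"
        logger.info("multi_tissue_weight: excluding %s (%s)", name, excluded[name])
    agg = _AGGREGATORS[aggregator]
    w = sub[defined].apply(lambda row: agg(row.to_numpy()), axis=1)
    return MultiTissueWeights(w=w, tissues=tissues, excluded=excluded, aggregator=aggregator)
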