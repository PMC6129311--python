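"""Synthetic HPA-like data and p-value studies for testing the pipeline.

``simulate_hpa`` produces an RNA expression table, an IHC detection table
and a GMT-style gene set collection in which chosen gene sets are
"planted": their members are over-expressed by a fold multiplier in one
target tissue and guaranteed IHC-detected there.  ``simulate_pvalue_study``
produces per-set p-values under a configurable null/alternative mixture
together with raw weights whose association with the true alternatives
can be favorable, independent or adverse — the three regimes that decide
whether p-value weighting gains or loses power.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionTable, GeneSet, GeneSetCollection, IHCTable

_DETECTED_LEVELS = ("Low", "Medium", "High")


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run.

    For HPA-style simulations, ``planted`` maps each planted set name to
    its (target tissue, fold multiplier, member genes).  For p-value
    studies, ``is_alternative`` labels every generated set exactly once.
    """

    seed: int
    planted: dict[str, tuple[str, float, tuple[str, ...]]] = field(default_factory=dict)
    is_alternative: pd.Series | None = None

    def planted_in(self, tissue: str) -> list[str]:
        return [n for n, (t, _, _) in self.planted.items() if t == tissue]


def simulate_hpa(
    n_genes: int,
    tissues: Sequence[str],
    planted: Sequence[tuple[int, str, float]] = (),
    n_decoy_sets: int = 100,
    meanlog: float = 1.0,
    sdlog: float = 1.0,
    ihc_detect_prob: float = 0.7,
    ihc_rank_coupled: bool = True,
    rna_missing_rate: float = 0.0,
    ihc_missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionTable, IHCTable, GeneSetCollection, SimulationTruth]:
    """Generate an HPA-like RNA/IHC/collection triple with planted sets.

    Baseline expression is log-normal (FPKM-like right skew) per gene and
    tissue.  Each ``planted`` entry (set size, target tissue, fold
    multiplier > 1) claims a disjoint block of genes whose expression in
    the target tissue is multiplied by the fold and which are always
    IHC-detected there.  Other (gene, tissue) pairs are detected with
    probability ``ihc_detect_prob``; with ``ihc_rank_coupled`` (default)
    the probability increases with the gene's expression rank in that
    tissue, mirroring RNA-protein concordance.  The collection holds the
    planted sets plus ``n_decoy_sets`` decoys of matching sizes drawn
    uniformly (without replacement within a set, with replacement across
    sets).  ``rna_missing_rate``/``ihc_missing_rate`` blank out random
    RNA cells / IHC records to exercise the missing-data rules.
    """
    tissues = list(tissues)
    if len(tissues) < 2:
        raise ValueError("at least two tissues required")
    if len(set(tissues)) != len(tissues):
        raise ValueError("tissue names must be unique")
    for size, target, fold in planted:
        if fold <= 1:
            raise ValueError(f"fold multiplier must be > 1, got {fold}")
        if target not in tissues:
            raise ValueError(f"target tissue {target!r} not in tissue list")
        if size < 1:
            raise ValueError("planted set size must be >= 1")
    total_planted = sum(size for size, _, _ in planted)
    if total_planted > n_genes:
        raise ValueError(
            f"planted sets need {total_planted} genes but only {n_genes} exist"
        )

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    expr = rng.lognormal(mean=meanlog, sigma=sdlog, size=(n_genes, len(tissues)))

    # Disjoint planted blocks, in a random order of the gene pool.
    pool = rng.permutation(n_genes)
    truth = SimulationTruth(seed=seed)
    sets: list[GeneSet] = []
    offset = 0
    per_tissue_counter: dict[str, int] = {}
    for size, target, fold in planted:
        idx = np.sort(pool[offset : offset + size])
        offset += size
        expr[idx, tissues.index(target)] *= fold
        per_tissue_counter[target] = per_tissue_counter.get(target, 0) + 1
        name = f"PLANTED_{target.upper().replace(' ', '_')}_{per_tissue_counter[target]}"
        members = tuple(genes[i] for i in idx)
        sets.append(GeneSet(name, f"planted in {target} at fold {fold}", members))
        truth.planted[name] = (target, float(fold), members)

    # Decoy sets with sizes matched to the planted ones (or 20 if none).
    sizes = [size for size, _, _ in planted] or [20]
    for d in range(n_decoy_sets):
        size = sizes[d % len(sizes)]
        idx = np.sort(rng.choice(n_genes, size=size, replace=False))
        sets.append(
            GeneSet(f"DECOY_{d + 1:03d}", "decoy set", tuple(genes[i] for i in idx))
        )
    collection = GeneSetCollection(sets)

    # IHC detection: planted genes always detected in their target tissue.
    if ihc_rank_coupled:
        # Linear in within-tissue expression rank, centred on the base rate.
        ranks = expr.argsort(axis=0).argsort(axis=0) / max(n_genes - 1, 1)
        half_range = min(ihc_detect_prob, 1.0 - ihc_detect_prob)
        p_detect = ihc_detect_prob + (ranks - 0.5) * half_range
    else:
        p_detect = np.full_like(expr, ihc_detect_prob)
    detected = rng.random(expr.shape) < p_detect
    for name, (target, _, members) in truth.planted.items():
        t_idx = tissues.index(target)
        for g in members:
            detected[genes.index(g), t_idx] = True

    levels = np.where(
        detected,
        rng.choice(_DETECTED_LEVELS, size=expr.shape),
        "Not detected",
    )

    values = pd.DataFrame(expr, index=genes, columns=tissues)
    if rna_missing_rate > 0:
        blank = rng.random(expr.shape) < rna_missing_rate
        values = values.mask(blank)
    expr_table = ExpressionTable(values)

    rec = pd.DataFrame(
        {
            "gene": np.repeat(genes, len(tissues)),
            "tissue": np.tile(tissues, n_genes),
            "cell_type": "",
            "level": levels.ravel(),
            "reliability": "Approved",
        }
    )
    if ihc_missing_rate > 0:
        keep = rng.random(len(rec)) >= ihc_missing_rate
        rec = rec[keep].reset_index(drop=True)
    ihc_table = IHCTable(rec)

    return expr_table, ihc_table, collection, truth


def simulate_pvalue_study(
    g: int,
    pi0: float,
    alt_beta: tuple[float, float] = (0.1, 1.0),
    weight_association: str = "independent",
    weight_multiplier: float = 10.0,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, SimulationTruth]:
    """Simulate per-set p-values and raw weights for a wFDR study.

    A fraction ``pi0`` of the ``g`` sets are null with p ~ Uniform(0, 1);
    the rest are alternatives with p ~ Beta(``alt_beta``), stochastically
    small.  Raw weights are log-normal and drawn independently of the
    p-values; ``weight_association`` then couples them to the truth
    labels: "favorable" multiplies the alternatives' weights by
    ``weight_multiplier`` (weights prioritize true discoveries),
    "adverse" multiplies the nulls' instead, and "independent" leaves
    them untouched.
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError(f"pi0 must be in [0, 1], got {pi0}")
    if weight_association not in ("favorable", "independent", "adverse"):
        raise ValueError(
            "weight_association must be 'favorable', 'independent' or 'adverse'"
        )
    rng = np.random.default_rng(seed)
    names = [f"SET_{i:05d}" for i in range(1, g + 1)]
    n_alt = int(round(g * (1.0 - pi0)))
    is_alt = np.zeros(g, dtype=bool)
    is_alt[rng.choice(g, size=n_alt, replace=False)] = True

    p = rng.uniform(size=g)
    if n_alt:
        p[is_alt] = rng.beta(*alt_beta, size=n_alt)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    w = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    if weight_association == "favorable":
        w[is_alt] *= weight_multiplier
    elif weight_association == "adverse":
        w[~is_alt] *= weight_multiplier

    truth = SimulationTruth(seed=seed, is_alternative=pd.Series(is_alt, index=names))
    return pd.Series(p, index=names), pd.Series(w, index=names), truth
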