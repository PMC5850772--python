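"""Exact binomial tests for parallel evolution (recurrent gene hits).

Multiple independent clones acquiring mutations in the same gene is the
classic signature of positive selection in an evolution experiment.  For a
gene hit in ``k`` distinct clones the null probability of at least ``k``
hits is the exact binomial upper tail ``P(X >= k)``, ``X ~ Bin(n, p_hit)``,
under one of two nulls:

* ``per_mutation`` (default): each of the cohort's ``n`` total mutations
  independently lands in the gene with probability
  ``gene_length / target_length``;
* ``per_clone``: each of the ``n`` clones independently hits the gene at
  least once, with ``p_hit = 1 - (1 - gene_length/target_length)**m`` where
  ``m`` is the cohort's mean mutation count per clone.

Multiple hits within one clone count once (distinct clones).  P-values are
Benjamini–Hochberg adjusted across the genes tested (Bonferroni optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cladecall.errors import ConfigurationError


def binomial_recurrence(k: int, n: int, p_hit: float) -> float:
    """Exact upper-tail probability ``P(X >= k)`` for ``X ~ Bin(n, p_hit)``."""
    if not (0 <= k <= n):
        raise ConfigurationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p_hit <= 1.0):
        raise ConfigurationError(f"p_hit must be in [0, 1], got {p_hit}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p_hit))


RESULT_COLUMNS = ("gene", "k", "n", "p_hit", "p_value", "adjusted_p")


class RecurrenceTest:
    """Recurrence model over a cohort's mutation table.

    Parameters
    ----------
    mutations
        DataFrame with at least ``clone`` and ``gene`` columns (the tidy
        mutation-table layout of :mod:`cladecall.simulate`); ``intergenic``
        records are ignored.
    gene_lengths
        Mapping gene -> coding length in bp; required for every tested gene.
    target_length
        Total mutational target in bp (>= the largest gene length).
    null
        ``"per_mutation"`` (default) or ``"per_clone"``.
    adjust
        ``"bh"`` (default) or ``"bonferroni"``.
    min_clones
        Only genes hit in at least this many distinct clones are tested.
    """

    def __init__(
        self,
        mutations: pd.DataFrame,
        gene_lengths: Mapping[str, int],
        target_length: int,
        null: str = "per_mutation",
        adjust: str = "bh",
        min_clones: int = 2,
    ) -> None:
        if null not in ("per_mutation", "per_clone"):
            raise ConfigurationError(f"unknown null {null!r}")
        if adjust not in ("bh", "bonferroni"):
            raise ConfigurationError(f"unknown adjustment {adjust!r}")
        if gene_lengths and target_length < max(gene_lengths.values()):
            raise ConfigurationError("target_length smaller than the largest gene")
        self.mutations = mutations
        self.gene_lengths = dict(gene_lengths)
        self.target_length = int(target_length)
        self.null = null
        self.adjust = adjust
        self.min_clones = int(min_clones)

    def fit(self) -> "RecurrenceResults":
        muts = self.mutations[self.mutations["gene"] != "intergenic"]
        hit_clones = muts.groupby("gene")["clone"].nunique()
        tested = sorted(hit_clones.index[hit_clones >= self.min_clones])
        missing = [g for g in tested if g not in self.gene_lengths]
        if missing:
            raise ConfigurationError(f"no gene length for: {missing}")

        n_clones = int(self.mutations["clone"].nunique())
        n_mut = int(len(self.mutations))
        rows = []
        for gene in tested:
            frac = self.gene_lengths[gene] / self.target_length
            k = int(hit_clones[gene])
            if self.null == "per_mutation":
                n = n_mut
                p_hit = frac
            else:
                n = n_clones
                mean_per_clone = n_mut / n_clones if n_clones else 0.0
                p_hit = 1.0 - (1.0 - frac) ** mean_per_clone
            k_eff = min(k, n)  # distinct clones can exceed trials only pathologically
            rows.append((gene, k, n, p_hit, binomial_recurrence(k_eff, n, p_hit)))

        table = pd.DataFrame(
            rows, columns=["gene", "k", "n", "p_hit", "p_value"]
        )
        if len(table):
            method = "fdr_bh" if self.adjust == "bh" else "bonferroni"
            table["adjusted_p"] = multipletests(
                table["p_value"].to_numpy(), method=method
            )[1]
        else:
            table["adjusted_p"] = pd.Series(dtype=float)
        table = table.sort_values(
            ["adjusted_p", "p_value", "gene"], kind="mergesort"
        ).reset_index(drop=True)
        return RecurrenceResults(model=self, table=table)


@dataclass
class RecurrenceResults:
    """Per-gene recurrence statistics with multiplicity adjustment."""

    model: RecurrenceTest
    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adjusted_p"] <= alpha]

    def summary(self) -> str:
        lines = [
            f"Recurrent-mutation test ({self.model.null} null, "
            f"{self.model.adjust.upper()} adjustment)",
            f"  cohort: {self.model.mutations['clone'].nunique()} clones, "
            f"{len(self.model.mutations)} mutations, "
            f"target {self.model.target_length} bp",
            f"  genes tested (>= {self.model.min_clones} clones hit): "
            f"{len(self.table)}",
        ]
        for row in self.table.itertuples(index=False):
            lines.append(
                f"  {row.gene:<12s} k={row.k:<3d} n={row.n:<6d} "
                f"p_hit={row.p_hit:.3g} P={row.p_value:.3g} "
                f"adj={row.adjusted_p:.3g}"
            )
        return "\n".join(lines)
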