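"""The copy-number-ratio statistic.

A raw family count is not comparable across genomes of different sizes, so
each count is expressed relative to (a) the species' total gene count and
(b) the family's share of all genes in the data set:

    r_ij = (L_ij / L_total,i) / (N_j / N_total)

where L_ij is the copy number of family j in species i, L_total,i the
species' total gene count, N_j = sum_i L_ij and N_total = sum_i L_total,i.

The statistic is dimensionless, zero exactly when the raw count is zero, and
normalized so that for every family the L_total-weighted mean across species
equals one:  sum_i (L_total,i / N_total) * r_ij = 1.  The *unweighted* mean
equals one only when all genomes are the same size; with heterogeneous
genome sizes it can deviate from one, which is why the weighted identity is
the one asserted throughout this package.

Because N_j and N_total are computed over whatever species are present,
ratios change when the species set changes; the pipeline therefore computes
them once on the full set and subsets afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CopyNumberTable, DataError

logger = logging.getLogger(__name__)


@dataclass
class RatioMatrix:
    """Species-by-family copy-number ratios, plus the table they came from.

    ``source`` retains the raw counts so that family aggregates can re-run
    the normalization on summed counts rather than averaging ratios.
    """

    ratios: pd.DataFrame
    source: CopyNumberTable
    dropped_families: list[str]

    @property
    def species_ids(self) -> list[str]:
        return list(self.ratios.index)

    @property
    def families(self) -> list[str]:
        return list(self.ratios.columns)


def compute_ratios(table: CopyNumberTable) -> RatioMatrix:
    """Compute r_ij for every species and family in ``table``.

    Families whose column sum N_j is zero on the current species set carry no
    information and would produce 0/0; they are dropped with a log note.
    """
    if table.n_species == 0:
        raise DataError("empty table")
    totals = table.totals.to_numpy(dtype=float)
    if (totals <= 0).any():
        raise DataError("every species must have total_genes > 0")
    counts = table.counts.to_numpy(dtype=float)
    n_j = counts.sum(axis=0)
    dropped = [f for f, s in zip(table.families, n_j) if s == 0]
    if dropped:
        logger.info("dropping %d all-zero families: %s", len(dropped), ", ".join(dropped))
    keep = n_j > 0
    n_total = totals.sum()
    with np.errstate(invalid="ignore"):
        r = (counts[:, keep] / totals[:, None]) / (n_j[keep] / n_total)
    frame = pd.DataFrame(
        r, index=table.counts.index, columns=np.asarray(table.families)[keep]
    )
    return RatioMatrix(ratios=frame, source=table, dropped_families=dropped)


def mean_ratio_per_species(r: RatioMatrix | pd.DataFrame) -> pd.Series:
    """Unweighted arithmetic mean of a species' ratios across families."""
    frame = r.ratios if isinstance(r, RatioMatrix) else r
    if frame.shape[1] == 0:
        raise DataError("ratio matrix has no families")
    out = frame.mean(axis=1)
    out.name = "mean_ratio"
    return out
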