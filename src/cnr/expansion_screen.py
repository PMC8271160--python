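"""Per-family PGLS screens: life-form contrasts, growth-rate regression, and
the genome-size correlation diagnostic.

``run_family_screen`` regresses every family's copy-number ratio on life
form (trees as baseline) with Pagel's-lambda PGLS, attaches per-contrast
Storey q-values across families, and flags families whose ratio is
significantly lower in *both* herb groups than in trees — the signature of
expansion in trees.

``run_growth_screen`` regresses the ratio of selected families on the log
mean height-growth rate (m/year) within tree species, the inverse-longevity
proxy: a negative slope means slow-growing (long-lived) trees carry more
copies.  The regression direction (response = ratio, predictor = ln rate)
and the natural log are package conventions; a base-10 log would scale the
slope by ln(10).

``aggregate_family_ratio`` pools a set of paralog families by re-running the
ratio normalization on summed counts (never by averaging per-family ratios,
which weights members incorrectly when their sizes differ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CopyNumberTable, DataError, GrowthTable, Phylogeny, SpeciesRecord
from .multiplicity import qvalues
from .normalization import RatioMatrix
from .pgls import DesignMatrix, encode_lifeforms, pgls_fit, phylo_covariance

logger = logging.getLogger(__name__)

CONTRASTS = ("perennial_herb", "annual_herb")


@dataclass
class ScreenResult:
    """Per-family life-form PGLS results (the machine-readable screen table)."""

    table: pd.DataFrame
    q_threshold: float
    skipped_families: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["expanded_in_trees"]])


@dataclass
class GrowthScreenResult:
    table: pd.DataFrame
    n_species: int


def run_family_screen(
    r: RatioMatrix,
    species: list[SpeciesRecord],
    tree: Phylogeny,
    q_threshold: float = 0.05,
) -> ScreenResult:
    """PGLS of every family's ratio on life form, with per-contrast q-values.

    ``species`` must be the PGLS analysis set (algae and shrubs removed, all
    species on the tree) and must contain trees and both herb groups.
    Zero-variance families are skipped with a log note.
    """
    frame = r.ratios
    ids = [s.species_id for s in species]
    if list(frame.index) != ids:
        raise DataError("species list does not match ratio matrix rows")
    forms = {s.life_form for s in species}
    needed = {"tree", *CONTRASTS}
    if not needed <= forms:
        raise DataError(f"missing life forms for the screen: {sorted(needed - forms)}")
    X = encode_lifeforms(species, baseline="tree")
    C = phylo_covariance(tree, ids)
    rows, skipped = [], []
    for fam in frame.columns:
        y = frame[fam].to_numpy()
        if np.ptp(y) == 0:
            skipped.append(fam)
            continue
        fit = pgls_fit(y, X, C)
        row: dict[str, float] = {"lambda_hat": fit.lambda_hat,
                                 "lambda_at_boundary": fit.lambda_at_boundary}
        for con in CONTRASTS:
            i = fit.names.index(con)
            row[f"{con}_coef"] = fit.beta[i]
            row[f"{con}_se"] = fit.se[i]
            row[f"{con}_t"] = fit.t_stat[i]
            row[f"{con}_p"] = fit.p_value[i]
        rows.append(pd.Series(row, name=fam))
    if skipped:
        logger.info("skipped zero-variance families: %s", ", ".join(skipped))
    if not rows:
        raise DataError("no family with variance; nothing to screen")
    table = pd.DataFrame(rows)
    for con in CONTRASTS:
        table[f"{con}_q"] = qvalues(
            np.clip(table[f"{con}_p"].to_numpy(), 1e-300, 1.0)
        ).q_values
    table["expanded_in_trees"] = np.logical_and.reduce(
        [
            (table[f"{con}_coef"] < 0) & (table[f"{con}_q"] < q_threshold)
            for con in CONTRASTS
        ]
    )
    return ScreenResult(table=table, q_threshold=q_threshold, skipped_families=skipped)


def run_growth_screen(
    r: RatioMatrix,
    growth: GrowthTable,
    tree: Phylogeny,
    families: list[str],
    include_aggregate: bool = True,
) -> GrowthScreenResult:
    """PGLS of copy-number ratio on ln(mean growth rate) across tree species.

    One fit per requested family, plus (by default) the pooled aggregate of
    all requested families under the label "ALL".  q-values are computed
    across the tested set.
    """
    if not families:
        raise DataError("no families requested")
    missing = [f for f in families if f not in r.ratios.columns]
    if missing:
        raise DataError(f"families not in ratio matrix: {missing}")
    ids = [s for s in growth.species_ids if s in r.ratios.index]
    absent = set(growth.species_ids) - set(ids)
    if absent:
        raise DataError(f"growth species without ratios: {sorted(absent)}")
    n = len(ids)
    if n < 5:
        raise DataError(f"growth screen needs at least 5 species, got {n}")
    rates = growth.rates.loc[ids, "mean_rate"].to_numpy(dtype=float)
    if (rates <= 0).any():
        raise DataError("growth rates must be positive")
    pruned = tree.prune_to(ids)
    C = phylo_covariance(pruned, ids)
    X = DesignMatrix(
        names=["intercept", "log_growth_rate"],
        X=np.column_stack([np.ones(n), np.log(rates)]),
    )
    targets: dict[str, np.ndarray] = {
        fam: r.ratios.loc[ids, fam].to_numpy() for fam in families
    }
    if include_aggregate and len(families) > 1:
        targets["ALL"] = aggregate_family_ratio(r, families).loc[ids].to_numpy()
    rows = []
    for fam, y in targets.items():
        fit = pgls_fit(y, X, C)
        i = fit.names.index("log_growth_rate")
        rows.append(
            pd.Series(
                {
                    "n": n,
                    "coef": fit.beta[i],
                    "se": fit.se[i],
                    "t": fit.t_stat[i],
                    "p_value": fit.p_value[i],
                    "lambda_hat": fit.lambda_hat,
                    "lambda_at_boundary": fit.lambda_at_boundary,
                },
                name=fam,
            )
        )
    table = pd.DataFrame(rows)
    table["q_value"] = qvalues(
        np.clip(table["p_value"].to_numpy(), 1e-300, 1.0)
    ).q_values
    return GrowthScreenResult(table=table, n_species=n)


def aggregate_family_ratio(r: RatioMatrix, member_columns: list[str]) -> pd.Series:
    """Pooled copy-number ratio of a family set, from summed raw counts."""
    if not member_columns:
        raise DataError("empty member set")
    table: CopyNumberTable = r.source
    missing = [f for f in member_columns if f not in table.families]
    if missing:
        raise DataError(f"members not in count table: {missing}")
    counts = table.counts[member_columns].sum(axis=1).to_numpy(dtype=float)
    totals = table.totals.to_numpy(dtype=float)
    n_agg = counts.sum()
    if n_agg == 0:
        raise DataError("aggregate family has zero total count")
    n_total = totals.sum()
    vals = (counts / totals) / (n_agg / n_total)
    return pd.Series(vals, index=table.counts.index, name="+".join(member_columns))


def copy_total_correlation(table: CopyNumberTable, family: str) -> float:
    """Spearman rank correlation of raw family copy number vs total genes.

    Average ranks for ties.  A constant copy-number column has no rank
    ordering; NaN is returned with a warning.
    """
    if family not in table.families:
        raise DataError(f"unknown family {family!r}")
    if table.n_species < 3:
        raise DataError("need at least 3 species for a rank correlation")
    counts = table.counts[family].to_numpy(dtype=float)
    totals = table.totals.to_numpy(dtype=float)
    if np.ptp(counts) == 0 or np.ptp(totals) == 0:
        logger.warning("constant column; Spearman correlation undefined")
        return float("nan")
    rho = stats.spearmanr(counts, totals).statistic
    return float(rho)
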