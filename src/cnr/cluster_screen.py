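"""Species clustering on ratio profiles and the associated screening tests.

Species are clustered hierarchically on the Euclidean distance between their
copy-number-ratio profiles using Ward's criterion (Ward.D2: merge the pair
of clusters minimizing the increase in total within-cluster sum of squares).
Each cluster is then screened two ways:

* life-form enrichment: for every (cluster, life form) pair, a two-sided
  Fisher's exact test on the 2x2 membership table, with the point-probability
  two-sided convention (sum all hypergeometric outcomes no more probable than
  the observed one);
* mean-ratio shift: a one-sample two-sided t test of the cluster's
  per-species mean ratios against 1, the all-species expectation under the
  normalization.

Both sets of p-values receive Storey q-values (which reduce to
Benjamini-Hochberg at these small test counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_io import DataError, SpeciesRecord, LIFE_FORMS
from .multiplicity import qvalues
from .normalization import RatioMatrix, mean_ratio_per_species

logger = logging.getLogger(__name__)


@dataclass
class ClusterReport:
    k: int
    assignment: pd.Series
    enrichment: pd.DataFrame
    mean_tests: pd.DataFrame


def _as_frame(r) -> pd.DataFrame:
    return r.ratios if isinstance(r, RatioMatrix) else r


def ward_cluster(r, k: int, criterion: str = "ward_d2") -> pd.Series:
    """Cut a Ward dendrogram of species ratio profiles into k clusters.

    Rows are sorted by species id before linkage, so the partition does not
    depend on input order; cluster ids (1..k) are assigned in order of first
    appearance along the canonical ordering.  ``criterion`` may be "ward_d2"
    (default, textbook Ward on Euclidean distances) or "ward_d" (the variant
    that applies the Ward recurrence to unsquared distances) for sensitivity
    checks.
    """
    frame = _as_frame(r)
    n = frame.shape[0]
    if frame.shape[1] < 1:
        raise DataError("ratio matrix has no families")
    if not 1 <= k <= n:
        raise DataError(f"k must lie in [1, {n}], got {k}")
    canon = frame.sort_index()
    if criterion == "ward_d2":
        Z = hierarchy.linkage(canon.to_numpy(), method="ward")
    elif criterion == "ward_d":
        # Ward.D on d is Ward.D2 on sqrt(d): same merge sequence, other heights.
        Z = hierarchy.linkage(np.sqrt(pdist(canon.to_numpy())), method="ward")
    else:
        raise DataError(f"unknown criterion {criterion!r}")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    out = pd.Series([relabel[lab] for lab in raw], index=canon.index, name="cluster")
    return out.loc[frame.index]


def fisher_enrichment(
    assignment: pd.Series, species: list[SpeciesRecord]
) -> pd.DataFrame:
    """Two-sided Fisher enrichment of each life form in each cluster.

    Returns one row per (cluster, life form present): the 2x2 table
    [in-cluster & form, in-cluster & other; out-cluster & form, out-cluster &
    other], the odds ratio, p and q.  Life forms absent from the data are
    skipped with a log note.
    """
    forms = pd.Series({s.species_id: s.life_form for s in species})
    forms = forms.loc[assignment.index]
    if len(forms) < 2:
        raise DataError("need at least 2 species for enrichment tests")
    present = [f for f in LIFE_FORMS if (forms == f).any()]
    skipped = [f for f in LIFE_FORMS if f not in present]
    if skipped:
        logger.info("life forms absent from data, skipped: %s", ", ".join(skipped))
    if len(present) < 2:
        logger.warning("fewer than 2 life forms present; no enrichment tests run")
        return pd.DataFrame(
            columns=["cluster", "life_form", "a", "b", "c", "d", "odds_ratio",
                     "p_value", "q_value"]
        )
    rows = []
    for cl in sorted(assignment.unique()):
        in_cl = assignment == cl
        for form in present:
            is_form = forms == form
            a = int((in_cl & is_form).sum())
            b = int((in_cl & ~is_form).sum())
            c = int((~in_cl & is_form).sum())
            d = int((~in_cl & ~is_form).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append((cl, form, a, b, c, d, odds, p))
    df = pd.DataFrame(
        rows, columns=["cluster", "life_form", "a", "b", "c", "d", "odds_ratio",
                       "p_value"]
    )
    df["q_value"] = qvalues(np.clip(df["p_value"].to_numpy(), 1e-300, 1.0)).q_values
    return df


def cluster_mean_test(r, assignment: pd.Series, mu0: float = 1.0) -> pd.DataFrame:
    """One-sample t tests of per-cluster mean copy-number ratios against mu0.

    The unit of observation is a species' mean ratio across families.
    Singleton clusters are reported untested (NaN statistics); a zero-variance
    cluster gets t = +/-inf with p = 0 and a flag.
    """
    means = mean_ratio_per_species(_as_frame(r))
    means = means.loc[assignment.index]
    rows = []
    for cl in sorted(assignment.unique()):
        vals = means[assignment == cl].to_numpy()
        n = vals.size
        if n < 2:
            rows.append((cl, n, float(vals.mean()), np.nan, np.nan, np.nan, False))
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            delta = vals.mean() - mu0
            t = 0.0 if delta == 0 else np.inf * np.sign(delta)
            p = 1.0 if delta == 0 else 0.0
            rows.append((cl, n, float(vals.mean()), float(t), n - 1, float(p), True))
            continue
        t, p = stats.ttest_1samp(vals, popmean=mu0)
        rows.append((cl, n, float(vals.mean()), float(t), n - 1, float(p), False))
    df = pd.DataFrame(
        rows, columns=["cluster", "n", "mean", "t", "df", "p_value", "zero_variance"]
    )
    tested = df["p_value"].notna()
    df["q_value"] = np.nan
    if tested.any():
        df.loc[tested, "q_value"] = qvalues(
            np.clip(df.loc[tested, "p_value"].to_numpy(), 1e-300, 1.0)
        ).q_values
    return df


def cluster_report(r, species: list[SpeciesRecord], k: int = 4,
                   criterion: str = "ward_d2") -> ClusterReport:
    """Run clustering plus both screens and bundle the results."""
    assignment = ward_cluster(r, k, criterion=criterion)
    return ClusterReport(
        k=k,
        assignment=assignment,
        enrichment=fisher_enrichment(assignment, species),
        mean_tests=cluster_mean_test(r, assignment),
    )
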