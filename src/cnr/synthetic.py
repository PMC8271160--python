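"""Synthetic data with the statistical structure the pipeline assumes.

The generator produces, from one master seed, a complete input bundle: an
ultrametric Yule phylogeny of unit height; phylogenetically clumped life
forms (a Brownian liability thresholded at quantiles); a species-by-family
copy-number matrix emitted from a latent Gaussian process on the tree
(``counts = round(exp(z))`` with z ~ MVN(mu_j + life-form effect,
sigma^2 V(lambda_true))); heterogeneous genome totals (log-normal,
independent of the families); and, for tree species, growth rates inversely
coupled to a designated "planted" family's ratio.

The latent-Gaussian count emission is deliberately the linear-Gaussian model
PGLS assumes, so parameter recovery on these data is a meaningful check of
the estimator; a birth-death gain/loss emitter is out of scope.  Stage-
specific random substreams are spawned from the master seed, so adding a
stage never perturbs earlier draws and one seed fixes every output
bit-exactly.

Defaults mirror the reference comparative study design: 59 species
(23 trees, 15 perennial herbs, 21 annual herbs), 121 gene families of
2-6 mean copies, one planted tree-expanded family with a -0.5 latent herb
offset, lambda = 0.5, and genome totals around 30k genes (CV 0.2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CopyNumberTable,
    DataError,
    GrowthTable,
    Phylogeny,
    SpeciesRecord,
    write_copy_number_table,
    write_growth_table,
    write_species_table,
)
from .pgls import lambda_transform, phylo_covariance


@dataclass
class SimConfig:
    """Tunable knobs of the generator (defaults = study-like conditions)."""

    n_species: int = 59
    n_families: int = 121
    seed: int = 0
    lambda_true: float = 0.5
    herb_effect: float = -0.5      # latent log-scale offset of both herb groups
    sigma: float = 0.15            # residual scale of the latent process
    planted_families: tuple[int, ...] = (0,)
    base_copy_low: float = 2.0     # family baseline mean copies ~ logU[low, high]
    base_copy_high: float = 6.0
    planted_base_copy: float = 3.0
    genome_mean: float = 30000.0
    genome_cv: float = 0.2
    growth_slope: float = 0.7      # b in  ln g = a - b * r_planted + noise
    growth_noise: float = 0.1
    growth_mean_rate: float = 0.5  # target mean growth rate, m/year
    growth_spread_frac: float = 0.2
    lifeform_props: tuple[float, float, float] = (23 / 59, 15 / 59, 21 / 59)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DataError("sigma must be positive")
        if abs(sum(self.lifeform_props) - 1.0) > 1e-9:
            raise DataError("lifeform_props must sum to 1")


@dataclass
class SimBundle:
    """One simulated data set plus the ground truth that generated it."""

    species: list[SpeciesRecord]
    table: CopyNumberTable
    tree: Phylogeny
    growth: GrowthTable
    truth: dict = field(default_factory=dict)


_FORMS = ("tree", "perennial_herb", "annual_herb")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def simulate_tree(n: int, seed_or_rng) -> Phylogeny:
    """Yule (pure-birth) topology, rescaled to root-to-tip height 1.

    Starts from the crown (two lineages); waiting times are exponential with
    rate equal to the current lineage count; the present is one extra
    waiting time after the n-th lineage appears, so every pendant edge has
    positive length.
    """
    if n < 2:
        raise DataError("need at least 2 tips")
    rng = _as_rng(seed_or_rng)
    next_id = [0]

    def new_node(birth: float) -> dict:
        node = {"birth": birth, "children": [], "label": None}
        return node

    t = 0.0
    root = new_node(0.0)
    left, right = new_node(0.0), new_node(0.0)
    root["children"] = [left, right]
    active = [left, right]
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active[i]
        a, b = new_node(t), new_node(t)
        node["children"] = [a, b]
        node["death"] = t
        active[i] = a
        active.append(b)
    t += rng.exponential(1.0 / n)
    height = t
    labels = iter(f"S{i + 1:03d}" for i in range(n))

    def newick(node: dict) -> str:
        if not node["children"]:
            length = (height - node["birth"]) / height
            return f"{next(labels)}:{length:.12f}"
        length = (node.get("death", height) - node["birth"]) / height
        inner = ",".join(newick(c) for c in node["children"])
        return f"({inner}):{length:.12f}"

    inner = ",".join(newick(c) for c in root["children"])
    return Phylogeny.from_newick_string(f"({inner}):0.0;")


def simulate_lifeforms(tree: Phylogeny, props, seed_or_rng) -> pd.Series:
    """Phylogenetically clumped life-form labels via a Brownian liability.

    A zero-mean Brownian trait is simulated on the tree; species are sorted
    by liability and cut at quantiles so the three group sizes match
    ``props`` exactly (largest-remainder rounding).  Low liabilities become
    trees, then perennial herbs, then annual herbs, which makes whole clades
    share a habit, as in real data.
    """
    props = np.asarray(props, dtype=float)
    if props.size != 3 or abs(props.sum() - 1.0) > 1e-9:
        raise DataError("props must be 3 proportions summing to 1")
    rng = _as_rng(seed_or_rng)
    tips = tree.tip_labels
    n = len(tips)
    C = phylo_covariance(tree, tips).matrix
    liability = _mvn(rng, np.zeros(n), C)
    counts = _largest_remainder(props, n)
    order = np.argsort(liability, kind="stable")
    labels = np.empty(n, dtype=object)
    start = 0
    for form, cnt in zip(_FORMS, counts):
        labels[order[start : start + cnt]] = form
        start += cnt
    return pd.Series(labels, index=tips, name="life_form")


def simulate_counts(
    tree: Phylogeny, labels: pd.Series, cfg: SimConfig, seed_or_rng=None
) -> CopyNumberTable:
    """Emit the copy-number matrix and genome totals from the latent model."""
    rng = _as_rng(cfg.seed if seed_or_rng is None else seed_or_rng)
    tips = tree.tip_labels
    n = len(tips)
    if set(labels.index) != set(tips):
        raise DataError("labels do not match tree tips")
    labels = labels.loc[tips]
    bad = [i for i in cfg.planted_families if not 0 <= i < cfg.n_families]
    if bad:
        raise DataError(f"planted family index out of range: {bad}")
    V = lambda_transform(phylo_covariance(tree, tips), cfg.lambda_true).matrix
    Lchol = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    herb = labels.isin(["perennial_herb", "annual_herb"]).to_numpy()
    base = np.exp(
        rng.uniform(
            np.log(cfg.base_copy_low), np.log(cfg.base_copy_high), cfg.n_families
        )
    )
    base[list(cfg.planted_families)] = cfg.planted_base_copy
    counts = np.zeros((n, cfg.n_families), dtype=np.int64)
    for j in range(cfg.n_families):
        mu = np.full(n, np.log(base[j]))
        if j in cfg.planted_families:
            mu = mu + np.where(herb, cfg.herb_effect, 0.0)
        z = mu + cfg.sigma * (Lchol @ rng.standard_normal(n))
        counts[:, j] = np.maximum(np.round(np.exp(z)), 0).astype(np.int64)
    s = np.sqrt(np.log1p(cfg.genome_cv**2))
    totals = np.round(
        np.exp(rng.normal(np.log(cfg.genome_mean) - 0.5 * s * s, s, size=n))
    ).astype(np.int64)
    totals = np.maximum(totals, counts.sum(axis=1))  # inflate so sums fit
    species = [
        SpeciesRecord(tip, labels[tip], int(tot)) for tip, tot in zip(tips, totals)
    ]
    frame = pd.DataFrame(
        counts, index=tips, columns=[f"fam{j + 1:03d}" for j in range(cfg.n_families)]
    )
    return CopyNumberTable(species=species, counts=frame)


def simulate_growth(
    labels: pd.Series, planted_ratio: pd.Series, cfg: SimConfig, seed_or_rng=None
) -> GrowthTable:
    """Growth rates for tree species, anti-coupled to the planted ratio.

    ln g_i = a - b * r_i + eps,  b = cfg.growth_slope, eps ~ N(0, noise^2);
    the intercept a centers the mean rate near cfg.growth_mean_rate.  Min and
    max rates bracket the mean by +/- growth_spread_frac * mean.
    """
    rng = _as_rng(cfg.seed if seed_or_rng is None else seed_or_rng)
    trees = labels.index[labels == "tree"]
    if len(trees) == 0:
        raise DataError("no tree species to assign growth rates")
    r = planted_ratio.loc[trees].to_numpy(dtype=float)
    a = np.log(cfg.growth_mean_rate) + cfg.growth_slope * float(r.mean())
    lng = a - cfg.growth_slope * r
    if cfg.growth_noise > 0:
        lng = lng + rng.normal(0.0, cfg.growth_noise, size=len(trees))
    g = np.exp(lng)
    df = pd.DataFrame(
        {
            "mean_rate": g,
            "min_rate": g * (1.0 - cfg.growth_spread_frac),
            "max_rate": g * (1.0 + cfg.growth_spread_frac),
        },
        index=pd.Index(trees, name="species_id"),
    )
    return GrowthTable(rates=df)


def simulate_bundle(cfg: SimConfig | None = None) -> SimBundle:
    """Run every stage from one master seed and return the full bundle."""
    cfg = cfg or SimConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    tree = simulate_tree(cfg.n_species, np.random.default_rng(streams[0]))
    labels = simulate_lifeforms(
        tree, cfg.lifeform_props, np.random.default_rng(streams[1])
    )
    table = simulate_counts(tree, labels, cfg, np.random.default_rng(streams[2]))
    from .normalization import compute_ratios

    ratios = compute_ratios(table)
    planted_names = [table.families[i] for i in cfg.planted_families]
    first = planted_names[0]
    if first in ratios.ratios.columns:
        planted_ratio = ratios.ratios[first]
    else:  # planted family all-zero (vanishingly unlikely at defaults)
        planted_ratio = pd.Series(0.0, index=table.counts.index)
    growth = simulate_growth(
        labels, planted_ratio, cfg, np.random.default_rng(streams[3])
    )
    truth = {
        "config": asdict(cfg),
        "planted_families": planted_names,
        "lambda_true": cfg.lambda_true,
        "herb_effect": cfg.herb_effect,
        "growth_slope": cfg.growth_slope,
        "lifeform_counts": labels.value_counts().to_dict(),
    }
    return SimBundle(
        species=table.species, table=table, tree=tree, growth=growth, truth=truth
    )


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write species.tsv, counts.tsv, tree.nwk, growth.tsv and truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_species_table(bundle.species, out / "species.tsv")
    write_copy_number_table(bundle.table, out / "counts.tsv")
    bundle.tree.write(out / "tree.nwk")
    write_growth_table(bundle.growth, out / "growth.tsv")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _mvn(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    return mean + L @ rng.standard_normal(mean.size)


def _largest_remainder(props: np.ndarray, n: int) -> np.ndarray:
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts
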