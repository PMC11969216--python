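"""Synthetic trees and trait tables with known ground truth.

Generates data with the statistical structure the comparative analysis
assumes: an ultrametric pure-birth (Yule) phylogeny, log10 generation time
evolving by Brownian motion on that tree, and log10 per-year mutation rate
equal to a linear function of log10 generation time plus an independent
Brownian residual.  Optional independent normal measurement error can be
injected into the observed log10 generation time; the per-generation rate
written to the table is always consistent with the TRUE generation time,
so the injected error propagates into mu_y exactly as a real measurement
error in the denominator of mu_G / GT would.

Default parameter choices mirror the study conditions the package targets
(133 species in 9 taxonomic groups, log-log slope -0.71) — see
docs/methods.md for the rationale behind the Brownian rates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .phylo import leaf_names, parse_newick

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_brownian",
    "simulate_traits",
    "generate_dataset",
    "write_fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    n_species: int = 133
    birth_rate: float = 1.0  # Yule speciation rate per unit time
    true_slope: float = -0.71  # log10 mu_y per log10 year
    true_intercept: float = -8.5  # log10 mu_y at GT = 1 year
    sigma2_bm: float = 0.075  # Brownian rate of the residual process
    sigma2_gt_bm: float = 0.15  # Brownian rate of log10 GT
    gt_error_sd: float = 0.0  # SD of injected error on observed log10 GT
    root_log10_gt: float = 0.0  # root state: GT = 1 year
    n_groups: int = 9
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise AnalysisError("n_species must be >= 3")
        if self.birth_rate <= 0:
            raise AnalysisError("birth_rate must be > 0")
        if min(self.sigma2_bm, self.sigma2_gt_bm, self.gt_error_sd) < 0:
            raise AnalysisError("variances must be >= 0")
        if not 1 <= self.n_groups <= self.n_species:
            raise AnalysisError("need 1 <= n_groups <= n_species")


@dataclass(frozen=True)
class SyntheticDataset:
    tree: object  # dendropy.Tree
    table: pd.DataFrame  # observed columns + *_true truth columns
    truth: GeneratorConfig

    def rates_table(self):
        """Observed columns as a validated RatesTable with derived rates."""
        from . import trait_table

        tbl = trait_table.RatesTable(
            self.table[["species", "mu_g", "generation_time", "group"]].copy()
        )
        return trait_table.compute_mu_y(tbl)


def simulate_yule_tree(n_species: int, birth_rate: float, rng):
    """Ultrametric pure-birth tree with ``n_species`` extant tips.

    Lineages split at rate ``birth_rate`` each; after the (n-1)th split one
    further exponential waiting time is appended so terminal branches are
    strictly positive.  ``rng`` is a seed or a numpy Generator.  Returns a
    dendropy tree with tips labelled sp0001..spNNNN.
    """
    if n_species < 2:
        raise AnalysisError("a tree needs at least 2 tips")
    rng = np.random.default_rng(rng)
    return parse_newick(_simulate_yule_newick(n_species, birth_rate, rng))


class _Node:
    __slots__ = ("birth", "children", "label", "end")

    def __init__(self, birth: float):
        self.birth = birth  # time the lineage's pendant edge starts
        self.children: list["_Node"] = []
        self.label: str | None = None
        self.end: float | None = None  # split time (internal) or present (tip)

    def newick(self) -> str:
        length = self.end - self.birth
        if self.label is not None:
            return f"{self.label}:{length!r}"
        inner = ",".join(ch.newick() for ch in self.children)
        return f"({inner}):{length!r}"


def _simulate_yule_newick(n_species: int, birth_rate: float, rng) -> str:
    # crown start: two lineages at time 0, so there is no stem edge
    left, right = _Node(0.0), _Node(0.0)
    tips = [left, right]
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        idx = int(rng.integers(len(tips)))
        node = tips[idx]
        node.end = t
        a, b = _Node(t), _Node(t)
        node.children = [a, b]
        tips[idx] = a
        tips.append(b)
    t += rng.exponential(1.0 / (birth_rate * len(tips)))
    for i, tip in enumerate(tips):
        tip.label = f"sp{i + 1:04d}"
        tip.end = t
    return f"({left.newick()},{right.newick()});"


def simulate_brownian(tree, rate: float, rng, root_state: float = 0.0) -> dict[str, float]:
    """Brownian motion on the tree; returns tip label -> value.

    Increments along each branch are Normal(0, rate * branch length),
    independent across branches; the root edge (if any) is included.
    """
    values = {}
    root = tree.seed_node
    root_len = root.edge.length or 0.0
    values[root] = root_state + (
        rng.normal(0.0, np.sqrt(rate * root_len)) if rate > 0 and root_len > 0 else 0.0
    )
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(rate * bl)) if rate > 0 and bl > 0 else 0.0
        values[node] = values[node.parent_node] + step
    return {lf.taxon.label: values[lf] for lf in tree.leaf_node_iter()}


def _group_labels(n: int, n_groups: int) -> list[str]:
    # contiguous leaf blocks, so groups are clades-ish, mimicking taxonomy
    sizes = np.full(n_groups, n // n_groups)
    sizes[: n % n_groups] += 1
    labels = []
    for g, size in enumerate(sizes):
        labels.extend([f"group_{g + 1:02d}"] * size)
    return labels


def simulate_traits(tree, config: GeneratorConfig, rng) -> SyntheticDataset:
    """Simulate a trait table on an existing tree under ``config``."""
    rng = np.random.default_rng(rng)
    names = leaf_names(tree)
    n = len(names)
    gt_true = simulate_brownian(tree, config.sigma2_gt_bm, rng, config.root_log10_gt)
    resid = simulate_brownian(tree, config.sigma2_bm, rng, 0.0)
    log10_gt_true = np.array([gt_true[nm] for nm in names])
    log10_mu_y_true = (
        config.true_intercept
        + config.true_slope * log10_gt_true
        + np.array([resid[nm] for nm in names])
    )
    err = rng.normal(0.0, config.gt_error_sd, n) if config.gt_error_sd > 0 else np.zeros(n)
    log10_gt_obs = log10_gt_true + err
    # mu_G is consistent with the TRUE generation time; the observed table
    # column carries the (possibly error-laden) generation time
    mu_g = 10.0 ** (log10_mu_y_true + log10_gt_true)
    table = pd.DataFrame(
        {
            "species": names,
            "mu_g": mu_g,
            "generation_time": 10.0**log10_gt_obs,
            "group": _group_labels(n, config.n_groups),
            "log10_gt_true": log10_gt_true,
            "log10_mu_y_true": log10_mu_y_true,
        }
    )
    return SyntheticDataset(tree=tree, table=table, truth=config)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Tree + traits from a single seeded generator run."""
    rng = np.random.default_rng(config.seed)
    tree = parse_newick(_simulate_yule_newick(config.n_species, config.birth_rate, rng))
    return simulate_traits(tree, config, rng)


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write table (TSV), tree (Newick) and truth (JSON) into ``out_dir``.

    The files round-trip through read_species_table / parse_newick; the
    fixture regenerates byte-identically from the recorded config (floats
    are serialized with repr precision).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "table.tsv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    cols = ["species", "mu_g", "generation_time", "group", "log10_gt_true", "log10_mu_y_true"]
    with open(paths["table"], "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in dataset.table.iterrows():
            fh.write(
                "\t".join(
                    str(row[c]) if c in ("species", "group") else repr(float(row[c]))
                    for c in cols
                )
                + "\n"
            )
    with open(paths["tree"], "w") as fh:
        fh.write(
            dataset.tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            )
        )
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(dataset.truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
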