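"""Report assembly and the end-to-end analysis pipeline.

``run_full_analysis`` chains the pipeline stages — trait table ingestion,
tree matching, global PGLS, per-group PGLS, mixed-model comparison, and
the generation-time error sweep — and writes a machine-readable JSON
report plus human-readable tables.  The error sweep is self-calibrating:
the fixed total variance of observed log generation time and the target
slope are both taken from the data under analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata, resources
from pathlib import Path

import numpy as np

from . import error_sim, pglmm, pgls, phylo, trait_table
from .errors import ConfigurationError, MutclockError

log = logging.getLogger(__name__)

try:
    __version__ = metadata.version("mutclock")
except metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


@dataclass
class RunConfig:
    table_path: str
    tree_path: str
    out_dir: str
    column_map: dict = field(default_factory=dict)
    lam: float | str = 1.0  # Pagel's lambda, or "ml"
    min_group_n: int = 3
    error_sim_replicates: int = 100
    error_sim_grid_max: float = 4.0
    error_sim_grid_step: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for p in (self.table_path, self.tree_path):
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
        if self.min_group_n < 3:
            raise ConfigurationError("min_group_n must be >= 3")


def _sig_mark(p: float) -> str:
    if p < 0.01:
        return "b"
    if p < 0.05:
        return "a"
    return ""


def _fmt_p(p: float) -> str:
    return f"{p:.4f}" if p >= 1e-4 else f"{p:.2e}"


def render_fit_summary(fit: pgls.RegressionFit) -> str:
    lines = [
        f"PGLS fit (lambda = {fit.lam:g}, n = {fit.n})",
        f"  slope     = {fit.slope:.2f}  (SE {fit.standard_errors[1]:.3f}, "
        f"P = {_fmt_p(float(fit.p_values[1]))})",
        f"  intercept = {fit.intercept:.2f}  (SE {fit.standard_errors[0]:.3f})",
        f"  adjusted R^2 = {fit.adjusted_r2:.2f}",
        f"  doubling generation time changes mu_y by "
        f"-{pgls.doubling_effect(fit.slope):.0f}%",
    ]
    return "\n".join(lines)


def render_group_table(group_table) -> str:
    """Per-group PGLS table: group, n, slope (2 dp), P, adj R^2 (2 dp),
    with significance marks a (P < 0.05) and b (P < 0.01)."""
    if len(group_table) == 0:
        raise MutclockError("empty group table")
    header = f"{'group':<16}{'n':>5}  {'slope':>7}  {'P-value':>10}  {'adj R2':>7}"
    lines = [header, "-" * len(header)]
    for _, row in group_table.iterrows():
        mark = _sig_mark(row["p_value"])
        lines.append(
            f"{row['group']:<16}{row['n']:>5}  {row['slope']:>7.2f}  "
            f"{_fmt_p(row['p_value']):>9}{mark:<1}  {row['adjusted_r2']:>7.2f}"
        )
    return "\n".join(lines)


def render_sweep_summary(sweep: error_sim.SweepResult) -> str:
    lines = [
        "Generation-time error sweep "
        f"(n = {sweep.config.n_species}, {sweep.config.n_replicates} replicates/point)",
        f"  target slope: {sweep.target_slope:.2f}",
        f"  Monte-Carlo crossing ratio (error var / systematic var): "
        f"{sweep.crossing_ratio:.2f}",
        f"  analytic crossing ratio: {sweep.analytic_crossing_ratio:.2f}",
    ]
    return "\n".join(lines)


REPORT_REQUIRED_KEYS = {
    "version": str,
    "seed": int,
    "config": dict,
    "data": dict,
    "global_fit": dict,
    "groups": list,
    "model_comparison": dict,
    "error_sweep": dict,
}


def validate_report(report: dict) -> None:
    """Structural check of a report against the shipped JSON schema.

    The schema (schemas/report.schema.json) documents the layout; this
    checker enforces the required keys and their container types.
    """
    for key, typ in REPORT_REQUIRED_KEYS.items():
        if key not in report:
            raise MutclockError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise MutclockError(f"report key {key!r} must be {typ.__name__}")


def report_schema() -> dict:
    with resources.files("mutclock").joinpath("schemas/report.schema.json").open() as fh:
        return json.load(fh)


def _fit_dict(fit: pgls.RegressionFit) -> dict:
    return {
        "coefficients": {"intercept": fit.intercept, "slope": fit.slope},
        "standard_errors": {
            "intercept": float(fit.standard_errors[0]),
            "slope": float(fit.standard_errors[1]),
        },
        "p_values": {
            "intercept": float(fit.p_values[0]),
            "slope": float(fit.p_values[1]),
        },
        "adjusted_r2": fit.adjusted_r2,
        "residual_variance": fit.residual_variance,
        "lambda": fit.lam,
        "n": fit.n,
        "df_residual": fit.df_residual,
        "log_likelihood": fit.log_likelihood,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``config.out_dir``.

    Returns the report dictionary.  Partial outputs are removed if any
    stage fails.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        stage = "trait_table"
        table = trait_table.read_species_table(config.table_path, config.column_map)
        n_read, n_rejected = table.n, len(table.rejects)
        table = trait_table.compute_mu_y(table)
        stage = "phylo"
        tree = phylo.read_newick(config.tree_path)
        table, tree, dropped = trait_table.match_to_tree(table, tree)
        if not phylo.is_ultrametric(tree, 1e-3):
            log.warning("tree is not ultrametric to 0.1%%; check time calibration")
        log.info(
            "read %d species (%d rejected); %d matched to tree, %d dropped",
            n_read, n_rejected, table.n, len(dropped),
        )
        C = phylo.brownian_vcv(tree)
        y = table.data["log10_mu_y"].to_numpy()
        x = table.data["log10_gt"].to_numpy()
        groups = table.data["group"].to_numpy()

        stage = "pgls"
        gfit = pgls.fit_pgls(y, x, C, lam=config.lam)
        group_table, skipped, _ = pgls.fit_groups(
            table, tree, min_n=config.min_group_n, lam=config.lam
        )

        stage = "pglmm"
        fits = [
            (name, pglmm.fit_pglmm(y, x, groups, C, formula=name))
            for name in ("base", "group", "interaction")
            if name == "base" or len(set(groups)) >= 2
        ]
        comparison = pglmm.compare_models(
            fits,
            nested_pairs=[(a, b) for (a, _), (b, _) in zip(fits, fits[1:])],
        )

        stage = "error_sim"
        sim_cfg = error_sim.ErrorSimConfig(
            n_species=table.n,
            n_replicates=config.error_sim_replicates,
            var_log_gt_obs=float(np.var(x, ddof=1)),
            var_log_mu_y_true=float(np.var(y, ddof=1)),
            ratio_grid=np.arange(
                0.0, config.error_sim_grid_max + 1e-9, config.error_sim_grid_step
            ),
            seed=config.seed,
        )
        sweep = error_sim.run_sweep(sim_cfg, target_slope=gfit.slope)

        stage = "report"
        report = {
            "version": __version__,
            "seed": config.seed,
            "config": {
                **{k: v for k, v in dataclasses.asdict(config).items()},
            },
            "data": {
                "n_read": n_read,
                "n_rejected": n_rejected,
                "n_matched": table.n,
                "dropped_from_tree": dropped,
            },
            "global_fit": {
                **_fit_dict(gfit),
                "doubling_effect_percent": pgls.doubling_effect(gfit.slope),
            },
            "groups": group_table.to_dict(orient="records"),
            "groups_skipped": [{"group": g, "n": n} for g, n in skipped],
            "model_comparison": {
                "aic": comparison.table,
                "lrt": [
                    {**d, "pair": list(d["pair"])} for d in comparison.lrt
                ],
            },
            "error_sweep": {
                "config": {
                    "n_species": sim_cfg.n_species,
                    "n_replicates": sim_cfg.n_replicates,
                    "var_log_gt_obs": sim_cfg.var_log_gt_obs,
                    "var_log_mu_y_true": sim_cfg.var_log_mu_y_true,
                    "ratio_grid": [float(r) for r in sim_cfg.ratio_grid],
                    "seed": sim_cfg.seed,
                },
                "target_slope": sweep.target_slope,
                "crossing_ratio": sweep.crossing_ratio,
                "analytic_crossing_ratio": sweep.analytic_crossing_ratio,
                "grid": sweep.grid.to_dict(orient="records"),
            },
        }
        validate_report(report)

        paths = {
            "report": out / "report.json",
            "groups": out / "groups.tsv",
            "sweep": out / "sweep.tsv",
            "summary": out / "summary.txt",
            "tree": out / "pruned_tree.nwk",
            "table": out / "rates_table.tsv",
            "rejects": out / "rejects.tsv",
        }
        written.extend(paths.values())
        with open(paths["report"], "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        group_table.to_csv(paths["groups"], sep="\t", index=False)
        sweep.grid.to_csv(paths["sweep"], sep="\t", index=False)
        phylo.write_newick(tree, paths["tree"])
        trait_table.write_rates_table(table, paths["table"], paths["rejects"])
        summary = "\n\n".join(
            [
                f"mutclock {__version__} (seed {config.seed})",
                render_fit_summary(gfit),
                render_group_table(group_table) if len(group_table) else "(no group fits)",
                render_sweep_summary(sweep),
            ]
        )
        with open(paths["summary"], "w") as fh:
            fh.write(summary + "\n")
        return report
    except MutclockError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
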