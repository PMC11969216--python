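"""Species trait table: ingestion, validation, per-year rate computation,
and reconciliation with a phylogeny.

A table row holds, per species, the germline mutation rate per site per
generation (mu_g), the generation time in years, and a taxonomic group
label.  The per-year mutation rate is mu_y = mu_g / generation_time; all
downstream regressions operate on log10(mu_y) and log10(generation time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError, ValidationError
from . import phylo

log = logging.getLogger(__name__)

#: canonical column names of a rates table
CANONICAL_COLUMNS = ("species", "mu_g", "generation_time", "group")
DERIVED_COLUMNS = ("mu_y", "log10_mu_y", "log10_gt")


@dataclass
class RatesTable:
    """Validated species trait table.

    data
        One row per species with at least the canonical columns; derived
        columns are added by :func:`compute_mu_y`.
    rejects
        Rows excluded during ingestion, with a ``reason`` column.
    """

    data: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=[*CANONICAL_COLUMNS, "reason"])
    )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    def require_derived(self) -> None:
        if not set(DERIVED_COLUMNS) <= set(self.data.columns):
            raise AnalysisError("derived rate columns missing; call compute_mu_y first")


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw frame into (valid rows, rejects-with-reason)."""
    df = df.copy()
    df["species"] = df["species"].astype(str).str.strip()
    for col in ("mu_g", "generation_time"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    reasons = pd.Series("", index=df.index)
    reasons[df["species"] == ""] = "empty species name"
    reasons[(reasons == "") & df["mu_g"].isna()] = "missing mutation rate"
    reasons[(reasons == "") & df["generation_time"].isna()] = "missing generation time"
    reasons[(reasons == "") & (df["mu_g"] <= 0)] = "non-positive mutation rate"
    reasons[(reasons == "") & (df["generation_time"] <= 0)] = "non-positive generation time"
    bad = reasons != ""
    rejects = df[bad].assign(reason=reasons[bad])
    valid = df[~bad].reset_index(drop=True)
    dupes = valid["species"][valid["species"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(
            f"duplicate species rows (one estimate per species expected): {sorted(dupes)}"
        )
    if bad.any():
        for _, row in rejects.iterrows():
            log.warning("excluded %r: %s", row["species"], row["reason"])
    return valid, rejects.reset_index(drop=True)


def read_species_table(path, column_map: dict | None = None, sep: str | None = None) -> RatesTable:
    """Read a delimited trait table (comma or tab, header row required).

    ``column_map`` maps canonical names (species, mu_g, generation_time,
    group) to the file's column headers; canonical headers are assumed when
    omitted.  Rows with missing or non-positive rate / generation time are
    excluded and reported in the returned table's ``rejects``.
    """
    colmap = {c: c for c in CANONICAL_COLUMNS}
    colmap.update(column_map or {})
    try:
        raw = pd.read_csv(path, sep=sep, engine="python")
    except FileNotFoundError:
        raise ConfigurationError(f"trait table not found: {path}") from None
    missing = [colmap[c] for c in CANONICAL_COLUMNS if colmap[c] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"required column(s) {missing} not found in {path}; "
            f"available columns: {list(raw.columns)}"
        )
    frame = raw[[colmap[c] for c in CANONICAL_COLUMNS]].copy()
    frame.columns = list(CANONICAL_COLUMNS)
    valid, rejects = _validate_frame(frame)
    return RatesTable(valid, rejects)


def compute_mu_y(table: RatesTable) -> RatesTable:
    """Add mu_y = mu_g / generation_time and the log10 trait columns.

    Input row order is preserved; the round trip mu_y * generation_time ==
    mu_g holds to floating precision.
    """
    df = table.data.copy()
    df["mu_y"] = df["mu_g"] / df["generation_time"]
    df["log10_mu_y"] = np.log10(df["mu_y"])
    df["log10_gt"] = np.log10(df["generation_time"])
    if not np.isfinite(df[["log10_mu_y", "log10_gt"]].to_numpy()).all():
        raise ValidationError("non-finite log10 trait encountered")
    return RatesTable(df, table.rejects)


def normalize_name(name: str) -> str:
    """Case-fold and map spaces to underscores (exact matching otherwise)."""
    return name.strip().lower().replace(" ", "_")


def match_to_tree(table: RatesTable, tree, name_normalizer=normalize_name):
    """Reconcile the table with a phylogeny.

    Returns ``(table, pruned_tree, dropped)`` where the table is restricted
    to species found among the tree tips, the tree is pruned to exactly
    those tips, and ``dropped`` lists table species absent from the tree.
    The pruned tree's tip order defines the row order of the table (the
    canonical ordering for all downstream matrices).
    """
    tip_labels = phylo.leaf_names(tree)
    norm_to_tip: dict[str, str] = {}
    for lb in tip_labels:
        key = name_normalizer(lb)
        if key in norm_to_tip:
            raise ValidationError(f"tree tips collide after name normalization: {lb!r}")
        norm_to_tip[key] = lb
    df = table.data.copy()
    df["_norm"] = df["species"].map(name_normalizer)
    if df["_norm"].duplicated().any():
        raise ValidationError("table species collide after name normalization")
    matched = df["_norm"].isin(norm_to_tip)
    dropped = list(df.loc[~matched, "species"])
    if dropped:
        log.warning("%d species absent from tree: %s", len(dropped), dropped)
    df = df[matched]
    if len(df) < 3:
        raise AnalysisError(
            f"only {len(df)} species matched the tree; regression needs >= 3"
        )
    keep_tips = [norm_to_tip[k] for k in df["_norm"]]
    pruned = phylo.prune_to(tree, keep_tips)
    order = {name_normalizer(lb): i for i, lb in enumerate(phylo.leaf_names(pruned))}
    df = df.sort_values("_norm", key=lambda s: s.map(order)).drop(columns="_norm")
    df = df.reset_index(drop=True)
    return RatesTable(df, table.rejects), pruned, dropped


def write_rates_table(table: RatesTable, path, rejects_path=None) -> None:
    """Write the table as TSV; rejects go to a sidecar TSV with a reason column."""
    table.data.to_csv(path, sep="\t", index=False)
    if rejects_path is not None:
        table.rejects.to_csv(rejects_path, sep="\t", index=False)
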