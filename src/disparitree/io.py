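"""Readers and writers for the plain-text formats the pipeline uses.

Trees travel as Newick or NEXUS (branch lengths are durations in Myr;
node ages can be annotated as comments).  Tables are comma-separated
UTF-8 with a mandatory header row and '.' decimals; ages are in Ma with
larger = older.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import dendropy
import pandas as pd
import yaml

from .disparity import TimeBin, validate_bin_series
from .trees import InputError, Tree
from .treetime import NodeConstraint, StratRange, TimeScaleSpec

__all__ = [
    "read_tree", "write_tree",
    "read_ranges_csv", "write_ranges_csv",
    "read_bins_csv", "write_bins_csv",
    "read_constraints_csv",
    "read_covariate_points_csv", "read_covariate_bins_csv",
    "load_config",
]


def _schema_for(path, schema: Optional[str]) -> str:
    if schema:
        return schema
    suffix = Path(path).suffix.lower()
    return "nexus" if suffix in (".nex", ".nexus", ".nxs") else "newick"


def read_tree(path, schema: Optional[str] = None) -> Tree:
    schema = _schema_for(path, schema)
    try:
        dtree = dendropy.Tree.get(path=str(path), schema=schema,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise InputError(f"cannot parse {path} as {schema}: {exc}") from exc
    return Tree.from_dendropy(dtree)


def write_tree(path, tree: Tree, schema: Optional[str] = None,
               ages_as_comments: bool = True) -> None:
    schema = _schema_for(path, schema)
    dtree = tree.to_dendropy(with_ages_as_comments=ages_as_comments)
    dtree.write(path=str(path), schema=schema,
                suppress_rooting=(schema == "newick"))


def read_ranges_csv(path) -> list[StratRange]:
    df = pd.read_csv(path)
    need = {"tip_id", "older_bound", "younger_bound"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: needs columns {sorted(need)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(StratRange(str(row.tip_id), float(row.older_bound),
                                  float(row.younger_bound)))
        except (InputError, ValueError) as exc:
            raise InputError(f"{path}: record {i + 1}: {exc}") from exc
    return out


def write_ranges_csv(path, ranges: Sequence[StratRange]) -> None:
    pd.DataFrame([{"tip_id": r.tip_id, "older_bound": r.older_bound,
                   "younger_bound": r.younger_bound}
                  for r in ranges]).to_csv(path, index=False)


def read_bins_csv(path) -> list[TimeBin]:
    df = pd.read_csv(path)
    need = {"name", "older", "younger"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: needs columns {sorted(need)}")
    bins = [TimeBin(str(r["name"]), float(r.older), float(r.younger))
            for _, r in df.iterrows()]
    validate_bin_series(bins)
    return bins


def write_bins_csv(path, bins: Sequence[TimeBin]) -> None:
    pd.DataFrame([{"name": b.name, "older": b.older, "younger": b.younger}
                  for b in bins]).to_csv(path, index=False)


def read_constraints_csv(path) -> list[list[NodeConstraint]]:
    """Long-format node-constraint table: one row per constraint, with
    columns ``sample_id`` (one constraint set per clock-tree sample),
    ``tips`` (tip labels separated by ';') and ``min_age`` (Ma)."""
    df = pd.read_csv(path)
    need = {"sample_id", "tips", "min_age"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: needs columns {sorted(need)}")
    sets = []
    for _, group in df.groupby("sample_id", sort=True):
        entries = []
        for i, row in group.iterrows():
            tips = frozenset(t.strip() for t in str(row.tips).split(";")
                             if t.strip())
            if not tips:
                raise InputError(f"{path}: record {i + 1}: empty tip set")
            entries.append(NodeConstraint(tips, float(row.min_age)))
        sets.append(entries)
    return sets


def read_covariate_points_csv(path) -> list[tuple]:
    df = pd.read_csv(path)
    need = {"age", "value"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: needs columns {sorted(need)}")
    return [(float(r.age), float(r.value)) for _, r in df.iterrows()]


def read_covariate_bins_csv(path, bins: Sequence[TimeBin]):
    """Per-bin covariate table (columns ``bin``, ``value``), aligned to
    the given bin series by name; bins absent from the table are NaN."""
    import numpy as np
    df = pd.read_csv(path)
    need = {"bin", "value"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: needs columns {sorted(need)}")
    lookup = dict(zip(df["bin"].astype(str), df["value"].astype(float)))
    return np.array([lookup.get(b.name, np.nan) for b in bins])


def load_config(path):
    """Load a pipeline configuration from YAML (see PipelineConfig)."""
    from .pipeline import PipelineConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent

    def resolve(p):
        return str(base / p) if p is not None else None

    ts = raw.get("timescale", {})
    spec = TimeScaleSpec(
        vartime=ts.get("vartime", 1.0),
        fossil_age_mode=ts.get("fossil_age_mode", "older_bound"),
        resolve_polytomies=ts.get("resolve_polytomies", True),
        n_replicates=ts.get("n_replicates", 1),
        seed=ts.get("seed", raw.get("seed", 0)),
    )
    return PipelineConfig(
        topology=resolve(raw["topology"]),
        ranges=resolve(raw["ranges"]),
        bins=resolve(raw["bins"]),
        scores=resolve(raw.get("scores")),
        tps=resolve(raw.get("tps")),
        constraints=resolve(raw.get("constraints")),
        covariate_points={k: resolve(v) for k, v in
                          raw.get("covariate_points", {}).items()},
        covariate_bins={k: resolve(v) for k, v in
                        raw.get("covariate_bins", {}).items()},
        timescale=spec,
        clades={k: list(v) for k, v in raw.get("clades", {}).items()},
        exclude_fossils=raw.get("exclude_fossils", False),
        n_retained=raw.get("n_retained"),
        outdir=resolve(raw.get("outdir", "results")),
    )
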