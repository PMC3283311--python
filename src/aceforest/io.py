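"""Readers and writers for the plain-text interchange formats.

- tree topology: Newick (one shared topology file);
- profile matrix: TSV, rows = families, columns = organism names, cells 0/1/?;
- co-evolution edges: TSV with family_i, family_j, w00, w01, w10, w11;
- tree-edge tables: TSV keyed by child node name with four weight columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .forest import MISSING, CoEvolvingForest, Topology
from .result import SolveResult
from .tables import WeightTable, table_from_joint

__all__ = ["read_forest", "write_forest", "write_result", "write_dces_result"]

DEFAULT_MISSING_TOKEN = "?"


def _read_profiles(path, missing_token: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise InputError(f"{path}: duplicate family ids")
    return df


def _profile_matrix(df: pd.DataFrame, organisms: list[str], missing_token: str, path) -> np.ndarray:
    missing_cols = set(organisms) - set(df.columns)
    extra_cols = set(df.columns) - set(organisms)
    if missing_cols or extra_cols:
        raise InputError(
            f"{path}: profile columns do not match tree leaves "
            f"(missing {sorted(missing_cols)}, unexpected {sorted(extra_cols)})"
        )
    df = df[organisms]
    out = np.empty(df.shape, dtype=np.int8)
    for r, (fam, row) in enumerate(df.iterrows()):
        for c, val in enumerate(row):
            val = str(val).strip()
            if val == missing_token:
                out[r, c] = MISSING
            elif val in ("0", "1"):
                out[r, c] = int(val)
            else:
                raise InputError(
                    f"{path}: bad cell {val!r} at row {r + 1} "
                    f"(family {fam!r}, organism {organisms[c]!r})"
                )
    return out


def _derive_coevo_from_mi(
    labels: np.ndarray, mi_floor: float
) -> dict[tuple[int, int], WeightTable]:
    from .dces import mutual_information

    F = labels.shape[0]
    tables = {}
    for i in range(F):
        for j in range(i + 1, F):
            if mutual_information(labels[i], labels[j]) >= mi_floor:
                ok = (labels[i] != MISSING) & (labels[j] != MISSING)
                counts = np.zeros((2, 2), dtype=int)
                for x, y in zip(labels[i, ok], labels[j, ok]):
                    counts[x, y] += 1
                tables[(i, j)] = table_from_joint(counts)
    return tables


def read_forest(
    tree_path,
    profiles_path,
    coevo_edges_path=None,
    tree_tables_path=None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    mi_floor: float = 0.05,
) -> CoEvolvingForest:
    """Assemble and validate a forest from its on-disk representation.

    With no co-evolution edge file, edges are derived from profile mutual
    information: every family pair at or above ``mi_floor`` is linked, with
    a table built from the -log joint distribution of the pair.
    """
    topo = Topology.from_newick(Path(tree_path).read_text())
    df = _read_profiles(profiles_path, missing_token)
    labels = _profile_matrix(df, topo.organisms, missing_token, profiles_path)
    families = [str(f) for f in df.index]
    fam_index = {f: i for i, f in enumerate(families)}

    coevo_tables: dict[tuple[int, int], WeightTable] = {}
    if coevo_edges_path is not None:
        edges = pd.read_csv(coevo_edges_path, sep="\t", dtype=str)
        required = {"family_i", "family_j", "w00", "w01", "w10", "w11"}
        if not required <= set(edges.columns):
            raise InputError(
                f"{coevo_edges_path}: missing columns {sorted(required - set(edges.columns))}"
            )
        for r, row in edges.iterrows():
            for fam in (row["family_i"], row["family_j"]):
                if fam not in fam_index:
                    raise InputError(
                        f"{coevo_edges_path}: row {r + 1} references unknown family {fam!r}"
                    )
            i, j = sorted((fam_index[row["family_i"]], fam_index[row["family_j"]]))
            if i == j:
                raise InputError(f"{coevo_edges_path}: row {r + 1} links a family to itself")
            try:
                ws = [float(row[k]) for k in ("w00", "w01", "w10", "w11")]
            except ValueError as exc:
                raise InputError(f"{coevo_edges_path}: row {r + 1}: {exc}") from exc
            if any(w < 0 for w in ws):
                raise InputError(f"{coevo_edges_path}: row {r + 1} has a negative weight")
            coevo_tables[(i, j)] = WeightTable(*ws)
    else:
        coevo_tables = _derive_coevo_from_mi(labels, mi_floor)

    tree_tables: dict[tuple[int, int], WeightTable] = {}
    if tree_tables_path is not None:
        tt = pd.read_csv(tree_tables_path, sep="\t", dtype=str)
        required = {"child", "w00", "w01", "w10", "w11"}
        if not required <= set(tt.columns):
            raise InputError(
                f"{tree_tables_path}: missing columns {sorted(required - set(tt.columns))}"
            )
        for r, row in tt.iterrows():
            child = row["child"]
            if child not in topo.name_to_id:
                raise InputError(
                    f"{tree_tables_path}: row {r + 1} references unknown node {child!r}"
                )
            v = topo.name_to_id[child]
            if topo.parent[v] < 0:
                raise InputError(f"{tree_tables_path}: node {child!r} is the root")
            try:
                ws = [float(row[k]) for k in ("w00", "w01", "w10", "w11")]
            except ValueError as exc:
                raise InputError(f"{tree_tables_path}: row {r + 1}: {exc}") from exc
            if any(w < 0 for w in ws):
                raise InputError(f"{tree_tables_path}: row {r + 1} has a negative weight")
            table = WeightTable(*ws)
            for f in range(len(families)):
                tree_tables[(f, v)] = table

    return CoEvolvingForest(
        topology=topo,
        families=families,
        leaf_labels=labels,
        tree_tables=tree_tables,
        coevo_tables=coevo_tables,
    )


def write_forest(
    forest: CoEvolvingForest, out_dir, missing_token: str = DEFAULT_MISSING_TOKEN
) -> dict[str, Path]:
    """Write tree.nwk, profiles.tsv, coevo_edges.tsv, tree_tables.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["tree"] = out / "tree.nwk"
    paths["tree"].write_text(forest.topology.to_newick() + "\n")

    cells = np.where(
        forest.leaf_labels == MISSING, missing_token, forest.leaf_labels.astype(str)
    )
    df = pd.DataFrame(cells, index=forest.families, columns=forest.topology.organisms)
    df.index.name = "family"
    paths["profiles"] = out / "profiles.tsv"
    df.to_csv(paths["profiles"], sep="\t")

    rows = [
        {
            "family_i": forest.families[i],
            "family_j": forest.families[j],
            "w00": t.w00,
            "w01": t.w01,
            "w10": t.w10,
            "w11": t.w11,
        }
        for (i, j), t in sorted(forest.coevo_tables.items())
    ]
    paths["coevo"] = out / "coevo_edges.tsv"
    pd.DataFrame(rows, columns=["family_i", "family_j", "w00", "w01", "w10", "w11"]).to_csv(
        paths["coevo"], sep="\t", index=False
    )

    # only uniform-per-node tables round-trip through the keyed-by-child format
    trows = []
    for _, c in forest.topology.edges():
        t = forest.tree_table(0, c)
        trows.append(
            {
                "child": forest.topology.names[c],
                "w00": t.w00,
                "w01": t.w01,
                "w10": t.w10,
                "w11": t.w11,
            }
        )
    paths["tree_tables"] = out / "tree_tables.tsv"
    pd.DataFrame(trows, columns=["child", "w00", "w01", "w10", "w11"]).to_csv(
        paths["tree_tables"], sep="\t", index=False
    )
    return paths


def write_result(result: SolveResult, forest: CoEvolvingForest, out_dir) -> dict[str, Path]:
    """Write labels.tsv (families x node names) and metrics.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if result.labeling is not None:
        df = pd.DataFrame(
            result.labeling.labels,
            index=forest.families,
            columns=forest.topology.names,
        )
        df.index.name = "family"
        paths["labels"] = out / "labels.tsv"
        df.to_csv(paths["labels"], sep="\t")
    metrics = {
        "method": result.method,
        "cost": result.cost,
        "optimal": result.optimal,
        "lower_bound": result.lower_bound,
        "info": _json_safe(result.info),
    }
    paths["metrics"] = out / "metrics.json"
    paths["metrics"].write_text(json.dumps(metrics, indent=2) + "\n")
    return paths


def write_dces_result(result, out_dir) -> dict[str, Path]:
    """Write ds.tsv, imputed.tsv and metrics.json for a dominant-set run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["ds"] = out / "ds.tsv"
    pd.DataFrame({"family": result.ds}).to_csv(paths["ds"], sep="\t", index=False)
    paths["imputed"] = out / "imputed.tsv"
    pd.DataFrame(
        sorted(result.imputed.items()), columns=["family", "value"]
    ).to_csv(paths["imputed"], sep="\t", index=False)
    metrics = {
        "w1": result.w1,
        "w2": result.w2,
        "ds_size": len(result.ds),
        "error_rate": result.error_rate,
        "coevo_usage": result.coevo_usage,
        "converged": result.converged,
        "error_rate_denominator": "all imputed (non-set) sites",
    }
    paths["metrics"] = out / "metrics.json"
    paths["metrics"].write_text(json.dumps(_json_safe(metrics), indent=2) + "\n")
    return paths


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj
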