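"""Reading and writing the package's file formats.

Genotype files are delimited text (TSV): rows are markers, columns are
individuals, the first column holds the marker name, and cells hold the
codes A / H / B with "-" or "U" for missing.  A manifest (YAML or JSON)
lists the per-dataset genotype files with their cross types and optional
weights.  Maps are written as TSV with 1-based cM positions from the left
end; integral maps export to GraphML and DOT.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import (
    CODE_TO_INT,
    INT_TO_CODE,
    ConsensusProblem,
    CrossType,
    Dataset,
    MapSolution,
    RFMatrix,
    SharedOrder,
)
from .exceptions import ValidationError
from .twopoint import build_rf_matrix

__all__ = [
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_manifest",
    "write_manifest",
    "write_map_tsv",
    "write_shared_order_tsv",
    "write_rf_tsv",
    "write_conflict_report_json",
    "write_graphml",
    "write_dot",
]


def read_genotypes_tsv(
    path: str | Path, cross_type: CrossType | str, dataset_id: int = 0
) -> Dataset:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    try:
        geno = df.map(lambda c: CODE_TO_INT[c.strip().upper()]).to_numpy(
            dtype=np.int8
        )
    except KeyError as e:
        raise ValidationError(f"unknown genotype code {e.args[0]!r} in {path}")
    return Dataset(dataset_id, CrossType(cross_type), list(df.index), geno)


def write_genotypes_tsv(dataset: Dataset, path: str | Path) -> None:
    codes = np.vectorize(INT_TO_CODE.get)(dataset.genotypes)
    df = pd.DataFrame(
        codes,
        index=pd.Index(dataset.markers, name="marker"),
        columns=[f"ind{j + 1}" for j in range(dataset.sample_size)],
    )
    df.to_csv(path, sep="\t")


def write_manifest(
    entries: list[dict], path: str | Path
) -> None:
    """``entries``: dicts with keys path, cross_type, optional weight."""
    path = Path(path)
    payload = {"populations": entries}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_manifest(
    path: str | Path, min_informative: int = 10
) -> ConsensusProblem:
    """Load a manifest and its genotype files; builds RF matrices."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict) or "populations" not in payload:
        raise ValidationError("manifest must contain a 'populations' list")
    datasets, rfms, weights = [], [], []
    any_weight = False
    for i, entry in enumerate(payload["populations"]):
        p = Path(entry["path"])
        if not p.is_absolute():
            p = path.parent / p
        ds = read_genotypes_tsv(p, entry["cross_type"], dataset_id=i)
        datasets.append(ds)
        rfms.append(build_rf_matrix(ds, min_informative=min_informative))
        w = entry.get("weight")
        any_weight = any_weight or w is not None
        weights.append(1.0 if w is None else float(w))
    return ConsensusProblem(datasets, rfms, weights if any_weight else None)


def write_map_tsv(
    solutions: list[MapSolution],
    shared: set[str],
    path: str | Path,
) -> None:
    """Per-dataset maps: marker, position_cM, shared_flag, dataset_id."""
    rows = []
    for ds_i, sol in enumerate(solutions):
        for m, pos in zip(sol.order, sol.positions_cM):
            rows.append(
                {
                    "marker": m,
                    "position_cM": round(pos, 4),
                    "shared_flag": int(m in shared),
                    "dataset_id": ds_i,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_shared_order_tsv(g: SharedOrder, path: str | Path) -> None:
    pd.DataFrame(
        {"rank": range(1, len(g) + 1), "marker": list(g.sequence)}
    ).to_csv(path, sep="\t", index=False)


def write_rf_tsv(rf: RFMatrix, path: str | Path) -> None:
    pd.DataFrame(rf.rf, index=rf.markers, columns=rf.markers).to_csv(
        path, sep="\t"
    )


def write_conflict_report_json(result, path: str | Path) -> None:
    """Conflict pairs and regions of a :class:`~consmap.pipeline.RunResult`."""
    from .local_exact import estimate_complexity

    payload = {
        "n_conflicts": len(result.conflicts),
        "pairs": [
            {
                "markers": sorted((cp.marker_a, cp.marker_b)),
                "datasets": sorted(cp.dataset_ids),
            }
            for cp in result.conflicts
        ],
        "regions": [],
    }
    for region in result.regions:
        est = estimate_complexity(region)
        payload["regions"].append(
            {
                "shared": list(region.shared),
                "k": region.k,
                "n_by_dataset": {str(i): region.n_i(i) for i in region.windows},
                "windows": {str(i): list(w) for i, w in region.windows.items()},
                "stage2_combinations": est.stage2_combinations,
                "feasibility": "exact" if est.feasible else "heuristic",
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2))


def write_graphml(G: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def write_dot(G: nx.DiGraph, path: str | Path) -> None:
    """Minimal DOT export (no pydot dependency)."""
    lines = ["digraph integral_map {"]
    for n, attrs in G.nodes(data=True):
        shape = "box" if attrs.get("shared") else "ellipse"
        lines.append(f'  "{n}" [shape={shape}];')
    for a, b, attrs in G.edges(data=True):
        dists = ", ".join(
            f"{k[1:]}:{v:.1f}" for k, v in sorted(attrs.items()) if k.startswith("d")
        )
        label = f' [label="{dists}"]' if dists else ""
        lines.append(f'  "{a}" -> "{b}"{label};')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
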