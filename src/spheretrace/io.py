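"""Readers and writers for the pipeline's file formats.

GCT 1.2 / plain TSV expression matrices, two-class CLS phenotype files,
GMT node-set collections, two-column annotation maps, long-format MID CSV,
dual-tracer channel CSV, and the tabular/JSON result files.  All readers
raise :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gsea import ModuleEnrichment, NodeSetCollection
from .mid import LabelingIndexTable, MIDPanel
from .sources import DualTracerPanel

__all__ = [
    "ParseError",
    "read_gct", "write_gct",
    "read_tsv_matrix", "write_tsv_matrix",
    "read_cls", "write_cls",
    "read_gmt", "write_gmt",
    "read_map_tsv", "write_map_tsv",
    "read_mid_panel", "write_mid_panel",
    "read_dual_tracer", "write_dual_tracer",
    "read_labels_csv", "write_labels_csv",
    "write_enrichment_tsv", "read_enrichment_tsv",
    "write_labeling_index", "read_labeling_index",
    "write_json", "read_json",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def _fail(path, lineno: int | None, msg: str) -> None:
    where = f"{path}" + (f", line {lineno}" if lineno is not None else "")
    raise ParseError(f"{where}: {msg}")


# ---------------------------------------------------------------- expression


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 matrix (probes in rows, samples in columns)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#1.2"):
        _fail(path, 1, "expected GCT version line '#1.2'")
    try:
        nrows, ncols = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        _fail(path, 2, "expected '<nrows>\\t<ncols>' dimension line")
    header = lines[2].split("\t")
    if len(header) != ncols + 2:
        _fail(path, 3, f"header declares {len(header) - 2} samples, dimensions say {ncols}")
    body = lines[3:]
    body = [ln for ln in body if ln.strip()]
    if len(body) != nrows:
        _fail(path, None, f"declared {nrows} rows but found {len(body)}")
    ids, rows = [], []
    for i, ln in enumerate(body, start=4):
        parts = ln.split("\t")
        if len(parts) != ncols + 2:
            _fail(path, i, f"expected {ncols + 2} fields, found {len(parts)}")
        ids.append(parts[0])
        try:
            rows.append([float(x) for x in parts[2:]])
        except ValueError:
            _fail(path, i, "non-numeric expression value")
    if len(set(ids)) != len(ids):
        _fail(path, None, "duplicate probe ids")
    return pd.DataFrame(rows, index=ids, columns=header[2:])


def write_gct(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for probe, row in df.iterrows():
            fh.write(str(probe) + "\tna\t" + "\t".join(repr(v) for v in row) + "\n")


def read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        _fail(path, None, "duplicate row ids")
    return df


def write_tsv_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_cls(path) -> pd.Series:
    """Read a two-class CLS phenotype file; returns positional class labels."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) == 3:  # standard: count line, '# name name', labels
        head = lines[0].split()
        names_line, label_line = lines[1], lines[2]
        if not names_line.startswith("#"):
            _fail(path, 2, "expected '# <classA> <classB>'")
        names = names_line[1:].split()
        labels = label_line.split()
        if len(head) >= 2 and int(head[1]) != 2:
            _fail(path, 1, "only two-class CLS files supported")
    elif len(lines) == 2:  # two-line variant: '# name name', labels
        names = lines[0][1:].split() if lines[0].startswith("#") else lines[0].split()
        labels = lines[1].split()
    else:
        _fail(path, None, f"expected a 2- or 3-line CLS file, found {len(lines)} lines")
    if len(names) != 2:
        _fail(path, None, f"expected two class names, found {names}")
    out = []
    for tok in labels:
        if tok in names:
            out.append(tok)
        elif tok in ("0", "1"):
            out.append(names[int(tok)])
        else:
            _fail(path, None, f"unrecognized class token {tok!r}")
    if len(set(out)) != 2:
        _fail(path, None, "both classes must be present")
    return pd.Series(out)


def write_cls(labels: pd.Series, path, classes: tuple[str, str] | None = None) -> None:
    labels = pd.Series(labels)
    if classes is None:
        classes = tuple(pd.unique(labels))
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(str(v) for v in labels) + "\n")


# ----------------------------------------------------------------- node sets


def read_gmt(path) -> NodeSetCollection:
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            _fail(path, i, "GMT line needs name, description and >= 1 member")
        mid, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
        if mid in sets:
            _fail(path, i, f"duplicate module id {mid!r}")
        if not members:
            _fail(path, i, "empty member list")
        sets[mid] = frozenset(members)
        names[mid] = desc
    if not sets:
        _fail(path, None, "no modules found")
    return NodeSetCollection(sets=sets, names=names)


def write_gmt(collection: NodeSetCollection, path) -> None:
    with open(path, "w") as fh:
        for mid in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[mid]))
            fh.write(f"{mid}\t{collection.display_name(mid)}\t{members}\n")


def read_map_tsv(path, multi: bool = False):
    """Two-column TSV map; with ``multi`` values accumulate into tuples."""
    single: dict[str, str] = {}
    multi_map: dict[str, list[str]] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != 2:
            _fail(path, i, f"expected 2 tab-separated fields, found {len(parts)}")
        k, v = parts
        if multi:
            multi_map.setdefault(k, []).append(v)
        else:
            if k in single and single[k] != v:
                _fail(path, i, f"conflicting mapping for {k!r}")
            single[k] = v
    if multi:
        return {k: tuple(vs) for k, vs in multi_map.items()}
    return single


def write_map_tsv(mapping, path) -> None:
    with open(path, "w") as fh:
        for k in sorted(mapping):
            v = mapping[k]
            if isinstance(v, (tuple, list, frozenset, set)):
                for item in sorted(v):
                    fh.write(f"{k}\t{item}\n")
            else:
                fh.write(f"{k}\t{v}\n")


# ----------------------------------------------------------------------- MID


def read_mid_panel(data_path, samples_path, tracer_element: str = "C",
                   tracer_enrichment: float = 1.0) -> MIDPanel:
    """Long-format MID CSV + per-sample CSV -> :class:`MIDPanel`."""
    long = pd.read_csv(data_path)
    req = {"metabolite", "formula", "isotopologue_index", "sample", "intensity"}
    if not req <= set(long.columns):
        _fail(data_path, 1, f"expected columns {sorted(req)}")
    formulas = long.drop_duplicates("metabolite").set_index("metabolite")["formula"]
    conflicting = long.groupby("metabolite")["formula"].nunique()
    if (conflicting > 1).any():
        bad = list(conflicting.index[conflicting > 1])
        _fail(data_path, None, f"conflicting formulas for {bad}")
    data = long.pivot_table(
        index=["metabolite", "isotopologue_index"],
        columns="sample",
        values="intensity",
        fill_value=0.0,
        aggfunc="sum",
    )
    data.columns.name = None
    samples = pd.read_csv(samples_path).set_index("sample")
    for col in ("internal_standard_intensity", "cell_count"):
        if col not in samples.columns:
            _fail(samples_path, 1, f"missing column {col!r}")
    data = data[[c for c in samples.index if c in data.columns]]
    return MIDPanel(data=data, formulas=formulas, samples=samples,
                    tracer_element=tracer_element, tracer_enrichment=tracer_enrichment)


def write_mid_panel(panel: MIDPanel, data_path, samples_path) -> None:
    long = (
        panel.data.stack()
        .rename("intensity")
        .reset_index()
        .rename(columns={"level_2": "sample"})
    )
    long.columns = ["metabolite", "isotopologue_index", "sample", "intensity"]
    long.insert(1, "formula", long["metabolite"].map(panel.formulas))
    long.to_csv(data_path, index=False)
    panel.samples.to_csv(samples_path)


# --------------------------------------------------------------- dual tracer


def read_dual_tracer(path, labels_path=None) -> DualTracerPanel:
    data = pd.read_csv(path)
    req = {"sample", "carbon_shift", "n15_count", "intensity"}
    if not req <= set(data.columns):
        _fail(path, 1, f"expected columns {sorted(req)}")
    labels = read_labels_csv(labels_path) if labels_path else None
    return DualTracerPanel(data=data[sorted(req, key=list(data.columns).index)], labels=labels)


def write_dual_tracer(panel: DualTracerPanel, path, labels_path=None) -> None:
    panel.data.to_csv(path, index=False)
    if labels_path and panel.labels is not None:
        write_labels_csv(panel.labels, labels_path)


def read_labels_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        _fail(path, 1, "expected columns sample, group")
    return df.set_index(df.columns[0])[df.columns[1]]


def write_labels_csv(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample": labels.index, "group": labels.values}).to_csv(path, index=False)


# ------------------------------------------------------------------- results


def write_enrichment_tsv(results: list[ModuleEnrichment], path) -> None:
    rows = [
        (r.module_id, r.n_nodes, r.es, r.nes, r.p, r.q, r.enriched_in, r.flagged)
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["module_id", "n_nodes", "ES", "NES", "p", "q", "enriched_in", "flagged"],
    ).to_csv(path, sep="\t", index=False)


def read_enrichment_tsv(path) -> list[ModuleEnrichment]:
    df = pd.read_csv(path, sep="\t")
    return [
        ModuleEnrichment(
            module_id=str(r.module_id), n_nodes=int(r.n_nodes), es=float(r.ES),
            nes=float(r.NES), p=float(r.p), q=float(r.q),
            enriched_in=str(r.enriched_in), flagged=bool(r.flagged),
        )
        for r in df.itertuples()
    ]


def write_labeling_index(table: LabelingIndexTable, path) -> None:
    out = table.values.where(table.valid)
    out.index.name = "metabolite"
    out.to_csv(path, sep="\t")


def read_labeling_index(path) -> LabelingIndexTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return LabelingIndexTable(values=values, valid=values.notna())


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
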