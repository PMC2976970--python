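"""Tabular I/O for the screen pipeline.

Every table is tab-separated UTF-8 with a header row. Readers validate and
reject bad files, reporting *every* offending line (header is line 1, the
first data row is line 2); they never silently coerce. Well addresses are
normalized to upper-case row letters with zero-padded two-digit columns
("A01"), case-insensitive on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

#: assay condition labels, in canonical order
ASSAYS = ("CON_LUC", "M3_LUC", "NDELTA_M3", "NICD_M3")
#: the three conditions measured in the primary screen
SCREEN_ASSAYS = ("CON_LUC", "M3_LUC", "NDELTA_M3")

#: localization vocabulary for annotation tables
LOCALIZATIONS = ("extracellular", "membrane", "cytosolic", "nuclear", "unknown")

_WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")

_PLATE_ROWS = {96: "ABCDEFGH", 384: "ABCDEFGHIJKLMNOP"}
_PLATE_COLS = {96: 12, 384: 24}


class TableValidationError(ValueError):
    """Raised when a table fails schema validation.

    Carries ``errors``, one message per offending line.
    """

    def __init__(self, path, errors: list[str]):
        self.path = str(path)
        self.errors = list(errors)
        msg = f"{path}: {len(self.errors)} validation error(s)\n" + "\n".join(
            "  " + e for e in self.errors
        )
        super().__init__(msg)


def normalize_well(well: str, plate_format: int = 384) -> str:
    """Normalize a well address like ``a1`` to ``A01``.

    Raises ``ValueError`` when the address is outside the plate format
    (rows A-P / columns 1-24 for 384; A-H / 1-12 for 96).
    """
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"malformed well address {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    rows = _PLATE_ROWS[plate_format]
    if row not in rows or not 1 <= col <= _PLATE_COLS[plate_format]:
        raise ValueError(
            f"well {well!r} out of range for {plate_format}-well plate"
        )
    return f"{row}{col:02d}"


def well_to_rc(well: str, plate_format: int = 384) -> tuple[int, int]:
    """Zero-based (row, column) of a normalized well address."""
    w = normalize_well(well, plate_format)
    return _PLATE_ROWS[plate_format].index(w[0]), int(w[1:]) - 1


def rc_to_well(row: int, col: int, plate_format: int = 384) -> str:
    """Inverse of :func:`well_to_rc`."""
    rows = _PLATE_ROWS[plate_format]
    if not (0 <= row < len(rows) and 0 <= col < _PLATE_COLS[plate_format]):
        raise ValueError(f"(row={row}, col={col}) outside {plate_format}-well plate")
    return f"{rows[row]}{col + 1:02d}"


def _read_raw(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path, errors):
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"line 1: missing required column(s): {', '.join(missing)}")
        raise TableValidationError(path, errors)


def _line(i: int) -> int:
    # dataframe row i sits on file line i+2 (after the header)
    return i + 2


def _check_duplicates(df, keys, path_label, errors):
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        for _, grp in df[dup].groupby(keys, sort=False):
            lines = ", ".join(str(_line(i)) for i in grp.index)
            key = tuple(grp.iloc[0][k] for k in keys)
            errors.append(f"lines {lines}: duplicate {path_label} key {key}")


def read_plate_map(path) -> pd.DataFrame:
    """Read a plate map: screening well -> dsRNA -> stock-plate well."""
    df = _read_raw(path)
    errors: list[str] = []
    _require_columns(
        df, ["screen_plate_id", "well", "dsrna_id", "stock_plate_id", "stock_well"],
        path, errors,
    )
    for i in df.index:
        for col, fmt in (("well", 384), ("stock_well", 96)):
            try:
                df.at[i, col] = normalize_well(df.at[i, col], fmt)
            except ValueError as exc:
                errors.append(f"line {_line(i)}: {exc}")
    _check_duplicates(df, ["screen_plate_id", "well"], "screening-well", errors)
    _check_duplicates(df, ["stock_plate_id", "stock_well"], "stock-well", errors)
    if errors:
        raise TableValidationError(path, errors)
    return df


def read_measurements(path) -> pd.DataFrame:
    """Read a long-format luminescence table."""
    df = _read_raw(path)
    errors: list[str] = []
    _require_columns(
        df, ["assay", "plate_copy", "screen_plate_id", "well", "signal"], path, errors
    )
    for i in df.index:
        if df.at[i, "assay"] not in ASSAYS:
            errors.append(
                f"line {_line(i)}: unknown assay {df.at[i, 'assay']!r} "
                f"(expected one of {', '.join(ASSAYS)})"
            )
        try:
            df.at[i, "well"] = normalize_well(df.at[i, "well"], 384)
        except ValueError as exc:
            errors.append(f"line {_line(i)}: {exc}")
        try:
            sig = float(df.at[i, "signal"])
            if sig < 0:
                errors.append(f"line {_line(i)}: negative signal {sig}")
        except ValueError:
            errors.append(f"line {_line(i)}: malformed signal {df.at[i, 'signal']!r}")
        try:
            int(df.at[i, "plate_copy"])
        except ValueError:
            errors.append(
                f"line {_line(i)}: malformed plate_copy {df.at[i, 'plate_copy']!r}"
            )
    if not errors:
        df["plate_copy"] = df["plate_copy"].astype(int)
        df["signal"] = df["signal"].astype(float)
        _check_duplicates(
            df, ["assay", "screen_plate_id", "well", "plate_copy"], "measurement", errors
        )
    if errors:
        raise TableValidationError(path, errors)
    return df


def read_annotations(path) -> pd.DataFrame:
    """Read the dsRNA/gene annotation table."""
    df = _read_raw(path)
    errors: list[str] = []
    _require_columns(df, ["dsrna_id", "gene_id", "gene_symbol", "offtarget_count"], path, errors)
    if "go_class" not in df.columns:
        df["go_class"] = ""
    if "localization" not in df.columns:
        df["localization"] = "unknown"
    for i in df.index:
        try:
            n = int(df.at[i, "offtarget_count"])
            if n < 0:
                errors.append(f"line {_line(i)}: negative offtarget_count {n}")
        except ValueError:
            errors.append(
                f"line {_line(i)}: malformed offtarget_count "
                f"{df.at[i, 'offtarget_count']!r}"
            )
        loc = df.at[i, "localization"] or "unknown"
        if loc not in LOCALIZATIONS:
            errors.append(
                f"line {_line(i)}: unknown localization {loc!r} "
                f"(expected one of {', '.join(LOCALIZATIONS)})"
            )
        df.at[i, "localization"] = loc
    _check_duplicates(df, ["dsrna_id"], "dsRNA", errors)
    if errors:
        raise TableValidationError(path, errors)
    df["offtarget_count"] = df["offtarget_count"].astype(int)
    return df


def read_interactions(path) -> pd.DataFrame:
    """Read a physical-interaction edge table.

    Edges are undirected: duplicates are collapsed on the sorted gene pair
    (the first source_tag wins). Self-loops are kept but flagged.
    """
    df = _read_raw(path)
    errors: list[str] = []
    _require_columns(df, ["gene_a", "gene_b"], path, errors)
    if "source_tag" not in df.columns:
        df["source_tag"] = ""
    for i in df.index:
        if not df.at[i, "gene_a"] or not df.at[i, "gene_b"]:
            errors.append(f"line {_line(i)}: empty gene identifier")
    if errors:
        raise TableValidationError(path, errors)
    a = df[["gene_a", "gene_b"]].min(axis=1)
    b = df[["gene_a", "gene_b"]].max(axis=1)
    df = df.assign(gene_a=a, gene_b=b)
    df = df.drop_duplicates(subset=["gene_a", "gene_b"], keep="first").reset_index(drop=True)
    df["self_loop"] = df["gene_a"] == df["gene_b"]
    return df


def read_retest_measurements(path) -> pd.DataFrame:
    """Read a quadruplicate four-condition retest table."""
    df = _read_raw(path)
    errors: list[str] = []
    _require_columns(df, ["gene_id", "condition", "replicate", "signal"], path, errors)
    for i in df.index:
        if df.at[i, "condition"] not in ASSAYS:
            errors.append(
                f"line {_line(i)}: unknown condition {df.at[i, 'condition']!r}"
            )
        try:
            if float(df.at[i, "signal"]) < 0:
                errors.append(f"line {_line(i)}: negative signal")
        except ValueError:
            errors.append(f"line {_line(i)}: malformed signal {df.at[i, 'signal']!r}")
    if not errors:
        df["replicate"] = df["replicate"].astype(int)
        df["signal"] = df["signal"].astype(float)
        _check_duplicates(df, ["gene_id", "condition", "replicate"], "retest", errors)
    if errors:
        raise TableValidationError(path, errors)
    return df


_READERS = {
    "plate_map": read_plate_map,
    "measurements": read_measurements,
    "annotations": read_annotations,
    "interactions": read_interactions,
    "retest": read_retest_measurements,
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Dispatching reader; ``kind`` is one of plate_map, measurements,
    annotations, interactions, retest."""
    try:
        reader = _READERS[kind]
    except KeyError:
        raise ValueError(f"unknown table kind {kind!r}") from None
    return reader(path)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table in the canonical tab-separated dialect."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export / import

NETWORK_FORMATS = ("sif", "tsv", "graphml")


def export_network(graph: nx.Graph, path, fmt: str = "sif") -> None:
    """Write a network in SIF, edge-list TSV or GraphML.

    SIF lines are ``geneA <tab> pp <tab> geneB``; for SIF and TSV a node
    attribute table (role, area, z-scores, localization) is written next to
    the edge file as ``<stem>.nodes.tsv``.
    """
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; use one of {NETWORK_FORMATS}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        g = nx.Graph()
        for n, attrs in graph.nodes(data=True):
            g.add_node(n, **{k: v for k, v in attrs.items() if v is not None and v == v})
        for u, v, attrs in graph.edges(data=True):
            g.add_edge(u, v, **{k: w for k, w in attrs.items() if w is not None})
        nx.write_graphml(g, path)
        return
    nodes = sorted(graph.nodes())
    with open(path, "w") as fh:
        if fmt == "sif":
            for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
                fh.write(f"{u}\tpp\t{v}\n")
            for n in nodes:
                if graph.degree(n) == 0:
                    fh.write(f"{n}\n")
        else:
            fh.write("gene_a\tgene_b\tsource_tag\n")
            for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
                tag = graph.edges[u, v].get("source_tag", "")
                fh.write(f"{u}\t{v}\t{tag}\n")
    attr_cols = ("role", "area", "z_con", "z_m3", "localization")
    rows = []
    for n in nodes:
        attrs = graph.nodes[n]
        rows.append({"gene_id": n, **{c: attrs.get(c, "") for c in attr_cols}})
    node_df = pd.DataFrame(rows, columns=("gene_id",) + attr_cols)
    write_table(node_df, path.with_suffix(path.suffix + ".nodes.tsv"))


def import_network(path, fmt: str = "sif") -> nx.Graph:
    """Read a network written by :func:`export_network` (round-trip aid)."""
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; use one of {NETWORK_FORMATS}")
    if fmt == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    with open(path) as fh:
        if fmt == "sif":
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) == 3:
                    g.add_edge(parts[0], parts[2])
        else:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                rec = dict(zip(header, line.rstrip("\n").split("\t")))
                g.add_edge(rec["gene_a"], rec["gene_b"], source_tag=rec.get("source_tag", ""))
    return g
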