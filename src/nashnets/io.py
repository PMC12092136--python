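"""Readers and writers for the package's plain-text formats.

Formats
-------
Edge-list TSV
    One edge per line: two 1-based integer ids separated by a tab.
    Blank lines and ``#`` comments are ignored.  An optional first
    data line ``n=<int>`` declares the vertex count explicitly (needed
    for graphs with trailing isolated vertices); otherwise n is the
    largest id seen.
Adjacency-matrix CSV
    Square, symmetric 0/1 matrix with a zero diagonal.
Profile JSON
    Object with key ``"strategies"`` holding an ordered 0/1 array;
    position i (0-based) is player i+1.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

from .core import LabeledGraph, StrategyProfile
from .errors import InputError

__all__ = [
    "load_graph",
    "write_graph",
    "load_profile",
    "write_profile",
    "write_histogram_csv",
    "write_experiment_csv",
]


def _parse_error(path: Path, lineno: int, message: str) -> InputError:
    return InputError(f"{path}:{lineno}: {message}")


def _load_edge_list(path: Path) -> LabeledGraph:
    edges: set[tuple[int, int]] = set()
    declared_n: int | None = None
    max_id = 0
    seen_edge_line = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("n="):
                if seen_edge_line or declared_n is not None:
                    raise _parse_error(path, lineno, "n= header must come first")
                try:
                    declared_n = int(line[2:])
                except ValueError:
                    raise _parse_error(path, lineno, f"bad header {line!r}") from None
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise _parse_error(
                    path, lineno, f"expected two tab-separated ids, got {line!r}"
                )
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise _parse_error(path, lineno, f"non-integer id in {line!r}") from None
            if i == j:
                raise _parse_error(path, lineno, f"self-loop on vertex {i}")
            if i < 1 or j < 1:
                raise _parse_error(path, lineno, "vertex ids are 1-based positives")
            e = (i, j) if i < j else (j, i)
            if e in edges:
                raise _parse_error(path, lineno, f"duplicate edge {e}")
            edges.add(e)
            max_id = max(max_id, i, j)
            seen_edge_line = True
    n = declared_n if declared_n is not None else max_id
    if n < max_id:
        raise InputError(f"{path}: header n={n} smaller than largest id {max_id}")
    if n == 0:
        raise InputError(f"{path}: empty edge list and no n= header")
    return LabeledGraph(n, frozenset(edges))


def _load_adjacency(path: Path) -> LabeledGraph:
    with path.open(newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]
    if not rows:
        raise InputError(f"{path}: empty adjacency matrix")
    n = len(rows)
    matrix: list[list[int]] = []
    for lineno, row in enumerate(rows, start=1):
        if len(row) != n:
            raise _parse_error(path, lineno, f"row has {len(row)} columns, expected {n}")
        vals = []
        for c in row:
            c = c.strip()
            if c not in ("0", "1"):
                raise _parse_error(path, lineno, f"entries must be 0/1, got {c!r}")
            vals.append(int(c))
        matrix.append(vals)
    edges = set()
    for i in range(n):
        if matrix[i][i] != 0:
            raise _parse_error(path, i + 1, "nonzero diagonal entry")
        for j in range(i + 1, n):
            if matrix[i][j] != matrix[j][i]:
                raise InputError(
                    f"{path}: matrix not symmetric at ({i + 1},{j + 1})"
                )
            if matrix[i][j]:
                edges.add((i + 1, j + 1))
    return LabeledGraph(n, frozenset(edges))


def load_graph(path: str | Path, format: str = "auto") -> LabeledGraph:
    """Read a graph from an edge-list TSV or adjacency-matrix CSV.

    ``format`` is ``"edge-list"``, ``"adjacency"`` or ``"auto"``
    (``.csv`` suffix means adjacency, anything else edge-list).
    """
    path = Path(path)
    if format == "auto":
        format = "adjacency" if path.suffix.lower() == ".csv" else "edge-list"
    if format == "edge-list":
        return _load_edge_list(path)
    if format == "adjacency":
        return _load_adjacency(path)
    raise InputError(f"unknown graph format {format!r}")


def write_graph(graph: LabeledGraph, path: str | Path, format: str = "auto") -> None:
    """Write a graph in either supported format (see :func:`load_graph`)."""
    path = Path(path)
    if format == "auto":
        format = "adjacency" if path.suffix.lower() == ".csv" else "edge-list"
    if format == "edge-list":
        lines = [f"n={graph.n}"]
        lines += [f"{i}\t{j}" for i, j in sorted(graph.edges)]
        path.write_text("\n".join(lines) + "\n")
    elif format == "adjacency":
        adj = graph.adjacency()
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            for i in range(1, graph.n + 1):
                writer.writerow(
                    [1 if j in adj[i] else 0 for j in range(1, graph.n + 1)]
                )
    else:
        raise InputError(f"unknown graph format {format!r}")


def load_profile(path: str | Path) -> StrategyProfile:
    """Read a profile from JSON (``{"strategies": [...]}``)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(payload, dict) or "strategies" not in payload:
        raise InputError(f"{path}: expected an object with a 'strategies' key")
    strategies = payload["strategies"]
    if not isinstance(strategies, list):
        raise InputError(f"{path}: 'strategies' must be an array")
    return StrategyProfile(tuple(strategies))


def write_profile(profile: StrategyProfile, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"strategies": list(profile.strategies)}) + "\n"
    )


def write_histogram_csv(rows: Iterable[tuple[int, int]], path: str | Path) -> None:
    """Write (edges, N1) rows."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["edges", "N1"])
        writer.writerows(rows)


def write_experiment_csv(
    rows: Iterable[tuple[int, int, int, float]], path: str | Path
) -> None:
    """Write (edges, N1, N2, ratio) rows."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["edges", "N1", "N2", "ratio"])
        for e, n1, n2, ratio in rows:
            writer.writerow([e, n1, n2, f"{ratio:.10g}"])
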