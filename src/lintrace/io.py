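"""Plain-text I/O: character matrices (TSV), trees (newick), priors (JSON),
allele tables (TSV)."""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .core import MISSING, CharacterMatrix, LineageTree, PriorSet

_MISSING_TOKENS = {"-", "NA", "?", ""}


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------

def read_character_matrix(path) -> CharacterMatrix:
    """Tab-separated matrix: header of character names, first column the cell
    id; entries are integers, with "-", "NA" or "?" marking missing data."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        characters = header[1:]
        cell_ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path.name}:{ln}: expected {len(header)} fields, "
                    f"got {len(parts)}")
            cell_ids.append(parts[0])
            row = []
            for col, tok in enumerate(parts[1:], start=2):
                tok = tok.strip()
                if tok in _MISSING_TOKENS:
                    row.append(MISSING)
                else:
                    try:
                        row.append(int(tok))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path.name}:{ln}: column {col} "
                            f"({characters[col - 2]}): non-integer state "
                            f"{tok!r}") from exc
            rows.append(row)
    return CharacterMatrix(np.array(rows, dtype=np.int64).reshape(
        len(rows), len(characters)), cell_ids, characters)


def write_character_matrix(matrix: CharacterMatrix, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("cellBC\t" + "\t".join(matrix.characters) + "\n")
        for cid, row in zip(matrix.cell_ids, matrix.values):
            toks = ["-" if v == MISSING else str(int(v)) for v in row]
            fh.write(cid + "\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# newick trees
# ---------------------------------------------------------------------------

def tree_to_newick(tree: LineageTree, branch_lengths: bool = True) -> str:
    """Newick string with internal-node labels; branch length is the edge's
    mutation count (falling back to the stored length attribute)."""

    def length(u, v) -> float:
        data = tree.graph.edges[u, v]
        muts = data.get("mutations")
        if muts is not None:
            return float(len(muts))
        return float(data.get("length", 0.0))

    def label_of(v) -> str:
        if isinstance(v, tuple):  # simulator internal nodes: (generation, i)
            return "n" + "_".join(str(x) for x in v)
        text = str(v)
        for ch in "(),:;[] '\"":
            text = text.replace(ch, "_")
        return text

    def render(v) -> str:
        kids = tree.children(v)
        label = label_of(v)
        if not kids:
            return label
        inner = ",".join(
            render(c) + (f":{length(v, c):g}" if branch_lengths else "")
            for c in kids)
        return f"({inner}){label}"

    return render(tree.root) + ";"


def write_newick(tree: LineageTree, path, collapse_singles: bool = False,
                 branch_lengths: bool = True) -> None:
    if collapse_singles:
        tree = tree.collapse_singles()
    Path(path).write_text(tree_to_newick(tree, branch_lengths) + "\n")


def read_newick(path_or_string) -> LineageTree:
    """Parse a rooted newick tree (file path or literal string)."""
    text = str(path_or_string)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=False)
    g = nx.DiGraph()
    counter = [0]

    def name_of(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        counter[0] += 1
        return f"anon{counter[0]}"

    names: dict = {}

    def walk(node) -> str:
        name = names.setdefault(id(node), name_of(node))
        g.add_node(name)
        for child in node.child_nodes():
            cname = walk(child)
            g.add_edge(name, cname,
                       length=float(child.edge.length or 0.0))
        return name

    root = walk(dt.seed_node)
    return LineageTree(g, root)


# ---------------------------------------------------------------------------
# priors and provenance
# ---------------------------------------------------------------------------

def write_priors(priors: PriorSet, path) -> None:
    payload = {
        "state_priors": [{str(s): q for s, q in d.items()}
                         for d in priors.state_priors],
        "mutation_rates": list(priors.mutation_rates),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_priors(path) -> PriorSet:
    payload = json.loads(Path(path).read_text())
    return PriorSet([{int(s): float(q) for s, q in d.items()}
                     for d in payload["state_priors"]],
                    [float(p) for p in payload.get("mutation_rates", [])])


def read_allele_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"cellBC": str, "intBC": str, "allele": str,
                              "UMI": int})


def write_allele_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
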