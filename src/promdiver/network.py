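"""Protein-interaction degree from an undirected edge list.

The raw edge list (2-column TSV or SIF) is cleaned into a simple undirected
graph — self-interactions dropped, (A,B)/(B,A) unified, duplicates collapsed
— and each protein's degree is its number of distinct interaction partners.
Genes absent from the network get no degree by default (coverage of curated
interactomes is partial), with an optional degree-0 policy.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = ["EdgeFormatError", "parse_edges", "clean_network", "degree_table"]


class EdgeFormatError(ValueError):
    pass


def parse_edges(stream: Iterable[str]) -> list[tuple[str, str]]:
    """Read raw interaction pairs, keeping duplicates and self-pairs.

    Tab-separated lines use the first two columns. Space-separated SIF lines
    (``A pp B``) use the first and third tokens; the middle interaction-type
    token is ignored.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" in line:
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise EdgeFormatError(f"line {lineno}: expected >=2 tab-separated columns")
            pairs.append((fields[0].strip(), fields[1].strip()))
        else:
            fields = line.split()
            if len(fields) == 2:
                pairs.append((fields[0], fields[1]))
            elif len(fields) >= 3:
                pairs.append((fields[0], fields[2]))
            else:
                raise EdgeFormatError(f"line {lineno}: expected >=2 columns")
    return pairs


def clean_network(pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    """Build the simple undirected interaction graph.

    Self-pairs are removed; orientation and duplicates collapse. Idempotent:
    cleaning an already-clean edge set changes nothing.
    """
    g = nx.Graph()
    for a, b in pairs:
        if a == b:
            continue
        g.add_edge(a, b)
    return g


def degree_table(g: nx.Graph) -> pd.DataFrame:
    """Per-node connectivity: ``id  degree``, sorted by id."""
    rows = sorted(g.degree())
    return pd.DataFrame(rows, columns=["id", "degree"])
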