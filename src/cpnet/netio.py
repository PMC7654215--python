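"""Readers and writers for the pipeline's tabular artifacts.

Formats follow the exports of the STRING/STITCH-style interaction services
the analysis emulates: TSV edge tables with a combined-confidence score
(either the 0-999 integer dialect or the unit interval), GMT gene-set
collections, disease-association tables, node-attribute tables, alias maps,
survival tables and morphometry tables. Undirected edges are keyed by the
sorted node pair; duplicate orientations collapse to the maximum confidence.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DialectError, InputError

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["node_a", "node_b", "confidence", "kind_a", "kind_b"]

# Unicode hyphen variants occasionally found in exported identifiers.
_HYPHENS = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


def _clean_id(name: str) -> str:
    return unicodedata.normalize("NFC", str(name).strip()).translate(_HYPHENS)


@dataclass
class InteractionTable:
    """Weighted undirected edge list over protein/chemical identifiers."""

    edges: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in ("kind_a", "kind_b"):
            if col not in self.edges.columns:
                self.edges[col] = "protein"
        self.edges = self.edges[EDGE_COLUMNS].reset_index(drop=True)

    def __len__(self):
        return len(self.edges)

    @property
    def nodes(self) -> set:
        return set(self.edges["node_a"]) | set(self.edges["node_b"])

    def node_kinds(self) -> dict:
        kinds = {}
        for a, b, ka, kb in self.edges[["node_a", "node_b", "kind_a", "kind_b"]].itertuples(
            index=False
        ):
            kinds[a] = ka
            kinds[b] = kb
        return kinds

    def subset(self, nodes) -> "InteractionTable":
        """Edges with both endpoints inside ``nodes``."""
        nodes = set(nodes)
        keep = self.edges["node_a"].isin(nodes) & self.edges["node_b"].isin(nodes)
        return InteractionTable(self.edges[keep].copy(), dict(self.meta))


@dataclass
class DiseaseAssociationTable:
    rows: pd.DataFrame  # columns: gene, confidence
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.rows)


@dataclass
class GeneSetCollection:
    """Named, de-duplicated gene sets with optional descriptions."""

    sets: dict  # name -> set of gene ids
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __iter__(self):
        return iter(self.sets.items())

    def union(self) -> set:
        out = set()
        for members in self.sets.values():
            out |= members
        return out


def _canonical_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Key undirected edges by sorted node pair, carrying kinds along."""
    flip = df["node_a"] > df["node_b"]
    df = df.copy()
    df.loc[flip, ["node_a", "node_b"]] = df.loc[flip, ["node_b", "node_a"]].values
    df.loc[flip, ["kind_a", "kind_b"]] = df.loc[flip, ["kind_b", "kind_a"]].values
    return df


def normalize_edges(df: pd.DataFrame) -> pd.DataFrame:
    """Drop self-pairs, canonicalize orientation, collapse dupes to max score."""
    n_self = int((df["node_a"] == df["node_b"]).sum())
    if n_self:
        log.info("dropping %d self-pair(s)", n_self)
        df = df[df["node_a"] != df["node_b"]]
    df = _canonical_pairs(df)
    df = (
        df.sort_values("confidence")
        .drop_duplicates(subset=["node_a", "node_b"], keep="last")
        .sort_values(["node_a", "node_b"], kind="mergesort")
        .reset_index(drop=True)
    )
    return df


def read_edge_table(path, dialect: str = "auto") -> InteractionTable:
    """Read a TSV edge table in the string9 (0-999) or unit-interval dialect.

    ``auto`` decides by whether any score exceeds 1. Duplicate undirected
    pairs collapse to the maximum confidence; self-pairs are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, encoding="utf-8")
    if df.empty:
        raise InputError(f"empty edge table: {path}")
    if df.shape[1] < 3:
        raise InputError(f"edge table needs >= 3 columns: {path}")
    cols = list(df.columns)
    out = pd.DataFrame(
        {
            "node_a": df[cols[0]].map(_clean_id),
            "node_b": df[cols[1]].map(_clean_id),
            "confidence": pd.to_numeric(df[cols[2]]),
        }
    )
    for src, dst in (("kind_a", "kind_a"), ("kind_b", "kind_b")):
        out[dst] = df[src].astype(str) if src in df.columns else "protein"

    score = out["confidence"].to_numpy(dtype=float)
    if np.any(score < 0):
        raise DialectError("unknown score dialect: negative score")
    if dialect == "auto":
        dialect = "string9" if np.any(score > 1) else "unit"
    if dialect == "string9":
        if np.any(score > 999):
            raise DialectError("unknown score dialect: score > 999")
        out["confidence"] = score / 1000.0
    elif dialect == "unit":
        if np.any(score > 1):
            raise DialectError("unknown score dialect: score > 1 in unit dialect")
    else:
        raise InputError(f"unknown dialect {dialect!r}")
    return InteractionTable(normalize_edges(out))


def write_edge_table(table: InteractionTable, path) -> None:
    """Write unit-interval TSV; round-trips through :func:`read_edge_table`."""
    table.edges.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gmt(path) -> GeneSetCollection:
    sets, descriptions = {}, {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {_clean_id(g) for g in genes if g}
            descriptions[name] = desc
    if not sets:
        raise InputError(f"empty GMT file: {path}")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_disease_table(path) -> DiseaseAssociationTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, encoding="utf-8")
    if df.empty:
        raise InputError(f"empty disease table: {path}")
    cols = list(df.columns)
    rows = pd.DataFrame(
        {"gene": df[cols[0]].map(_clean_id), "confidence": pd.to_numeric(df[cols[1]])}
    )
    return DiseaseAssociationTable(rows)


def write_disease_table(table: DiseaseAssociationTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_alias_map(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    cols = list(df.columns)
    return {
        _clean_id(syn): _clean_id(canon)
        for syn, canon in zip(df[cols[0]], df[cols[1]])
    }


def resolve_aliases(names, aliases: dict):
    """Map synonyms to canonical identifiers; report names not in the map."""
    resolved, unmapped = [], []
    for name in names:
        name = _clean_id(name)
        if name in aliases:
            resolved.append(aliases[name])
        else:
            resolved.append(name)
            unmapped.append(name)
    return resolved, unmapped


def read_expression_tsv(path):
    """Expression matrix: first column gene id, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    df.index = df.index.map(_clean_id)
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_attribute_table(path) -> dict:
    """Node-attribute TSV (node, key, value) -> nested dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    out = {}
    for node, key, value in df.itertuples(index=False):
        out.setdefault(_clean_id(node), {})[key] = value
    return out


def write_attribute_table(attrs: dict, path) -> None:
    rows = [
        {"node": node, "key": key, "value": value}
        for node in sorted(attrs)
        for key, value in sorted(attrs[node].items())
    ]
    pd.DataFrame(rows, columns=["node", "key", "value"]).to_csv(path, sep="\t", index=False)
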