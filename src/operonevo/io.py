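"""Readers and writers: gene-order dialect, Newick trees, history tables, config.

Gene-order dialect (one genome per file): whitespace-separated tokens on one
logical line.  ``<o>`` and ``<t>`` mark the origin and terminus of
replication; operons are bracketed ``[ ... ]`` with an optional leading ``-``
for the reverse strand; singletons are bare gene tokens.  A gene token is an
optional ``-`` plus ``tRNA-Xxx(nnn)`` (3-letter lowercase anticodon) or an
rRNA subunit ``16S``/``23S``/``5S``.  Genes of an operon are listed in
genome (circle) order.  Example::

    <o> [16S 23S 5S tRNA-Ala(tgc)] tRNA-Ile(gat) <t> -[tRNA-Asn(gtt)]
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import dendropy
import yaml

from operonevo.model import (
    AnnotationError,
    Event,
    Gene,
    GeneOrder,
    OPERON,
    SINGLETON,
    Unit,
)
from operonevo.phylo import PhyloNode, Phylogeny

__all__ = [
    "ParseError",
    "read_gene_order",
    "read_gene_orders",
    "write_gene_order",
    "gene_order_to_text",
    "gene_order_from_text",
    "read_newick",
    "write_history",
    "read_history",
    "load_config",
    "save_config",
]


class ParseError(ValueError):
    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        where = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(message + where)
        self.line = line
        self.column = column


_GENE_RE = re.compile(r"^(-?)(?:tRNA-([A-Z][a-z]{2})\(([acgt]{3})\)|(16S|23S|5S))$")


def _gene_token(g: Gene, with_sign: bool = True) -> str:
    s = "-" if (with_sign and g.sign < 0) else ""
    if g.anticodon:
        return f"{s}tRNA-{g.identity_class}({g.anticodon})"
    return f"{s}{g.identity_class}"


def _parse_gene(tok: str, sign: int, line: int, col: int) -> Gene:
    m = _GENE_RE.match(tok)
    if not m:
        raise ParseError(f"unknown token {tok!r}", line, col)
    tok_sign = -1 if m.group(1) else 1
    try:
        if m.group(2):
            return Gene(m.group(2), m.group(3), sign * tok_sign)
        return Gene(m.group(4), None, sign * tok_sign)
    except AnnotationError as ex:
        raise ParseError(str(ex), line, col) from ex


def gene_order_to_text(order: GeneOrder) -> str:
    parts = ["<o>"]
    for i, u in enumerate(order.units):
        if i == order.terminus:
            parts.append("<t>")
        if u.kind == OPERON:
            inner = " ".join(_gene_token(g, with_sign=False) for g in u.genes)
            parts.append(("-" if u.orientation < 0 else "") + "[" + inner + "]")
        else:
            parts.append(_gene_token(u.genes[0]))
    if order.terminus == len(order.units):
        parts.append("<t>")
    return " ".join(parts) + "\n"


def gene_order_from_text(text: str, genome_id: str) -> GeneOrder:
    # tokenize with positions; brackets may hug their first/last gene token
    tokens: list[tuple[str, int, int]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.lstrip().startswith("#"):
            continue
        for m in re.finditer(r"\S+", line):
            tokens.append((m.group(), ln, m.start() + 1))

    units: list[Unit] = []
    origin_seen = 0
    terminus_at: int | None = None
    i = 0
    while i < len(tokens):
        tok, ln, col = tokens[i]
        if tok == "<o>":
            origin_seen += 1
            if origin_seen > 1:
                raise ParseError("duplicate origin marker", ln, col)
            if units or terminus_at is not None:
                raise ParseError("the origin marker must come first", ln, col)
            i += 1
            continue
        if tok == "<t>":
            if terminus_at is not None:
                raise ParseError("duplicate terminus marker", ln, col)
            terminus_at = len(units)
            i += 1
            continue
        if tok.startswith("[") or tok.startswith("-["):
            sign = -1 if tok.startswith("-") else 1
            body = tok.lstrip("-")[1:]
            genes: list[Gene] = []
            closed = False
            while True:
                if body.endswith("]"):
                    body = body[:-1]
                    closed = True
                if body:
                    genes.append(_parse_gene(body, sign, ln, col))
                if closed:
                    break
                i += 1
                if i >= len(tokens):
                    raise ParseError("unclosed bracket", ln, col)
                body, ln, col = tokens[i]
            units.append(Unit(OPERON, genes))
            i += 1
            continue
        units.append(Unit(SINGLETON, [_parse_gene(tok, 1, ln, col)]))
        i += 1

    if origin_seen == 0:
        raise ParseError(f"{genome_id}: missing origin marker")
    if terminus_at is None:
        raise ParseError(f"{genome_id}: missing terminus marker")
    order = GeneOrder(genome_id, units, terminus_at)
    try:
        order.validate()
    except AnnotationError as ex:
        raise ParseError(str(ex)) from ex
    return order


def read_gene_order(path: str | Path) -> GeneOrder:
    path = Path(path)
    return gene_order_from_text(path.read_text(), genome_id=path.stem)


def read_gene_orders(paths: list[str | Path]) -> dict[str, GeneOrder]:
    out: dict[str, GeneOrder] = {}
    for p in paths:
        order = read_gene_order(p)
        if order.genome_id in out:
            raise ParseError(f"duplicate genome id {order.genome_id!r} ({p})")
        out[order.genome_id] = order
    return out


def write_gene_order(order: GeneOrder, path: str | Path) -> None:
    Path(path).write_text(gene_order_to_text(order))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> Phylogeny:
    """Rooted binary phylogeny; branch lengths are accepted and ignored."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )

    def convert(node: dendropy.Node) -> PhyloNode:
        name = node.taxon.label if node.taxon is not None else (node.label or None)
        return PhyloNode(name, [convert(c) for c in node.child_nodes()])

    return Phylogeny(convert(tree.seed_node))


# ---------------------------------------------------------------------------
# History tables
# ---------------------------------------------------------------------------


def _genes_to_json(genes) -> list[str]:
    return [_gene_token(g) for g in genes]


def _genes_from_json(tokens: list[str]) -> list[Gene]:
    return [_parse_gene(t, 1, 0, 0) for t in tokens]


def _params_to_json(p: dict) -> dict:
    out = {}
    for k, v in p.items():
        if k == "content":
            out[k] = _genes_to_json(v)
        else:
            out[k] = list(v) if isinstance(v, tuple) else v
    return out


def _params_from_json(p: dict) -> dict:
    out = {}
    for k, v in p.items():
        if k == "content":
            out[k] = _genes_from_json(v)
        elif k in ("target", "span", "position", "from_value", "to_value", "source") and v is not None:
            out[k] = tuple(v)
        else:
            out[k] = v
    return out


_HISTORY_HEADER = "branch\tevent_type\tsize\tnested\tparams\taffected\n"


def write_history(
    events: dict[str, list[Event]], path: str | Path, terminus: dict[str, int] | None = None
) -> None:
    """Tab-separated event table, one record per event (lossless round-trip)."""
    lines = [_HISTORY_HEADER]
    for branch in sorted(events):
        if terminus is not None and branch in terminus:
            lines.append(f"#terminus\t{branch}\t{terminus[branch]}\n")
        for e in events[branch]:
            aff = dict(e.affected) if e.affected is not None else None
            if aff is not None:
                aff = {
                    k: (list(v) if isinstance(v, tuple) else v) for k, v in aff.items()
                }
                if aff.get("content"):
                    aff["content"] = [list(c) for c in aff["content"]]
            lines.append(
                "\t".join(
                    [
                        branch,
                        e.event_type,
                        str(e.size),
                        "1" if e.nested else "0",
                        json.dumps(_params_to_json(e.params), sort_keys=True),
                        json.dumps(aff, sort_keys=True),
                    ]
                )
                + "\n"
            )
    Path(path).write_text("".join(lines))


def _affected_from_json(a: dict | None) -> dict | None:
    if a is None:
        return None
    out = dict(a)
    out["positions"] = tuple(a.get("positions", ()))
    out["content"] = tuple(tuple(c) for c in a.get("content", ()))
    return out


def read_history(path: str | Path) -> tuple[dict[str, list[Event]], dict[str, int]]:
    events: dict[str, list[Event]] = {}
    terminus: dict[str, int] = {}
    lines = Path(path).read_text().splitlines()
    for ln in lines[1:]:
        if not ln.strip():
            continue
        if ln.startswith("#terminus"):
            _, branch, t = ln.split("\t")
            terminus[branch] = int(t)
            continue
        branch, etype, size, nested, params, affected = ln.split("\t")
        e = Event(
            etype,
            branch,
            int(size),
            _params_from_json(json.loads(params)),
            nested=nested == "1",
            affected=_affected_from_json(json.loads(affected)),
        )
        events.setdefault(branch, []).append(e)
    return events, terminus


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path}: expected a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
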