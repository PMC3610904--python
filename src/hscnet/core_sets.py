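"""Gene-set and universe data model.

Gene sets (e.g. a stem-cell expression "fingerprint", a differential-expression
list, the genes of a disease protein-interaction network) are unordered
collections of gene symbols drawn from a declared universe — the set of all
genes that could have been sampled on the platform that produced the list.
Comparing lists across platforms or species requires three plumbing steps that
this module owns: symbol-case normalization, ortholog mapping through homology
groups, and restriction of a comparator to the fixed set's universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .overlap_stats import ContingencyTable

log = logging.getLogger(__name__)

__all__ = [
    "GeneSet", "Universe", "OrthologMap", "GmtParseError",
    "read_gmt", "write_gmt", "read_universe", "read_ortholog_map",
    "normalize_symbols", "map_orthologs", "restrict_universe",
    "overlap_counts",
]


class GmtParseError(ValueError):
    """A GMT line that cannot be parsed (carries the 1-based line number)."""


def _check_symbols(symbols: Iterable[str]) -> frozenset[str]:
    out = frozenset(symbols)
    for s in out:
        if not isinstance(s, str) or not s:
            raise ValueError(f"gene symbols must be non-empty strings, got {s!r}")
    return out


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene symbols within a declared universe."""

    name: str
    symbols: frozenset[str]
    universe_name: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        object.__setattr__(self, "symbols", _check_symbols(self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


@dataclass(frozen=True)
class Universe:
    """The pool of all genes a set could have been drawn from (size N >= 1)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", _check_symbols(self.symbols))
        if len(self.symbols) < 1:
            raise ValueError("universe must contain at least one symbol")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


@dataclass(frozen=True)
class OrthologMap:
    """Homology groups, each a (source symbols, target symbols) pair.

    A symbol may belong to at most one group per side; groups are non-empty on
    both sides. Built from two-column (source, target) pairs by taking
    connected components, so many-to-many homology is represented faithfully.
    """

    groups: tuple[tuple[frozenset[str], frozenset[str]], ...]
    policy: str = "upper"

    def __post_init__(self) -> None:
        seen_src: set[str] = set()
        seen_tgt: set[str] = set()
        for src, tgt in self.groups:
            if not src or not tgt:
                raise ValueError("homology groups must be non-empty on both sides")
            if seen_src & src:
                raise ValueError(f"source symbol(s) {sorted(seen_src & src)} "
                                 "appear in more than one group")
            if seen_tgt & tgt:
                raise ValueError(f"target symbol(s) {sorted(seen_tgt & tgt)} "
                                 "appear in more than one group")
            seen_src |= src
            seen_tgt |= tgt

    def group_for_source(self, symbol: str):
        idx = self._source_index()
        return self.groups[idx[symbol]] if symbol in idx else None

    def _source_index(self) -> Mapping[str, int]:
        cached = self.__dict__.get("_src_idx")
        if cached is None:
            cached = {s: i for i, (src, _) in enumerate(self.groups) for s in src}
            object.__setattr__(self, "_src_idx", cached)
        return cached

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   policy: str = "upper") -> "OrthologMap":
        """Group (source, target) pairs into homology groups by connectivity."""
        norm = _normalizer(policy)
        parent: dict[tuple[str, str], tuple[str, str]] = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            for node in (x, y):
                parent.setdefault(node, node)
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[rx] = ry

        cleaned = []
        for s, t in pairs:
            s, t = norm(s), norm(t)
            if not s or not t:
                raise ValueError("ortholog pairs need non-empty symbols on both sides")
            cleaned.append((s, t))
            union(("s", s), ("t", t))
        comps: dict[tuple[str, str], tuple[set, set]] = {}
        for side, sym in parent:
            root = find((side, sym))
            src, tgt = comps.setdefault(root, (set(), set()))
            (src if side == "s" else tgt).add(sym)
        groups = tuple(sorted(
            ((frozenset(src), frozenset(tgt)) for src, tgt in comps.values()),
            key=lambda g: min(g[0]),
        ))
        return cls(groups=groups, policy=policy)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, line) skipping blanks and '#' comments."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


def read_gmt(path, policy: str = "upper") -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...).

    Symbols are normalized per ``policy`` and deduplicated; the description
    field is discarded (logged at debug level). Duplicate set names are an
    error, not a silent merge.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtParseError(f"line {lineno}: expected >=3 tab-separated "
                                f"fields, got {len(fields)}")
        name, description, *genes = fields
        if name in seen:
            raise GmtParseError(f"line {lineno}: duplicate gene-set name {name!r}")
        seen.add(name)
        log.debug("GMT set %s: discarding description %r", name, description)
        gs = GeneSet(name=name, symbols=frozenset(g for g in genes if g))
        sets.append(normalize_symbols(gs, policy))
    if not sets:
        log.warning("GMT file %s contained no gene sets", path)
    return sets


def write_gmt(sets: Sequence[GeneSet], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.symbols)]) + "\n")


def read_universe(path, name: str | None = None, policy: str = "upper") -> Universe:
    """Read a universe from a header-less one-symbol-per-line (or -column) file."""
    norm = _normalizer(policy)
    symbols = set()
    for _, line in _data_lines(path):
        symbols.add(norm(line.split("\t")[0].strip()))
    return Universe(name=name or Path(path).stem, symbols=frozenset(symbols))


def read_ortholog_map(path, policy: str = "upper") -> OrthologMap:
    """Read a two-column (source_symbol, target_symbol) TSV into homology groups."""
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
        pairs.append((fields[0].strip(), fields[1].strip()))
    return OrthologMap.from_pairs(pairs, policy=policy)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def _normalizer(policy: str):
    if policy == "upper":
        return str.upper
    if policy == "asis":
        return lambda s: s
    raise ValueError(f"unknown normalization policy {policy!r}")


def normalize_symbols(gene_set: GeneSet, policy: str = "upper") -> GeneSet:
    """Return a new GeneSet with symbols case-normalized and deduplicated.

    ``upper`` maps everything to upper case — the default, because mouse
    (``Gata2``) and human (``GATA2``) symbol conventions differ only in case.
    ``asis`` leaves symbols untouched for same-species work.
    """
    norm = _normalizer(policy)
    return GeneSet(name=gene_set.name,
                   symbols=frozenset(norm(s) for s in gene_set.symbols),
                   universe_name=gene_set.universe_name)


def map_orthologs(gene_set: GeneSet, ortholog_map: OrthologMap,
                  policy: str = "all_targets") -> GeneSet:
    """Map a gene set through homology groups to the target symbol space.

    ``all_targets``: every source symbol found in a group contributes all of
    that group's target symbols (union semantics). ``drop_ambiguous``: groups
    with more than one target are skipped. Unmapped symbols are counted and
    logged; the result may be smaller than the input.
    """
    if policy not in ("all_targets", "drop_ambiguous"):
        raise ValueError(f"unknown ortholog policy {policy!r}")
    mapped: set[str] = set()
    unmapped = 0
    for sym in gene_set.symbols:
        group = ortholog_map.group_for_source(sym)
        if group is None:
            unmapped += 1
            continue
        _, targets = group
        if policy == "drop_ambiguous" and len(targets) > 1:
            continue
        mapped |= targets
    if unmapped:
        log.warning("map_orthologs(%s): %d of %d symbols had no homology group",
                    gene_set.name, unmapped, len(gene_set))
    if not mapped:
        log.warning("map_orthologs(%s): no symbols mapped", gene_set.name)
    return GeneSet(name=gene_set.name, symbols=frozenset(mapped))


def restrict_universe(fixed_universe: Universe, comparator: GeneSet) -> GeneSet:
    """Intersect a comparator with the fixed set's universe.

    Cross-platform comparisons must only count genes that *could* have been
    sampled on both sides; symbols absent from the universe are discarded
    (count logged).
    """
    kept = comparator.symbols & fixed_universe.symbols
    discarded = len(comparator.symbols) - len(kept)
    if discarded:
        log.info("restrict_universe(%s -> %s): discarded %d symbols",
                 comparator.name, fixed_universe.name, discarded)
    if not kept:
        log.warning("restrict_universe(%s): empty intersection with universe %s",
                    comparator.name, fixed_universe.name)
    return GeneSet(name=comparator.name, symbols=frozenset(kept),
                   universe_name=fixed_universe.name)


def overlap_counts(fixed: GeneSet, comparator: GeneSet,
                   universe: Universe) -> ContingencyTable:
    """2x2 contingency table of two sets over a universe.

    Both sets must be subsets of the universe (apply
    :func:`restrict_universe` first); violations raise with the offending
    symbols named.
    """
    for gs in (fixed, comparator):
        stray = gs.symbols - universe.symbols
        if stray:
            shown = ", ".join(sorted(stray)[:5])
            raise ValueError(f"set {gs.name!r} is not a subset of universe "
                             f"{universe.name!r}; e.g. {shown}")
    a = len(fixed.symbols & comparator.symbols)
    b = len(fixed.symbols) - a
    c = len(comparator.symbols) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)
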