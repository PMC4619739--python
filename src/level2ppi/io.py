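"""Readers and writers for every file format the toolkit touches.

Formats
-------
* Edge lists: generic two-column TSV, or the HPRD binary-interaction
  flat-file dialect (gene symbols in columns 1 and 4, 1-based).
* Gene lists: one symbol per line, ``#`` comments allowed.
* Gene sets: standard GMT (name, description, members, tab-separated).
* Candidate tables: the ranked TSV emitted by the prediction stage.

Gene identity throughout the package is the uppercased, whitespace-trimmed
symbol string; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A line in an input file does not match the declared dialect."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return symbol.strip().upper()


@dataclass
class EdgeList:
    """Raw undirected interaction pairs as read from a file.

    Duplicates and orientation are preserved; deduplication and self-loop
    removal happen at graph build.
    """

    edges: list[tuple[str, str]] = field(default_factory=list)
    source_dialect: str = "generic2col"

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneList:
    """An ordered list of unique, normalized gene symbols."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique: list[str] = []
        for g in self.genes:
            g = normalize_symbol(g)
            if g and g not in seen:
                seen.add(g)
                unique.append(g)
        self.genes = unique

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in set(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO/KEGG style): name -> (description, member set)."""

    sets: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> set[str]:
        return self.sets[name][1]


def _open_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, line) with newline chars stripped.

    UTF-8; LF and CRLF both tolerated.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            yield lineno, raw.rstrip("\r\n")


def _detect_dialect(path: str | Path) -> str:
    """Guess the edge-list dialect from the first non-comment line.

    HPRD binary-interaction rows carry at least 4 tab-separated columns with
    the interactor symbols in columns 1 and 4; anything narrower is treated
    as a generic two-column edge list.
    """
    for _, line in _open_lines(path):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        return "hprd" if len(line.split("\t")) >= 4 else "generic2col"
    return "generic2col"


def read_edge_list(path: str | Path, dialect: str = "auto") -> EdgeList:
    """Read an interaction file into an :class:`EdgeList`.

    Parameters
    ----------
    path
        TSV file. Lines starting with ``#`` are comments; blank lines skipped.
    dialect
        ``generic2col`` (symbols in the first two columns), ``hprd``
        (symbols in columns 1 and 4 of the HPRD binary-interaction flat
        file), or ``auto`` to sniff from the first data line.

    Raises
    ------
    ParseError
        If a line has fewer columns than the dialect requires or a symbol
        is empty after normalization.
    """
    if dialect not in ("generic2col", "hprd", "auto"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if dialect == "auto":
        dialect = _detect_dialect(path)
        logger.info("auto-detected edge-list dialect %r for %s", dialect, path)

    col_a, col_b = (0, 3) if dialect == "hprd" else (0, 1)
    min_cols = max(col_a, col_b) + 1

    edges: list[tuple[str, str]] = []
    for lineno, line in _open_lines(path):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < min_cols:
            raise ParseError(
                f"{path}:{lineno}: expected at least {min_cols} tab-separated "
                f"columns for dialect {dialect!r}, found {len(cols)}"
            )
        a, b = normalize_symbol(cols[col_a]), normalize_symbol(cols[col_b])
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty gene symbol")
        edges.append((a, b))

    if not edges:
        logger.warning("edge list %s is empty", path)
    return EdgeList(edges=edges, source_dialect=dialect)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; dedup keeps first occurrence.

    Raises
    ------
    ValueError
        If the file contains no gene symbols after comment/blank filtering.
    """
    genes: list[str] = []
    for _, line in _open_lines(path):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        genes.append(line)
    gl = GeneList(name=name or Path(path).stem, genes=genes)
    if not gl.genes:
        raise ValueError(f"gene list {path} is empty after filtering")
    return gl


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member1<TAB>member2...``.

    Raises
    ------
    ParseError
        For lines with fewer than three fields or duplicate set names.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    for lineno, line in _open_lines(path):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                f"found {len(cols)}"
            )
        name, desc = cols[0].strip(), cols[1]
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        members = {normalize_symbol(m) for m in cols[2:] if m.strip()}
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a :class:`GeneSetCollection` as GMT (members sorted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


CANDIDATE_TABLE_COLUMNS = (
    "gene",
    "direct_score",
    "indirect_score",
    "level1_member",
    "level2_member",
    "level2_only",
    "prior_level1",
    "prior_level2",
    "rank",
)


def write_candidate_table(records: Sequence, path: str | Path) -> None:
    """Write ranked candidate records as TSV (booleans as 1/0).

    The file order is the record order, which callers must have ranked;
    :func:`read_candidate_table` round-trips it bit-exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CANDIDATE_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        str(r.direct_score),
                        str(r.indirect_score),
                        "1" if r.level1_member else "0",
                        "1" if r.level2_member else "0",
                        "1" if r.level2_only else "0",
                        "1" if r.prior_level1 else "0",
                        "1" if r.prior_level2 else "0",
                        str(r.rank),
                    ]
                )
                + "\n"
            )


def read_candidate_table(path: str | Path) -> list:
    """Read a candidate TSV written by :func:`write_candidate_table`."""
    from .prediction import CandidateRecord  # avoid import cycle

    records: list[CandidateRecord] = []
    lines = list(_open_lines(path))
    if not lines:
        raise ParseError(f"{path}: empty candidate table (no header)")
    header = lines[0][1].split("\t")
    if tuple(header) != CANDIDATE_TABLE_COLUMNS:
        raise ParseError(f"{path}: unexpected header {header!r}")
    for lineno, line in lines[1:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != len(CANDIDATE_TABLE_COLUMNS):
            raise ParseError(f"{path}:{lineno}: expected {len(CANDIDATE_TABLE_COLUMNS)} columns")
        records.append(
            CandidateRecord(
                gene=cols[0],
                direct_score=int(cols[1]),
                indirect_score=int(cols[2]),
                level1_member=cols[3] == "1",
                level2_member=cols[4] == "1",
                level2_only=cols[5] == "1",
                prior_level1=cols[6] == "1",
                prior_level2=cols[7] == "1",
                rank=int(cols[8]),
            )
        )
    return records
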