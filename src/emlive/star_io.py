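"""Lossless STAR-format metadata I/O.

STAR (a CIF relative) is the text convention RELION uses for every piece
of processing metadata: one or more ``data_<name>`` blocks, each holding
simple ``_label value`` pairs and/or a ``loop_`` table (one ``_label``
per line followed by whitespace-delimited rows).

The containers here preserve everything a round trip needs: block order,
label order, row order and cell values.  Cells are typed individually —
integer if the token is an integer literal, real if a float literal
(scientific notation included), text otherwise — mirroring RELION's
untyped convention.  Reals are serialized with six decimal places (fixed
notation, falling back to scientific for extreme magnitudes), so
round-trip equality is defined after one write: ``parse(write(doc))``
reproduces ``doc`` exactly when ``doc``'s reals are already expressible
at that precision, and ``write ∘ parse ∘ write`` is always byte-stable.

Labels are matched case-sensitively but queries may drop the leading
underscore and/or the ``rln`` prefix (``"CtfMaxResolution"`` resolves
``"_rlnCtfMaxResolution"``), matching how the labels are referred to in
prose and figure captions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pandas as pd

Scalar = Union[int, float, str]

__all__ = [
    "Scalar",
    "LoopTable",
    "StarBlock",
    "StarDocument",
    "StarParseError",
    "StarValidationError",
    "StarLookupError",
    "parse_star",
    "write_star",
    "read_star",
    "write_star_file",
    "get_table",
    "add_column",
    "format_value",
]

GENERATED_BY = "# Written by emlive"


class StarParseError(ValueError):
    """Raised for syntactically invalid STAR text."""


class StarValidationError(ValueError):
    """Raised when a container invariant would be violated."""


class StarLookupError(KeyError):
    """Raised when a requested block / label does not exist."""

    def __str__(self) -> str:  # keep the message readable, not repr-quoted
        return self.args[0] if self.args else ""


_INT_RE = re.compile(r"[+-]?\d+$")
_FLOAT_RE = re.compile(r"[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?$")


def _type_cell(token: str) -> Scalar:
    if _INT_RE.match(token):
        return int(token)
    if _FLOAT_RE.match(token) and any(c in token for c in ".eE"):
        return float(token)
    return token


def format_value(value: Scalar) -> str:
    """Render a cell the way RELION-style columns do.

    Reals use six decimal places; magnitudes outside a comfortable
    fixed-notation range switch to scientific notation.  Integers and
    text pass through verbatim (text is quoted only when it contains
    whitespace).
    """
    if isinstance(value, bool):  # bool is an int subclass; be explicit
        raise StarValidationError("boolean cells are not part of the STAR convention")
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return "nan"
        if value == 0.0:
            return "0.000000"
        if 1e-4 <= abs(value) < 1e6:
            return f"{value:.6f}"
        return f"{value:.6e}"
    text = str(value)
    if "\n" in text:
        raise StarValidationError("multi-line text cells are not supported")
    if text == "":
        return '""'
    needs_quote = (
        any(ch.isspace() for ch in text)
        or "#" in text
        or text.startswith(("'", '"', "_"))
        # numeric-looking text must stay text after a round trip
        or not isinstance(_type_cell(text), str)
    )
    if not needs_quote:
        return text
    if '"' not in text:
        return '"' + text + '"'
    if "'" not in text:
        return "'" + text + "'"
    raise StarValidationError(
        f"cannot serialize text containing both quote characters: {text!r}"
    )


def _label_variants(query: str) -> Tuple[str, ...]:
    q = query.strip()
    base = q.lstrip("_")
    variants = [q]
    if not q.startswith("_"):
        variants.append("_" + q)
    if not base.startswith("rln"):
        variants.append("_rln" + base)
        variants.append("rln" + base)
    return tuple(dict.fromkeys(variants))


@dataclass
class LoopTable:
    """An ordered ``loop_`` table: labels plus rows of typed cells."""

    labels: List[str]
    rows: List[Tuple[Scalar, ...]]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise StarValidationError(f"duplicate labels in loop: {self.labels}")
        for label in self.labels:
            if not label.startswith("_"):
                raise StarValidationError(f"loop label must start with '_': {label!r}")
        width = len(self.labels)
        self.rows = [tuple(r) for r in self.rows]
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise StarValidationError(
                    f"row {i} has {len(row)} cells, expected {width}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def resolve_label(self, query: str) -> str:
        """Map a possibly prefix-less query to the stored label."""
        for cand in _label_variants(query):
            if cand in self.labels:
                return cand
        raise StarLookupError(
            f"label {query!r} not found; available: {self.labels}"
        )

    def column(self, query: str) -> List[Scalar]:
        label = self.resolve_label(query)
        idx = self.labels.index(label)
        return [row[idx] for row in self.rows]

    def subset(self, indices: Iterable[int]) -> "LoopTable":
        rows = [self.rows[i] for i in indices]
        return LoopTable(list(self.labels), rows)

    def to_pandas(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LoopTable):
            return NotImplemented
        return self.labels == other.labels and self.rows == other.rows


def add_column(table: LoopTable, label: str, values: Sequence[Scalar]) -> LoopTable:
    """Return a new table with ``label`` appended as the last column."""
    if not label.startswith("_"):
        label = "_" + label
    if label in table.labels:
        raise StarValidationError(f"label {label!r} already present")
    if len(values) != table.n_rows:
        raise StarValidationError(
            f"{len(values)} values for {table.n_rows} rows"
        )
    rows = [row + (v,) for row, v in zip(table.rows, values)]
    return LoopTable(table.labels + [label], rows)


@dataclass
class StarBlock:
    """One ``data_<name>`` block: simple pairs, a loop table, or both."""

    name: str
    pairs: dict = field(default_factory=dict)  # insertion-ordered label -> scalar
    table: Optional[LoopTable] = None

    def __post_init__(self) -> None:
        for label in self.pairs:
            if not label.startswith("_"):
                raise StarValidationError(f"pair label must start with '_': {label!r}")

    def get_pair(self, query: str) -> Scalar:
        for cand in _label_variants(query):
            if cand in self.pairs:
                return self.pairs[cand]
        raise StarLookupError(
            f"pair {query!r} not found in block {self.name!r}; "
            f"available: {list(self.pairs)}"
        )

    def has_pair(self, query: str) -> bool:
        return any(cand in self.pairs for cand in _label_variants(query))


@dataclass
class StarDocument:
    """An ordered collection of uniquely named blocks."""

    blocks: List[StarBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise StarValidationError(f"duplicate block names: {names}")

    def __iter__(self) -> Iterator[StarBlock]:
        return iter(self.blocks)

    def block_names(self) -> List[str]:
        return [b.name for b in self.blocks]

    def get_block(self, name: str) -> StarBlock:
        stripped = name[5:] if name.startswith("data_") else name
        for block in self.blocks:
            if block.name == stripped:
                return block
        raise StarLookupError(
            f"block {name!r} not found; available: "
            f"{['data_' + b.name for b in self.blocks]}"
        )

    def has_block(self, name: str) -> bool:
        stripped = name[5:] if name.startswith("data_") else name
        return any(b.name == stripped for b in self.blocks)


def get_table(doc: StarDocument, block: str = "first-loop") -> LoopTable:
    """Fetch a loop table by block name, or the first loop in the document.

    ``block="first-loop"`` returns the loop of the first block that has
    one (RELION files often put a pairs-only ``data_optics`` or general
    block first).
    """
    if block == "first-loop":
        for b in doc.blocks:
            if b.table is not None:
                return b.table
        raise StarLookupError(
            f"no loop table in document; blocks: "
            f"{['data_' + b.name for b in doc.blocks]}"
        )
    b = doc.get_block(block)
    if b.table is None:
        raise StarLookupError(
            f"block 'data_{b.name}' has no loop table; blocks with loops: "
            f"{['data_' + x.name for x in doc.blocks if x.table is not None]}"
        )
    return b.table


# ---------------------------------------------------------------------------
# Parsing


def _tokenize(line: str) -> List[Tuple[str, bool]]:
    """Split a STAR data line into (token, was_quoted) pairs.

    Honours single/double quotes and strips ``#`` comments.  Quoted
    tokens are always treated as text downstream, never re-typed.
    """
    tokens: List[Tuple[str, bool]] = []
    i, n = 0, len(line)
    while i < n:
        ch = line[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "#":
            break
        if ch in "'\"":
            j = line.find(ch, i + 1)
            if j < 0:
                raise StarParseError(f"unterminated quote in line: {line!r}")
            tokens.append((line[i + 1 : j], True))
            i = j + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            tokens.append((line[i:j], False))
            i = j
    return tokens


def _cell(token: str, quoted: bool) -> Scalar:
    return token if quoted else _type_cell(token)


def parse_star(text: str) -> StarDocument:
    """Parse STAR text into a :class:`StarDocument`.

    Comments (``#`` to end of line) are discarded.  Malformed loops
    (row width differing from the label count) and duplicate block names
    raise :class:`StarParseError` naming the offending line.
    """
    blocks: List[StarBlock] = []
    cur: Optional[StarBlock] = None
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        raw = lines[i]
        stripped = raw.strip()
        i += 1
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("data_"):
            name = stripped[5:]
            if any(b.name == name for b in blocks):
                raise StarParseError(
                    f"line {i}: duplicate block name 'data_{name}'"
                )
            cur = StarBlock(name=name)
            blocks.append(cur)
            continue
        if cur is None:
            raise StarParseError(f"line {i}: content before any data_ block: {raw!r}")
        if stripped == "loop_":
            if cur.table is not None:
                raise StarParseError(
                    f"line {i}: second loop_ in block 'data_{cur.name}'"
                )
            labels: List[str] = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith("#"):
                    i += 1
                    continue
                if s.startswith("_"):
                    labels.append(_tokenize(s)[0][0])
                    i += 1
                    continue
                break
            if not labels:
                raise StarParseError(f"line {i}: loop_ without labels")
            rows: List[Tuple[Scalar, ...]] = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith("#"):
                    i += 1
                    continue
                if s.startswith("data_") or s == "loop_" or s.startswith("_"):
                    break
                cells = _tokenize(s)
                if len(cells) != len(labels):
                    raise StarParseError(
                        f"line {i + 1}: loop row has {len(cells)} cells, "
                        f"expected {len(labels)}"
                    )
                rows.append(tuple(_cell(tok, q) for tok, q in cells))
                i += 1
            cur.table = LoopTable(labels, rows)
            continue
        if stripped.startswith("_"):
            tokens = _tokenize(stripped)
            if len(tokens) != 2:
                raise StarParseError(
                    f"line {i}: expected '_label value', got {raw!r}"
                )
            (label, _), (value, quoted) = tokens
            if label in cur.pairs:
                raise StarParseError(
                    f"line {i}: duplicate pair label {label!r} "
                    f"in block 'data_{cur.name}'"
                )
            cur.pairs[label] = _cell(value, quoted)
            continue
        raise StarParseError(f"line {i}: unexpected content: {raw!r}")
    return StarDocument(blocks)


# ---------------------------------------------------------------------------
# Writing


def write_star(doc: StarDocument, header: bool = True) -> str:
    """Serialize a document; pairs are emitted before the loop in each block."""
    out: List[str] = []
    if header:
        out.append(GENERATED_BY)
        out.append("")
    for block in doc.blocks:
        out.append(f"data_{block.name}")
        out.append("")
        if block.pairs:
            width = max(len(lbl) for lbl in block.pairs)
            for label, value in block.pairs.items():
                if not label.startswith("_"):
                    raise StarValidationError(
                        f"pair label must start with '_': {label!r}"
                    )
                out.append(f"{label.ljust(width)}  {format_value(value)}")
            out.append("")
        if block.table is not None:
            table = block.table
            out.append("loop_")
            for label in table.labels:
                if not label.startswith("_"):
                    raise StarValidationError(
                        f"loop label must start with '_': {label!r}"
                    )
                out.append(label)
            for row in table.rows:
                out.append("  ".join(format_value(c) for c in row))
            out.append("")
    return "\n".join(out) + "\n"


def read_star(path) -> StarDocument:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_star(fh.read())


def write_star_file(doc: StarDocument, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_star(doc))
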