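"""Morphological character matrices: parsing, validation, subsetting, I/O.

Cells are coded as admissible-state sets: an observed cell has one state, a
polymorphic cell (``[01]``) several, and missing (``?``) or inapplicable
(``-``) cells admit every state of their character.  Three text dialects are
supported: ``simple`` (one taxon per line), ``tnt`` (xread) and ``nexus``
(DATA block).  The bundled data set is the published 33-taxon x 63-character
matrix for the vent-shrimp family Alvinocarididae with both caridean
outgroups.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

Dialect = Literal["simple", "tnt", "nexus"]
Kind = Literal["observed", "polymorphic", "missing", "inapplicable"]

_TOKEN = re.compile(r"\[[0-9]+\]|[0-9]|\?|-")


class MatrixError(ValueError):
    pass


@dataclass(frozen=True)
class CharacterDefinition:
    """One column of the matrix: a discrete, unordered character."""

    index: int
    label: str
    state_labels: tuple[str, ...]

    @property
    def max_state(self) -> int:
        return len(self.state_labels) - 1

    def __post_init__(self):
        if not 0 <= self.max_state <= 7:
            raise MatrixError(f"character {self.index}: max_state out of range")


@dataclass(frozen=True)
class CellCoding:
    """Admissible-state set of one taxon for one character."""

    kind: Kind
    states: frozenset[int]

    def __post_init__(self):
        if self.kind == "observed" and len(self.states) != 1:
            raise MatrixError("observed cell must have exactly one state")
        if self.kind == "polymorphic" and len(self.states) < 2:
            raise MatrixError("polymorphic cell must have >= 2 states")
        if not self.states:
            raise MatrixError("empty state set")

    def __eq__(self, other):
        if not isinstance(other, CellCoding):
            return NotImplemented
        if self.kind != other.kind:
            return False
        if self.kind in ("missing", "inapplicable"):
            return True  # admissible set is derived, not data
        return self.states == other.states

    def __hash__(self):
        return hash((self.kind, None if self.kind in ("missing", "inapplicable")
                     else self.states))

    def token(self) -> str:
        if self.kind == "missing":
            return "?"
        if self.kind == "inapplicable":
            return "-"
        if self.kind == "observed":
            return str(next(iter(self.states)))
        return "[" + "".join(str(s) for s in sorted(self.states)) + "]"


@dataclass
class CharacterMatrix:
    """A taxa x characters grid of admissible-state sets."""

    taxa: tuple[str, ...]
    characters: tuple[CharacterDefinition, ...]
    cells: tuple[tuple[CellCoding, ...], ...]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon names")
        nc = len(self.characters)
        for name, row in zip(self.taxa, self.cells):
            if len(row) != nc:
                raise MatrixError(
                    f"taxon {name!r} has {len(row)} scores, expected {nc}")
            for c, cell in enumerate(row):
                if not cell.states <= set(range(self.characters[c].max_state + 1)):
                    raise MatrixError(
                        f"taxon {name!r}, character {c}: state outside declared range")

    # -- queries --------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> tuple[CellCoding, ...]:
        return self.cells[self.taxa.index(taxon)]

    def multistate_characters(self) -> list[int]:
        """Indices of characters with three or more defined states."""
        return [c.index for c in self.characters if c.max_state >= 2]

    def __eq__(self, other):
        return (isinstance(other, CharacterMatrix)
                and self.taxa == other.taxa
                and self.n_characters == other.n_characters
                and self.cells == other.cells)


def _cell_from_token(tok: str, max_state: int, pos: str) -> CellCoding:
    full = frozenset(range(max_state + 1))
    if tok == "?":
        return CellCoding("missing", full)
    if tok == "-":
        return CellCoding("inapplicable", full)
    if tok.startswith("["):
        states = frozenset(int(ch) for ch in tok[1:-1])
        return CellCoding("polymorphic", states)
    if tok.isdigit():
        return CellCoding("observed", frozenset({int(tok)}))
    raise MatrixError(f"unknown symbol {tok!r} at {pos}")


def _tokenize_row(scores: str, taxon: str) -> list[str]:
    toks = _TOKEN.findall(scores)
    if sum(len(t) for t in toks) != len(re.sub(r"\s", "", scores)):
        bad = re.sub(r"\s|\[[0-9]+\]|[0-9?-]", "", scores)
        raise MatrixError(f"unknown symbol {bad[:1]!r} in row for {taxon!r}")
    return toks


def _build(rows: list[tuple[str, list[str]]],
           characters: Sequence[CharacterDefinition] | None,
           expected_nchar: int | None = None) -> CharacterMatrix:
    if not rows:
        raise MatrixError("no taxon rows found")
    nchar = expected_nchar or (len(characters) if characters else len(rows[0][1]))
    for name, toks in rows:
        if len(toks) != nchar:
            raise MatrixError(
                f"taxon {name!r} has {len(toks)} scores, expected {nchar}")
    if characters is None:
        maxstate = [1] * nchar  # binary floor; raised by observations
        for _, toks in rows:
            for c, t in enumerate(toks):
                for ch in t.strip("[]"):
                    if ch.isdigit():
                        maxstate[c] = max(maxstate[c], int(ch))
        characters = [
            CharacterDefinition(c, f"char_{c}",
                                tuple(str(s) for s in range(maxstate[c] + 1)))
            for c in range(nchar)
        ]
    taxa = tuple(name for name, _ in rows)
    cells = tuple(
        tuple(_cell_from_token(t, characters[c].max_state,
                               f"{name!r} character {c}")
              for c, t in enumerate(toks))
        for name, toks in rows)
    return CharacterMatrix(taxa, tuple(characters), cells)


def normalize_name(label: str) -> str:
    """Strip italics markers and collapse spaces to underscores."""
    label = label.replace("*", "").replace("_", " ").strip()
    return re.sub(r"\s+", "_", label)


# -- dialect parsing ------------------------------------------------------

def parse_matrix(text: str, dialect: Dialect = "simple",
                 characters: Sequence[CharacterDefinition] | None = None
                 ) -> CharacterMatrix:
    """Parse a character matrix.

    ``?`` is missing, ``-`` inapplicable, ``[ab]`` a polymorphic cell and a
    digit an observed state; whitespace inside a row is ignored.
    """
    if not text.strip():
        raise MatrixError("empty matrix text")
    if dialect == "simple":
        return _parse_simple(text, characters)
    if dialect == "tnt":
        return _parse_tnt(text, characters)
    if dialect == "nexus":
        return _parse_nexus(text, characters)
    raise MatrixError(f"unsupported dialect {dialect!r}")


def _parse_simple(text, characters):
    rows = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        try:
            name, scores = ln.split(None, 1)
        except ValueError:
            raise MatrixError(f"malformed row: {ln[:40]!r}")
        rows.append((normalize_name(name), _tokenize_row(scores, name)))
    return _build(rows, characters)


def _parse_tnt(text, characters):
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*?);",
                  text, re.S | re.I)
    if not m:
        raise MatrixError("no xread block found")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    rows = []
    for ln in m.group(3).splitlines():
        ln = ln.strip()
        if not ln:
            continue
        name, scores = ln.split(None, 1)
        rows.append((normalize_name(name), _tokenize_row(scores, name)))
    if len(rows) != ntax:
        raise MatrixError(f"xread declares {ntax} taxa, found {len(rows)}")
    return _build(rows, characters, expected_nchar=nchar)


def _parse_nexus(text, characters):
    m = re.search(r"matrix(.*?);", text, re.S | re.I)
    dims = re.search(r"ntax\s*=\s*(\d+).*?nchar\s*=\s*(\d+)", text, re.S | re.I)
    if not m or not dims:
        raise MatrixError("no NEXUS matrix block found")
    ntax, nchar = int(dims.group(1)), int(dims.group(2))
    rows = []
    for ln in m.group(1).splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("["):
            continue
        if ln.startswith("'"):
            name, scores = re.match(r"'([^']*)'\s*(.*)", ln).groups()
        else:
            name, scores = ln.split(None, 1)
        rows.append((normalize_name(name), _tokenize_row(scores, name)))
    if len(rows) != ntax:
        raise MatrixError(f"NEXUS declares {ntax} taxa, found {len(rows)}")
    return _build(rows, characters, expected_nchar=nchar)


# -- writing --------------------------------------------------------------

def write_matrix(matrix: CharacterMatrix, dialect: Dialect = "simple") -> str:
    """Serialize; ``parse_matrix(write_matrix(m), d)`` reproduces ``m``."""
    rows = [(t, "".join(c.token() for c in row))
            for t, row in zip(matrix.taxa, matrix.cells)]
    width = max(len(t) for t, _ in rows) + 2
    body = "\n".join(f"{t:<{width}}{s}" for t, s in rows)
    if dialect == "simple":
        return body + "\n"
    if dialect == "tnt":
        return (f"xread 'exported matrix' {matrix.n_characters} {matrix.n_taxa}\n"
                f"{body}\n;\nproc /;\n")
    if dialect == "nexus":
        symbols = "".join(str(s) for s in range(
            max(c.max_state for c in matrix.characters) + 1))
        return ("#NEXUS\nBEGIN DATA;\n"
                f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n"
                f"  FORMAT DATATYPE=STANDARD SYMBOLS=\"{symbols}\" "
                "MISSING=? GAP=-;\n  MATRIX\n"
                + "\n".join("    " + f"{t:<{width}}{s}" for t, s in rows)
                + "\n  ;\nEND;\n")
    raise MatrixError(f"unsupported dialect {dialect!r}")


# -- subsetting ------------------------------------------------------------

def subset_taxa(matrix: CharacterMatrix, keep: Iterable[str]) -> CharacterMatrix:
    """Restrict and reorder rows to *keep*; characters unchanged."""
    keep = list(keep)
    index = {t: i for i, t in enumerate(matrix.taxa)}
    missing = [t for t in keep if t not in index]
    if missing:
        raise MatrixError(f"unknown taxa: {', '.join(missing)}")
    if len(set(keep)) != len(keep):
        raise MatrixError("duplicate taxa in keep list")
    return CharacterMatrix(
        tuple(keep), matrix.characters,
        tuple(matrix.cells[index[t]] for t in keep),
        aliases={k: v for k, v in matrix.aliases.items() if k in keep})


# -- bundled data ----------------------------------------------------------

#: Taxon-label aliases: the published matrix rows use these labels although
#: the accompanying text treats the aliased names as the valid ones.
BUNDLED_ALIASES = {
    "Rimicaris_loihi": "Opaepele_loihi",
    "Alvinocaris_chelis": "Alvinocaris_chelys",
}


def load_bundled_characters() -> tuple[CharacterDefinition, ...]:
    text = resources.files("morphoclad.data").joinpath(
        "alvinocarididae_characters.tsv").read_text()
    chars = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        idx, label, states = ln.split("\t")
        chars.append(CharacterDefinition(int(idx), label,
                                         tuple(states.split(";"))))
    return tuple(chars)


def load_bundled_matrix() -> CharacterMatrix:
    """The packaged 33 x 63 Alvinocarididae matrix, validated."""
    chars = load_bundled_characters()
    text = resources.files("morphoclad.data").joinpath(
        "alvinocarididae_matrix.txt").read_text()
    m = _parse_simple(text, chars)
    m.aliases.update(BUNDLED_ALIASES)
    if (m.n_taxa, m.n_characters) != (33, 63):
        raise MatrixError("bundled matrix is corrupt")
    return m
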