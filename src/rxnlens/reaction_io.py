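"""Parsing, tokenization and serialization of reaction SMILES.

Every other part of the toolkit consumes the two containers defined here:

* :class:`ReactionRecord` — one reaction (``reactants>reagents>products``),
  each side a list of SMILES strings.
* :class:`TokenizedInput` — an atom-level tokenization of a SMILES (or
  reaction-SMILES) string together with per-token character spans, so that
  attribution values computed on tokens can always be mapped back onto the
  exact characters of the input.

The tokenizer follows the atom-level convention used by SMILES
sequence-to-sequence models: multi-character elements (``Cl``, ``Br``),
bracket atoms (``[OH-]``, ``[nH]``) and two-digit ring closures (``%12``)
are single tokens; every other character (digits, bonds, parentheses,
``.``, ``>``) is its own token.  Concatenating the tokens reproduces the
input string exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ReactionRecord",
    "TokenizedInput",
    "TokenizationError",
    "ReactionFormatError",
    "SmilesParseError",
    "tokenize_smiles",
    "canonicalize",
    "parse_reaction_line",
    "reaction_line",
    "source_string",
    "read_corpus",
    "write_corpus",
    "read_src_tgt",
]

# Atom-level SMILES tokenization (bracket blocks, two-char elements and
# %NN ring closures kept whole).  The trailing "." branch catches any
# single character so unknown characters can be reported with an offset.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|%\d{2}|Cl|Br|Si|Se|se|@@|[BCNOPSFIbcnops]"
    r"|[=#\-\+\\/:~\*\$\(\)\.>@]|\d)"
)

_VALID_TOKEN_RE = re.compile(
    r"\A(\[[^\]]+\]|%\d{2}|Cl|Br|Si|Se|se|@@|[BCNOPSFIbcnops]"
    r"|[=#\-\+\\/:~\*\$\(\)\.>@]|\d)\Z"
)


class TokenizationError(ValueError):
    """A character that is not part of the SMILES token alphabet."""


class ReactionFormatError(ValueError):
    """A reaction line that does not follow ``reactants>reagents>products``."""


class SmilesParseError(ValueError):
    """A SMILES string the chemistry toolkit cannot parse."""


@dataclass(frozen=True)
class TokenizedInput:
    """A tokenized source string with per-token character offsets.

    ``spans`` are 0-based half-open ``(start, end)`` offsets into ``raw``;
    they are contiguous, non-overlapping and cover the whole string, so
    ``"".join(tokens) == raw`` always holds.
    """

    raw: str
    tokens: tuple[str, ...]
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise ValueError("TokenizedInput requires at least one token")
        if "".join(self.tokens) != self.raw:
            raise ValueError("tokens do not concatenate to raw string")
        if len(self.tokens) != len(self.spans):
            raise ValueError("tokens and spans length mismatch")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class ReactionRecord:
    """One reaction: reactants, reagents (may be empty) and products."""

    id: str
    reactants: list[str]
    reagents: list[str]
    products: list[str]
    metadata: dict[str, str] = field(default_factory=dict)


def tokenize_smiles(s: str) -> TokenizedInput:
    """Tokenize a SMILES or reaction-SMILES string at the atom level.

    Raises :class:`TokenizationError` naming the character offset if a
    character outside the token alphabet is met.
    """
    if not s:
        raise TokenizationError("cannot tokenize an empty string")
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    for m in _TOKEN_RE.finditer(s):
        if m.start() != pos:
            raise TokenizationError(
                f"unrecognized character {s[pos]!r} at offset {pos} in {s!r}"
            )
        tokens.append(m.group(0))
        spans.append((m.start(), m.end()))
        pos = m.end()
    if pos != len(s):
        raise TokenizationError(
            f"unrecognized character {s[pos]!r} at offset {pos} in {s!r}"
        )
    return TokenizedInput(raw=s, tokens=tuple(tokens), spans=tuple(spans))


def is_token(s: str) -> bool:
    """True if ``s`` is a single token of the SMILES alphabet."""
    return bool(_VALID_TOKEN_RE.match(s))


def canonicalize(s: str) -> str:
    """Return the toolkit-canonical SMILES of ``s``.  Idempotent."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {s!r}")
    return Chem.MolToSmiles(mol)


def _parse_side(side: str, what: str, line: str) -> list[str]:
    side = side.strip()
    if not side:
        return []
    mols = side.split(".")
    for m in mols:
        if Chem.MolFromSmiles(m) is None:
            raise SmilesParseError(
                f"molecule {m!r} in {what} of line {line!r} does not parse"
            )
    return mols


def parse_reaction_line(line: str, id: str = "") -> ReactionRecord:
    """Parse one ``reactants>reagents>products`` line into a record.

    The line must contain exactly two ``>`` separators; every molecule must
    parse; the products side must be non-empty.
    """
    stripped = line.strip()
    parts = stripped.split(">")
    if len(parts) != 3:
        raise ReactionFormatError(
            f"expected exactly two '>' separators, got {len(parts) - 1} "
            f"in line {line!r}"
        )
    reactants = _parse_side(parts[0], "reactants", stripped)
    reagents = _parse_side(parts[1], "reagents", stripped)
    products = _parse_side(parts[2], "products", stripped)
    if not reactants:
        raise ReactionFormatError(f"empty reactants in line {line!r}")
    if not products:
        raise ReactionFormatError(f"empty products in line {line!r}")
    return ReactionRecord(
        id=id, reactants=reactants, reagents=reagents, products=products
    )


def reaction_line(record: ReactionRecord) -> str:
    """Serialize a record back to ``reactants>reagents>products``."""
    return ">".join(
        (
            ".".join(record.reactants),
            ".".join(record.reagents),
            ".".join(record.products),
        )
    )


def source_string(record: ReactionRecord) -> str:
    """The single source string fed to the model: reactants then reagents,
    in input order, joined by ``.``."""
    return ".".join(record.reactants + record.reagents)


def reagent_molecule_indices(record: ReactionRecord) -> tuple[int, ...]:
    """Indices (in the ``.``-split of :func:`source_string`) of the reagent
    molecules."""
    n = len(record.reactants)
    return tuple(range(n, n + len(record.reagents)))


def read_corpus(path) -> list[ReactionRecord]:
    """Read a reaction-line file; ids are ``r0, r1, ...`` in file order."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            records.append(parse_reaction_line(line, id=f"r{i}"))
    return records


def write_corpus(records, path, dialect: str = "reaction-line") -> None:
    """Write a corpus.

    ``reaction-line``: one ``reactants>reagents>products`` line per record,
    written to ``path``.

    ``src-tgt``: two parallel files ``<path>.src`` / ``<path>.tgt`` of
    space-joined tokens; source is the reactant-reagent string, target the
    product string.
    """
    if dialect == "reaction-line":
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(reaction_line(r) + "\n")
    elif dialect == "src-tgt":
        with open(f"{path}.src", "w", encoding="utf-8") as fs, open(
            f"{path}.tgt", "w", encoding="utf-8"
        ) as ft:
            for r in records:
                src = tokenize_smiles(source_string(r))
                tgt = tokenize_smiles(".".join(r.products))
                fs.write(" ".join(src.tokens) + "\n")
                ft.write(" ".join(tgt.tokens) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_src_tgt(prefix) -> list[tuple[list[str], list[str]]]:
    """Read parallel ``<prefix>.src`` / ``<prefix>.tgt`` token files."""
    with open(f"{prefix}.src", encoding="utf-8") as fs:
        src = [line.split() for line in fs if line.strip()]
    with open(f"{prefix}.tgt", encoding="utf-8") as ft:
        tgt = [line.split() for line in ft if line.strip()]
    if len(src) != len(tgt):
        raise ReactionFormatError(
            f"parallel files differ in length: {len(src)} vs {len(tgt)}"
        )
    return list(zip(src, tgt))
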