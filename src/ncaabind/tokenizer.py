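"""Parsing and tokenization of the IEDB modified-peptide name notation.

An IEDB ``Name`` cell such as ``GILGFVFTV + OTH(V9)`` carries a base peptide
sequence followed, after a ``+`` sign, by one or more modification groups.
The text between the ``+`` and the parentheses is the modification method;
the parenthetical lists the modified residues as ``<letter><1-based
position>`` items.  Tokenization replaces each modified position's
one-letter token with a compound non-canonical token, by default
``<letter>_<method>`` (e.g. ``V_OTH``), so the downstream chemistry lookup
can distinguish a modified valine from the canonical one.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .errors import PeptideParseError
from .registry import CANONICAL_TOKENS

_GROUP_RE = re.compile(r"([A-Za-z0-9\-]+)\s*\(([^()]*)\)")
_ITEM_RE = re.compile(r"^([A-Z])(\d+)$")
_BASE_RE = re.compile(r"^[A-Z]+$")

#: Peptide lengths the fixed-width encoder supports.
DEFAULT_LENGTHS = frozenset({9, 10})


@dataclass(frozen=True)
class ModificationTag:
    """One modified residue: method label, residue letter, 1-based position."""

    method: str
    residue_letter: str
    position: int


def default_naming(tag: ModificationTag) -> str:
    """Author-style compound token id: ``<letter>_<method>``."""
    return f"{tag.residue_letter}_{tag.method}"


@dataclass(frozen=True)
class TokenizedPeptide:
    """Ordered residue tokens for one peptide, N- to C-terminus."""

    base_sequence: str
    tokens: tuple[str, ...]
    mods: tuple[ModificationTag, ...] = ()

    def __post_init__(self):
        if len(self.tokens) != len(self.base_sequence):
            raise ValueError("token list length must equal base sequence length")

    @property
    def length(self) -> int:
        return len(self.base_sequence)

    @property
    def ncaa_positions(self) -> tuple[int, ...]:
        return tuple(sorted(m.position for m in self.mods))

    def render_name(self) -> str:
        """Inverse of :func:`parse_name`: rebuild the IEDB ``Name`` notation.

        Modification groups are emitted in order of first appearance of each
        method, each listing its positions N->C.
        """
        if not self.mods:
            return self.base_sequence
        by_method: dict[str, list[ModificationTag]] = {}
        for tag in sorted(self.mods, key=lambda t: t.position):
            by_method.setdefault(tag.method, []).append(tag)
        groups = ", ".join(
            f"{method}({', '.join(f'{t.residue_letter}{t.position}' for t in tags)})"
            for method, tags in by_method.items()
        )
        return f"{self.base_sequence} + {groups}"


def parse_name(name_field: str) -> tuple[str, list[ModificationTag]]:
    """Split an IEDB ``Name`` cell into base sequence and modification tags.

    The cell is split on the first ``+``; the left part is the base sequence
    and the right part, when present, is one or more comma-separated
    ``METHOD(XN[, XN...])`` groups.  Unrecognized suffix syntax is rejected
    rather than guessed.
    """
    if not name_field or not name_field.strip():
        raise PeptideParseError("empty Name field")
    head, plus, tail = name_field.partition("+")
    base = head.strip()
    if not _BASE_RE.match(base):
        raise PeptideParseError(
            f"base sequence {base!r} in {name_field!r} must be uppercase letters only"
        )
    mods: list[ModificationTag] = []
    if plus:
        tail = tail.strip()
        if not tail:
            raise PeptideParseError(f"{name_field!r}: '+' with no modification groups")
        consumed = _GROUP_RE.sub("", tail).replace(",", "").strip()
        if consumed:
            raise PeptideParseError(
                f"{name_field!r}: unrecognized modification syntax {consumed!r}"
            )
        for method, inner in _GROUP_RE.findall(tail):
            items = [it.strip() for it in inner.split(",")]
            if not any(items):
                raise PeptideParseError(f"{name_field!r}: empty parenthetical for {method}")
            for item in items:
                m = _ITEM_RE.match(item)
                if not m:
                    raise PeptideParseError(
                        f"{name_field!r}: malformed residue item {item!r} in {method}(...)"
                    )
                letter, pos = m.group(1), int(m.group(2))
                if not 1 <= pos <= len(base):
                    raise PeptideParseError(
                        f"{name_field!r}: position {pos} outside 1..{len(base)}"
                    )
                if base[pos - 1] != letter:
                    raise PeptideParseError(
                        f"{name_field!r}: residue letter {letter} does not match "
                        f"base sequence character {base[pos - 1]!r} at position {pos}"
                    )
                mods.append(ModificationTag(method=method, residue_letter=letter, position=pos))
    return base, mods


def tokenize(
    base_sequence: str,
    mods: Sequence[ModificationTag] = (),
    naming: Callable[[ModificationTag], str] = default_naming,
    allowed_lengths: frozenset[int] | set[int] | None = DEFAULT_LENGTHS,
) -> TokenizedPeptide:
    """Produce the ordered token list for one peptide.

    Position ``i`` carries the one-letter code when unmodified, otherwise the
    compound token produced by *naming*.  Two modifications at the same
    position are rejected (the notation cannot express stacking order).
    """
    if allowed_lengths is not None and len(base_sequence) not in allowed_lengths:
        raise PeptideParseError(
            f"peptide length {len(base_sequence)} not in supported lengths "
            f"{sorted(allowed_lengths)}: {base_sequence!r}"
        )
    if not _BASE_RE.match(base_sequence):
        raise PeptideParseError(f"invalid base sequence {base_sequence!r}")
    positions = [m.position for m in mods]
    dupes = {p for p in positions if positions.count(p) > 1}
    if dupes:
        raise PeptideParseError(
            f"duplicate modification positions {sorted(dupes)} on {base_sequence!r}"
        )
    tokens = list(base_sequence)
    for tag in mods:
        if base_sequence[tag.position - 1] != tag.residue_letter:
            raise PeptideParseError(
                f"tag {tag} inconsistent with base sequence {base_sequence!r}"
            )
        tokens[tag.position - 1] = naming(tag)
    return TokenizedPeptide(
        base_sequence=base_sequence,
        tokens=tuple(tokens),
        mods=tuple(sorted(mods, key=lambda t: t.position)),
    )


def tokenize_name(name_field: str, **kwargs) -> TokenizedPeptide:
    """Convenience: :func:`parse_name` followed by :func:`tokenize`."""
    base, mods = parse_name(name_field)
    return tokenize(base, mods, **kwargs)


def is_ncaa_token(token: str) -> bool:
    """Multi-character tokens denote non-canonical amino acids."""
    return len(token) > 1 or token not in CANONICAL_TOKENS


@dataclass
class TokenCensus:
    """Dataset-wide token usage: overall and per-position counts."""

    per_token_counts: dict[str, int] = field(default_factory=dict)
    per_position_counts: dict[tuple[int, str], int] = field(default_factory=dict)

    @property
    def n_canonical_tokens(self) -> int:
        return sum(1 for t in self.per_token_counts if not is_ncaa_token(t))

    @property
    def n_ncaa_tokens(self) -> int:
        return sum(1 for t in self.per_token_counts if is_ncaa_token(t))

    @property
    def total_residues(self) -> int:
        return sum(self.per_token_counts.values())

    def to_dict(self) -> dict:
        return {
            "per_token_counts": dict(sorted(self.per_token_counts.items())),
            "per_position_counts": {
                f"{pos}:{tok}": n
                for (pos, tok), n in sorted(self.per_position_counts.items())
            },
            "n_canonical_tokens": self.n_canonical_tokens,
            "n_ncaa_tokens": self.n_ncaa_tokens,
        }


def census(dataset: Iterable[TokenizedPeptide]) -> TokenCensus:
    """Count token usage overall and per residue position (1-based, N->C)."""
    per_token: Counter[str] = Counter()
    per_position: Counter[tuple[int, str]] = Counter()
    for pep in dataset:
        for i, tok in enumerate(pep.tokens, start=1):
            per_token[tok] += 1
            per_position[(i, tok)] += 1
    return TokenCensus(per_token_counts=dict(per_token), per_position_counts=dict(per_position))
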