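"""RNA secondary structures in dot-bracket form.

Parsing, serialization, validation against pairing rules, a deterministic
base-pair-maximization predictor (Nussinov-style dynamic programming), and
Vienna-style structure file I/O.

Indices are 0-based throughout and run 5'->3'.  Only round brackets are
supported; pseudoknots are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "StructureFormatError",
    "SecondaryStructure",
    "PairingRules",
    "CANONICAL_RULES",
    "PairCheck",
    "ValidationReport",
    "parse_dot_bracket",
    "to_dot_bracket",
    "validate_structure",
    "predict_structure",
    "read_vienna",
    "write_vienna",
]

_DB_CHARS = frozenset(".()")
_PSEUDOKNOT_CHARS = frozenset("[]{}<>")


class StructureFormatError(ValueError):
    """Raised for malformed dot-bracket strings or structure files."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of non-crossing base pairs over a sequence of given length.

    Attributes
    ----------
    length:
        Number of nucleotides.
    dot_bracket:
        Dot-bracket string over ``.()``, length ``length``.
    pairs:
        Frozen set of ``(i, j)`` index pairs, 0-based, ``i < j``.
    """

    length: int
    dot_bracket: str
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != self.length:
            raise StructureFormatError(
                f"dot-bracket length {len(self.dot_bracket)} != declared length {self.length}"
            )

    @property
    def paired_fraction(self) -> float:
        """Fraction of positions involved in a base pair."""
        if self.length == 0:
            return 0.0
        return 2.0 * len(self.pairs) / self.length

    def paired_positions(self) -> frozenset[int]:
        return frozenset(i for p in self.pairs for i in p)


@dataclass(frozen=True)
class PairingRules:
    """Which nucleotide pairs may bond, and the minimum hairpin loop size."""

    allowed_pairs: frozenset[str] = frozenset(
        {"AU", "UA", "GC", "CG", "GU", "UG"}
    )
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        for p in self.allowed_pairs:
            if p[::-1] not in self.allowed_pairs:
                raise ValueError(f"allowed_pairs not symmetric: {p} without {p[::-1]}")

    def allows(self, a: str, b: str) -> bool:
        return a + b in self.allowed_pairs


CANONICAL_RULES = PairingRules()


def parse_dot_bracket(db: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Raises
    ------
    StructureFormatError
        On empty input, illegal characters (including pseudoknot bracket
        types), or unbalanced brackets.
    """
    if not db:
        raise StructureFormatError("empty dot-bracket string")
    pairs: set[tuple[int, int]] = set()
    stack: list[int] = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureFormatError(
                    f"unbalanced dot-bracket: unmatched ')' at position {idx}"
                )
            pairs.add((stack.pop(), idx))
        elif ch == ".":
            continue
        elif ch in _PSEUDOKNOT_CHARS:
            raise StructureFormatError(
                f"pseudoknot bracket {ch!r} at position {idx} is not supported"
            )
        else:
            raise StructureFormatError(f"illegal character {ch!r} at position {idx}")
    if stack:
        raise StructureFormatError(
            f"unbalanced dot-bracket: unmatched '(' at position {stack[-1]}"
        )
    return SecondaryStructure(length=len(db), dot_bracket=db, pairs=frozenset(pairs))


def to_dot_bracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    """Serialize a non-crossing pair set to a dot-bracket string.

    The inverse of :func:`parse_dot_bracket`:
    ``parse_dot_bracket(to_dot_bracket(p, n)).pairs == p``.
    """
    pair_list = sorted(tuple(p) for p in pairs)
    chars = ["."] * length
    seen: set[int] = set()
    for i, j in pair_list:
        if not (0 <= i < j < length):
            raise StructureFormatError(f"pair ({i}, {j}) out of range for length {length}")
        if i in seen or j in seen:
            raise StructureFormatError(f"index reused by pair ({i}, {j})")
        seen.update((i, j))
        chars[i], chars[j] = "(", ")"
    # crossing check: pairs sorted by i; a crossing exists iff some later pair
    # starts inside an earlier one and ends outside it
    for a in range(len(pair_list)):
        i, j = pair_list[a]
        for b in range(a + 1, len(pair_list)):
            k, l = pair_list[b]
            if k >= j:
                break
            if l > j:
                raise StructureFormatError(
                    f"crossing pairs ({i},{j}) and ({k},{l}): pseudoknots unsupported"
                )
    return "".join(chars)


def structure_from_pairs(pairs: Iterable[tuple[int, int]], length: int) -> SecondaryStructure:
    """Build a :class:`SecondaryStructure` from a pair set."""
    db = to_dot_bracket(pairs, length)
    return SecondaryStructure(length=length, dot_bracket=db, pairs=frozenset(map(tuple, pairs)))


@dataclass(frozen=True)
class PairCheck:
    pair: tuple[int, int]
    nucleotides: str
    pair_allowed: bool
    loop_ok: bool

    @property
    def ok(self) -> bool:
        return self.pair_allowed and self.loop_ok


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[PairCheck, ...]

    @property
    def ok(self) -> bool:
        return all(c.ok for c in self.checks)

    def failures(self) -> list[PairCheck]:
        return [c for c in self.checks if not c.ok]


def validate_structure(
    seq: str, s: SecondaryStructure, rules: PairingRules = CANONICAL_RULES
) -> ValidationReport:
    """Check every pair of ``s`` against ``rules`` for the sequence ``seq``."""
    if len(seq) != s.length:
        raise ValueError(
            f"sequence length {len(seq)} does not match structure length {s.length}"
        )
    seq = seq.upper().replace("T", "U")
    checks = []
    for i, j in sorted(s.pairs):
        checks.append(
            PairCheck(
                pair=(i, j),
                nucleotides=seq[i] + seq[j],
                pair_allowed=rules.allows(seq[i], seq[j]),
                loop_ok=(j - i - 1) >= rules.min_loop,
            )
        )
    return ValidationReport(checks=tuple(checks))


def predict_structure(
    seq: str, rules: PairingRules = CANONICAL_RULES
) -> SecondaryStructure:
    """Predict a maximum-base-pair non-crossing structure by dynamic programming.

    Maximizes the number of allowed pairs subject to ``rules.min_loop``.
    Traceback is deterministic: when leaving position ``i`` unpaired achieves
    the optimum it is preferred; otherwise ``i`` pairs with the smallest
    optimal partner ``j``.

    Parameters
    ----------
    seq:
        RNA sequence over ``{A, C, G, U}`` (``T`` is accepted and read as
        ``U``); any other symbol raises ``ValueError``.
    """
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"ambiguous or invalid nucleotides {sorted(bad)} in sequence")
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    min_loop = rules.min_loop

    # N[i][j]: max pairs in seq[i..j] inclusive
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if rules.allows(seq[i], seq[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    rest = N[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            N[i][j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < min_loop + 1:
            continue
        if N[i][j] == N[i + 1][j]:  # tie-break: prefer i unpaired
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):  # smallest optimal partner
            if rules.allows(seq[i], seq[k]):
                inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                rest = N[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + rest == N[i][j]:
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return structure_from_pairs(pairs, n)


# ---------------------------------------------------------------------------
# Vienna-style structure files


def read_vienna(path: str | Path) -> list[tuple[str, str, SecondaryStructure]]:
    """Read a Vienna-style structure file.

    Records are either three lines (``>id`` / sequence / dot-bracket) or two
    lines (sequence / dot-bracket); the two forms may not be mixed within a
    file. Returns ``(id, sequence, structure)`` triples; anonymous records
    get ids ``seq1, seq2, ...``.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    records: list[tuple[str, str, SecondaryStructure]] = []
    i = 0
    counter = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            if i + 2 >= len(lines):
                raise StructureFormatError(
                    f"truncated record {lines[i]!r} at line {i + 1}"
                )
            rid, seq, db = lines[i][1:].strip(), lines[i + 1].strip(), lines[i + 2].strip()
            i += 3
        else:
            if i + 1 >= len(lines):
                raise StructureFormatError(f"truncated record at line {i + 1}")
            counter += 1
            rid, seq, db = f"seq{counter}", lines[i].strip(), lines[i + 1].strip()
            i += 2
        s = parse_dot_bracket(db)
        if s.length != len(seq):
            raise StructureFormatError(
                f"record {rid!r}: structure length {s.length} != sequence length {len(seq)}"
            )
        records.append((rid, seq, s))
    return records


def write_vienna(
    records: Sequence[tuple[str, str, SecondaryStructure]], path: str | Path
) -> None:
    """Write ``(id, sequence, structure)`` triples in three-line Vienna form."""
    out = []
    for rid, seq, s in records:
        if s.length != len(seq):
            raise StructureFormatError(
                f"record {rid!r}: structure length {s.length} != sequence length {len(seq)}"
            )
        out.append(f">{rid}\n{seq}\n{s.dot_bracket}\n")
    Path(path).write_text("".join(out))
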