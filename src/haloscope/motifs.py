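"""Degenerate protein-motif compilation and scanning.

Flavin-dependent halogenases (FDHs) carry three diagnostic sequence
motifs: the N-terminal flavin-binding Rossmann fingerprint ``GxGxxG``,
the ``WxWxIP`` motif that blocks monooxygenase chemistry, and the
halogenase motif written here as ``Fx.Px.SxG``.  Genome mining for new
FDH candidates amounts to requiring all three motifs in N→C order.

Motif notation
--------------
``x`` matches exactly one arbitrary residue.  A ``.`` immediately
following an ``x`` (or another ``.``) widens that wildcard by one
position, so ``x.`` spans two residues and ``Fx.Px.SxG`` expands to
``F??P??S?G`` (minimum match length 9).  Any other uppercase residue
letter is a literal.  Users with a different reading of the published
motif can supply their own pattern string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_MOTIFS",
    "MotifPattern",
    "MotifHit",
    "ProteinSequence",
    "compile_motif",
    "scan_motifs",
    "screen_halogenase_candidates",
]

#: The 20 canonical residues plus 'X' (unknown), as accepted in sequences.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: The three FDH signature motifs in their required N→C order.
DEFAULT_MOTIFS = ("GxGxxG", "WxWxIP", "Fx.Px.SxG")


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence (uppercase, no gaps)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: "
                + ", ".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif.

    ``tokens`` is the ordered mix of literals and wildcards; each token is
    either a single residue letter or an integer wildcard span.
    """

    name: str
    tokens: tuple[str | int, ...]
    regex: re.Pattern = field(compare=False, repr=False)

    @property
    def min_length(self) -> int:
        return sum(t if isinstance(t, int) else 1 for t in self.tokens)

    def matches(self, fragment: str) -> bool:
        """Whether ``fragment`` satisfies the pattern exactly (full span)."""
        return len(fragment) == self.min_length and bool(
            self.regex.match(fragment)
        )


@dataclass(frozen=True)
class MotifHit:
    """One match of a motif in a sequence (0-based start, half-open span)."""

    motif_name: str
    sequence_id: str
    start: int
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched)


def compile_motif(pattern_text: str, name: str | None = None) -> MotifPattern:
    """Compile motif notation into a :class:`MotifPattern`.

    Parameters
    ----------
    pattern_text:
        Motif in the notation described in the module docstring, e.g.
        ``"GxGxxG"`` or ``"Fx.Px.SxG"``.
    name:
        Optional display name; defaults to the pattern text itself.

    Raises
    ------
    ValueError
        On an empty pattern, an illegal character (named in the message),
        a ``.`` with no preceding wildcard, or a pattern with no literal.
    """
    if not pattern_text:
        raise ValueError("motif pattern is empty")
    tokens: list[str | int] = []
    for ch in pattern_text:
        if ch == "x":
            if tokens and isinstance(tokens[-1], int):
                tokens[-1] += 1  # consecutive wildcards merge
            else:
                tokens.append(1)
        elif ch == ".":
            if not tokens or not isinstance(tokens[-1], int):
                raise ValueError(
                    f"'.' at position {len(tokens)} in {pattern_text!r} "
                    "does not follow a wildcard"
                )
            tokens[-1] += 1
        elif ch in AMINO_ACIDS or ch == "X":
            tokens.append(ch)
        else:
            raise ValueError(
                f"illegal character {ch!r} in motif pattern {pattern_text!r}"
            )
    if not any(isinstance(t, str) for t in tokens):
        raise ValueError(f"motif {pattern_text!r} has no literal residue")
    regex = re.compile(
        "".join(f".{{{t}}}" if isinstance(t, int) else re.escape(t) for t in tokens)
    )
    return MotifPattern(name=name or pattern_text, tokens=tuple(tokens), regex=regex)


def scan_motifs(
    seq: ProteinSequence, patterns: list[MotifPattern] | tuple[MotifPattern, ...]
) -> list[MotifHit]:
    """Find every (possibly overlapping) motif match in ``seq``.

    Returns hits sorted by ``(motif_name, start)``.  An empty list is a
    valid result.
    """
    hits: list[MotifHit] = []
    for pat in patterns:
        # lookahead makes overlapping matches visible
        finder = re.compile(f"(?=({pat.regex.pattern}))")
        for m in finder.finditer(seq.residues):
            hits.append(
                MotifHit(
                    motif_name=pat.name,
                    sequence_id=seq.id,
                    start=m.start(),
                    matched=m.group(1),
                )
            )
    hits.sort(key=lambda h: (h.motif_name, h.start))
    return hits


def _ordered_chain_exists(starts_by_motif: list[list[int]]) -> bool:
    """Whether one hit per motif can be picked with strictly ascending starts."""
    prev = -1
    for starts in starts_by_motif:
        nxt = [s for s in starts if s > prev]
        if not nxt:
            return False
        prev = min(nxt)  # greedy choice is optimal for a chain
    return True


def screen_halogenase_candidates(
    seqs: list[ProteinSequence],
    patterns: tuple[MotifPattern, MotifPattern, MotifPattern] | None = None,
) -> list[str]:
    """Select sequences carrying all three FDH motifs in N→C order.

    A sequence passes iff it has at least one hit of each motif and one
    hit per motif can be chosen with starts in ascending order
    motif1 < motif2 < motif3 (the flavin-binding motif is N-terminal in
    FDHs, so order is part of the signature).
    """
    if patterns is None:
        patterns = tuple(compile_motif(p) for p in DEFAULT_MOTIFS)  # type: ignore[assignment]
    if len(patterns) != 3:
        raise ValueError("exactly three motif patterns are required")
    selected = []
    for seq in seqs:
        hits = scan_motifs(seq, list(patterns))
        starts_by_motif = [
            sorted(h.start for h in hits if h.motif_name == pat.name)
            for pat in patterns
        ]
        if all(starts_by_motif) and _ordered_chain_exists(starts_by_motif):
            selected.append(seq.id)
    return selected
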