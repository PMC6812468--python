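"""Spaced seeds, reduced amino-acid alphabets, and spaced k-mer extraction.

A spaced seed is a match/don't-care pattern (written as a string of ``1``/``0``)
used to key k-mer lookups: only the residues under the ``1`` positions enter the
key, so mismatches are tolerated at the ``0`` positions.  The number of match
positions is the seed's *weight*.  A consecutive seed is the special case where
weight equals length.

Reduced alphabets group the 20 standard residues into fewer classes by
physico-chemical similarity; keying spaced k-mers on the reduced sequence
raises seed sensitivity at the cost of specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues outside the standard 20 (ambiguity/rare codes and the stop ``*``)
#: collapse to this wildcard group; windows whose match positions hit it are
#: skipped at indexing time to avoid spurious seed matches.
WILDCARD = "X"
AMBIGUOUS_RESIDUES = "XBZJUO*"


@dataclass(frozen=True)
class SpacedSeed:
    """A match/don't-care pattern governing spaced k-mer extraction."""

    pattern: str

    def __post_init__(self) -> None:
        p = self.pattern
        if not p:
            raise ValueError("empty spaced-seed pattern")
        bad = set(p) - {"0", "1"}
        if bad:
            raise ValueError(
                f"spaced seed {p!r}: invalid characters {sorted(bad)!r}; "
                "only '0' and '1' are allowed"
            )
        if p[0] != "1" or p[-1] != "1":
            raise ValueError(
                f"spaced seed {p!r} must start and end with a match "
                "position ('1'); leading/trailing don't-cares are meaningless"
            )

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def weight(self) -> int:
        """Number of match positions."""
        return self.pattern.count("1")

    @property
    def match_positions(self) -> Tuple[int, ...]:
        """0-based offsets of the match ('1') positions."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "1")

    @property
    def is_consecutive(self) -> bool:
        return self.weight == self.length

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.pattern


def parse_spaced_seed(pattern_text: str) -> SpacedSeed:
    """Parse a ``1``/``0`` pattern string into a :class:`SpacedSeed`.

    Tolerates surrounding whitespace; anything else malformed is rejected
    with a message naming the offending pattern.
    """
    return SpacedSeed(pattern_text.strip())


def parse_seed_list(text: str) -> List[SpacedSeed]:
    """Parse a comma-separated list of seed patterns, e.g. ``"1011111,11111"``."""
    seeds = [parse_spaced_seed(tok) for tok in text.split(",") if tok.strip()]
    if not seeds:
        raise ValueError(f"no seed patterns found in {text!r}")
    return seeds


def dont_care_positions(seed: SpacedSeed) -> List[int]:
    """1-based positions of the don't-care ('0') slots, ascending.

    The seed ``101101`` allows mismatches at positions 2 and 5.
    """
    return [i + 1 for i, c in enumerate(seed.pattern) if c == "0"]


#: The two default spaced-seed patterns (both weight 8).
DEFAULT_SEED_PATTERNS = ("1110100010001011", "11010110111")


def default_seeds() -> List[SpacedSeed]:
    """Both default weight-8 patterns; candidate generation unions their matches."""
    return [SpacedSeed(p) for p in DEFAULT_SEED_PATTERNS]


@dataclass(frozen=True)
class ReducedAlphabet:
    """A total mapping from residue letters to group letters.

    The mapping covers the 20 standard residues; ambiguity codes
    (``X B Z J U O *``) map to the wildcard group.  Group letters map to
    themselves so that reduction is idempotent.
    """

    name: str
    mapping: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        m = dict(self.mapping)
        missing = [a for a in STANDARD_AMINO_ACIDS if a not in m]
        if missing:
            raise ValueError(
                f"alphabet {self.name!r}: no group for residues {missing}"
            )
        for a in AMBIGUOUS_RESIDUES:
            m.setdefault(a, WILDCARD)
        # close the mapping over its own group letters (idempotence)
        for g in list(m.values()):
            m.setdefault(g, g)
        object.__setattr__(self, "mapping", m)
        table = str.maketrans(m)
        object.__setattr__(self, "_table", table)

    @property
    def group_count(self) -> int:
        """Number of distinct groups over the 20 standard residues."""
        return len({self.mapping[a] for a in STANDARD_AMINO_ACIDS})

    @property
    def is_identity(self) -> bool:
        return all(self.mapping[a] == a for a in STANDARD_AMINO_ACIDS)

    def reduce(self, seq: str) -> str:
        """Reduce a protein string; same length, unknown letters → wildcard."""
        up = seq.upper()
        out = up.translate(self._table)
        # letters never seen in the mapping (digits, gaps, ...) → wildcard
        if any(c not in self.mapping for c in set(up)):
            out = "".join(
                self.mapping.get(c, WILDCARD) for c in up
            )
        return out

    def induced(self) -> "ReducedAlphabet":
        """The alphabet acting on already-reduced strings (a no-op mapping)."""
        groups = {self.mapping[a] for a in STANDARD_AMINO_ACIDS}
        m: Dict[str, str] = {g: g for g in groups}
        # standard residues not serving as group letters still need an image
        for a in STANDARD_AMINO_ACIDS:
            m.setdefault(a, self.mapping[a])
        return ReducedAlphabet(name=f"{self.name}-induced", mapping=m)


def _from_groups(name: str, groups: Sequence[str]) -> ReducedAlphabet:
    mapping: Dict[str, str] = {}
    for group in groups:
        rep = group[0]
        for residue in group:
            mapping[residue] = rep
    return ReducedAlphabet(name=name, mapping=mapping)


def identity_alphabet() -> ReducedAlphabet:
    """The regular 20-amino-acid alphabet (the default)."""
    return ReducedAlphabet(
        name="identity20", mapping={a: a for a in STANDARD_AMINO_ACIDS}
    )


# Murphy et al. (2000) reductions, written as residue groups whose first
# member is the group letter.
_MURPHY10 = ("LVIM", "C", "A", "G", "ST", "P", "FYW", "EDNQ", "KR", "H")
_MURPHY15 = (
    "LVIM", "C", "A", "G", "S", "T", "P", "FY", "W", "E", "D", "N", "Q",
    "KR", "H",
)


def parse_alphabet(name_or_groups: str) -> ReducedAlphabet:
    """Resolve an alphabet by name or by an explicit grouping string.

    Names: ``identity20`` (alias ``20``), ``murphy10``, ``murphy15``.
    A grouping string lists comma-separated residue groups, e.g. ``"KR,DE"``;
    each group is represented by its first letter and unlisted residues map
    to themselves.
    """
    key = name_or_groups.strip()
    named = {
        "identity20": identity_alphabet,
        "identity": identity_alphabet,
        "20": identity_alphabet,
        "murphy10": lambda: _from_groups("murphy10", _MURPHY10),
        "murphy15": lambda: _from_groups("murphy15", _MURPHY15),
    }
    if key.lower() in named:
        return named[key.lower()]()
    if "," in key or set(key.upper()) <= set(STANDARD_AMINO_ACIDS):
        groups = [g.strip().upper() for g in key.split(",") if g.strip()]
        mapping = {a: a for a in STANDARD_AMINO_ACIDS}
        for group in groups:
            rep = group[0]
            for residue in group:
                if residue not in STANDARD_AMINO_ACIDS:
                    raise ValueError(
                        f"alphabet grouping {name_or_groups!r}: {residue!r} is not a "
                        "standard residue"
                    )
                mapping[residue] = rep
        return ReducedAlphabet(name=key, mapping=mapping)
    raise ValueError(f"unknown alphabet {name_or_groups!r}")


def reduce_sequence(seq: str, alphabet: ReducedAlphabet) -> str:
    """Apply an alphabet reduction to a protein string (uppercased)."""
    return alphabet.reduce(seq)


@dataclass(frozen=True)
class SeededKmer:
    """A spaced k-mer: group letters at the seed's match positions.

    ``position`` is the 0-based offset of the window start in the source
    sequence; ``len(key)`` equals the seed's weight.
    """

    key: str
    position: int


def extract_spaced_kmers(
    seq: str,
    seed: SpacedSeed,
    alphabet: ReducedAlphabet,
    skip_wildcard: bool = False,
) -> List[SeededKmer]:
    """Extract one :class:`SeededKmer` per window of the sequence.

    The window count is ``max(0, len(seq) - seed.length + 1)``.  With
    ``skip_wildcard`` (used when building an index) windows whose match
    positions contain the wildcard group are dropped.
    """
    reduced = alphabet.reduce(seq)
    positions = seed.match_positions
    n_windows = len(reduced) - seed.length + 1
    out: List[SeededKmer] = []
    for start in range(max(0, n_windows)):
        key = "".join(reduced[start + p] for p in positions)
        if skip_wildcard and WILDCARD in key:
            continue
        out.append(SeededKmer(key=key, position=start))
    return out


def iter_index_kmers(
    seq: str, seeds: Iterable[SpacedSeed], alphabet: ReducedAlphabet
) -> Iterable[Tuple[int, str, int]]:
    """Yield ``(seed_ordinal, key, position)`` for every indexable window.

    Wildcard-containing keys are skipped; keys from different seeds are kept
    distinct by the seed ordinal so patterns of equal weight cannot collide.
    """
    for si, seed in enumerate(seeds):
        for kmer in extract_spaced_kmers(seq, seed, alphabet, skip_wildcard=True):
            yield si, kmer.key, kmer.position
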