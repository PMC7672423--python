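"""Sequence and domain algebra.

The circuit grammar is built from short named *domains* (toeholds,
branch-migration segments, outputs) concatenated 5'->3' into *strands*.
A starred reference (``"d2*"``) denotes the reverse complement of the
named domain in the same material.  Only Watson-Crick complementarity is
modelled here; wobble (G.U) pairs are deliberately excluded from the
core algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

RNA = "RNA"
DNA = "DNA"

_ALPHABET = {RNA: frozenset("ACGU"), DNA: frozenset("ACGT")}
_COMPLEMENT_TABLE = {
    RNA: str.maketrans("ACGU", "UGCA"),
    DNA: str.maketrans("ACGT", "TGCA"),
}
#: Watson-Crick partners used by the pairing predicates (keys uppercase).
WC_PAIRS = {("A", "U"), ("U", "A"), ("A", "T"), ("T", "A"),
            ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G"), ("G", "T"), ("T", "G")}


class AlphabetError(ValueError):
    """A sequence contains a character outside its declared alphabet."""


class MaterialError(ValueError):
    """Two sequences of different materials were combined or compared."""


class CompositionError(ValueError):
    """A strand references a domain that does not exist."""


def validate_sequence(seq: str, material: str = RNA) -> str:
    """Uppercase *seq* and check it against the material's alphabet.

    Raises :class:`AlphabetError` naming the first offending position.
    """
    if material not in _ALPHABET:
        raise MaterialError(f"unknown material {material!r}; expected RNA or DNA")
    up = seq.upper()
    allowed = _ALPHABET[material]
    for pos, ch in enumerate(up):
        if ch not in allowed:
            raise AlphabetError(
                f"invalid character {ch!r} at position {pos} for {material} sequence"
            )
    return up


def revcomp(seq: str, material: str = RNA) -> str:
    """Reverse complement of *seq* in the given material.

    An involution: ``revcomp(revcomp(x)) == x``.
    """
    up = validate_sequence(seq, material)
    return up.translate(_COMPLEMENT_TABLE[material])[::-1]


def complement_base(a: str, b: str, allow_gu: bool = False) -> bool:
    """True if bases *a* and *b* can form a pair (Watson-Crick, optionally G.U)."""
    key = (a.upper(), b.upper())
    return key in WC_PAIRS or (allow_gu and key in GU_PAIRS)


def transcribe(seq: str) -> str:
    """Explicit DNA -> RNA conversion (T -> U). The only sanctioned T/U bridge."""
    return validate_sequence(seq, DNA).replace("T", "U")


def reverse_transcribe(seq: str) -> str:
    """Explicit RNA -> DNA conversion (U -> T)."""
    return validate_sequence(seq, RNA).replace("U", "T")


def gc_content(seq: str) -> float:
    """Fraction of G/C bases; 0.0 for the empty string."""
    if not seq:
        return 0.0
    up = seq.upper()
    return (up.count("G") + up.count("C")) / len(up)


@dataclass(frozen=True)
class Domain:
    """A named sequence segment with a functional role.

    Roles follow strand-displacement convention: ``toehold`` nucleates,
    ``migration`` is displaced through, ``output`` is the exposed product
    segment, ``structural`` is everything else (scaffold, linker).
    """

    name: str
    sequence: str
    role: str = "structural"
    material: str = RNA

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("domain name must be non-empty")
        if not self.sequence:
            raise ValueError(f"domain {self.name!r}: sequence must be non-empty")
        if self.role not in {"toehold", "migration", "output", "structural"}:
            raise ValueError(f"domain {self.name!r}: unknown role {self.role!r}")
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, self.material)
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Strand:
    """An ordered 5'->3' list of domain references with a concrete sequence.

    ``domain_refs`` are names, a trailing ``*`` meaning reverse complement
    (stars do not nest).  The concrete sequence is derived on demand by
    :func:`assemble`.
    """

    name: str
    material: str
    domain_refs: tuple[str, ...]
    domains: tuple[Domain, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.domain_refs:
            raise CompositionError(f"strand {self.name!r} has no domains")
        by_name = {d.name for d in self.domains}
        for ref in self.domain_refs:
            base = ref.rstrip("*")
            if ref.endswith("**"):
                raise CompositionError(f"strand {self.name!r}: stars do not nest ({ref!r})")
            if base not in by_name:
                raise CompositionError(
                    f"strand {self.name!r}: dangling domain reference {ref!r}"
                )

    def _domain(self, base: str) -> Domain:
        for d in self.domains:
            if d.name == base:
                return d
        raise CompositionError(f"strand {self.name!r}: dangling domain reference {base!r}")

    @property
    def sequence(self) -> str:
        return assemble(self)

    def segment_bounds(self) -> list[tuple[str, int, int]]:
        """Half-open [start, end) coordinates of each domain ref, 5'->3'."""
        out = []
        pos = 0
        for ref in self.domain_refs:
            n = len(self._domain(ref.rstrip("*")))
            out.append((ref, pos, pos + n))
            pos += n
        return out

    def segment(self, ref: str) -> tuple[int, int]:
        """Coordinates of the first occurrence of *ref*."""
        for r, a, b in self.segment_bounds():
            if r == ref:
                return a, b
        raise CompositionError(f"strand {self.name!r}: no segment {ref!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def assemble(strand: Strand) -> str:
    """Concatenate the strand's domains 5'->3', reverse-complementing starred refs.

    Total and deterministic: depends only on domain sequences and order.
    """
    parts: list[str] = []
    for ref in strand.domain_refs:
        starred = ref.endswith("*")
        dom = strand._domain(ref.rstrip("*"))
        seq = dom.sequence
        if dom.material != strand.material:
            raise MaterialError(
                f"strand {strand.name!r} is {strand.material} but domain "
                f"{dom.name!r} is {dom.material}; transcribe explicitly"
            )
        parts.append(revcomp(seq, dom.material) if starred else seq)
    return "".join(parts)


@dataclass(frozen=True)
class SimilarityReport:
    """Longest-common-substring statistics between two sequences.

    ``lcs_len``: longest shared substring (identity); ``lcs_rc_len``:
    longest substring of one that occurs in the reverse complement of the
    other; ``max_duplex_run``: longest perfectly complementary antiparallel
    run.  Under pure Watson-Crick rules the last two coincide.
    """

    lcs_len: int
    lcs_rc_len: int
    max_duplex_run: int


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring (contiguous), by DP in O(|a||b|)."""
    if not a or not b:
        return 0
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def similarity(a: str, b: str, material: str = RNA) -> SimilarityReport:
    """LCS-based similarity between two same-material sequences.

    Symmetric in ``lcs_len``.  Raises :class:`MaterialError` when the
    sequences are not alphabet-compatible with *material*.
    """
    ua = validate_sequence(a, material)
    ub = validate_sequence(b, material)
    if not ua or not ub:
        raise ValueError("similarity requires two non-empty sequences")
    rc = longest_common_substring(ua, revcomp(ub, material))
    return SimilarityReport(
        lcs_len=longest_common_substring(ua, ub),
        lcs_rc_len=rc,
        max_duplex_run=rc,
    )
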