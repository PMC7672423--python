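"""Secondary-structure verification for designed strands.

The folding backend is base-pair maximization (Nussinov dynamic
programming) over Watson-Crick pairs, which is sufficient to certify
that a designed hairpin forms its intended stem and that functional
single-stranded regions (toeholds) are not sequestered by a competing
structure.  Ensemble/partition-function energetics and pseudoknots are
out of scope.

Pair maximization carries no loop-entropy penalty, so a maximum-pairing
structure routinely decorates a design with isolated or 2-3-bp helices
that are not stable at 37 C.  Accessibility therefore counts a toehold
base as sequestered only when it sits in a *competing* helix (one sharing
no pair with the intended structure) of at least nucleation length
(``sequester_helix_min``, default 5 bp — the same word length the
designer treats as a usable toehold elsewhere); shorter contacts are
transient and cannot stably block nucleation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import AlphabetError, complement_base

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


MIN_LOOP_DEFAULT = 3
_VALID = frozenset("ACGUTN")  # N = masked, never pairs


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) set of base pairs for one strand."""

    pairs: frozenset[tuple[int, int]]
    dot_bracket: str

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    def paired_indices(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out


@dataclass(frozen=True)
class FoldReport:
    """Per-strand verdict of the structure check."""

    strand: str
    intended_stem_recovered: float
    spurious_helix_max: int
    toehold_accessible: dict[str, float]
    dot_bracket: str
    passed: bool


@dataclass(frozen=True)
class FoldThresholds:
    """Pass thresholds: stem recovery fraction, toehold free fraction, and
    the minimum competing-helix length that counts as sequestration."""

    stem_min: float = 0.9
    toehold_min: float = 0.8
    sequester_helix_min: int = 5


def _pair_matrix(seq: str, allow_gu: bool, banned: frozenset[int] = frozenset()) -> np.ndarray:
    n = len(seq)
    can = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        if i in banned or seq[i] == "N":
            continue
        for j in range(i + 1, n):
            if j in banned or seq[j] == "N":
                continue
            if complement_base(seq[i], seq[j], allow_gu):
                can[i, j] = True
    return can


@njit(cache=True)
def _nussinov_table(can: np.ndarray, min_loop: int) -> np.ndarray:  # pragma: no cover
    n = can.shape[0]
    K = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = K[i + 1, j]  # i unpaired
            # i paired with t
            for t in range(i + min_loop + 1, j + 1):
                if can[i, t]:
                    v = 1 + (K[i + 1, t - 1] if t - 1 > i else 0)
                    if t + 1 <= j:
                        v += K[t + 1, j]
                    if v > best:
                        best = v
            K[i, j] = best
    return K


def _table(seq: str, min_loop: int, allow_gu: bool,
           banned: frozenset[int] = frozenset()) -> np.ndarray:
    return _nussinov_table(_pair_matrix(seq, allow_gu, banned), min_loop)


def _check_alphabet(seq: str) -> str:
    up = seq.upper()
    for pos, ch in enumerate(up):
        if ch not in _VALID:
            raise AlphabetError(f"invalid character {ch!r} at position {pos}")
    return up


def max_pairs(seq: str, min_loop: int = MIN_LOOP_DEFAULT, allow_gu: bool = False,
              banned: frozenset[int] = frozenset()) -> int:
    """Maximum number of nested base pairs (positions in *banned* may not pair)."""
    seq = _check_alphabet(seq)
    if len(seq) <= min_loop:
        return 0
    return int(_table(seq, min_loop, allow_gu, banned)[0, len(seq) - 1])


def nussinov_fold(seq: str, min_loop: int = MIN_LOOP_DEFAULT,
                  allow_gu: bool = False) -> SecondaryStructure:
    """Maximum base-pair structure with a deterministic traceback.

    Tie-break: the leftmost base of an interval pairs whenever pairing is
    optimal, and among optimal partners the most distal (largest index) is
    taken, which favours the long exterior helices of designed hairpins.
    """
    seq = _check_alphabet(seq)
    n = len(seq)
    if n <= min_loop:
        return SecondaryStructure(frozenset(), "." * n)
    can = _pair_matrix(seq, allow_gu)
    K = _nussinov_table(can, min_loop)
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = K[i, j]
        chosen = -1
        for t in range(j, i + min_loop, -1):  # largest partner first
            if can[i, t]:
                v = 1 + (K[i + 1, t - 1] if t - 1 > i else 0)
                if t + 1 <= j:
                    v += K[t + 1, j]
                if v == target:
                    chosen = t
                    break
        if chosen >= 0:
            pairs.add((i, chosen))
            if chosen - 1 > i:
                stack.append((i + 1, chosen - 1))
            if chosen + 1 <= j:
                stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return SecondaryStructure(frozenset(pairs), "".join(db))


def brute_force_fold(seq: str, min_loop: int = MIN_LOOP_DEFAULT,
                     allow_gu: bool = False) -> int:
    """Maximum pair count by exhaustive recursion over all nested pairings.

    Independent test oracle for :func:`nussinov_fold`; guarded to short
    sequences because the structure space grows exponentially.
    """
    seq = _check_alphabet(seq)
    if len(seq) > 20:
        raise ValueError("brute_force_fold is guarded to sequences of length <= 20")

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        b = best(i + 1, j)  # leave i unpaired
        for t in range(i + min_loop + 1, j + 1):
            if seq[i] != "N" and seq[t] != "N" and complement_base(seq[i], seq[t], allow_gu):
                v = 1 + best(i + 1, t - 1) + (best(t + 1, j) if t < j else 0)
                if v > b:
                    b = v
        return b

    return best(0, len(seq) - 1)


def accessibility(structure: SecondaryStructure, positions: list[int],
                  intended: set[tuple[int, int]] | None = None,
                  sequester_helix_min: int = 5) -> float:
    """Fraction of *positions* not sequestered by a stable competing helix.

    A base is sequestered when it lies in a predicted helix of at least
    ``sequester_helix_min`` stacked pairs that shares no pair with the
    intended structure; shorter contacts lack the stability to block
    toehold nucleation and are ignored.
    """
    if not positions:
        return 1.0
    blocked = _blocked_positions(structure, intended or set(), sequester_helix_min)
    free = sum(1 for p in positions if p not in blocked)
    return free / len(positions)


def _blocked_positions(structure: SecondaryStructure,
                       intended: set[tuple[int, int]],
                       sequester_helix_min: int) -> set[int]:
    """Positions held by stable competing helices (>= threshold, no intended pair)."""
    blocked: set[int] = set()
    for helix in _helices(set(structure.pairs)):
        if len(helix) >= sequester_helix_min and not any(
                p in intended for p in helix):
            for i, j in helix:
                blocked.add(i)
                blocked.add(j)
    return blocked


def _helices(pairs: set[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into stacked helices ((i,j) stacks with (i+1,j-1))."""
    remaining = set(pairs)
    out = []
    while remaining:
        i, j = min(remaining)
        helix = [(i, j)]
        remaining.remove((i, j))
        while (i + 1, j - 1) in remaining:
            i, j = i + 1, j - 1
            helix.append((i, j))
            remaining.remove((i, j))
        out.append(helix)
    return out


def spurious_helix_max(predicted: SecondaryStructure,
                       intended: set[tuple[int, int]]) -> int:
    """Length of the longest predicted helix containing no intended pair."""
    worst = 0
    for helix in _helices(set(predicted.pairs)):
        if not any(p in intended for p in helix):
            worst = max(worst, len(helix))
    return worst


def fold_report(strand_name: str, seq: str, intended: set[tuple[int, int]],
                toeholds: dict[str, list[int]],
                thresholds: FoldThresholds = FoldThresholds(),
                min_loop: int = MIN_LOOP_DEFAULT,
                allow_gu: bool = False) -> FoldReport:
    """Fold one strand and score it against its intended structure.

    *intended* are 0-based (i, j) pairs; *toeholds* maps a label to the
    positions that must stay single-stranded.  Masked positions may be
    encoded as 'N' in *seq*.
    """
    structure = nussinov_fold(seq, min_loop, allow_gu)
    blocked = _blocked_positions(structure, intended, thresholds.sequester_helix_min)
    if intended:
        # An intended pair is recovered when predicted outright, or when it
        # was displaced only by competing helices too short to be stable
        # (below nucleation length), so the intended pair can reform.
        hit = sum(
            1 for (i, j) in intended
            if (i, j) in structure.pairs or (i not in blocked and j not in blocked)
        )
        recovered = hit / len(intended)
    else:
        recovered = 1.0
    access = {
        label: accessibility(structure, pos, intended,
                             thresholds.sequester_helix_min)
        for label, pos in toeholds.items()
    }
    spur = spurious_helix_max(structure, intended)
    passed = recovered >= thresholds.stem_min and all(
        a >= thresholds.toehold_min for a in access.values()
    )
    return FoldReport(
        strand=strand_name,
        intended_stem_recovered=recovered,
        spurious_helix_max=spur,
        toehold_accessible=access,
        dot_bracket=structure.dot_bracket,
        passed=passed,
    )
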