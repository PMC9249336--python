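"""Bit-packed linear algebra over GF(2).

Vectors are Python integers used as bitmasks; a basis is kept in reduced
form keyed by pivot (highest set bit), which makes rank, span-membership
and online insertion all O(rank) big-int operations.  Exact by
construction -- no floating point anywhere.
"""

from __future__ import annotations

__all__ = ["Gf2Basis", "gf2_rank"]


class Gf2Basis:
    """An online-reduced basis of GF(2) vectors (ints as bitmasks)."""

    def __init__(self):
        self._pivots: dict[int, int] = {}  # pivot bit position -> vector

    @property
    def rank(self) -> int:
        return len(self._pivots)

    def reduce(self, vec: int) -> int:
        """Reduce ``vec`` against the basis; 0 means it is in the span."""
        while vec:
            piv = vec.bit_length() - 1
            row = self._pivots.get(piv)
            if row is None:
                return vec
            vec ^= row
        return 0

    def add(self, vec: int) -> bool:
        """Insert ``vec``; returns True if it enlarged the span."""
        residual = self.reduce(vec)
        if residual:
            self._pivots[residual.bit_length() - 1] = residual
            return True
        return False

    def contains(self, vec: int) -> bool:
        return self.reduce(vec) == 0

    def vectors(self):
        """The reduced basis vectors (pivot order unspecified)."""
        return list(self._pivots.values())


def gf2_rank(columns) -> int:
    """Rank of a GF(2) matrix given as an iterable of bitmask columns."""
    basis = Gf2Basis()
    for col in columns:
        basis.add(col)
    return basis.rank
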