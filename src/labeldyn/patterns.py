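"""Binary encoding of positional 13C labelling patterns.

A metabolite with n carbons has 2**n positional isotopomers.  Each is encoded
as an integer whose binary representation has one bit per skeleton carbon,
``1`` for 13C — the leftmost (most significant) bit is carbon 1.  So for a
hexose ``"010101"`` is code 21 and ``"111111"`` is 63.  Enzymatic skeleton
chemistry then becomes bit arithmetic: an aldolase-type split of a hexose into
two trioses is a split of the 6-bit code into its leading and trailing 3 bits,
a decarboxylation drops a bit, a condensation concatenates codes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "encode",
    "decode",
    "split_pattern",
    "condense_patterns",
    "decarboxylate_first",
    "bit_counts",
    "gather_bits",
    "mass_distribution",
]


def encode(pattern: str) -> int:
    """Encode a bit string such as ``"010101"`` to its integer code (21)."""
    if not pattern or any(ch not in "01" for ch in pattern):
        raise ValueError(f"not a binary label pattern: {pattern!r}")
    return int(pattern, 2)


def decode(code: int, n: int) -> str:
    """Decode an integer code to an n-carbon bit string."""
    if not 0 <= code < (1 << n):
        raise ValueError(f"code {code} out of range for {n} carbons")
    return format(code, f"0{n}b")


def split_pattern(code: int, n_total: int, n_left: int) -> tuple[int, int]:
    """Split an n_total-carbon code into leading n_left and trailing bits.

    ``split_pattern(21, 6, 3) == (0b010, 0b101) == (2, 5)``.
    """
    if not 0 < n_left < n_total:
        raise ValueError("need 0 < n_left < n_total")
    if not 0 <= code < (1 << n_total):
        raise ValueError(f"code {code} out of range for {n_total} carbons")
    n_right = n_total - n_left
    return code >> n_right, code & ((1 << n_right) - 1)


def condense_patterns(left: int, right: int, n_right: int) -> int:
    """Concatenate two codes; inverse of :func:`split_pattern`."""
    if right >= (1 << n_right) or right < 0:
        raise ValueError(f"right code {right} out of range for {n_right} carbons")
    return (left << n_right) | right


def decarboxylate_first(code: int, n: int) -> int:
    """Remove carbon 1 (the leading bit); its label leaves as CO2.

    ``"101" -> "01"``, ``"011" -> "11"``.
    """
    if n < 2:
        raise ValueError("need at least 2 carbons to decarboxylate")
    if not 0 <= code < (1 << n):
        raise ValueError(f"code {code} out of range for {n} carbons")
    return code & ((1 << (n - 1)) - 1)


def bit_counts(n: int) -> np.ndarray:
    """Number of set bits for every code 0..2**n-1."""
    codes = np.arange(1 << n, dtype=np.uint32)
    counts = np.zeros(1 << n, dtype=np.int64)
    for b in range(n):
        counts += (codes >> b) & 1
    return counts


def gather_bits(codes: np.ndarray, n: int, positions: list[int]) -> np.ndarray:
    """Extract the bits at 1-based carbon ``positions`` from each code.

    Returns codes over len(positions) carbons, ordered as given.  Used to
    build carbon maps (a product's code is a gather of substrate bits) and to
    restrict a pattern to the carbon range covered by a GC/MS fragment.
    """
    codes = np.asarray(codes, dtype=np.int64)
    out = np.zeros_like(codes)
    k = len(positions)
    for i, pos in enumerate(positions):
        if not 1 <= pos <= n:
            raise ValueError(f"carbon position {pos} outside 1..{n}")
        bit = (codes >> (n - pos)) & 1
        out |= bit << (k - 1 - i)
    return out


def mass_distribution(x: np.ndarray, n: int, fragment_carbons: list[int] | None = None) -> np.ndarray:
    """Mass-isotopomer distribution of a positional-isotopomer vector.

    Parameters
    ----------
    x:
        Concentrations (or amounts) indexed by label-pattern code, length 2**n.
    n:
        Carbon count of the metabolite.
    fragment_carbons:
        1-based carbon positions covered by the measured fragment; defaults to
        the whole skeleton.  m_j sums all patterns with j labelled carbons
        inside the fragment, normalised by the pool total.

    Returns
    -------
    numpy.ndarray
        Fractions m0..mk, k = len(fragment_carbons), summing to 1.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (1 << n,):
        raise ValueError(f"expected {1 << n} isotopomers, got {x.shape}")
    total = x.sum()
    if total <= 0:
        raise ValueError("empty pool: cannot form a mass distribution")
    if fragment_carbons is None:
        fragment_carbons = list(range(1, n + 1))
    frag = gather_bits(np.arange(1 << n), n, fragment_carbons)
    weights = bit_counts(len(fragment_carbons))[frag]
    mid = np.bincount(weights, weights=x, minlength=len(fragment_carbons) + 1)
    return mid / total
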