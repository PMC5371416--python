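"""Domain model of attC recombination sites.

An attC site is an imperfect inverted repeat recombined by the integron
integrase as a folded single strand.  Reading the double-stranded site along
the top strand, the four integrase binding boxes appear in the order
R'' < L'' < L' < R'; the variable terminal structure (VTS) lies between the
two L boxes.  The *bottom* strand (the strand recombined preferentially) is
the reverse complement of the top strand and, read 5'->3', passes through
R' (carrying the 5'-YAAC-3' core), L', the VTS, L'' and finally R''
(carrying the 5'-GTTR-3' core).  In the recombinogenic fold the L' box pairs
the L'' box and the YAAC core pairs the GTTR core.

Coordinates are 0-based half-open on the top strand throughout; the bottom
strand index of top-strand position ``i`` is ``L - 1 - i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "AttCSite",
    "BoxAnnotation",
    "ConstraintSet",
    "InvalidAlphabetError",
    "UnannotatableSiteError",
    "ConstraintError",
    "bottom_strand",
    "reverse_complement",
    "iupac_match",
    "is_watson_crick",
    "locate_boxes",
    "recombinogenic_constraints",
    "NATURAL_LENGTH_RANGE",
]

# Soft bounds of naturally observed site lengths (bp).
NATURAL_LENGTH_RANGE = (57, 141)

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

# IUPAC degeneracy expansion used when matching anchor motifs.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "S": "CG", "W": "AT", "B": "CGT", "V": "ACG",
    "D": "AGT", "H": "ACT", "N": "ACGT",
}

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


class InvalidAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class UnannotatableSiteError(ValueError):
    """No box assignment could be located; supply explicit boxes instead."""


class ConstraintError(ValueError):
    """A recombinogenic constraint set could not be constructed."""


def _validate_sequence(seq: str) -> str:
    if not seq:
        raise InvalidAlphabetError("empty sequence")
    s = seq.upper()
    bad = set(s) - set(_COMPLEMENT)
    if bad:
        raise InvalidAlphabetError(f"non-IUPAC characters: {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string, written 5'->3'."""
    s = _validate_sequence(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def iupac_match(code: str, base: str) -> bool:
    """True when concrete ``base`` is compatible with IUPAC ``code``."""
    return base in _IUPAC[code]


def is_watson_crick(x: str, y: str) -> bool:
    """Strict Watson-Crick pairing test on concrete bases."""
    return (x, y) in _WC


@dataclass(frozen=True)
class BoxAnnotation:
    """Integrase-binding box intervals in top-strand coordinates.

    Intervals are 0-based half-open and must be disjoint and ordered
    ``r_dprime < l_dprime < l_prime < r_prime``.  Both R boxes span the full
    7 bp and the two L boxes have equal length.  Derived spacers: ``spacer1``
    between R'' and L'', ``vts`` between the L boxes and ``spacer2`` between
    L' and R'.
    """

    r_dprime: tuple[int, int]
    l_dprime: tuple[int, int]
    l_prime: tuple[int, int]
    r_prime: tuple[int, int]

    def __post_init__(self) -> None:
        ivs = [self.r_dprime, self.l_dprime, self.l_prime, self.r_prime]
        for s, e in ivs:
            if s < 0 or e < s:
                raise ValueError(f"malformed interval {(s, e)}")
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if not b <= c:
                raise ValueError("box intervals must be disjoint and ordered "
                                 "r_dprime < l_dprime < l_prime < r_prime")
        if self._len(self.r_dprime) != 7 or self._len(self.r_prime) != 7:
            raise ValueError("R boxes must span the full 7 bp")
        if self._len(self.l_dprime) != self._len(self.l_prime):
            raise ValueError("L boxes must have equal length")

    @staticmethod
    def _len(iv: tuple[int, int]) -> int:
        return iv[1] - iv[0]

    @property
    def spacer1(self) -> tuple[int, int]:
        return (self.r_dprime[1], self.l_dprime[0])

    @property
    def vts(self) -> tuple[int, int]:
        return (self.l_dprime[1], self.l_prime[0])

    @property
    def spacer2(self) -> tuple[int, int]:
        return (self.l_prime[1], self.r_prime[0])

    @property
    def l_length(self) -> int:
        return self._len(self.l_prime)

    @property
    def span(self) -> tuple[int, int]:
        return (self.r_dprime[0], self.r_prime[1])


@dataclass
class AttCSite:
    """One attC record: top-strand sequence plus optional box annotation."""

    id: str
    top_strand: str
    boxes: Optional[BoxAnnotation] = None
    origin_class: str = "unknown"
    host_taxon: Optional[str] = None
    source: Optional[tuple] = None  # (replicon_id, (start, end), strand)

    def __post_init__(self) -> None:
        self.top_strand = _validate_sequence(self.top_strand)
        if self.origin_class not in {"MI", "SCI", "MCI", "unknown"}:
            raise ValueError(f"unknown origin class {self.origin_class!r}")
        n = len(self.top_strand)
        if self.boxes is not None and self.boxes.span[1] > n:
            raise ValueError("box intervals exceed sequence length")
        lo, hi = NATURAL_LENGTH_RANGE
        if not lo <= n <= hi:
            warnings.warn(
                f"site {self.id!r} length {n} bp outside the natural range "
                f"[{lo}, {hi}] bp", stacklevel=2)

    def __len__(self) -> int:
        return len(self.top_strand)

    @property
    def bottom(self) -> str:
        return reverse_complement(self.top_strand)


def bottom_strand(site) -> str:
    """Bottom strand (reverse complement of the top strand), 5'->3'.

    Accepts an :class:`AttCSite` or a raw sequence string.
    """
    seq = site.top_strand if isinstance(site, AttCSite) else site
    return reverse_complement(seq)


def top_to_bottom_interval(iv: tuple[int, int], length: int) -> tuple[int, int]:
    """Map a top-strand half-open interval to bottom-strand coordinates."""
    s, e = iv
    return (length - e, length - s)


def top_to_bottom_index(i: int, length: int) -> int:
    return length - 1 - i


# ---------------------------------------------------------------------------
# Heuristic box location
# ---------------------------------------------------------------------------

# Bottom-strand box consensus.  Site sequences include the full 7-bp R boxes
# at their ends, so R' occupies the first 7 nt of the bottom strand (core
# 5'-YAAC-3' in its last four positions) and R'' the last 7 nt (core
# 5'-GTTR-3' in its first four positions).
_RPRIME_CONSENSUS = "RYYYAAC"
_RDPRIME_CONSENSUS = "GTTRRRY"


def _matches(consensus: str, segment: str) -> bool:
    return len(segment) == len(consensus) and all(
        iupac_match(c, b) for c, b in zip(consensus, segment))


def locate_boxes(
    top_strand: str,
    *,
    max_l_mismatch: int = 2,
    l_length_range: tuple[int, int] = (4, 24),
    max_spacer: int = 12,
) -> BoxAnnotation:
    """Best-effort box assignment for a site sequence spanning R'' .. R'.

    Anchors on the terminal R-box core motifs (YAAC in R', GTTR in R'' on the
    bottom strand) and then searches for the pair of equal-length L boxes with
    the highest pairing score (complementary positions minus mismatches,
    mismatches capped at ``max_l_mismatch``).  Explicit annotations always
    beat this heuristic; it exists to annotate well-formed fixtures.
    """
    top = _validate_sequence(top_strand)
    n = len(top)
    if n < 40:
        raise UnannotatableSiteError("sequence shorter than 40 bp")
    bottom = reverse_complement(top)

    if not (_matches(_RPRIME_CONSENSUS, bottom[:7])
            and _matches(_RDPRIME_CONSENSUS, bottom[-7:])):
        raise UnannotatableSiteError(
            "terminal R-box anchor motifs (bottom strand 5'-RYYYAAC ... "
            "GTTRRRY-3') not found; supply explicit box annotations")

    lo, hi = l_length_range
    best = None  # (score, -(o5+o3), l_len, o5, o3)
    for l_len in range(lo, hi + 1):
        for o5 in range(max_spacer + 1):
            lp_s = 7 + o5                    # L' start on the bottom strand
            if lp_s + l_len > n - 7:
                break
            for o3 in range(max_spacer + 1):
                ld_e = n - 7 - o3            # L'' end on the bottom strand
                ld_s = ld_e - l_len
                if ld_s < lp_s + l_len + 3:  # leave >=3 nt for the VTS loop
                    continue
                lp = bottom[lp_s:lp_s + l_len]
                ld = bottom[ld_s:ld_e]
                mism = sum(
                    not is_watson_crick(lp[k], ld[l_len - 1 - k])
                    for k in range(l_len))
                if mism > max_l_mismatch:
                    continue
                cand = (l_len - 2 * mism, -(o5 + o3), l_len, o5, o3)
                if best is None or cand > best:
                    best = cand

    if best is None:
        raise UnannotatableSiteError(
            "no L-box pairing found within the allowed spacer window; "
            "supply explicit box annotations")

    _, _, l_len, o5, o3 = best
    # Convert bottom-strand intervals back to top-strand coordinates.
    lp_b = (7 + o5, 7 + o5 + l_len)
    ld_b = (n - 7 - o3 - l_len, n - 7 - o3)
    return BoxAnnotation(
        r_dprime=(0, 7),
        l_dprime=top_to_bottom_interval(ld_b, n),
        l_prime=top_to_bottom_interval(lp_b, n),
        r_prime=(n - 7, n),
    )


# ---------------------------------------------------------------------------
# Recombinogenic constraint sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintSet:
    """Forced base pairs defining the recombinogenic structure.

    ``forced_pairs`` are (i, j) index pairs with i < j on the strand named by
    ``strand_label``; they must be non-crossing and each index may appear at
    most once.
    """

    forced_pairs: frozenset = field(default_factory=frozenset)
    strand_label: str = "bottom"

    def __post_init__(self) -> None:
        if self.strand_label not in {"bottom", "top"}:
            raise ValueError("strand_label must be 'bottom' or 'top'")
        pairs = sorted(self.forced_pairs)
        used: set[int] = set()
        for i, j in pairs:
            if i >= j:
                raise ConstraintError(f"pair {(i, j)} not ordered i < j")
            if i in used or j in used:
                raise ConstraintError(f"index reused in pair {(i, j)}")
            used.update((i, j))
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                i1, j1 = pairs[a]
                i2, j2 = pairs[b]
                if i1 < i2 < j1 < j2:
                    raise ConstraintError(
                        f"crossing forced pairs {(i1, j1)} / {(i2, j2)}")

    def __len__(self) -> int:
        return len(self.forced_pairs)

    def __iter__(self):
        return iter(sorted(self.forced_pairs))

    def to_strand(self, strand: str, length: int) -> "ConstraintSet":
        """Express the same physical pairs on the other strand."""
        if strand == self.strand_label:
            return self
        flipped = frozenset(
            tuple(sorted((length - 1 - i, length - 1 - j)))
            for i, j in self.forced_pairs)
        return ConstraintSet(flipped, strand)


def recombinogenic_constraints(
    site: AttCSite,
    strand: str = "bottom",
    *,
    mismatch: str = "error",
) -> ConstraintSet:
    """Forced pairs of the recombinogenic structure for one site.

    Pairs every position of L' against its counterpart in L'' plus the four
    core positions YAAC (in R') against GTTR (in R'').  ``mismatch`` controls
    L positions whose bases are not Watson-Crick complementary:

    - ``"error"``  -- raise :class:`ConstraintError` (default);
    - ``"drop"``   -- omit those pairs (cohort pipelines use this);
    - ``"keep"``   -- emit them; folding then reports an empty constrained
      ensemble and pfold = 0.
    """
    if mismatch not in {"error", "drop", "keep"}:
        raise ValueError("mismatch must be 'error', 'drop' or 'keep'")
    boxes = site.boxes if site.boxes is not None else locate_boxes(site.top_strand)
    n = len(site)
    b = site.bottom

    rp_b = top_to_bottom_interval(boxes.r_prime, n)    # first on the bottom
    rd_b = top_to_bottom_interval(boxes.r_dprime, n)   # last on the bottom
    lp_b = top_to_bottom_interval(boxes.l_prime, n)
    ld_b = top_to_bottom_interval(boxes.l_dprime, n)

    pairs: set[tuple[int, int]] = set()
    # Core: YAAC occupies the last 4 nt of R' (bottom), GTTR the first 4 nt
    # of R''; antiparallel pairing matches YAAC[k] with GTTR[3-k].
    a = rp_b[1] - 4
    g = rd_b[0]
    for k in range(4):
        i, j = a + k, g + 3 - k
        if not is_watson_crick(b[i], b[j]):
            raise ConstraintError(
                f"site {site.id!r}: R-box core positions {i}/{j} "
                f"({b[i]}/{b[j]}) cannot pair")
        pairs.add((i, j))
    # L' against L'', base by base (antiparallel).
    l_len = boxes.l_length
    for k in range(l_len):
        i = lp_b[0] + k
        j = ld_b[1] - 1 - k
        if not is_watson_crick(b[i], b[j]):
            if mismatch == "error":
                raise ConstraintError(
                    f"site {site.id!r}: L-box positions {i}/{j} "
                    f"({b[i]}/{b[j]}) cannot pair; use mismatch='drop' "
                    "to omit non-complementary L pairs")
            if mismatch == "drop":
                continue
        pairs.add((i, j))

    cs = ConstraintSet(frozenset(pairs), "bottom")
    return cs.to_strand(strand, n) if strand != "bottom" else cs
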