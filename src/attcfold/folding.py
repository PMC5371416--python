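"""Single-stranded DNA secondary-structure thermodynamics.

Two energy backends sit behind one contract:

* :class:`ReferenceModel` -- a deliberately small nearest-neighbour model
  (Watson-Crick pairs, published DNA stack free energies, a flat hairpin
  initiation penalty, no bulge/internal-loop or dangling-end terms).  Its
  partition function and MFE are computed both by exhaustive enumeration
  (:func:`enumerate_structures`, the oracle) and by dynamic programming
  (:func:`fold`), which must agree to floating-point accuracy.
* :class:`~attcfold.vienna.ViennaDNAModel` -- the full DNA nearest-neighbour
  parameter set via the ViennaRNA bindings, used to compute pfold values on
  the same footing as published site analyses.

The recombinogenic-structure probability is

    pfold = exp((Eu - Ec) / (R T)) = Z_constrained / Z_unconstrained,

where Eu and Ec are the ensemble free energies without and with the hard
constraints that force the recombinogenic base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .attc import AttCSite, ConstraintSet, recombinogenic_constraints

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "ReferenceModel",
    "SecondaryStructure",
    "FoldOutcome",
    "PfoldResult",
    "EmptyEnsembleError",
    "enumerate_structures",
    "fold",
    "pfold",
    "strand_stability_gap",
]

GAS_CONSTANT_KCAL = 1.98717e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE_K = 310.15  # 37 degC, the folding default

MIN_HAIRPIN_LOOP = 3  # unpaired nucleotides enclosed by any pair

# Unified DNA nearest-neighbour stack free energies at 37 degC (kcal/mol),
# indexed by the 5'->3' dinucleotide on one strand of the stack; the table is
# reverse-complement symmetric.
_STACK_DG37 = {
    "AA": -1.00, "AT": -0.88, "AG": -1.28, "AC": -1.44,
    "TA": -0.58, "TT": -1.00, "TG": -1.45, "TC": -1.30,
    "GA": -1.30, "GT": -1.44, "GG": -1.84, "GC": -2.24,
    "CA": -1.45, "CT": -1.28, "CC": -1.84, "CG": -2.17,
}

_WC_CODE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


class EmptyEnsembleError(ValueError):
    """No structure satisfies the constraints (pfold callers map this to 0)."""


class SecondaryStructure(str):
    """Dot-bracket string; validated to be balanced and non-crossing."""

    def __new__(cls, s: str):
        depth = 0
        for c in s:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket string")
            elif c != ".":
                raise ValueError(f"invalid dot-bracket character {c!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket string")
        return super().__new__(cls, s)

    def pairs(self) -> frozenset:
        stack: list[int] = []
        out = set()
        for k, c in enumerate(self):
            if c == "(":
                stack.append(k)
            elif c == ")":
                out.add((stack.pop(), k))
        return frozenset(out)

    @classmethod
    def from_pairs(cls, pairs, length: int) -> "SecondaryStructure":
        chars = ["."] * length
        for i, j in pairs:
            chars[i], chars[j] = "(", ")"
        return cls("".join(chars))


@dataclass(frozen=True)
class ReferenceModel:
    """Stacking/hairpin simplification of the DNA nearest-neighbour model.

    ``hairpin_penalty`` is charged once per hairpin loop (a pair enclosing no
    other pair); every stack of adjacent pairs contributes the published
    dinucleotide free energy.  The open chain has energy exactly 0.  Stack
    free energies are 37 degC values; ``temperature`` only enters through the
    Boltzmann factor.
    """

    temperature: float = DEFAULT_TEMPERATURE_K
    hairpin_penalty: float = 3.0  # kcal/mol per hairpin loop
    parameter_set_id: str = "reference-stack-dg37"

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature

    @staticmethod
    def pairable(x: str, y: str) -> bool:
        return (x, y) in _WC_CODE

    @staticmethod
    def stack_energy(seq: str, i: int, j: int) -> float:
        """Free energy of stacking pair (i, j) on pair (i+1, j-1)."""
        return _STACK_DG37[seq[i] + seq[i + 1]]

    def energy(self, seq: str, structure) -> float:
        """Energy of an explicit structure by direct summation.

        ``structure`` may be a dot-bracket string or an iterable of pairs.
        Used by the enumeration oracle; independent of the DP recurrences.
        """
        pairs = (structure.pairs() if isinstance(structure, SecondaryStructure)
                 else SecondaryStructure(structure).pairs()
                 if isinstance(structure, str) else frozenset(structure))
        e = 0.0
        pairset = set(pairs)
        for i, j in pairs:
            if (i + 1, j - 1) in pairset:
                e += self.stack_energy(seq, i, j)
            if not any(i < a and b < j for a, b in pairs):
                e += self.hairpin_penalty
        return e


# ---------------------------------------------------------------------------
# Constraint masks
# ---------------------------------------------------------------------------


def _constraint_masks(seq: str, model: ReferenceModel,
                      constraints: Optional[ConstraintSet]):
    """(allow_pair, allow_unpaired) boolean masks for the DP and the oracle."""
    n = len(seq)
    allow_pair = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            allow_pair[i, j] = model.pairable(seq[i], seq[j])
    allow_unpaired = np.ones(n, dtype=bool)
    if constraints is not None and len(constraints):
        forced = sorted(constraints)
        for a, b in forced:
            if not (0 <= a < b < n):
                raise ValueError(f"forced pair {(a, b)} outside sequence")
        keep = {(a, b): bool(allow_pair[a, b]) for a, b in forced}
        for a, b in forced:
            allow_unpaired[a] = allow_unpaired[b] = False
            for p in (a, b):
                allow_pair[p, :] = False
                allow_pair[:, p] = False
        for (a, b), ok in keep.items():
            allow_pair[a, b] = ok
    return allow_pair, allow_unpaired


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

_ENUM_LIMIT = 20


def enumerate_structures(
    seq: str,
    model: Optional[ReferenceModel] = None,
    constraints: Optional[ConstraintSet] = None,
) -> list[tuple[SecondaryStructure, float]]:
    """Every valid structure with its energy, by brute-force enumeration.

    Refuses sequences longer than 20 nt: this is the oracle for testing the
    dynamic programs, not a production path.
    """
    seq = seq.upper()
    if len(seq) > _ENUM_LIMIT:
        raise ValueError(
            f"enumeration oracle limited to {_ENUM_LIMIT} nt "
            f"(got {len(seq)})")
    model = model or ReferenceModel()
    allow_pair, allow_unpaired = _constraint_masks(seq, model, constraints)
    forced = frozenset(constraints) if constraints else frozenset()
    n = len(seq)

    def gen(i: int, j: int) -> Iterator[frozenset]:
        # All pair sets over seq[i..j], decomposing on the fate of i.
        if i > j:
            yield frozenset()
            return
        if allow_unpaired[i]:
            yield from gen(i + 1, j)
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if allow_pair[i, k]:
                for inner in gen(i + 1, k - 1):
                    for outer in gen(k + 1, j):
                        yield frozenset({(i, k)}) | inner | outer

    out = []
    for pairs in gen(0, n - 1):
        if not forced <= pairs:
            continue
        out.append((SecondaryStructure.from_pairs(pairs, n),
                    model.energy(seq, pairs)))
    return out


# ---------------------------------------------------------------------------
# Dynamic programs
# ---------------------------------------------------------------------------

_INF = float("inf")


def _dp_mfe(seq: str, model: ReferenceModel, allow_pair, allow_unpaired):
    """Minimum free energy and one optimal pair set, or None if no valid
    structure exists under the constraints."""
    n = len(seq)
    H = model.hairpin_penalty
    stack = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            if allow_pair[i, j]:
                stack[i, j] = model.stack_energy(seq, i, j)

    # emp_ok[i][j]: positions i..j-1 may all stay unpaired (prefix trick).
    free = np.concatenate(([0], np.cumsum(allow_unpaired)))

    def emp_ok(i: int, j: int) -> bool:  # interval [i, j] inclusive; i>j ok
        if i > j:
            return True
        return free[j + 1] - free[i] == j - i + 1

    u_pen = np.where(allow_unpaired, 0.0, _INF)

    V = np.full((n, n), _INF)    # MFE given (i, j) paired
    W = np.full((n, n + 1), _INF)  # W[i, j+1] = MFE of seq[i..j]; W[i, i]=0
    Wne = np.full((n, n + 1), _INF)  # same, >=1 pair
    for i in range(n):
        W[i, i] = 0.0

    for j in range(n):
        # V[:, j]
        for i in range(j - MIN_HAIRPIN_LOOP - 1, -1, -1):
            if not allow_pair[i, j]:
                continue
            best = _INF
            if emp_ok(i + 1, j - 1):
                best = H
            if j - 1 >= i + 1:
                best = min(best, Wne[i + 1, j])
                if allow_pair[i + 1, j - 1] and V[i + 1, j - 1] < _INF:
                    best = min(best, stack[i, j] + V[i + 1, j - 1])
            V[i, j] = best
        # W[:, j+1] and Wne[:, j+1]
        ks = np.arange(0, j - MIN_HAIRPIN_LOOP)
        for i in range(j, -1, -1):
            w = u_pen[j] + W[i, j]
            wne = u_pen[j] + Wne[i, j] if j > i else _INF
            if ks.size:
                kk = ks[ks >= i]
                if kk.size:
                    cand = V[kk, j] + W[i, kk]
                    m = cand.min()
                    w = min(w, m)
                    wne = min(wne, m)
            W[i, j + 1] = w
            Wne[i, j + 1] = wne

    mfe = W[0, n]
    if not np.isfinite(mfe):
        return None

    # Traceback (deterministic branch order).
    pairs: list[tuple[int, int]] = []

    def trace_W(i: int, j: int, nonempty: bool) -> None:
        while j >= i:
            tab = Wne if nonempty else W
            target = tab[i, j + 1]
            if (allow_unpaired[j]
                    and math.isclose(target, u_pen[j] + tab[i, j],
                                     rel_tol=0.0, abs_tol=1e-9)
                    and np.isfinite(tab[i, j])):
                j -= 1
                continue
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                if np.isfinite(V[k, j]) and np.isfinite(W[i, k]) and \
                        math.isclose(target, V[k, j] + W[i, k],
                                     rel_tol=0.0, abs_tol=1e-9):
                    trace_V(k, j)
                    j = k - 1
                    nonempty = False
                    break
            else:  # pragma: no cover - internal inconsistency
                raise AssertionError("traceback failed")
        return

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        v = V[i, j]
        if emp_ok(i + 1, j - 1) and math.isclose(v, H, abs_tol=1e-9):
            return
        if (j - 1 >= i + 1 and allow_pair[i + 1, j - 1]
                and np.isfinite(V[i + 1, j - 1])
                and math.isclose(v, stack[i, j] + V[i + 1, j - 1],
                                 abs_tol=1e-9)):
            trace_V(i + 1, j - 1)
            return
        trace_W(i + 1, j - 1, nonempty=True)

    trace_W(0, n - 1, nonempty=False)
    return float(mfe), pairs


def _dp_logz(seq: str, model: ReferenceModel, allow_pair, allow_unpaired,
             mfe: float) -> float:
    """log of the constrained partition function (scaled to avoid overflow).

    Boltzmann factors are rescaled by exp(mfe / (n RT)) per nucleotide so the
    minimum-energy structure carries scaled weight ~1; terms smaller by more
    than ~700 nats underflow harmlessly.
    """
    n = len(seq)
    rt = model.rt
    c = mfe / n  # per-base shift; s = exp(-c/rt) is the scale factor
    log_s = -c / rt
    s = math.exp(log_s)
    H = math.exp(-model.hairpin_penalty / rt)

    sigma = np.ones((n, n)) * 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if allow_pair[i, j]:
                sigma[i, j] = math.exp(-model.stack_energy(seq, i, j) / rt)

    free = np.concatenate(([0], np.cumsum(allow_unpaired)))

    def emp_weight(i: int, j: int) -> float:
        # scaled weight of the all-unpaired configuration of [i, j]
        if i > j:
            return 1.0
        if free[j + 1] - free[i] != j - i + 1:
            return 0.0
        m = j - i + 1
        t = m * log_s
        return math.exp(t) if t < 700.0 else math.inf

    Z = np.zeros((n, n + 1))   # Z[i, j+1] = scaled Z of seq[i..j]; Z[i,i]=1
    Zb = np.zeros((n, n))      # scaled Z with (i, j) paired
    for i in range(n):
        Z[i, i] = 1.0
    u = np.where(allow_unpaired, s, 0.0)

    for j in range(n):
        for i in range(j - MIN_HAIRPIN_LOOP - 1, -1, -1):
            if not allow_pair[i, j]:
                continue
            ew = emp_weight(i + 1, j - 1)
            interior = H * ew + (Z[i + 1, j] - ew)
            if j - 1 >= i + 1 and allow_pair[i + 1, j - 1]:
                interior += (sigma[i, j] - 1.0) * Zb[i + 1, j - 1]
            Zb[i, j] = (s * s) * interior
        ks = np.arange(0, j - MIN_HAIRPIN_LOOP)
        for i in range(j, -1, -1):
            z = u[j] * Z[i, j]
            if ks.size:
                kk = ks[ks >= i]
                if kk.size:
                    z += float(np.dot(Zb[kk, j], Z[i, kk]))
            Z[i, j + 1] = z

    total = Z[0, n]
    if total <= 0.0:
        return -math.inf
    return math.log(total) - n * log_s


@dataclass(frozen=True)
class FoldOutcome:
    """MFE structure/energy and ensemble free energy of one fold."""

    mfe_structure: SecondaryStructure
    mfe_energy: float
    ensemble_free_energy: float
    constrained: bool
    temperature: float

    def __post_init__(self):
        if self.ensemble_free_energy > self.mfe_energy + 1e-6:
            raise ValueError("ensemble free energy above MFE")


@dataclass(frozen=True)
class PfoldResult:
    """Unconstrained/constrained ensemble energies and the fold probability."""

    eu: float
    ec: float
    temperature: float
    pfold: float
    gas_constant: float = GAS_CONSTANT_KCAL


def _as_bottom_constraints(constraints, length: int):
    if constraints is None:
        return None
    return constraints


def fold(
    seq: str,
    model=None,
    constraints: Optional[ConstraintSet] = None,
) -> FoldOutcome:
    """MFE structure and ensemble free energy, optionally constrained.

    With constraints, minimisation and the partition function run only over
    structures containing every forced pair; an unsatisfiable constraint set
    raises :class:`EmptyEnsembleError`.
    """
    seq = seq.upper()
    model = model or ReferenceModel()
    if hasattr(model, "fold_outcome"):  # external backend (ViennaDNAModel)
        return model.fold_outcome(seq, constraints)
    allow_pair, allow_unpaired = _constraint_masks(seq, model, constraints)
    res = _dp_mfe(seq, model, allow_pair, allow_unpaired)
    if res is None:
        raise EmptyEnsembleError("no structure satisfies the constraints")
    mfe, pairs = res
    logz = _dp_logz(seq, model, allow_pair, allow_unpaired, mfe)
    efe = -model.rt * logz
    return FoldOutcome(
        mfe_structure=SecondaryStructure.from_pairs(pairs, len(seq)),
        mfe_energy=mfe,
        ensemble_free_energy=min(efe, mfe),  # clip fp noise at the invariant
        constrained=constraints is not None and len(constraints) > 0,
        temperature=model.temperature,
    )


def pfold(
    seq: str,
    model=None,
    constraints: Optional[ConstraintSet] = None,
) -> PfoldResult:
    """Boltzmann probability of the constrained (recombinogenic) ensemble."""
    model = model or ReferenceModel()
    unconstrained = fold(seq, model, None)
    eu = unconstrained.ensemble_free_energy
    if constraints is None or len(constraints) == 0:
        return PfoldResult(eu=eu, ec=eu, temperature=model.temperature,
                           pfold=1.0)
    try:
        constrained = fold(seq, model, constraints)
    except EmptyEnsembleError:
        return PfoldResult(eu=eu, ec=math.inf,
                           temperature=model.temperature, pfold=0.0)
    ec = constrained.ensemble_free_energy
    rt = GAS_CONSTANT_KCAL * model.temperature
    p = math.exp(min((eu - ec) / rt, 0.0))
    return PfoldResult(eu=eu, ec=ec, temperature=model.temperature, pfold=p)


def site_pfold(site: AttCSite, model=None, *,
               mismatch: str = "drop") -> PfoldResult:
    """pfold of a site's bottom strand under its recombinogenic constraints."""
    cs = recombinogenic_constraints(site, "bottom", mismatch=mismatch)
    return pfold(site.bottom, model, cs)


def strand_stability_gap(
    site: AttCSite,
    model=None,
    mode: str = "unconstrained",
) -> float:
    """MFE(bottom) - MFE(top) in kcal/mol; negative means the bottom strand
    folds more stably.  ``mode`` selects whether the recombinogenic
    constraints are imposed on each strand before minimisation."""
    if mode not in {"unconstrained", "constrained"}:
        raise ValueError("mode must be 'unconstrained' or 'constrained'")
    model = model or ReferenceModel()
    cs_b = cs_t = None
    if mode == "constrained":
        cs_b = recombinogenic_constraints(site, "bottom", mismatch="drop")
        cs_t = cs_b.to_strand("top", len(site))
    fb = fold(site.bottom, model, cs_b)
    ft = fold(site.top_strand, model, cs_t)
    return fb.mfe_energy - ft.mfe_energy
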