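"""Full nearest-neighbour DNA backend via the ViennaRNA bindings.

This backend matches the parameterisation used for published attC pfold
values: RNAfold-style MFE and partition-function folding with the DNA
nearest-neighbour parameter table, hard constraints enforcing the
recombinogenic base pairs, default temperature 37 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .attc import ConstraintSet
from .folding import (
    DEFAULT_TEMPERATURE_K,
    EmptyEnsembleError,
    FoldOutcome,
    SecondaryStructure,
)

__all__ = ["ViennaDNAModel"]

_PARAM_LOADERS = {
    "dna_mathews2004": "params_load_DNA_Mathews2004",
    "dna_mathews1999": "params_load_DNA_Mathews1999",
}

_loaded_params: Optional[str] = None


def _rna():
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - environment guard
        raise ImportError(
            "the ViennaRNA python bindings are required for the DNA "
            "parameter backend") from exc
    return RNA


def _ensure_params(parameter_set_id: str) -> None:
    global _loaded_params
    RNA = _rna()
    if _loaded_params == parameter_set_id:
        return
    loader = _PARAM_LOADERS.get(parameter_set_id)
    if loader is None:
        raise ValueError(
            f"unknown parameter set {parameter_set_id!r}; "
            f"choose from {sorted(_PARAM_LOADERS)}")
    getattr(RNA, loader)()
    _loaded_params = parameter_set_id


@dataclass(frozen=True)
class ViennaDNAModel:
    """EnergyModel backed by ViennaRNA with a DNA parameter table."""

    parameter_set_id: str = "dna_mathews2004"
    temperature: float = DEFAULT_TEMPERATURE_K

    @property
    def rt(self) -> float:
        from .folding import GAS_CONSTANT_KCAL
        return GAS_CONSTANT_KCAL * self.temperature

    def _compound(self, seq: str, constraints: Optional[ConstraintSet]):
        RNA = _rna()
        _ensure_params(self.parameter_set_id)
        md = RNA.md()
        md.temperature = self.temperature - 273.15
        fc = RNA.fold_compound(seq, md)
        if constraints is not None:
            for i, j in constraints:
                fc.hc_add_bp(
                    i + 1, j + 1,
                    RNA.CONSTRAINT_CONTEXT_ALL_LOOPS
                    | RNA.CONSTRAINT_CONTEXT_ENFORCE)
        return fc

    def fold_outcome(self, seq: str,
                     constraints: Optional[ConstraintSet] = None
                     ) -> FoldOutcome:
        seq = seq.upper().replace("U", "T")
        if constraints is not None and len(constraints):
            comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
            for i, j in constraints:
                if comp.get(seq[i]) != seq[j]:
                    raise EmptyEnsembleError(
                        f"forced pair {(i, j)} joins non-complementary "
                        f"bases {seq[i]}/{seq[j]}")
        fc = self._compound(seq, constraints)
        structure, mfe = fc.mfe()
        if constraints is not None and len(constraints):
            got = SecondaryStructure(structure).pairs()
            if not frozenset(constraints) <= got:
                raise EmptyEnsembleError(
                    "constraints unsatisfiable under the DNA parameter model")
        fc.exp_params_rescale(mfe)
        _, efe = fc.pf()
        if not math.isfinite(efe):
            raise EmptyEnsembleError("empty constrained ensemble")
        return FoldOutcome(
            mfe_structure=SecondaryStructure(structure),
            mfe_energy=float(mfe),
            ensemble_free_energy=float(min(efe, mfe)),
            constrained=constraints is not None and len(constraints) > 0,
            temperature=self.temperature,
        )
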