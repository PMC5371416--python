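"""Synthetic attC sites, cohorts and annotated replicons with ground truth.

The site generator assembles a bottom strand 5'->3' as

    R'(RYYYAAC) | UCS | spacer | L' | VTS | L'' | spacer | EHB | R''(GTTRRRY)

so that L' pairs L'' and the YAAC core pairs the GTTR core in the intended
recombinogenic hairpin; the UCS and EHB blocks bulge out of the stem.  The
reported top strand is the reverse complement, which places the boxes in
R'' < L'' < L' < R' order along the top strand.

Composition rules make the construction analysable:

* unpaired blocks (UCS, spacers, EHB, VTS filler) are drawn from a
  non-self-pairable alphabet -- purines {G, A} when the bottom strand is
  purine-biased (mobile-integron-like sites), {C, A} when the bias is
  reversed (Vibrio-SCI-like sites).  No Watson-Crick pair can form within or
  between these blocks, so the planted helices are the only helices and the
  box-location heuristic recovers the planted annotation exactly for clean
  sites.
* low-fold-probability sites emulate branched variable terminal structures:
  the VTS carries two decoy segments complementary to L' and L''
  respectively, plus one or more planted stem mismatches, so the
  unconstrained ensemble prefers the branched (non-recombinogenic) fold and
  pfold drops by orders of magnitude.

Cohort presets differ only through these documented parameter
distributions; replicons add a skew-biased background and planted integron
arrays in a requested orientation relative to replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .attc import (
    AttCSite,
    BoxAnnotation,
    reverse_complement,
    top_to_bottom_interval,
)
from .replichore import IntegronRecord

__all__ = [
    "AttCGeneratorParams",
    "CohortPreset",
    "COHORT_PRESETS",
    "SyntheticReplicon",
    "generate_attc",
    "generate_cohort",
    "generate_replicon",
]

_PURINE_ALPHABET = (("G", "A"), (0.4, 0.6))
_PYRIMIDINE_RICH_ALPHABET = (("C", "A"), (0.5, 0.5))


@dataclass(frozen=True)
class AttCGeneratorParams:
    """Knobs of one synthetic attC site (lengths in bp).

    ``purine_bias_bottom`` is the target purine fraction of the bottom
    strand's unpaired blocks; values >= 0.5 select the purine alphabet
    (G/A), values < 0.5 the C/A alphabet.  The paired stem contributes no
    net skew because its two arms are complementary.
    """

    stem_pairs: int = 14
    ehb_count: int = 3
    ucs_len: int = 3
    vts_len: int = 6
    spacer_len: int = 5
    purine_bias_bottom: float = 0.75
    stem_mismatches: int = 0
    vts_decoy: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.stem_pairs, self.ucs_len, self.spacer_len) < 0 or \
                min(self.ehb_count, self.vts_len) < 0:
            raise ValueError("negative length parameter")
        if self.vts_len < 3:
            raise ValueError("the VTS loop needs at least 3 nt")
        if self.stem_pairs < 4:
            raise ValueError("stem too short to define L boxes")
        if self.stem_mismatches >= self.stem_pairs:
            raise ValueError("more mismatches than stem pairs")

    @property
    def total_length(self) -> int:
        return (2 * (7 + self.stem_pairs + self.spacer_len)
                + self.ucs_len + self.vts_len + self.ehb_count)


def _unpaired_alphabet(bias: float):
    return _PURINE_ALPHABET if bias >= 0.5 else _PYRIMIDINE_RICH_ALPHABET


def _draw(rng: np.random.Generator, letters, probs, k: int) -> str:
    if k == 0:
        return ""
    return "".join(rng.choice(letters, size=k, p=probs))


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _revcomp4(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def generate_attc(params: AttCGeneratorParams, seed: Optional[int] = None,
                  *, site_id: str = "synthetic_attc",
                  origin_class: str = "unknown") -> tuple[AttCSite, dict]:
    """One synthetic site plus its ground truth.

    Deterministic under (params, seed).  The truth dict records the planted
    boxes (top-strand coordinates), the intended recombinogenic pairs
    (bottom-strand coordinates) and the construction parameters.
    """
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    letters, probs = _unpaired_alphabet(params.purine_bias_bottom)

    m = params.stem_pairs
    # R' bottom strand: R Y Y Y A A C (core YAAC in the last four positions).
    r_bases = ("A", "G")
    y_bases = ("C", "T")
    rp = (rng.choice(r_bases) + "".join(rng.choice(y_bases) for _ in range(3))
          + "AAC")
    rd = _revcomp4(rp)  # GTTRRRY, fully complementary to R'

    # Stem: L' drawn with a mild G/C guarantee; L'' is its pairing partner
    # with planted mismatches.
    while True:
        lp = _draw(rng, ("A", "C", "G", "T"), (0.25, 0.25, 0.25, 0.25), m)
        if sum(c in "GC" for c in lp) >= max(2, m // 4):
            break
    ld = list(_revcomp4(lp))
    mism_positions: list[int] = []
    if params.stem_mismatches:
        # One mismatch near the L'' 5' end keeps decoy helices from being
        # extended past the planted boxes by the location heuristic.
        pool = [1] + [int(p) for p in
                      rng.choice(np.arange(2, m - 1),
                                 size=params.stem_mismatches - 1,
                                 replace=False)] \
            if params.stem_mismatches > 1 else [1]
        for pos in pool:
            partner = lp[m - 1 - pos]
            choices = [c for c in "ACGT" if c != _COMP[partner]]
            ld[pos] = str(rng.choice(choices))
            mism_positions.append(pos)
    ld = "".join(ld)

    ucs = _draw(rng, letters, probs, params.ucs_len)
    sp5 = _draw(rng, letters, probs, params.spacer_len)
    sp3 = _draw(rng, letters, probs, params.spacer_len)
    ehb = _draw(rng, letters, probs, params.ehb_count)

    v = params.vts_len
    if params.vts_decoy:
        d1 = _revcomp4(lp)           # pairs L' in full
        d2 = _revcomp4(ld)           # pairs L'' in full
        need = 2 * m + 7             # pads of >= 2/3/2 around the decoys
        if v < need:
            raise ValueError(
                f"vts_len {v} too short for decoy segments (need >= {need})")
        pad_extra = v - 2 * m - 7
        p1 = 2 + pad_extra // 2
        p3 = 2 + (pad_extra - pad_extra // 2)
        vts = (_draw(rng, letters, probs, p1) + d1 + "AAA" + d2
               + _draw(rng, letters, probs, p3))
        # asymmetric pads break any mirror alignment of the two decoys
        if p1 == p3 and pad_extra >= 2:
            vts = (_draw(rng, letters, probs, p1 - 1) + d1 + "AAAA" + d2
                   + _draw(rng, letters, probs, p3))
    else:
        vts = _draw(rng, letters, probs, v)
    # block single-step extension of the L helix into the loop
    if len(vts) >= 4:
        vts = "AA" + vts[2:-2] + "AA"

    bottom = rp + ucs + sp5 + lp + vts + ld + sp3 + ehb + rd
    n = len(bottom)
    assert n == params.total_length

    # Bottom-strand intervals, then top-strand boxes.
    o_lp = 7 + params.ucs_len + params.spacer_len
    lp_b = (o_lp, o_lp + m)
    ld_b = (lp_b[1] + len(vts), lp_b[1] + len(vts) + m)
    boxes = BoxAnnotation(
        r_dprime=(0, 7),
        l_dprime=top_to_bottom_interval(ld_b, n),
        l_prime=top_to_bottom_interval(lp_b, n),
        r_prime=(n - 7, n),
    )
    top = reverse_complement(bottom)
    site = AttCSite(id=site_id, top_strand=top, boxes=boxes,
                    origin_class=origin_class)

    intended_pairs = {(3 + k, n - 7 + 3 - k) for k in range(4)}
    for k in range(m):
        if k not in (m - 1 - p for p in mism_positions):
            intended_pairs.add((lp_b[0] + k, ld_b[1] - 1 - k))
    truth = {
        "bottom_strand": bottom,
        "boxes": boxes,
        "intended_pairs_bottom": frozenset(intended_pairs),
        "stem_mismatch_positions": tuple(mism_positions),
        "params": params,
    }
    return site, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortPreset:
    """A named distribution over generator parameters."""

    name: str
    origin_class: str
    draw: Callable[[np.random.Generator], AttCGeneratorParams]


def _draw_mi_like(rng: np.random.Generator) -> AttCGeneratorParams:
    return AttCGeneratorParams(
        stem_pairs=int(rng.integers(13, 17)),
        ehb_count=int(rng.integers(2, 4)),
        ucs_len=int(rng.integers(2, 4)),
        vts_len=int(rng.integers(3, 13)),
        spacer_len=5,
        purine_bias_bottom=0.75,
        stem_mismatches=0,
        vts_decoy=False,
    )


def _draw_sci_other_like(rng: np.random.Generator) -> AttCGeneratorParams:
    return AttCGeneratorParams(
        stem_pairs=int(rng.integers(13, 17)),
        ehb_count=int(rng.integers(2, 4)),
        ucs_len=3,
        vts_len=int(rng.integers(5, 26)),
        spacer_len=5,
        purine_bias_bottom=0.65,
        stem_mismatches=int(rng.integers(0, 2)),
        vts_decoy=False,
    )


def _draw_sci_vibrio_like(rng: np.random.Generator) -> AttCGeneratorParams:
    stem = int(rng.integers(13, 17))
    total = int(rng.integers(120, 130))
    vts = total - (2 * (7 + stem + 5) + 3 + 3)
    return AttCGeneratorParams(
        stem_pairs=stem,
        ehb_count=3,
        ucs_len=3,
        vts_len=vts,
        spacer_len=5,
        purine_bias_bottom=0.30,
        stem_mismatches=int(rng.integers(1, 4)),
        vts_decoy=True,
    )


COHORT_PRESETS = {
    "MI_like": CohortPreset("MI_like", "MI", _draw_mi_like),
    "SCI_other_like": CohortPreset("SCI_other_like", "SCI",
                                   _draw_sci_other_like),
    "SCI_vibrio_like": CohortPreset("SCI_vibrio_like", "SCI",
                                    _draw_sci_vibrio_like),
}


def generate_cohort(preset, n: int, seed: int
                    ) -> tuple[list[AttCSite], pd.DataFrame]:
    """``n`` sites drawn from a preset's parameter distributions.

    ``preset`` is a :class:`CohortPreset` or a preset name.  Returns the
    sites and a truth table (one row per site) with the planted parameters.
    """
    if isinstance(preset, str):
        preset = COHORT_PRESETS[preset]
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sites, rows = [], []
    for k in range(n):
        params = preset.draw(rng)
        site_seed = int(rng.integers(0, 2**31 - 1))
        site, truth = generate_attc(
            params, site_seed,
            site_id=f"{preset.name}_{k:04d}",
            origin_class=preset.origin_class)
        sites.append(site)
        rows.append({
            "site_id": site.id,
            "preset": preset.name,
            "length": len(site),
            "stem_pairs": params.stem_pairs,
            "vts_len": params.vts_len,
            "stem_mismatches": params.stem_mismatches,
            "vts_decoy": params.vts_decoy,
            "purine_bias_bottom": params.purine_bias_bottom,
            "seed": site_seed,
        })
    return sites, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Replicons
# ---------------------------------------------------------------------------


@dataclass
class SyntheticReplicon:
    """A circular replicon with planted integron arrays and full truth."""

    replicon_id: str
    sequence: str
    oric: int
    ter: int
    records: list  # IntegronRecord per planted array
    cds_table: pd.DataFrame
    truth: dict


def _resolve_lengths(spec, n: int, rng: np.random.Generator) -> list[int]:
    if isinstance(spec, int):
        return [spec] * n
    if isinstance(spec, (list, tuple)) and spec and spec[0] == "lognormal":
        _, median, sigma = spec
        return [int(x) for x in
                np.round(median * np.exp(sigma * rng.standard_normal(n)))]
    lengths = [int(x) for x in spec]
    if len(lengths) != n:
        raise ValueError("cassette length list does not match n_cassettes")
    return lengths


def generate_replicon(
    length: int = 40000,
    oric: int = 0,
    arrays: Sequence[tuple] = ((("lagging_template"), 3, 600),),
    skew_strength: float = 0.5,
    seed: int = 0,
    *,
    replicon_id: str = "synthetic_replicon",
    cds_per_cassette: bool = True,
) -> SyntheticReplicon:
    """A circular replicon with GC-skewed replichores and planted arrays.

    Each array is ``(orientation, n_cassettes, cassette_lengths)`` where the
    orientation names the template strand the attC *bottom* strands should
    sit on, ``n_cassettes`` is the number of cassettes (the array carries
    ``n_cassettes + 1`` attC sites) and ``cassette_lengths`` is an int, an
    explicit list, or ``("lognormal", median, sigma)``.  The background is
    G-enriched on the leading strand of each replichore in proportion to
    ``skew_strength``; arrays are laid head-to-tail on the first replichore
    starting at 10% of the replicon length.
    """
    if not 0 <= skew_strength <= 1:
        raise ValueError("skew_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ter = (oric + length // 2) % length

    pg = 0.25 * (1 + skew_strength)
    pc = 0.25 * (1 - skew_strength)
    n_inc = length // 2
    bases = np.empty(length, dtype="U1")
    inc_block = rng.choice(["G", "C", "A", "T"], size=n_inc,
                           p=(pg, pc, 0.25, 0.25))
    dec_block = rng.choice(["G", "C", "A", "T"], size=length - n_inc,
                           p=(pc, pg, 0.25, 0.25))
    # arc oriC -> ter (rightward, with wraparound) gets the G-rich top strand
    idx_inc = (np.arange(n_inc) + oric) % length
    idx_dec = (np.arange(length - n_inc) + oric + n_inc) % length
    bases[idx_inc] = inc_block
    bases[idx_dec] = dec_block

    records: list[IntegronRecord] = []
    cds_rows: list[dict] = []
    truth_arrays: list[dict] = []
    cursor = (oric + length // 10) % length
    arc_end = (oric + n_inc - length // 20) % length

    for a_idx, (orientation, n_cassettes, length_spec) in enumerate(arrays):
        if orientation not in {"leading_template", "lagging_template"}:
            raise ValueError(f"bad orientation {orientation!r}")
        # on the 'increasing' replichore: '+'-annotated sites put the bottom
        # strand on the leading template
        strand = "+" if orientation == "leading_template" else "-"
        n_sites = n_cassettes + 1
        cassette_lengths = _resolve_lengths(length_spec, n_cassettes, rng)
        site_entries = []
        pos = cursor
        for s_idx in range(n_sites):
            params = _draw_mi_like(rng)
            site_seed = int(rng.integers(0, 2**31 - 1))
            site, _ = generate_attc(
                params, site_seed,
                site_id=f"{replicon_id}_a{a_idx}_s{s_idx}")
            text = site.top_strand if strand == "+" \
                else reverse_complement(site.top_strand)
            iv = (pos, pos + len(site))
            if iv[1] >= length:
                raise ValueError("planted arrays do not fit on the replicon")
            bases[iv[0]:iv[1]] = list(text)
            site_entries.append((iv, strand))
            if s_idx < n_cassettes:
                clen = cassette_lengths[s_idx]
                if clen <= len(site) + 60:
                    raise ValueError(
                        f"cassette length {clen} too short for the site")
                if cds_per_cassette:
                    cds_len = min(clen - len(site) - 60,
                                  int(rng.integers(200, 600)))
                    cds_start = iv[1] + 30
                    cds_rows.append({
                        "cds_id": f"{replicon_id}_a{a_idx}_c{s_idx}",
                        "start": cds_start, "end": cds_start + cds_len,
                        "strand": strand, "in_integron": True,
                    })
                pos += clen
        array_end = pos + len(site)
        if (array_end - oric) % length > (arc_end - oric) % length:
            raise ValueError("planted arrays overflow the first replichore")
        cursor = array_end + 5000  # keep arrays apart under 4-kb aggregation
        record = IntegronRecord(
            replicon_id=replicon_id,
            attc_sites=sorted(site_entries, key=lambda x: x[0][0]),
            id=f"{replicon_id}_array{a_idx}")
        records.append(record)
        truth_arrays.append({
            "array_id": record.id,
            "orientation": orientation,
            "strand": strand,
            "n_attc": n_sites,
            "cassette_lengths": cassette_lengths,
        })

    # background CDSs outside the arrays, longer than cassette CDSs
    bg_start = (oric + n_inc + length // 20) % length
    p = bg_start
    for k in range(max(3, length // 8000)):
        cds_len = int(rng.integers(700, 1100))
        if p + cds_len >= length:
            break
        cds_rows.append({
            "cds_id": f"{replicon_id}_bg{k}", "start": p, "end": p + cds_len,
            "strand": "+" if rng.random() < 0.5 else "-",
            "in_integron": False,
        })
        p += cds_len + int(rng.integers(100, 400))

    return SyntheticReplicon(
        replicon_id=replicon_id,
        sequence="".join(bases),
        oric=oric,
        ter=ter,
        records=records,
        cds_table=pd.DataFrame(cds_rows),
        truth={"oric": oric, "ter": ter, "skew_strength": skew_strength,
               "arrays": truth_arrays},
    )
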