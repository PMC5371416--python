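"""Replication geometry and integron/cassette genomics.

A circular replicon is split by the replication origin (oriC) and terminus
(ter) into two replichores.  Following the Z-curve convention, the leading
strand is the strand with an increasing gradient of GC disparity (excess of
G over C); on the replichore where the disparity of the annotated (plus)
strand increases, the plus strand is the leading strand, its complement is
the leading-strand *template*, and the plus strand itself serves as the
lagging-strand template.  The lagging-strand template is transiently
single-stranded between Okazaki fragments, which is what makes the
orientation of attC bottom strands relative to replication consequential.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReplichoreMap",
    "IntegronRecord",
    "CassetteRecord",
    "OrientationIndeterminateError",
    "gc_disparity_profile",
    "infer_replichores",
    "template_class",
    "aggregate_array",
    "orient_integron",
    "cassette_metrics",
    "classify_integron",
    "MOBILE_INTEGRASE_CLASSES",
]

LEADING = "leading_template"
LAGGING = "lagging_template"

#: Integrase classes of mobile integrons.
MOBILE_INTEGRASE_CLASSES = {"1", "2", "3", "4", "5"}


class OrientationIndeterminateError(ValueError):
    """No usable skew signal and no oriC supplied."""


def gc_disparity_profile(sequence: str) -> np.ndarray:
    """Cumulative excess of G over C along the top strand.

    Entry ``i`` is ``#G - #C`` in the prefix of length ``i + 1``; ambiguity
    codes contribute 0.
    """
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    inc = (arr == ord("G")).astype(np.int64) - (arr == ord("C"))
    return np.cumsum(inc)


@dataclass(frozen=True)
class ReplichoreMap:
    """oriC/ter geometry of a circular replicon."""

    replicon_length: int
    oric: int
    ter: int
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.circular:
            raise ValueError("only circular replicons are supported")
        if self.oric == self.ter:
            raise ValueError("oriC and ter must differ")
        for p in (self.oric, self.ter):
            if not 0 <= p < self.replicon_length:
                raise ValueError("oriC/ter outside the replicon")

    def fork_direction(self, position: int) -> str:
        """'increasing' on the arc oriC -> ter going rightward (with
        wraparound), 'decreasing' on the other arc."""
        p = position % self.replicon_length
        span = (self.ter - self.oric) % self.replicon_length
        return "increasing" if (p - self.oric) % self.replicon_length < span \
            else "decreasing"


def infer_replichores(
    profile: np.ndarray,
    oric: Optional[int] = None,
    circular: bool = True,
    ter: Optional[int] = None,
    min_amplitude: Optional[float] = None,
) -> ReplichoreMap:
    """Locate oriC/ter from the cumulative GC disparity of the top strand.

    The cumulative profile is detrended for circularity (the net disparity is
    spread evenly along the replicon); oriC is the global minimum of the
    detrended curve and ter the global maximum.  A user-supplied oriC always
    wins over inference.  Inference refuses profiles whose detrended
    amplitude stays below ``min_amplitude`` (default ``4 * sqrt(n)``, above
    the range of an unbiased composition's random walk), since the extrema
    of a signal-free profile carry no replichore information.
    """
    if not circular:
        raise ValueError("linear replicons have no replichore geometry")
    profile = np.asarray(profile)
    n = len(profile)
    if n < 2:
        raise ValueError("profile too short")
    detrended = profile - profile[-1] * (np.arange(1, n + 1) / n)
    amplitude = float(np.ptp(detrended))
    if min_amplitude is None:
        min_amplitude = 4.0 * math.sqrt(n)
    if oric is None:
        if amplitude < min_amplitude:
            raise OrientationIndeterminateError(
                "no usable GC disparity signal and no oriC supplied "
                f"(amplitude {amplitude:.0f} < {min_amplitude:.0f})")
        oric = int((np.argmin(detrended) + 1) % n)
    if ter is None:
        if amplitude == 0:
            ter = (oric + n // 2) % n
        else:
            ter = int((np.argmax(detrended) + 1) % n)
        if ter == oric:
            ter = (oric + n // 2) % n
    return ReplichoreMap(replicon_length=n, oric=int(oric), ter=int(ter))


def template_class(position: int, strand: str, rmap: ReplichoreMap) -> str:
    """Which template a strand serves as at a genomic position.

    Where the fork direction is 'increasing' the minus strand is the
    leading-strand template and the plus strand the lagging-strand template;
    the convention reverses on the other replichore.  Flipping the strand
    always flips the class.
    """
    if strand not in {"+", "-"}:
        raise ValueError("strand must be '+' or '-'")
    increasing = rmap.fork_direction(position) == "increasing"
    minus = strand == "-"
    return LEADING if (increasing == minus) else LAGGING


@dataclass
class IntegronRecord:
    """An integrase (optional) plus an ordered attC site array."""

    replicon_id: str
    attc_sites: list  # [( (start, end), strand ), ...] sorted by start
    integrase: Optional[tuple] = None  # ((start, end), strand, class)
    element_class: str = "unknown"
    id: Optional[str] = None

    def __post_init__(self) -> None:
        starts = [iv[0] for iv, _ in self.attc_sites]
        if starts != sorted(starts):
            raise ValueError("attC sites must be sorted by start")
        for _, strand in self.attc_sites:
            if strand not in {"+", "-"}:
                raise ValueError("attC strand must be '+' or '-'")
        if self.element_class not in {"SCI", "MI", "MCI", "unknown"}:
            raise ValueError(f"bad element class {self.element_class!r}")

    @property
    def n_attc(self) -> int:
        return len(self.attc_sites)

    @property
    def span(self) -> tuple[int, int]:
        coords = [c for iv, _ in self.attc_sites for c in iv]
        if self.integrase:
            coords.extend(self.integrase[0])
        return (min(coords), max(coords))


@dataclass(frozen=True)
class CassetteRecord:
    """One cassette: the region between two consecutive attC sites."""

    upstream_attc: tuple[int, int]
    downstream_attc: tuple[int, int]
    length: int
    cds_list: tuple = ()  # ((start, end), strand, is_arg)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("cassette length must be positive")


def aggregate_array(
    attc_sites: Sequence,
    max_distance: int = 4000,
) -> list[list]:
    """Group consecutive attC sites into arrays.

    Sites whose gap (start of the next minus end of the previous) is at most
    ``max_distance`` bp join the same array; the published re-aggregation of
    large sedentary arrays uses 15000 bp instead of the 4000 bp default.
    """
    if not attc_sites:
        return []
    sites = list(attc_sites)
    arrays = [[sites[0]]]
    for prev, cur in zip(sites, sites[1:]):
        gap = cur[0][0] - prev[0][1]
        if gap <= max_distance:
            arrays[-1].append(cur)
        else:
            arrays.append([cur])
    return arrays


@dataclass(frozen=True)
class OrientationCall:
    label: str            # leading_template | lagging_template | mixed
    n_leading: int
    n_lagging: int
    mixed: bool


def orient_integron(record: IntegronRecord, rmap: ReplichoreMap
                    ) -> OrientationCall:
    """Template-strand orientation of an integron's attC bottom strands.

    The bottom strand of each site is the strand opposite the annotated
    top-strand orientation.  The array label is the unanimous per-site class
    when all sites agree, the majority class otherwise (flagged as mixed);
    exact ties are labelled 'mixed'.
    """
    if record.n_attc < 1:
        raise ValueError("integron record has no attC sites")
    n_lead = n_lag = 0
    for (start, end), strand in record.attc_sites:
        bottom = "-" if strand == "+" else "+"
        mid = (start + end) // 2
        cls = template_class(mid, bottom, rmap)
        if cls == LEADING:
            n_lead += 1
        else:
            n_lag += 1
    if n_lead == n_lag:
        label = "mixed"
    elif n_lead > n_lag:
        label = LEADING
    else:
        label = LAGGING
    mixed = bool(n_lead and n_lag)
    return OrientationCall(label=label, n_leading=n_lead, n_lagging=n_lag,
                           mixed=mixed)


def cassette_metrics(
    record: IntegronRecord,
    annotations: Optional[pd.DataFrame] = None,
    arg_ids: Optional[set] = None,
    *,
    replicon_length: Optional[int] = None,
    length_mode: str = "start_to_start",
    exclude_args: bool = False,
) -> tuple[list[CassetteRecord], dict]:
    """Cassette lengths and CDS-length partitions for one integron.

    Cassette length defaults to the start-to-start distance of consecutive
    attC sites (one attC per cassette); ``length_mode='end_to_start'`` is the
    alternative.  ``annotations`` is a CDS table with columns
    ``start, end, strand`` and optionally ``cds_id``; CDS lengths are split
    into inside/outside the integron span, and antibiotic-resistance CDSs
    (ids in ``arg_ids``) can be excluded.
    """
    if length_mode not in {"start_to_start", "end_to_start"}:
        raise ValueError("length_mode must be start_to_start or end_to_start")
    sites = record.attc_sites
    for (s1, e1), _ in sites:
        for (s2, e2), _ in sites:
            if (s1, e1) != (s2, e2) and s1 < e2 and s2 < e1:
                raise ValueError("overlapping attC annotations")

    arg_ids = arg_ids or set()
    cassettes: list[CassetteRecord] = []
    for (iv1, _), (iv2, _) in zip(sites, sites[1:]):
        if length_mode == "start_to_start":
            length = iv2[0] - iv1[0]
        else:
            length = iv2[0] - iv1[1]
        if length <= 0 and replicon_length:
            length += replicon_length
        cds_here: list = []
        if annotations is not None and len(annotations):
            lo, hi = iv1[0], iv2[0]
            sel = annotations[(annotations["start"] >= lo)
                              & (annotations["end"] <= hi)]
            for _, row in sel.iterrows():
                is_arg = str(row.get("cds_id", "")) in arg_ids
                cds_here.append(((int(row["start"]), int(row["end"])),
                                 row.get("strand", "+"), is_arg))
        cassettes.append(CassetteRecord(
            upstream_attc=tuple(iv1), downstream_attc=tuple(iv2),
            length=int(length), cds_list=tuple(cds_here)))

    summary: dict = {
        "n_cassettes": len(cassettes),
        "cassette_lengths": [c.length for c in cassettes],
        "mean_cassette_length": (float(np.mean([c.length for c in cassettes]))
                                 if cassettes else float("nan")),
    }
    if annotations is not None and len(annotations):
        lo, hi = record.span
        inside = annotations[(annotations["start"] >= lo)
                             & (annotations["end"] <= hi)].copy()
        outside = annotations[(annotations["end"] <= lo)
                              | (annotations["start"] >= hi)].copy()
        if exclude_args and "cds_id" in annotations.columns:
            inside = inside[~inside["cds_id"].astype(str).isin(arg_ids)]
            outside = outside[~outside["cds_id"].astype(str).isin(arg_ids)]
        li = (inside["end"] - inside["start"]).to_numpy()
        lo_ = (outside["end"] - outside["start"]).to_numpy()
        summary["mean_cds_length_inside"] = float(np.mean(li)) if len(li) else float("nan")
        summary["mean_cds_length_outside"] = float(np.mean(lo_)) if len(lo_) else float("nan")
        summary["replicon_minus_integron_mean_cds"] = (
            summary["mean_cds_length_outside"]
            - summary["mean_cds_length_inside"])
    return cassettes, summary


@dataclass(frozen=True)
class Classification:
    label: str  # SCI | MI | unknown
    conflict: bool = False

    @property
    def chromosomal_label(self) -> str:
        """MI located on a chromosome is reported as MCI downstream."""
        return self.label


def classify_integron(
    record: IntegronRecord,
    cohort_metadata: Optional[dict] = None,
) -> Classification:
    """Sedentary-vs-mobile classification of one integron.

    SCI: present in all sequenced strains of the species, or more than 19
    attC sites.  MI: absent in more than 40% of the sequenced genomes, on a
    plasmid, or integrase from one of the five mobile classes.  SCI criteria
    take precedence; if both fire the record is flagged as a conflict and
    kept SCI; if neither fires the label is 'unknown'.
    """
    md = cohort_metadata or {}
    frac = md.get("fraction_of_strains_present")
    on_plasmid = md.get("on_plasmid")
    iclass = md.get("integrase_class")
    if iclass is None and record.integrase is not None:
        iclass = record.integrase[2]

    sci = (frac is not None and frac >= 1.0) or record.n_attc > 19
    mi = ((frac is not None and frac < 0.6)
          or bool(on_plasmid)
          or (iclass is not None and str(iclass) in MOBILE_INTEGRASE_CLASSES))
    if sci:
        return Classification("SCI", conflict=mi)
    if mi:
        return Classification("MI")
    return Classification("unknown")
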