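"""End-to-end runs: per-site folding metrics, array orientation, cohort
comparisons and report writing.

Each ``run_*`` function is a thin composition of the library modules so that
pipeline outputs equal module-level calls composed by hand; there is no
hidden state and every random choice is seeded from the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .attc import (
    AttCSite,
    UnannotatableSiteError,
    ConstraintError,
    locate_boxes,
    recombinogenic_constraints,
)
from .folding import (
    DEFAULT_TEMPERATURE_K,
    EmptyEnsembleError,
    ReferenceModel,
    fold,
    pfold,
)
from .replichore import (
    IntegronRecord,
    aggregate_array,
    gc_disparity_profile,
    infer_replichores,
    orient_integron,
    OrientationIndeterminateError,
)
from .stats import cohort_summary, linear_fit, rank_sum_test, skews

logger = logging.getLogger("attcfold")

__all__ = ["RunConfig", "make_model", "run_site_metrics", "run_orientation",
           "run_compare", "write_report"]


@dataclass
class RunConfig:
    """Serializable run configuration (plain key=value text file)."""

    temperature: float = DEFAULT_TEMPERATURE_K
    parameter_set_id: str = "dna_mathews2004"  # or "reference"
    pfold_threshold: float = 0.1
    aggregation_distance: int = 4000
    identity_match: float = 1.0
    identity_mismatch: float = -1.0
    identity_gap_open: float = -2.0
    identity_gap_extend: float = -1.0
    seed: int = 0
    exclude_args: bool = False
    exclude_taxon: Optional[str] = None

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = line.split("=", 1)
            key = key.strip()
            value = value.strip()
            if not hasattr(defaults, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if value == "None":
                kwargs[key] = None
            elif isinstance(current, bool):
                kwargs[key] = value.lower() in {"true", "1", "yes"}
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def make_model(config: RunConfig):
    """Energy model selected by the configuration."""
    if config.parameter_set_id == "reference":
        return ReferenceModel(temperature=config.temperature)
    from .vienna import ViennaDNAModel
    return ViennaDNAModel(parameter_set_id=config.parameter_set_id,
                          temperature=config.temperature)


def run_site_metrics(
    sites: list[AttCSite],
    config: Optional[RunConfig] = None,
    model=None,
) -> pd.DataFrame:
    """One row per site: length, pfold of the bottom strand, MFE of both
    strands (unconstrained and constrained), the strand-stability gap and
    top-strand skews.  Sites whose boxes cannot be located are logged and
    counted, not fatal."""
    if not sites:
        raise ValueError("no sites supplied")
    config = config or RunConfig()
    model = model or make_model(config)
    rows = []
    failures = 0
    for site in sites:
        sk = skews(site.top_strand)
        row = {
            "site_id": site.id,
            "origin_class": site.origin_class,
            "host_taxon": site.host_taxon or "",
            "length": len(site),
            "gc_skew": sk.gc_skew, "at_skew": sk.at_skew,
        }
        try:
            cs_b = recombinogenic_constraints(site, "bottom",
                                              mismatch="drop")
        except (UnannotatableSiteError, ConstraintError) as exc:
            failures += 1
            logger.warning("site %s unannotatable: %s", site.id, exc)
            rows.append(row)
            continue
        cs_t = cs_b.to_strand("top", len(site))
        fb_u = fold(site.bottom, model)
        ft_u = fold(site.top_strand, model)
        row["mfe_bs"] = fb_u.mfe_energy
        row["mfe_ts"] = ft_u.mfe_energy
        row["gap"] = fb_u.mfe_energy - ft_u.mfe_energy
        try:
            fb_c = fold(site.bottom, model, cs_b)
            ft_c = fold(site.top_strand, model, cs_t)
            row["mfe_bs_constrained"] = fb_c.mfe_energy
            row["mfe_ts_constrained"] = ft_c.mfe_energy
            rt = model.rt
            row["pfold"] = float(
                np.exp(min(0.0, (fb_u.ensemble_free_energy
                                 - fb_c.ensemble_free_energy) / rt)))
        except EmptyEnsembleError:
            row["pfold"] = 0.0
        rows.append(row)
    if failures:
        logger.info("%d/%d sites could not be annotated", failures,
                    len(sites))
    df = pd.DataFrame(rows)
    df.attrs["n_unannotatable"] = failures
    return df


def run_orientation(
    replicon_seqs: dict[str, str],
    integron_table: pd.DataFrame,
    oric_positions: Optional[dict[str, int]] = None,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """One row per aggregated attC array with its template orientation.

    ``integron_table`` uses internal coordinates (0-based half-open) as
    produced by :func:`attcfold.io.read_integron_table`.
    """
    config = config or RunConfig()
    oric_positions = oric_positions or {}
    rows = []
    counts: dict[str, int] = {}
    for replicon_id, grp in integron_table.groupby("replicon_id"):
        attc = grp[grp["element"].str.lower() == "attc"]
        if attc.empty:
            continue
        if replicon_id not in replicon_seqs:
            raise KeyError(
                f"no sequence supplied for annotated replicon "
                f"{replicon_id!r}")
        seq = replicon_seqs[replicon_id]
        profile = gc_disparity_profile(seq)
        try:
            rmap = infer_replichores(profile,
                                     oric=oric_positions.get(replicon_id))
        except OrientationIndeterminateError:
            rmap = None
        sites = sorted(
            (((int(r["start"]), int(r["end"])), str(r["strand"]))
             for _, r in attc.iterrows()),
            key=lambda x: x[0][0])
        arrays = aggregate_array(sites, config.aggregation_distance)
        for a_idx, arr in enumerate(arrays):
            row = {
                "replicon_id": replicon_id,
                "array_id": f"{replicon_id}_array{a_idx}",
                "n_attc": len(arr),
                "span_start": arr[0][0][0],
                "span_end": arr[-1][0][1],
            }
            if rmap is None:
                row["orientation"] = "indeterminate"
                row["mixed"] = False
            else:
                record = IntegronRecord(replicon_id=replicon_id,
                                        attc_sites=arr)
                call = orient_integron(record, rmap)
                row["orientation"] = call.label
                row["mixed"] = call.mixed
            counts[row["orientation"]] = counts.get(row["orientation"], 0) + 1
            rows.append(row)
    logger.info("array orientations: %s", counts)
    return pd.DataFrame(rows)


def run_compare(
    site_table: pd.DataFrame,
    grouping: str,
    config: Optional[RunConfig] = None,
) -> dict:
    """Group summaries, all pairwise rank-sum tests and within-group
    regressions (pfold and gap against site length)."""
    config = config or RunConfig()
    if grouping not in site_table.columns:
        raise ValueError(f"no grouping column {grouping!r}")
    if config.exclude_taxon and "host_taxon" in site_table.columns:
        site_table = site_table[
            site_table["host_taxon"] != config.exclude_taxon]
    groups = {name: grp for name, grp in site_table.groupby(grouping)
              if len(grp)}
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    summary = cohort_summary(site_table, grouping,
                             pfold_threshold=config.pfold_threshold)
    tests = []
    for (na, ga), (nb, gb) in combinations(groups.items(), 2):
        for col in ("pfold", "length", "gap"):
            if col not in site_table.columns:
                continue
            x = ga[col].dropna()
            y = gb[col].dropna()
            if x.empty or y.empty:
                continue
            res = rank_sum_test(x, y)
            tests.append({"group_a": na, "group_b": nb, "variable": col,
                          "statistic": res.statistic,
                          "p_two_sided": res.p_two_sided,
                          "method": res.method})
    regressions = []
    for name, grp in groups.items():
        for col in ("pfold", "gap"):
            if col not in grp.columns:
                continue
            sub = grp[["length", col]].dropna()
            if len(sub) < 3 or sub["length"].var() == 0:
                continue
            fit = linear_fit(sub["length"], sub[col])
            regressions.append({
                "group": name, "response": col, "slope": fit.slope,
                "intercept": fit.intercept, "r_squared": fit.r_squared,
                "p_slope": fit.p_slope})
    return {
        "summary": summary,
        "tests": pd.DataFrame(tests),
        "regressions": pd.DataFrame(regressions),
    }


def write_report(tables: dict, outdir, config: Optional[RunConfig] = None,
                 formats: tuple = ("tsv",)) -> dict:
    """Write tables plus a run manifest; returns name -> written path.

    TSV is always written; ``formats`` may add "json".  The manifest echoes
    every configuration field, the package version and the seed so a run can
    be reproduced byte for byte.
    """
    from .io import write_tsv

    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, table in tables.items():
        path = outdir / f"{name}.tsv"
        write_tsv(table, path)
        written[name] = path
        if "json" in formats:
            jpath = outdir / f"{name}.json"
            table.to_json(jpath, orient="records", indent=2)
            written[f"{name}.json"] = jpath
    manifest = outdir / "manifest.txt"
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write(f"attcfold_version={__version__}\n")
        for f in dataclasses.fields(config):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")
        for name in tables:
            fh.write(f"table={name}.tsv\n")
    written["manifest"] = manifest
    return written
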