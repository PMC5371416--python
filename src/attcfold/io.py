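"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; tables are tab-separated with a header row,
UTF-8, ``#`` comments.  GFF3 input is 1-based inclusive and converted to
internal 0-based half-open coordinates at this boundary.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .attc import AttCSite, BoxAnnotation

__all__ = [
    "read_sites_fasta",
    "write_sites_fasta",
    "read_fasta",
    "write_fasta",
    "read_box_table",
    "read_integron_table",
    "write_integron_table",
    "read_oric_table",
    "read_gff3_cds",
    "write_gff3_cds",
    "read_tsv",
    "write_tsv",
]

_BOX_NAMES = ("r_dprime", "l_dprime", "l_prime", "r_prime")


def read_fasta(path) -> dict[str, str]:
    """id -> sequence for every record in a FASTA file."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_sites_fasta(path, boxes: Optional[dict] = None,
                     origin_class: str = "unknown") -> list[AttCSite]:
    """attC sites from FASTA (top strands, 5'->3'; record id = site name).

    ``boxes`` optionally maps site ids to :class:`BoxAnnotation`; annotated
    boxes always override the location heuristic downstream.
    """
    boxes = boxes or {}
    sites = [AttCSite(id=rec.id, top_strand=str(rec.seq).upper(),
                      boxes=boxes.get(rec.id), origin_class=origin_class)
             for rec in SeqIO.parse(str(path), "fasta")]
    if not sites:
        raise ValueError(f"no sequences in {path}")
    return sites


def write_sites_fasta(sites: Iterable[AttCSite], path) -> None:
    write_fasta({s.id: s.top_strand for s in sites}, path)


def read_box_table(path) -> dict[str, BoxAnnotation]:
    """Explicit box annotations: TSV with columns site_id, box, start, end.

    ``box`` is one of r_dprime / l_dprime / l_prime / r_prime; coordinates
    are 0-based half-open on the top strand.
    """
    df = read_tsv(path)
    out: dict[str, BoxAnnotation] = {}
    for site_id, grp in df.groupby("site_id"):
        ivs = {row["box"]: (int(row["start"]), int(row["end"]))
               for _, row in grp.iterrows()}
        missing = set(_BOX_NAMES) - set(ivs)
        if missing:
            raise ValueError(f"site {site_id!r}: missing boxes {missing}")
        out[str(site_id)] = BoxAnnotation(**{k: ivs[k] for k in _BOX_NAMES})
    return out


def read_integron_table(path) -> pd.DataFrame:
    """Integron annotations in an IntegronFinder-like tabular layout.

    Required columns: replicon_id, element (attC / integrase / ...), start,
    end, strand; optional: integron_id, annotation, integrase_class,
    host_taxon.  Coordinates 1-based inclusive on input.
    """
    df = read_tsv(path)
    required = {"replicon_id", "element", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"integron table missing columns {sorted(missing)}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    return df


def write_integron_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1  # back to 1-based inclusive
    write_tsv(out, path)


def read_oric_table(path) -> dict[str, int]:
    """replicon_id -> oriC position (0-based) from a two-column TSV."""
    df = read_tsv(path)
    if not {"replicon_id", "position"} <= set(df.columns):
        raise ValueError("oriC table needs replicon_id and position columns")
    return {str(r["replicon_id"]): int(r["position"])
            for _, r in df.iterrows()}


_GFF_COLUMNS = ("seqid", "source", "type", "start", "end", "score",
                "strand", "phase", "attributes")


def _gff_attr(attributes: str, key: str) -> Optional[str]:
    for chunk in str(attributes).split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3_cds(path, arg_attribute: str = "arg") -> pd.DataFrame:
    """CDS features from GFF3 as a DataFrame (0-based half-open).

    Columns: replicon_id, cds_id, start, end, strand, length, is_arg.  A CDS
    is flagged as an antibiotic-resistance gene when its attribute column
    carries ``<arg_attribute>=true|1|yes``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=_GFF_COLUMNS, dtype=str)
    df = df[df["type"].str.upper() == "CDS"].copy()
    rows = []
    for _, r in df.iterrows():
        start = int(r["start"]) - 1
        end = int(r["end"])
        flag = (_gff_attr(r["attributes"], arg_attribute) or "").lower()
        rows.append({
            "replicon_id": r["seqid"],
            "cds_id": _gff_attr(r["attributes"], "ID") or f"cds{len(rows)}",
            "start": start, "end": end,
            "strand": r["strand"],
            "length": end - start,
            "is_arg": flag in {"true", "1", "yes"},
        })
    return pd.DataFrame(
        rows, columns=["replicon_id", "cds_id", "start", "end", "strand",
                       "length", "is_arg"])


def write_gff3_cds(df: pd.DataFrame, path, replicon_id: str) -> None:
    """Write a CDS table (0-based half-open) as minimal GFF3."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for _, r in df.iterrows():
            attrs = f"ID={r['cds_id']}"
            if "is_arg" in r and bool(r.get("is_arg")):
                attrs += ";arg=true"
            elif "in_integron" in r:
                attrs += f";in_integron={str(bool(r['in_integron'])).lower()}"
            fh.write("\t".join([
                str(r.get("replicon_id", replicon_id)), "attcfold", "CDS",
                str(int(r["start"]) + 1), str(int(r["end"])), ".",
                str(r.get("strand", "+")), "0", attrs]) + "\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
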