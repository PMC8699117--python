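"""Readers and writers for every on-disk format the pipeline touches.

TSV expression matrices, BED3/BED6 intervals, MEME-minimal motif text,
FASTA region sequences, cohort tables and YAML configs.  All writers emit
deterministic byte streams (fixed float formatting, ``\\n`` endings) so a
rerun with the same seed reproduces files exactly.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (ASE_TYPES, CohortSample, GenomicInterval,
                        IsoformAnnotation, IsoformQuant, MotifModel, to_rna)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

ANNOTATION_FIELDS = ("orf_length", "utr5_length", "utr3_length", "n_domains",
                     "has_intron_retention", "coding", "nmd_sensitive")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConfigError(ValueError):
    """Inconsistent configuration (e.g. unknown sample in a condition map)."""


# ---------------------------------------------------------------------------
# expression tables

def read_condition_map(path) -> dict[str, str]:
    """Read a two-column sample->condition TSV sidecar."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "condition"]:
        raise FormatError(f"{path}: expected columns 'sample' and 'condition'")
    return dict(zip(df["sample"], df["condition"]))


def read_expression_table(path, kind: str, condition_map: dict[str, str] | None = None
                          ) -> pd.DataFrame:
    """Read a feature x sample expression TSV.

    ``kind`` is "gene" (first column = gene id) or "isoform" (first column
    = isoform id, second = parent gene id).  Sample columns are everything
    else.  Duplicate feature ids are rejected; malformed numeric cells
    raise a :class:`FormatError` naming the offending row and column.
    Per-condition totals are attached as ``df.attrs['totals_by_condition']``
    when a condition map is given.
    """
    if kind not in ("gene", "isoform"):
        raise ValueError(f"kind must be 'gene' or 'isoform', not {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    meta_cols = [id_col] + (["gene_id"] if kind == "isoform" else [])
    if kind == "isoform" and "gene_id" not in df.columns:
        raise FormatError(f"{path}: isoform tables need a 'gene_id' column")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if df[id_col].duplicated().any():
        dupes = df[id_col][df[id_col].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate feature ids {dupes}")
    for col in sample_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()][id_col]
            raise FormatError(
                f"{path}: malformed numeric cell in column {col!r}, "
                f"row {bad.iloc[0]!r}") from None
    df = df.set_index(id_col)
    if df.empty:
        logger.warning("%s: table contains a header only", path)
    if condition_map is not None:
        unknown = set(sample_cols) - set(condition_map)
        if unknown:
            raise ConfigError(
                f"{path}: samples {sorted(unknown)} missing from condition map")
        totals = {}
        for cond in sorted(set(condition_map.values())):
            cols = [s for s in sample_cols if condition_map[s] == cond]
            totals[cond] = float(df[cols].to_numpy().sum()) if cols else 0.0
        df.attrs["totals_by_condition"] = totals
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, lineterminator="\n")


def read_annotation_table(path) -> dict[str, IsoformAnnotation]:
    """Read per-isoform structural annotations (sidecar TSV)."""
    df = pd.read_csv(path, sep="\t").set_index("isoform_id")
    out = {}
    for iso, row in df.iterrows():
        out[iso] = IsoformAnnotation(
            orf_length=int(row["orf_length"]),
            utr5_length=int(row["utr5_length"]),
            utr3_length=int(row["utr3_length"]),
            n_domains=int(row["n_domains"]),
            has_intron_retention=bool(row["has_intron_retention"]),
            coding=bool(row["coding"]),
            nmd_sensitive=bool(row["nmd_sensitive"]),
        )
    return out


def write_annotation_table(quants: list[IsoformQuant], path) -> None:
    rows = []
    for q in quants:
        rec = {"isoform_id": q.isoform_id}
        rec.update({f: getattr(q.annotation, f) for f in ANNOTATION_FIELDS})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def quants_from_frames(tpm: pd.DataFrame,
                       counts: pd.DataFrame | None = None,
                       annotations: dict[str, IsoformAnnotation] | None = None
                       ) -> list[IsoformQuant]:
    """Assemble IsoformQuant records from isoform-kind expression frames."""
    sample_cols = [c for c in tpm.columns if c != "gene_id"]
    out = []
    for iso, row in tpm.iterrows():
        cnt = {}
        if counts is not None and iso in counts.index:
            cnt = {s: int(counts.loc[iso, s]) for s in sample_cols}
        out.append(IsoformQuant(
            isoform_id=str(iso),
            gene_id=str(row["gene_id"]),
            tpm={s: float(row[s]) for s in sample_cols},
            counts=cnt,
            annotation=(annotations or {}).get(iso, IsoformAnnotation()),
        ))
    return out


# ---------------------------------------------------------------------------
# BED intervals

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into half-open intervals; BED3 strand defaults to '+'."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 else "+"
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: list[GenomicInterval], path,
              names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# MEME-minimal motif files

def read_pwm_file(path, pseudocount: float = 1e-4) -> list[MotifModel]:
    """Parse a MEME-minimal motif file over ACGU (T accepted, read as U).

    Each probability row must sum to 1 within 0.01 before the pseudocount;
    the pseudocount is then added and rows renormalized.  The background
    distribution is taken from the file's "Background letter frequencies"
    block when present, uniform 0.25 otherwise.
    """
    background = np.full(4, 0.25)
    motifs: list[MotifModel] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j].upper().replace("T", "U"): float(toks[j + 1])
                    for j in range(0, len(toks), 2)}
            background = np.array([freq[c] for c in "ACGU"])
            i += 1
            continue
        if line.startswith("MOTIF"):
            toks = line.split()
            motif_id = toks[1]
            rbp_name = toks[2] if len(toks) > 2 else motif_id
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: MOTIF {motif_id} has no matrix")
            i += 1
            rows = []
            while i < len(lines):
                toks = lines[i].split()
                if len(toks) != 4:
                    break
                try:
                    rows.append([float(t) for t in toks])
                except ValueError:
                    break
                i += 1
            mat = np.array(rows)
            if mat.size == 0:
                raise FormatError(f"{path}: MOTIF {motif_id} matrix empty")
            bad = np.abs(mat.sum(axis=1) - 1.0) > 0.01
            if bad.any():
                raise FormatError(
                    f"{path}: MOTIF {motif_id} row {int(np.where(bad)[0][0])} "
                    "does not sum to 1 within 0.01")
            mat = mat + pseudocount
            mat /= mat.sum(axis=1, keepdims=True)
            motifs.append(MotifModel(motif_id, rbp_name, mat, background.copy()))
            continue
        i += 1
    return motifs


def write_pwm_file(motifs: list[MotifModel], path,
                   background: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        if background is not None:
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{c} {background[i]:.6f}"
                              for i, c in enumerate("ACGU")) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id} {m.rbp_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(m)}\n")
            for row in m.pwm:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: RNA-alphabet sequence}."""
    return {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# splicing-event tables

def _serialize_regions(regions: dict[str, GenomicInterval]) -> str:
    return ";".join(f"{label}:{iv.start}-{iv.end}"
                    for label, iv in sorted(regions.items()))


def _parse_regions(text: str, chrom: str, strand: str) -> dict[str, GenomicInterval]:
    out = {}
    for part in text.split(";"):
        label, span = part.split(":")
        start, end = span.split("-")
        out[label] = GenomicInterval(chrom, int(start), int(end), strand)
    return out


def write_event_table(events, path) -> None:
    from .datamodel import SplicingEvent  # noqa: F401  (typing only)
    rows = []
    for ev in events:
        iv = next(iter(ev.regions.values()))
        row = {
            "event_id": ev.event_id, "gene_id": ev.gene_id,
            "ase_type": ev.ase_type, "chrom": iv.chrom, "strand": iv.strand,
            "regions": _serialize_regions(ev.regions),
            "inc_eff_len": ev.inc_eff_len, "skip_eff_len": ev.skip_eff_len,
            "dpsi": ev.dpsi, "pvalue": ev.pvalue, "adj_pvalue": ev.adj_pvalue,
        }
        for s in ev.samples:
            row[f"inc__{s}"] = ev.inc_counts[s]
            row[f"skip__{s}"] = ev.skip_counts[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FMT, lineterminator="\n")


def read_event_table(path) -> list:
    from .datamodel import SplicingEvent
    df = pd.read_csv(path, sep="\t")
    inc_cols = [c for c in df.columns if c.startswith("inc__")]
    samples = [c[len("inc__"):] for c in inc_cols]
    events = []
    for _, row in df.iterrows():
        if row["ase_type"] not in ASE_TYPES:
            raise FormatError(f"{path}: unknown ASE type {row['ase_type']!r}")
        events.append(SplicingEvent(
            event_id=row["event_id"], gene_id=row["gene_id"],
            ase_type=row["ase_type"],
            regions=_parse_regions(row["regions"], row["chrom"], row["strand"]),
            inc_counts={s: int(row[f"inc__{s}"]) for s in samples},
            skip_counts={s: int(row[f"skip__{s}"]) for s in samples},
            inc_eff_len=int(row["inc_eff_len"]),
            skip_eff_len=int(row["skip_eff_len"]),
            dpsi=float(row.get("dpsi", math.nan)),
            pvalue=float(row.get("pvalue", math.nan)),
            adj_pvalue=float(row.get("adj_pvalue", math.nan)),
        ))
    return events


# ---------------------------------------------------------------------------
# cohort tables

def write_cohort_table(samples: list[CohortSample], path) -> None:
    event_ids = sorted({e for s in samples for e in s.psi_by_event})
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "group": s.group,
               "marker_expr": s.marker_expr,
               "os_time": s.os_time, "os_event": int(s.os_event),
               "dfs_time": s.dfs_time, "dfs_event": int(s.dfs_event)}
        for e in event_ids:
            row[f"psi__{e}"] = s.psi_by_event.get(e, math.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FMT, lineterminator="\n")


def read_cohort_table(path) -> list[CohortSample]:
    df = pd.read_csv(path, sep="\t")
    psi_cols = [c for c in df.columns if c.startswith("psi__")]
    out = []
    for _, row in df.iterrows():
        psi = {}
        for c in psi_cols:
            v = float(row[c])
            if not math.isnan(v):
                if not 0.0 <= v <= 1.0:
                    raise FormatError(f"{path}: PSI {v} outside [0,1]")
                psi[c[len("psi__"):]] = v
        out.append(CohortSample(
            sample_id=str(row["sample_id"]), group=str(row["group"]),
            marker_expr=float(row["marker_expr"]), psi_by_event=psi,
            os_time=float(row["os_time"]), os_event=bool(row["os_event"]),
            dfs_time=float(row["dfs_time"]), dfs_event=bool(row["dfs_event"]),
        ))
    return out


# ---------------------------------------------------------------------------
# config

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
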