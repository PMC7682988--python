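"""Readers and writers for the tabular and genomic formats used here.

Canonical dialects: TSV (tab-delimited, ``#``-prefixed comments, UTF-8)
for tables, BED6 for gene annotations, bedGraph (0-based half-open spans)
for signal tracks. Readers validate and reject malformed records rather
than coercing them; every writer's output round-trips through its reader.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .fish import CellTally
from .genes import GeneModel
from .matrix import SampleMeta, SpectralCountMatrix
from .metagene import MetageneProfile
from .qpcr import CtMeasurement
from .tracks import ProbeSignalTrack, SmoothedTrack


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False)


# ---------------------------------------------------------------------------
# spectral counts + sample sheet
# ---------------------------------------------------------------------------

_SHEET_COLS = ["sample_id", "condition", "is_no_tag", "bait_protein",
               "replicate"]


def read_sample_sheet(path) -> list[SampleMeta]:
    df = _read_tsv(path)
    missing = [c for c in _SHEET_COLS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"sample sheet {path}: missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        flag = row["is_no_tag"].strip().lower()
        if flag not in ("true", "false", "0", "1"):
            raise ValidationError(
                f"sample sheet {path}: bad is_no_tag value {row['is_no_tag']!r}")
        is_no_tag = flag in ("true", "1")
        bait = row["bait_protein"].strip() or None
        try:
            rep = int(row["replicate"])
        except ValueError as e:
            raise ValidationError(
                f"sample sheet {path}: bad replicate {row['replicate']!r}"
            ) from e
        out.append(SampleMeta(sample_id=row["sample_id"],
                              condition=row["condition"],
                              is_no_tag=is_no_tag, bait_protein=bait,
                              replicate=rep))
    return out


def write_sample_sheet(samples: Sequence[SampleMeta], path) -> None:
    df = pd.DataFrame(
        [{"sample_id": s.sample_id, "condition": s.condition,
          "is_no_tag": str(s.is_no_tag).lower(),
          "bait_protein": s.bait_protein or "",
          "replicate": s.replicate} for s in samples])
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, sample_sheet_path) -> SpectralCountMatrix:
    """Counts TSV (first column protein ID, one column per sample) plus
    the sample sheet describing each column."""
    samples = read_sample_sheet(sample_sheet_path)
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"counts file {path}: no sample columns")
    df = df.set_index(df.columns[0])
    sheet_ids = [s.sample_id for s in samples]
    extra = [c for c in df.columns if c not in sheet_ids]
    if extra:
        raise ValidationError(
            f"counts file {path}: sample(s) {extra} absent from sample sheet")
    missing = [c for c in sheet_ids if c not in df.columns]
    if missing:
        raise ValidationError(
            f"counts file {path}: sample sheet sample(s) {missing} missing")
    try:
        values = df[sheet_ids].astype(float)
    except ValueError as e:
        raise ValidationError(f"counts file {path}: non-numeric count") from e
    if (values.to_numpy() < 0).any():
        raise ValidationError(f"counts file {path}: negative count")
    values.index.name = None
    return SpectralCountMatrix(values=values, samples=samples)


def write_counts_tsv(m: SpectralCountMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genes (BED6)
# ---------------------------------------------------------------------------

def read_genes_bed(path) -> list[GeneModel]:
    """BED6 gene annotation; strand is required ('.' is rejected because
    metagene anchoring needs it). Plus strand: TSS=start, pA=end;
    minus strand: TSS=end, pA=start. Coordinates stay 0-based half-open."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValidationError(
                    f"{path}:{ln}: BED6 requires 6 fields, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{ln}: non-integer coordinates") from exc
            genes.append(GeneModel.from_bed_fields(chrom, s, e, name, strand))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                     f"{g.strand}\n")


# ---------------------------------------------------------------------------
# probe tracks
# ---------------------------------------------------------------------------

def read_probe_tsv(path) -> ProbeSignalTrack:
    """Two-channel probe TSV: contig, position, ip, input (one contig)."""
    df = _read_tsv(path)
    for col in ("contig", "position", "ip", "input"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    contigs = df["contig"].unique()
    if len(contigs) != 1:
        raise ValidationError(f"{path}: expected one contig, got {list(contigs)}")
    try:
        pos = df["position"].astype(int).to_numpy()
        ip = df["ip"].astype(float).to_numpy()
        inp = df["input"].astype(float).to_numpy()
    except ValueError as e:
        raise ValidationError(f"{path}: non-numeric probe record") from e
    return ProbeSignalTrack(contig=str(contigs[0]), positions=pos,
                            ip=ip, inp=inp)


def write_probe_tsv(track: ProbeSignalTrack, path) -> None:
    if not track.is_two_channel:
        raise ValidationError("probe TSV holds two-channel tracks")
    pd.DataFrame({"contig": track.contig, "position": track.positions,
                  "ip": track.ip, "input": track.inp}
                 ).to_csv(path, sep="\t", index=False)


def read_bedgraph_track(path, span: int = 1) -> ProbeSignalTrack:
    """bedGraph of probe-level log2 ratios (span starts become probe
    positions)."""
    contig, starts, values = _read_bedgraph(path)
    return ProbeSignalTrack(contig=contig, positions=np.asarray(starts),
                            log2_ratio=np.asarray(values))


def write_bedgraph_track(track: ProbeSignalTrack, path, span: int = 1) -> None:
    if track.is_two_channel:
        raise ValidationError("bedGraph holds log2-ratio tracks")
    with open(path, "w") as fh:
        for p, v in zip(track.positions, track.log2_ratio):
            if np.isfinite(v):
                fh.write(f"{track.contig}\t{p}\t{p + span}\t{v:.6g}\n")


def _read_bedgraph(path):
    contig = None
    starts, values = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValidationError(
                    f"{path}:{ln}: bedGraph requires 4 fields")
            c, s, e, v = fields
            if contig is None:
                contig = c
            elif c != contig:
                raise ValidationError(f"{path}:{ln}: multiple contigs")
            try:
                starts.append(int(s))
                values.append(float(v))
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: malformed record") from exc
    if contig is None:
        raise ValidationError(f"{path}: empty bedGraph")
    return contig, starts, values


def write_smoothed_bedgraph(track: SmoothedTrack, path) -> None:
    with open(path, "w") as fh:
        for p, v in zip(track.grid_positions, track.values):
            if np.isfinite(v):
                fh.write(f"{track.contig}\t{p}\t{p + track.step}\t{v:.6g}\n")


def read_smoothed_bedgraph(path, step: int = 10) -> SmoothedTrack:
    contig, starts, values = _read_bedgraph(path)
    start0 = starts[0]
    n = (starts[-1] - start0) // step + 1
    vals = np.full(n, np.nan)
    for s, v in zip(starts, values):
        if (s - start0) % step:
            raise ValidationError(
                f"{path}: span start {s} off the {step}-bp grid")
        vals[(s - start0) // step] = v
    return SmoothedTrack(contig=contig, start=start0, step=step, values=vals)


# ---------------------------------------------------------------------------
# qPCR and FISH tables
# ---------------------------------------------------------------------------

def read_ct_tsv(path) -> list[CtMeasurement]:
    df = _read_tsv(path)
    for col in ("amplicon", "ct_input", "ct_ip"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(CtMeasurement(
                amplicon=row["amplicon"],
                ct_input=float(row["ct_input"]),
                ct_ip=float(row["ct_ip"]),
                input_fraction=float(row.get("input_fraction", 0.01) or 0.01),
                replicate=int(row.get("replicate", 1) or 1)))
        except ValueError as e:
            raise ValidationError(f"{path}: malformed Ct record") from e
    return out


def write_ct_tsv(measurements: Iterable[CtMeasurement], path) -> None:
    pd.DataFrame(
        [{"amplicon": c.amplicon, "ct_input": c.ct_input, "ct_ip": c.ct_ip,
          "input_fraction": c.input_fraction, "replicate": c.replicate}
         for c in measurements]).to_csv(path, sep="\t", index=False)


def read_tallies_tsv(path) -> list[CellTally]:
    df = _read_tsv(path)
    for col in ("strain", "n_scored", "n_retained"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(CellTally(strain=row["strain"],
                                 n_scored=int(row["n_scored"]),
                                 n_retained=int(row["n_retained"])))
        except ValueError as e:
            raise ValidationError(f"{path}: malformed tally record") from e
    return out


def write_tallies_tsv(tallies: Iterable[CellTally], path) -> None:
    pd.DataFrame([{"strain": t.strain, "n_scored": t.n_scored,
                   "n_retained": t.n_retained} for t in tallies]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Ties a pipeline output to its inputs, parameters, and seed."""

    command: str
    inputs: dict = field(default_factory=dict)      # path -> sha256
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    created: str = ""

    @classmethod
    def create(cls, command: str, input_paths: Sequence[str],
               parameters: Mapping, seed: int | None = None) -> "RunManifest":
        return cls(command=command,
                   inputs={str(p): _sha256(p) for p in input_paths},
                   parameters=dict(parameters), seed=seed,
                   created=datetime.now(timezone.utc).isoformat())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True,
                      default=str)
            fh.write("\n")
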