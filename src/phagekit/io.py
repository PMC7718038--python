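"""File formats: FASTA, titer TSV, distance TSV, GFF3, provenance JSON."""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .errors import InvalidInputError, ParseError
from .features import NucleotideSequence
from .kinetics import TiterSeries
from .phylo import DistanceMatrix, SequenceAlignment


def read_fasta(path, topology: str = "linear") -> list:
    """Read a (multi-record) FASTA into NucleotideSequence objects.

    Records are case-folded to upper; the id is the first whitespace token
    of the header.  An empty file yields an empty list with a warning.
    """
    from Bio import SeqIO

    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                records.append(NucleotideSequence(rec.id, str(rec.seq).upper(), topology))
            except InvalidInputError as exc:
                raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[NucleotideSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path, alphabet: str = "nt") -> SequenceAlignment:
    """Aligned FASTA -> SequenceAlignment (rows keep their gaps)."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise ParseError(f"{path}: no alignment records found")
    try:
        return SequenceAlignment(tuple(ids), tuple(rows), alphabet)
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


TITER_COLUMNS = ("time_min", "titer_pfu_ml")


def read_titer_tsv(path) -> TiterSeries:
    """Titer TSV dialect: tab-separated, columns ``time_min`` and
    ``titer_pfu_ml`` (optional ``od600``), ``#`` comment lines.  Rows are
    sorted by time; duplicate times are an error."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in TITER_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for col in [*TITER_COLUMNS, *(["od600"] if "od600" in df.columns else [])]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}")
        if coerced.isna().any():
            raise ParseError(f"{path}: empty cell in column {col!r}")
        df[col] = coerced
    df = df.sort_values("time_min")
    dup = df["time_min"].duplicated()
    if dup.any():
        t = df.loc[dup, "time_min"].iloc[0]
        raise ParseError(f"{path}: duplicate time point {t}")
    od = df["od600"].to_numpy() if "od600" in df.columns else None
    try:
        return TiterSeries(
            times=df["time_min"].to_numpy(),
            titers=df["titer_pfu_ml"].to_numpy(),
            od600=od,
        )
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_titer_tsv(series: TiterSeries, path) -> None:
    data = {"time_min": series.times, "titer_pfu_ml": series.titers}
    if series.od600 is not None:
        data["od600"] = series.od600
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_distance_tsv(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise ParseError(f"{path}: row and column labels differ")
    try:
        return DistanceMatrix(labels, df.to_numpy(dtype=float))
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_distance_tsv(d: DistanceMatrix, path) -> None:
    pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(path, sep="\t")


def features_to_gff(seq_id: str, promoters=(), rbs_sites=(), orfs=(), terminators=(), cut_sites=()) -> pd.DataFrame:
    """Collect scanner hits into a GFF3-shaped DataFrame (1-based inclusive)."""
    rows = []

    def add(ftype, start, end, strand, score=".", attrs=""):
        rows.append(
            (seq_id, "phagekit", ftype, int(min(start, end)), int(max(start, end)),
             score, strand, ".", attrs)
        )

    for h in promoters:
        add("promoter", h.start, h.end, h.strand,
            attrs=f"spacer={h.spacer_len};mismatches={h.mismatches}")
    for r in rbs_sites:
        add("RBS", r.start, r.end, r.strand,
            attrs=f"match={r.motif_match};gap={r.gap_to_start_codon}")
    for o in orfs:
        add("CDS", o.start, o.end, o.strand,
            attrs=f"start_codon={o.start_codon};gene_call={str(o.gene_call).lower()}")
    for t in terminators:
        add("terminator", t.position, t.position + 2 * t.stem_len + t.loop_len - 1,
            t.strand, score=f"{t.score:g}", attrs=f"stem={t.stem_len};loop={t.loop_len};u={t.u_count}")
    for enzyme_name, start, end in cut_sites:
        add("restriction_site", start, end, "+", attrs=f"enzyme={enzyme_name}")
    return pd.DataFrame(
        rows,
        columns=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )


def write_gff3(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    return df


def write_provenance(path, config: dict, seed=None) -> None:
    """Provenance record: configuration + package version + seed.
    Deliberately timestamp-free so identical runs are byte-identical."""
    record = {"phagekit_version": __version__, "seed": seed, "config": config}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
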