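"""Readers and writers for the on-disk formats used across the package.

All files carry 1-based inclusive coordinates (GFF3 convention); internal
arithmetic elsewhere in the package is 0-based half-open and converted only
at this boundary. Tables are tab-delimited with a single header row.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("paleoevo")

# IUPAC nucleotide one-letter codes (uppercase after normalisation).
IUPAC_NT = set("ACGTURYSWKMBDHVN")

GFF_COLUMNS = [
    "seq_id", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Parsing is case-insensitive; sequences are uppercased. Duplicate ids and
    non-IUPAC characters raise :class:`InputError`.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            # report the first offending line for debuggability
            lineno = _find_bad_line(path, bad)
            raise InputError(
                f"non-IUPAC characters {sorted(bad)} in record {rec.id!r} "
                f"of {path} (line {lineno})"
            )
        records[rec.id] = seq
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def _find_bad_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return 0


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for field in text.strip().split(";"):
        if not field:
            continue
        key, _, value = field.partition("=")
        attrs[unquote(key)] = unquote(value)
    return attrs


def _format_attributes(attrs: Mapping[str, str]) -> str:
    if not attrs:
        return "."
    safe = ":^*!+_()/|.,' -"  # characters GFF3 permits unescaped in values
    return ";".join(f"{quote(str(k), safe=safe)}={quote(str(v), safe=safe)}"
                    for k, v in attrs.items())


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a DataFrame.

    Coordinates stay 1-based inclusive. The ``attributes`` column holds a
    ``dict`` per row. Comment and directive lines are dropped.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith("##gff-version"):
            raise InputError(f"{path} lacks a ##gff-version header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            start, end = int(parts[3]), int(parts[4])
            if end < start:
                raise InputError(f"{path}:{lineno}: end < start")
            rows.append({
                "seq_id": parts[0], "source": parts[1], "type": parts[2],
                "start": start, "end": end,
                "score": parts[5], "strand": parts[6], "phase": parts[7],
                "attributes": _parse_attributes(parts[8]),
            })
    return pd.DataFrame(rows, columns=GFF_COLUMNS)


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write features sorted by (seq_id, start)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if len(features) == 0:
            return
        df = features.sort_values(["seq_id", "start"], kind="stable")
        for row in df.itertuples(index=False):
            attrs = row.attributes if isinstance(row.attributes, Mapping) else {}
            fh.write("\t".join([
                str(row.seq_id), str(row.source), str(row.type),
                str(int(row.start)), str(int(row.end)),
                str(row.score), str(row.strand), str(row.phase),
                _format_attributes(attrs),
            ]) + "\n")


# ---------------------------------------------------------------------------
# TSV / JSON helpers

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# Synteny blocks file

def write_blocks(blocks: Iterable, path: str | Path) -> None:
    """Write synteny blocks: one ``#block`` header line then gene-pair lines."""
    with open(path, "w") as fh:
        for i, blk in enumerate(blocks):
            fh.write(f"#block {i} {blk.chrom_a} {blk.chrom_b} "
                     f"{blk.orientation} {len(blk.pairs)} {blk.score:g}\n")
            for ga, gb in blk.pairs:
                fh.write(f"{ga}\t{gb}\n")


def read_blocks(path: str | Path):
    """Read a blocks file written by :func:`write_blocks`."""
    from .synteny import SyntenyBlock

    blocks = []
    with open(path) as fh:
        cur = None
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("#block"):
                _, _, ca, cb, orient, _, score = line.split()
                cur = SyntenyBlock(chrom_a=ca, chrom_b=cb, orientation=orient,
                                   pairs=[], score=float(score))
                blocks.append(cur)
            else:
                if cur is None:
                    raise InputError(f"{path}: pair line before #block header")
                ga, gb = line.split("\t")
                cur.pairs.append((ga, gb))
    return blocks
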