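"""Readers and writers for the on-disk formats the pipeline touches.

BED3/BED6 and ENCODE narrowPeak (10 columns), two-column chrom.sizes, SNP
lists (BED3 + name), gene tables (BED6 spans; the TSS is the 5' end per
strand), and the sample sheet (CSV).  All coordinates on disk are 0-based
half-open, as in the BED standard; narrowPeak's qValue column is -log10
transformed on disk and converted to a plain q-value in memory.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Sequence, Union

from .types import (
    Genome,
    GenomicInterval,
    Peak,
    SampleMeta,
    SnpRecord,
    TssRecord,
    validate_sample_sheet,
)

Region = Union[GenomicInterval, Peak]


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_regions(
    path, dialect: str = "bed", genome: Genome | None = None
) -> list[Region]:
    """Read a BED or narrowPeak file.

    * ``bed``: columns chrom/start/end (+ optional name/score/strand) ->
      :class:`GenomicInterval` (name and strand are dropped).
    * ``narrowPeak``: 10 columns; column 10 (0-based offset of the summit
      from start) becomes ``summit_offset``.  The ENCODE convention of -1
      for "no summit called" maps to the interval midpoint.

    ``genome``, when given, validates chromosome names and bounds; a
    malformed line raises naming the line number.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, f"expected >= 3 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise _parse_error(path, lineno, f"non-integer coordinate: {exc}")
            if genome is not None and chrom not in genome:
                raise _parse_error(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc))
            if genome is not None:
                genome.check(iv)
            if dialect == "bed":
                out.append(iv)
                continue
            if len(fields) < 10:
                raise _parse_error(
                    path, lineno, f"narrowPeak needs 10 columns, got {len(fields)}"
                )
            name = fields[3]
            score = float(fields[4])
            neglog_q = float(fields[8])
            qvalue = 1.0 if neglog_q < 0 else 10.0 ** (-neglog_q)
            summit_offset = int(fields[9])
            if summit_offset == -1:
                summit_offset = (end - start) // 2
            out.append(
                Peak(
                    interval=iv,
                    summit_offset=summit_offset,
                    score=score,
                    qvalue=min(1.0, qvalue),
                    name=name,
                )
            )
    return out


def write_regions(path, regions: Sequence[Region], dialect: str = "bed") -> None:
    """Write BED3 (intervals) / BED6-with-name or 10-column narrowPeak (peaks)."""
    with open(path, "w") as fh:
        for r in regions:
            if dialect == "bed":
                if isinstance(r, Peak):
                    fh.write(
                        f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t.\n"
                    )
                else:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            elif dialect == "narrowPeak":
                if not isinstance(r, Peak):
                    raise TypeError("narrowPeak output requires Peak records")
                neglog_q = 1000.0 if r.qvalue <= 0 else -math.log10(r.qvalue)
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t."
                    f"\t0\t-1\t{neglog_q:g}\t{r.summit_offset}\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise _parse_error(path, lineno, "expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_gene_table(path) -> tuple[list[TssRecord], list[GenomicInterval]]:
    """Read a BED6 gene-span table; derive the TSS as the strand-aware 5' end.

    Returns (tss records, gene span intervals), index-aligned.  For a '+'
    gene the TSS is ``start``; for a '-' gene it is ``end - 1`` (the last
    base of the half-open span).
    """
    tss: list[TssRecord] = []
    spans: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise _parse_error(path, lineno, "gene table needs 6 BED columns")
            chrom, start, end, gene_id, _score, strand = f[:6]
            if gene_id in seen:
                raise _parse_error(path, lineno, f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            start, end = int(start), int(end)
            pos = start if strand == "+" else end - 1
            tss.append(TssRecord(gene_id=gene_id, chrom=chrom, tss=pos, strand=strand))
            spans.append(GenomicInterval(chrom, start, end))
    return tss, spans


def write_gene_table(path, tss: Sequence[TssRecord], spans: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for t, s in zip(tss, spans):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{t.gene_id}\t0\t{t.strand}\n")


def read_snps(path) -> list[SnpRecord]:
    """SNPs as BED3 + name: chrom, pos, pos+1, snp_id."""
    out: list[SnpRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise _parse_error(path, lineno, "SNP list needs chrom/start/end/name")
            out.append(SnpRecord(snp_id=f[3], chrom=f[0], pos=int(f[1])))
    return out


def write_snps(path, snps: Sequence[SnpRecord]) -> None:
    with open(path, "w") as fh:
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.snp_id}\n")


SAMPLE_SHEET_COLUMNS = ["sample_id", "cell_type", "condition", "mark", "replicate", "role", "path"]


def read_sample_sheet(path) -> tuple[list[SampleMeta], dict[str, str]]:
    """Read the sample sheet CSV; returns (metas, sample_id -> reads path)."""
    metas: list[SampleMeta] = []
    paths: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(SAMPLE_SHEET_COLUMNS[:-1]) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
        for row in reader:
            meta = SampleMeta(
                sample_id=row["sample_id"],
                cell_type=row["cell_type"],
                condition=row["condition"],
                mark=row["mark"],
                replicate=int(row["replicate"]),
                role=row["role"],
            )
            metas.append(meta)
            paths[meta.sample_id] = row.get("path", "")
    validate_sample_sheet(metas)
    return metas, paths


def write_sample_sheet(path, metas: Sequence[SampleMeta], paths: dict[str, str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for m in metas:
            writer.writerow(
                [m.sample_id, m.cell_type, m.condition, m.mark, m.replicate, m.role,
                 paths.get(m.sample_id, "")]
            )


def read_reads_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read a reads BED3 into per-chromosome (start, end) lists — the
    high-volume path, kept free of per-record object construction."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.split("\t")
            if len(f) < 3:
                continue
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


def write_reads_bed(path, reads: dict[str, Sequence[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for chrom in reads:
            for s, e in reads[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")
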