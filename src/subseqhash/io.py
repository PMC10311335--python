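"""FASTA and TSV readers/writers.

All coordinates in files are 0-based; intervals are half-open.  Every
experiment output can carry ``#key=value`` header lines recording the
resolved configuration and seeds; readers skip them.

FASTA parsing goes through Biopython; sequences are uppercased on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dp import SeedHit
from .order import OrderScore
from .seeding import SeedMatch
from .simulate import GroundTruthAlignment

logger = logging.getLogger("subseqhash")

SEEDS_COLUMNS = (
    "seq_id",
    "method",
    "repeat",
    "window_start",
    "positions",
    "subseq",
    "psi",
    "omega",
)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, uppercased sequence) for every record."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    if not records and Path(path).stat().st_size > 0:
        raise ValueError(f"malformed FASTA {path}: no records parsed")
    return [(r.id, str(r.seq).upper()) for r in records]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def _write_header(fh, header: Mapping | None) -> None:
    if header:
        for key, value in header.items():
            fh.write(f"#{key}={value}\n")


def _data_lines(path):
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def write_seeds_tsv(path, hits: Iterable[SeedHit], method: str, header=None) -> None:
    """Seeds TSV: positions are comma-separated, absolute, 0-based."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("\t".join(SEEDS_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.sequence_id,
                        method,
                        str(h.repeat_index),
                        str(h.window_start),
                        ",".join(map(str, h.abs_positions)),
                        h.subseq,
                        str(h.score.psi),
                        str(h.score.omega),
                    )
                )
                + "\n"
            )


def read_seeds_tsv(path) -> list[SeedHit]:
    hits = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields == list(SEEDS_COLUMNS):
            continue
        if len(fields) != len(SEEDS_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(SEEDS_COLUMNS)} fields")
        seq_id, _method, rep, wstart, pos_s, subseq, psi, omega = fields
        wstart = int(wstart)
        abs_pos = tuple(int(p) for p in pos_s.split(","))
        hits.append(
            SeedHit(
                sequence_id=seq_id,
                window_start=wstart,
                repeat_index=int(rep),
                positions=tuple(p - wstart for p in abs_pos),
                subseq=subseq,
                score=OrderScore(int(psi), int(omega), subseq),
            )
        )
    return hits


def write_matches_tsv(path, matches: Iterable[SeedMatch], header=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("x_id\ty_id\trepeat\tx_positions\ty_positions\tsubseq\tlabel\n")
        for m in matches:
            fh.write(
                "\t".join(
                    (
                        m.hit_x.sequence_id,
                        m.hit_y.sequence_id,
                        str(m.hit_x.repeat_index),
                        ",".join(map(str, m.hit_x.abs_positions)),
                        ",".join(map(str, m.hit_y.abs_positions)),
                        m.hit_x.subseq,
                        m.label,
                    )
                )
                + "\n"
            )


def write_alignment_tsv(path, gt: GroundTruthAlignment, header=None) -> None:
    """Ground-truth alignment as tab-separated (i, j) pairs."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        for i, j in gt.pairs:
            fh.write(f"{i}\t{j}\n")


def read_alignment_tsv(path) -> GroundTruthAlignment:
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        pairs.append((int(fields[0]), int(fields[1])))
    return GroundTruthAlignment(pairs=tuple(pairs))


def write_intervals_tsv(path, ids, intervals, header=None) -> None:
    """Read source intervals, BED-like: read_id, start, end (half-open)."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        for name, (start, end) in zip(ids, intervals):
            fh.write(f"{name}\t{start}\t{end}\n")


def read_intervals_tsv(path) -> list[tuple[str, int, int]]:
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected three columns")
        out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
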