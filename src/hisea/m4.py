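"""M4-dialect overlap records: writer and round-trip reader.

One space-separated line per overlap, twelve columns in the BLASR-style
layout:

    qname tname score identity% qstrand qstart qend qlen tstrand tstart tend tlen

Coordinates are 0-based half-open on the forward strand of each read;
``qstrand`` is always 0 (queries are scanned forward only) and
``tstrand`` 1 means the target was reverse-complemented for the
alignment.  ``score`` is the seed-covered base count, ``identity%`` the
seed-density identity estimate as a percentage.  The dialect is versioned
in a leading '#' comment, which readers skip.
"""

from __future__ import annotations

from dataclasses import dataclass

from .extension import OverlapRecord

HEADER = "# hisea m4 v1: qname tname score identity qstrand qstart qend qlen tstrand tstart tend tlen"


@dataclass(frozen=True)
class M4Row:
    qname: str
    tname: str
    score: int
    identity: float  # percent
    qstrand: int
    qstart: int
    qend: int
    qlen: int
    tstrand: int
    tstart: int
    tend: int
    tlen: int


def format_record(rec: OverlapRecord, qname: str, tname: str) -> str:
    return (
        f"{qname} {tname} {rec.score} {100.0 * rec.identity:.2f} "
        f"0 {rec.q_start} {rec.q_end} {rec.q_len} "
        f"{rec.strand} {rec.r_start} {rec.r_end} {rec.r_len}"
    )


def write_m4(records, path, query_names, ref_names) -> None:
    """Write records (already sorted by the caller) as M4-dialect lines."""
    with open(path, "w") as fh:
        fh.write(HEADER + "\n")
        for rec in records:
            fh.write(
                format_record(
                    rec, query_names[rec.query_id], ref_names[rec.ref_id]
                )
                + "\n"
            )


def read_m4(path) -> list[M4Row]:
    """Parse an M4-dialect file back into rows; '#' lines are skipped."""
    rows: list[M4Row] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{line_no}: expected 12 fields, got {len(parts)}"
                )
            rows.append(
                M4Row(
                    qname=parts[0],
                    tname=parts[1],
                    score=int(parts[2]),
                    identity=float(parts[3]),
                    qstrand=int(parts[4]),
                    qstart=int(parts[5]),
                    qend=int(parts[6]),
                    qlen=int(parts[7]),
                    tstrand=int(parts[8]),
                    tstart=int(parts[9]),
                    tend=int(parts[10]),
                    tlen=int(parts[11]),
                )
            )
    return rows
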