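"""Two-bit packed read storage and FASTA/FASTQ input.

Reads are held in memory as 2-bit codes (A=0, C=1, G=2, T=3), four bases
per byte, with the reverse-complement strand materialized alongside the
forward strand.  With this coding the complement of a base is ``3 - code``,
so reverse complementation is a reversal plus a subtraction.

Non-ACGT characters have no representation in a 2-bit alphabet: lowercase
is uppercased, and any remaining character (N, IUPAC ambiguity codes, ...)
is replaced deterministically by 'A'; the number of replacements is kept on
the read and reported through the module logger.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code; anything outside ACGT maps to A (code 0)
_CODE_TABLE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i

_VALID = np.zeros(256, dtype=bool)
for _b in "ACGTacgt":
    _VALID[ord(_b)] = True

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# byte value -> its four 2-bit codes, lowest bits first
_UNPACK_TABLE = np.empty((256, 4), dtype=np.uint8)
for _v in range(256):
    _UNPACK_TABLE[_v] = [(_v >> (2 * _j)) & 3 for _j in range(4)]


def encode(seq: str) -> np.ndarray:
    """Pack an ACGT string into a 2-bit-per-base byte array.

    Non-ACGT characters are replaced by 'A' (see module docstring); use
    :func:`encode_with_warning` to also obtain the replacement count.
    """
    packed, _ = encode_with_warning(seq)
    return packed


def encode_with_warning(seq: str) -> tuple[np.ndarray, int]:
    """Pack ``seq``; return ``(packed bytes, number of non-ACGT replacements)``."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_bad = int((~_VALID[raw]).sum())
    codes = _CODE_TABLE[raw]
    return pack_codes(codes), n_bad


def pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack an array of 2-bit codes (values 0-3) into bytes, 4 per byte."""
    n = len(codes)
    padded = np.zeros((n + 3) // 4 * 4, dtype=np.uint8)
    padded[:n] = codes
    quads = padded.reshape(-1, 4)
    return (
        quads[:, 0]
        | (quads[:, 1] << 2)
        | (quads[:, 2] << 4)
        | (quads[:, 3] << 6)
    ).astype(np.uint8)


def unpack_codes(packed: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`pack_codes`: first ``length`` 2-bit codes."""
    if length > 4 * len(packed):
        raise IndexError(
            f"requested {length} bases but packed array holds at most {4 * len(packed)}"
        )
    return _UNPACK_TABLE[packed].reshape(-1)[:length].copy()


def decode(packed: np.ndarray, length: int) -> str:
    """Decode a packed 2-bit array back into an ACGT string."""
    return _BASES[unpack_codes(packed, length)].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PackedRead:
    """A read stored 2 bits per base, with both strands accessible.

    ``read_id`` is the 0-based ordinal of the record in its input file;
    ``name`` is the record identifier up to the first whitespace.
    """

    read_id: int
    name: str
    length: int
    forward_code: np.ndarray
    reverse_code: np.ndarray
    n_replaced: int = 0
    _fwd_codes: np.ndarray | None = field(default=None, repr=False, compare=False)
    _rev_codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_sequence(cls, read_id: int, name: str, seq: str) -> "PackedRead":
        if len(seq) == 0:
            raise ValueError(f"read {name!r} is empty")
        fwd, n_bad = encode_with_warning(seq)
        if n_bad:
            logger.warning(
                "read %s: %d non-ACGT base(s) replaced by 'A'", name, n_bad
            )
        fwd_codes = unpack_codes(fwd, len(seq))
        rev_codes = (3 - fwd_codes)[::-1].copy()
        return cls(
            read_id=read_id,
            name=name,
            length=len(seq),
            forward_code=fwd,
            reverse_code=pack_codes(rev_codes),
            n_replaced=n_bad,
        )

    def codes(self, strand: int) -> np.ndarray:
        """Unpacked 2-bit codes for the requested strand (0=forward, 1=reverse)."""
        if strand == 0:
            if self._fwd_codes is None:
                self._fwd_codes = unpack_codes(self.forward_code, self.length)
            return self._fwd_codes
        if self._rev_codes is None:
            self._rev_codes = unpack_codes(self.reverse_code, self.length)
        return self._rev_codes

    def sequence(self, strand: int = 0) -> str:
        code = self.forward_code if strand == 0 else self.reverse_code
        return decode(code, self.length)


def _open_text(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


def load_reads(path, fmt: str | None = None) -> list[PackedRead]:
    """Load FASTA or FASTQ (optionally gzipped) into a list of PackedRead.

    ``fmt`` is "fasta" or "fastq"; when omitted it is inferred from the
    file extension.  Qualities in FASTQ input are discarded — the overlap
    method never uses them.  An empty file yields an empty list.
    """
    p = str(path)
    if fmt is None:
        stem = p[:-3] if p.endswith(".gz") else p
        lower = stem.lower()
        if lower.endswith((".fq", ".fastq")):
            fmt = "fastq"
        elif lower.endswith((".fa", ".fasta", ".fna")):
            fmt = "fasta"
        else:
            raise ValueError(f"cannot infer sequence format from {path!r}")
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    reads: list[PackedRead] = []
    with _open_text(p) as handle:
        try:
            for i, rec in enumerate(SeqIO.parse(handle, fmt)):
                seq = str(rec.seq)
                if len(seq) == 0:
                    raise ValueError(
                        f"record {rec.id!r} in {path!r} has empty sequence"
                    )
                reads.append(PackedRead.from_sequence(i, rec.id, seq))
        except ValueError as exc:
            raise ValueError(
                f"malformed {fmt} record {len(reads)} in {path!r}: {exc}"
            ) from exc
    return reads


def reads_from_strings(seqs, names=None) -> list[PackedRead]:
    """Build PackedReads directly from in-memory strings (test/simulation aid)."""
    out = []
    for i, s in enumerate(seqs):
        name = names[i] if names is not None else f"read{i}"
        out.append(PackedRead.from_sequence(i, name, s))
    return out
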