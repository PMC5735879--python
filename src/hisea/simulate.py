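"""Synthetic long-read generator with exact ground truth.

Emulates SMRT-style sequencing: a uniform random genome, reads sampled
uniformly over placements and strands until a target coverage is met,
lognormal read lengths, and an indel-dominant i.i.d. per-base error
process (default 12% total error, split 50% insertion / 35% deletion /
15% substitution).  Every read's error-free template is the exact genomic
substring of its recorded placement, so true pairwise overlaps and their
expected in-read bounds follow from interval intersection of placements.

What this does not model: homopolymer-dependent error rates, chimeric
reads, quality values, and the coordinate drift that indels introduce
between placement coordinates and read coordinates (bounded by
error_rate * overlap length and absorbed by the evaluation tolerance).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import PackedRead, _BASES

TRUTH_COLUMNS = ["read_name", "contig", "start", "end", "strand"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    genome_length   genome size in bp.
    coverage        target fold coverage; reads are drawn until the sum of
                    template lengths reaches coverage * genome_length.
    read_len_*      lognormal read-length law: mean 8000 bp, redrawn until
                    inside [1000, 40000] (typical SMRT chemistry scale).
    error_rate      total per-base error probability (default 0.12).
    error_mix       (insertion, deletion, substitution) fractions, must sum
                    to 1; default (0.5, 0.35, 0.15).
    seed            RNG seed; the whole output is a pure function of it.
    """

    genome_length: int
    coverage: float
    read_len_mean: float = 8000.0
    read_len_min: int = 1000
    read_len_max: int = 40000
    read_len_sigma: float = 0.5
    error_rate: float = 0.12
    error_mix: tuple[float, float, float] = (0.5, 0.35, 0.15)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix fractions must sum to 1")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_len_min > self.genome_length:
            raise ValueError("minimum read length exceeds genome length")


@dataclass
class SimOutput:
    """Genome, reads, and the ground-truth placement table."""

    genome: np.ndarray  # 2-bit codes
    reads: list[PackedRead]
    truth: pd.DataFrame  # TRUTH_COLUMNS, 0-based half-open forward coords
    contig_name: str = "contig0"

    @property
    def genome_sequence(self) -> str:
        return _BASES[self.genome].tobytes().decode("ascii")


def simulate_genome(length: int, seed_or_rng) -> np.ndarray:
    """I.i.d. uniform ACGT genome as a 2-bit code array."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)


def mutate(template: np.ndarray, error_rate: float, error_mix, rng) -> np.ndarray:
    """Apply the i.i.d. error process to a template code array.

    Each position independently carries an error with probability
    ``error_rate``; the error type is drawn from ``error_mix``.  An
    insertion places one uniform random base before the position; a
    deletion drops the base; a substitution replaces it by one of the
    three other bases uniformly.
    """
    n = len(template)
    if n == 0 or error_rate == 0:
        return template.copy()
    f_ins, f_del, _f_sub = error_mix
    err = rng.random(n) < error_rate
    u = rng.random(n)
    ins = err & (u < f_ins)
    dele = err & ~ins & (u < f_ins + f_del)
    sub = err & ~ins & ~dele
    sub_shift = rng.integers(1, 4, size=n, dtype=np.int64)
    ins_base = rng.integers(0, 4, size=n, dtype=np.int64)

    out_bases = template.astype(np.int64)
    out_bases[sub] = (out_bases[sub] + sub_shift[sub]) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins] = 2
    idx = np.repeat(np.arange(n), counts)
    out = out_bases[idx]
    starts = np.cumsum(counts) - counts
    out[starts[ins]] = ins_base[ins]
    return out.astype(np.uint8)


def _draw_length(cfg: SimConfig, rng) -> int:
    mu = np.log(cfg.read_len_mean) - 0.5 * cfg.read_len_sigma**2
    hi = min(cfg.read_len_max, cfg.genome_length)
    for _ in range(1000):
        ell = int(round(rng.lognormal(mu, cfg.read_len_sigma)))
        if cfg.read_len_min <= ell <= hi:
            return ell
    return min(int(cfg.read_len_mean), hi)  # degenerate law; fall back to mean


def simulate_reads(genome: np.ndarray, config: SimConfig) -> SimOutput:
    """Sample reads with errors until target coverage; record placements."""
    rng = np.random.default_rng(config.seed)
    g = len(genome)
    target = config.coverage * g

    names, starts, ends, strands, reads = [], [], [], [], []
    total = 0
    i = 0
    while total < target:
        ell = _draw_length(config, rng)
        s = int(rng.integers(0, g - ell + 1))
        strand = int(rng.integers(0, 2))
        template = genome[s : s + ell]
        if strand == 1:
            template = (3 - template)[::-1]
        codes = mutate(template, config.error_rate, config.error_mix, rng)
        name = f"read{i:05d}"
        seq = _BASES[codes].tobytes().decode("ascii")
        reads.append(PackedRead.from_sequence(i, name, seq))
        names.append(name)
        starts.append(s)
        ends.append(s + ell)
        strands.append(strand)
        total += ell
        i += 1

    truth = pd.DataFrame(
        {
            "read_name": names,
            "contig": "contig0",
            "start": starts,
            "end": ends,
            "strand": strands,
        }
    )
    return SimOutput(genome=genome, reads=reads, truth=truth)


def simulate(config: SimConfig) -> SimOutput:
    """Genome + reads in one call; genome uses the same seed stream."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config.genome_length, rng)
    cfg_reads = SimConfig(**{**config.__dict__, "seed": config.seed + 1})
    return simulate_reads(genome, cfg_reads)


def true_overlaps(truth: pd.DataFrame, min_len: int = 1) -> pd.DataFrame:
    """All unordered read pairs whose placements intersect by >= min_len.

    Expected overlap bounds are projected into each read's own forward
    coordinates under the error-free approximation (indel drift ignored).
    ``strand`` is 0 when the two reads were sequenced from the same genomic
    strand, 1 otherwise.  Pairs are emitted with id_a < id_b, matching the
    aligner's self-overlap convention.
    """
    t = truth.reset_index(drop=True)
    n = len(t)
    starts = t["start"].to_numpy()
    ends = t["end"].to_numpy()
    strands = t["strand"].to_numpy()
    contigs = t["contig"].to_numpy()
    names = t["read_name"].to_numpy()
    order = np.argsort(starts, kind="stable")

    rows = []
    for ii in range(n):
        a = order[ii]
        for jj in range(ii + 1, n):
            b = order[jj]
            if starts[b] >= ends[a]:
                break
            if contigs[a] != contigs[b]:
                continue
            gs = max(starts[a], starts[b])
            ge = min(ends[a], ends[b])
            if ge - gs < min_len:
                continue
            ia, ib = (a, b) if a < b else (b, a)
            a_lo, a_hi = _proj_interval(gs, ge, starts[ia], ends[ia], strands[ia])
            b_lo, b_hi = _proj_interval(gs, ge, starts[ib], ends[ib], strands[ib])
            rows.append(
                (int(ia), int(ib), names[ia], names[ib], int(ge - gs),
                 a_lo, a_hi, b_lo, b_hi, int(strands[ia] != strands[ib]))
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "name_a", "name_b", "overlap_len",
            "a_start", "a_end", "b_start", "b_end", "strand",
        ],
    )
    return df.sort_values(["id_a", "id_b"], ignore_index=True)


def _proj_interval(
    gs: int, ge: int, s: int, e: int, strand: int
) -> tuple[int, int]:
    """Project genome interval [gs, ge) into read-forward coordinates."""
    if strand == 0:
        return gs - s, ge - s
    return e - ge, e - gs


def write_output(sim: SimOutput, outdir) -> dict:
    """Write genome FASTA, reads FASTQ (dummy qualities), truth TSV."""
    os.makedirs(outdir, exist_ok=True)
    genome_path = os.path.join(outdir, "genome.fasta")
    reads_path = os.path.join(outdir, "reads.fastq")
    truth_path = os.path.join(outdir, "truth.tsv")
    with open(genome_path, "w") as fh:
        fh.write(f">{sim.contig_name}\n")
        seq = sim.genome_sequence
        for off in range(0, len(seq), 80):
            fh.write(seq[off : off + 80] + "\n")
    with open(reads_path, "w") as fh:
        for read in sim.reads:
            s = read.sequence()
            fh.write(f"@{read.name}\n{s}\n+\n{'I' * len(s)}\n")
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    return {"genome": genome_path, "reads": reads_path, "truth": truth_path}


def load_truth(path) -> pd.DataFrame:
    """Read a truth table TSV (read_name, contig, start, end, strand)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table {path} missing columns {sorted(missing)}")
    return df
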