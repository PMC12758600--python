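"""Deterministic synthetic data: genomes, reads with substitution errors,
and toy variant files.

Every generator is a pure function of its arguments and seed, so all test
inputs are reproducible without downloads.  Foreign (non-host) reads are
drawn from an independently seeded synthetic genome rather than uniform
random strings, so their k-mer composition resembles real negative reads.
Sequencing realism is deliberately minimal: substitutions are i.i.d. per
base; there are no quality-dependent errors, indels, or long-read noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .fastqio import FastqRecord, write_fastq

__all__ = [
    "FixtureSpec",
    "ReadSet",
    "synth_genome",
    "sample_reads",
    "synth_vcf",
    "write_fixture_dir",
    "PRESETS",
]

_BASES = np.frombuffer(b"ACTG", dtype=np.uint8)  # digit -> ASCII, A=0,C=1,T=2,G=3
_COMP = np.array([2, 3, 0, 1], dtype=np.uint8)  # digit -> complement digit (^2)

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACTG"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic read set."""

    genome_length: int = 1_000_000
    read_length: int = 150
    n_reads: int = 200_000
    substitution_rate: float = 0.01
    insert_size: int = 350
    fraction_host: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genome_length, self.read_length, self.n_reads) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0 <= self.fraction_host <= 1:
            raise ValueError("fraction_host must be in [0, 1]")


@dataclass
class ReadSet:
    """Reads plus per-read truth: (name, label, position, strand)."""

    reads: list[FastqRecord]
    mates: list[FastqRecord] = field(default_factory=list)
    truth: list[tuple[str, str, int, str]] = field(default_factory=list)

    @property
    def paired(self) -> bool:
        return bool(self.mates)


def _digits_to_str(digits: np.ndarray) -> str:
    return _BASES[digits].tobytes().decode("ascii")


def _str_to_digits(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    d = _LUT[raw]
    if (d < 0).any():
        raise ValueError("genome must contain only A, C, G, T")
    return d.astype(np.uint8)


def synth_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. ACGT sequence of the given length, seeded."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng([int(seed), 0x67])
    return _digits_to_str(rng.integers(0, 4, size=length, dtype=np.uint8))


def _apply_substitutions(mat: np.ndarray, rate: float, rng) -> np.ndarray:
    """I.i.d. per-base substitutions to a *different* base, in place."""
    if rate <= 0:
        return mat
    hit = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    mat[hit] = (mat[hit] + shift[hit]) % 4
    return mat


def sample_reads(
    genome: str,
    n: int,
    read_length: int,
    substitution_rate: float,
    seed: int,
    *,
    paired: bool = False,
    insert_size: int | None = None,
    label: str = "host",
    name_prefix: str = "read",
) -> ReadSet:
    """Sample reads from uniform positions and strands of a genome.

    Single-end reads are genome substrings (reverse-complemented on the
    minus strand) with i.i.d. substitutions.  Paired mode draws a fragment
    of ``insert_size`` and returns proper forward/reverse mates.  The truth
    table records ``(name, label, 0-based start of the fragment, strand)``.
    """
    g = _str_to_digits(genome)
    L = g.shape[0]
    if read_length > L:
        raise ValueError("read_length exceeds genome length")
    span = read_length
    if paired:
        insert_size = insert_size or max(2 * read_length, read_length + 50)
        if insert_size < read_length or insert_size > L:
            raise ValueError(f"infeasible insert size {insert_size}")
        span = insert_size
    rng = np.random.default_rng([int(seed), 0x52])
    starts = rng.integers(0, L - span + 1, size=n, dtype=np.int64)
    strands = rng.integers(0, 2, size=n, dtype=np.int8)  # 0 = '+', 1 = '-'
    frag = g[starts[:, None] + np.arange(span)]  # (n, span)

    qual = "I" * read_length
    names = [f"{name_prefix}{i}" for i in range(n)]
    truth = [
        (names[i], label, int(starts[i]), "-" if strands[i] else "+")
        for i in range(n)
    ]

    def rows_to_records(mat: np.ndarray) -> list[FastqRecord]:
        chars = _BASES[mat]
        return [
            (names[i], chars[i].tobytes().decode("ascii"), qual)
            for i in range(n)
        ]

    if not paired:
        rc = _COMP[frag[:, ::-1]]
        mat = np.where(strands[:, None] == 1, rc, frag).astype(np.uint8)
        _apply_substitutions(mat, substitution_rate, rng)
        return ReadSet(reads=rows_to_records(mat), truth=truth)

    fwd = frag[:, :read_length]
    rev = _COMP[frag[:, -read_length:][:, ::-1]]
    # minus-strand fragments swap which end is sequenced first
    r1 = np.where(strands[:, None] == 1, rev, fwd).astype(np.uint8)
    r2 = np.where(strands[:, None] == 1, fwd, rev).astype(np.uint8)
    _apply_substitutions(r1, substitution_rate, rng)
    _apply_substitutions(r2, substitution_rate, rng)
    return ReadSet(reads=rows_to_records(r1), mates=rows_to_records(r2), truth=truth)


def synth_vcf(
    genome: str,
    n_variants: int,
    af_values,
    seed: int,
    *,
    chrom: str = "chr1",
) -> str:
    """A syntactically valid VCF with SNVs and short indels on *genome*.

    Variants sit at non-overlapping positions with correct reference
    alleles; indels use the shared-leading-base convention.  ``af_values``
    is a sequence of allele frequencies sampled uniformly per record and
    written to the INFO AF field.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    L = len(genome)
    af_values = list(af_values)
    spacing = 12  # > max indel span, keeps records non-overlapping
    if n_variants and L < (n_variants + 1) * spacing + 2:
        raise ValueError("genome too short for requested variants")
    rng = np.random.default_rng([int(seed), 0x5C])
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={L}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    if n_variants:
        slots = np.sort(rng.choice(np.arange(1, (L - 2) // spacing), size=n_variants,
                                   replace=False))
        positions = slots * spacing  # 0-based anchor positions
        for p in positions:
            p = int(p)
            af = float(rng.choice(af_values))
            kind = int(rng.integers(0, 3))
            anchor = genome[p]
            if kind == 0:  # SNV
                alt = "ACGT"[(("ACGT".index(anchor)) + int(rng.integers(1, 4))) % 4]
                ref_a, alt_a = anchor, alt
            elif kind == 1:  # insertion after the anchor base
                ins = "".join("ACGT"[d] for d in rng.integers(0, 4, size=int(rng.integers(1, 6))))
                ref_a, alt_a = anchor, anchor + ins
            else:  # deletion of 1-5 bases after the anchor base
                dlen = int(rng.integers(1, 6))
                ref_a, alt_a = genome[p:p + 1 + dlen], anchor
            lines.append(
                f"{chrom}\t{p + 1}\t.\t{ref_a}\t{alt_a}\t.\tPASS\tAF={af:g}"
            )
    return "\n".join(lines) + "\n"


PRESETS = {
    # tiny end-to-end smoke data
    "small": FixtureSpec(genome_length=5_000, read_length=100, n_reads=200,
                         substitution_rate=0.01, seed=0),
    # the synthetic classification benchmark: 1e5 host reads at 1%
    # substitutions plus 1e5 foreign reads of 150 bp
    "classify-bench": FixtureSpec(genome_length=1_000_000, read_length=150,
                                  n_reads=200_000, substitution_rate=0.01,
                                  seed=0),
}


def make_benchmark(spec: FixtureSpec, seed: int | None = None):
    """Host genome, host reads, and foreign reads for a FixtureSpec.

    Returns ``(genome, host_reads, foreign_reads)`` where the foreign reads
    come from an independently seeded genome of the same length.
    """
    seed = spec.seed if seed is None else seed
    n_host = int(round(spec.n_reads * spec.fraction_host))
    n_foreign = spec.n_reads - n_host
    genome = synth_genome(spec.genome_length, seed)
    foreign_genome = synth_genome(spec.genome_length, seed + 104729)
    host = sample_reads(genome, n_host, spec.read_length,
                        spec.substitution_rate, seed + 1,
                        label="host", name_prefix="host")
    foreign = sample_reads(foreign_genome, n_foreign, spec.read_length,
                           spec.substitution_rate, seed + 2,
                           label="foreign", name_prefix="foreign")
    return genome, host, foreign


def write_fixture_dir(preset: str, out_dir: str | os.PathLike, seed: int = 0) -> dict:
    """Write FASTA/FASTQ/VCF/truth-TSV files for a named preset."""
    try:
        spec = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    os.makedirs(out_dir, exist_ok=True)
    genome, host, foreign = make_benchmark(spec, seed)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "reads": os.path.join(out_dir, "reads.fq"),
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    with open(paths["genome"], "w") as fh:
        fh.write(">host_genome\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i:i + 80] + "\n")
    write_fastq(host.reads + foreign.reads, paths["reads"])
    n_var = min(20, max(0, (len(genome) - 40) // 50))
    with open(paths["vcf"], "w") as fh:
        fh.write(synth_vcf(genome, n_var, [0.005, 0.05, 0.5], seed))
    with open(paths["truth"], "w") as fh:
        fh.write("name\tlabel\tpos\tstrand\n")
        for row in host.truth + foreign.truth:
            fh.write("\t".join(map(str, row)) + "\n")
    return paths
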