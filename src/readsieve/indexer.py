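"""Build a host-genome seed index: stream FASTA references, extract
canonical gapped k-mer codes, optionally augment with common variants, and
insert everything into an exact table or a probabilistic filter.

Variant augmentation follows the pangenome recipe: for every variant at or
above the allele-frequency cutoff the affected reference region is replaced
by the alternative allele and the gapped k-mers of the new sequence plus a
flanking context (default +-50 bp) are added to the index.  Variants are
applied independently — nearby variants are not combined into haplotypes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from . import cuckoo
from .cuckoo import BucketedCuckooTable, WindowedCuckooFilter
from .fastqio import read_fasta
from .seedcodes import Mask, gapped_code_array, parse_mask

__all__ = [
    "IndexBuildConfig",
    "VariantRecord",
    "BuildReport",
    "IndexBuildError",
    "build_index",
    "load_variants",
    "apply_variants",
    "index_stats",
    "save_index",
    "load_index",
]

logger = logging.getLogger(__name__)

#: Rebuild policy on insertion failure: grow 1.5x, then reseed, then give up.
MAX_BUILD_ATTEMPTS = 3
GROWTH_FACTOR = 1.5


class IndexBuildError(RuntimeError):
    """Index construction failed even after growing and reseeding."""


@dataclass(frozen=True)
class IndexBuildConfig:
    """Configuration of an index build.

    ``fill_limit`` is the maximum tolerated load of the store (slots are
    allocated as ``size_estimate / fill_limit``); defaults are 0.88 for the
    exact table and 0.95 for the filter, matching each structure's safe
    operating load.
    """

    mask: Mask
    structure: str = "exact"  # "exact" | "filter"
    size_estimate: int = 1_000_000
    fill_limit: float | None = None
    min_af: float = 0.01
    flank: int = 50
    p_bits: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.mask, str):
            object.__setattr__(self, "mask", parse_mask(self.mask))
        if self.structure not in ("exact", "filter"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.size_estimate <= 0:
            raise ValueError("size_estimate must be positive")
        if self.fill_limit is None:
            object.__setattr__(
                self, "fill_limit", 0.88 if self.structure == "exact" else 0.95
            )
        if not 0 < self.fill_limit < 1:
            raise ValueError("fill_limit must be in (0, 1)")
        if not 0 <= self.min_af <= 1:
            raise ValueError("min_af must be in [0, 1]")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass(frozen=True)
class VariantRecord:
    """One alternative allele: 0-based half-open replacement interval."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive; ref allele spans [start, end)
    ref: str
    alt: str
    af: float


@dataclass
class BuildReport:
    n_sequences: int = 0
    n_windows: int = 0
    n_keys: int = 0
    load: float = 0.0
    n_variants_seen: int = 0
    n_variants_applied: int = 0
    n_variants_af_filtered: int = 0
    n_variants_mismatch: int = 0
    n_variants_no_af: int = 0
    n_fragments: int = 0
    attempts: int = 1
    sequences: dict = field(default_factory=dict)


def load_variants(vcf_path: str | os.PathLike) -> tuple[list[VariantRecord], int]:
    """Read variants from a VCF; AF taken from INFO/AF (one value per alt).

    Multi-allelic records are split into one VariantRecord per alt.  Records
    lacking AF are skipped; the second return value counts them.
    """
    records: list[VariantRecord] = []
    n_no_af = 0
    with pysam.VariantFile(os.fspath(vcf_path)) as vf:
        for rec in vf:
            afs = rec.info.get("AF")
            alts = rec.alts or ()
            if afs is None:
                n_no_af += len(alts)
                logger.warning("variant %s:%d lacks INFO/AF; skipped", rec.chrom, rec.pos)
                continue
            if not isinstance(afs, (tuple, list)):
                afs = (afs,)
            for alt, af in zip(alts, afs):
                if alt is None or af is None:
                    n_no_af += 1
                    continue
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        start=rec.pos - 1,  # VCF POS is 1-based
                        end=rec.pos - 1 + len(rec.ref),
                        ref=rec.ref,
                        alt=str(alt),
                        af=float(af),
                    )
                )
    return records, n_no_af


def apply_variants(
    ref_seq: str,
    variants: Sequence[VariantRecord],
    min_af: float,
    flank: int,
    report: BuildReport | None = None,
) -> list[str]:
    """Alternative fragments for all variants passing the AF cutoff.

    Each fragment is ``ref[start-flank:start] + alt + ref[end:end+flank]``
    clipped to the sequence bounds; variants whose ref allele does not match
    the reference are skipped with a warning.
    """
    L = len(ref_seq)
    fragments: list[str] = []
    for v in variants:
        if report is not None:
            report.n_variants_seen += 1
        if v.af < min_af:
            if report is not None:
                report.n_variants_af_filtered += 1
            continue
        if ref_seq[v.start:v.end].upper() != v.ref.upper():
            logger.warning(
                "ref allele mismatch at %s:%d (expected %r); record skipped",
                v.chrom, v.start + 1, v.ref,
            )
            if report is not None:
                report.n_variants_mismatch += 1
            continue
        frag = (
            ref_seq[max(0, v.start - flank):v.start]
            + v.alt
            + ref_seq[v.end:min(L, v.end + flank)]
        )
        fragments.append(frag)
        if report is not None:
            report.n_variants_applied += 1
    return fragments


def _new_store(config: IndexBuildConfig, n_slots: int, seed: int):
    if config.structure == "exact":
        return BucketedCuckooTable(n_slots, seed=seed, mask=config.mask.pattern)
    return WindowedCuckooFilter(n_slots, p_bits=config.p_bits, seed=seed,
                                mask=config.mask.pattern)


def _collect_codes(
    fasta_paths: Sequence[str | os.PathLike],
    vcf_paths: Sequence[str | os.PathLike],
    config: IndexBuildConfig,
    report: BuildReport,
) -> list[np.ndarray]:
    """Stream inputs once, returning per-sequence canonical code arrays."""
    mask = config.mask
    variants_by_chrom: dict[str, list[VariantRecord]] = {}
    for vp in vcf_paths:
        recs, n_no_af = load_variants(vp)
        report.n_variants_no_af += n_no_af
        for r in recs:
            variants_by_chrom.setdefault(r.chrom, []).append(r)

    chunks: list[np.ndarray] = []
    for path in fasta_paths:
        for name, seq in read_fasta(path):
            report.n_sequences += 1
            codes, valid = gapped_code_array(seq, mask)
            report.n_windows += int(valid.sum())
            report.sequences[name] = len(seq)
            chunks.append(codes[valid])
            for frag in apply_variants(
                seq, variants_by_chrom.get(name, ()),
                config.min_af, config.flank, report,
            ):
                report.n_fragments += 1
                fcodes, fvalid = gapped_code_array(frag, mask)
                report.n_windows += int(fvalid.sum())
                chunks.append(fcodes[fvalid])
    return chunks


def build_index(
    fasta_paths: Sequence[str | os.PathLike] | str | os.PathLike,
    config: IndexBuildConfig,
    vcf_paths: Sequence[str | os.PathLike] | str | os.PathLike = (),
):
    """Build the index; returns ``(store, BuildReport)``.

    On insertion failure the store is rebuilt with 1.5x slots, then with
    different hash seeds, for at most ``MAX_BUILD_ATTEMPTS`` attempts.
    """
    if isinstance(fasta_paths, (str, os.PathLike)):
        fasta_paths = [fasta_paths]
    if isinstance(vcf_paths, (str, os.PathLike)):
        vcf_paths = [vcf_paths]
    report = BuildReport()
    chunks = _collect_codes(fasta_paths, vcf_paths, config, report)

    n_slots = max(int(np.ceil(config.size_estimate / config.fill_limit)), 64)
    seed = config.seed
    for attempt in range(1, MAX_BUILD_ATTEMPTS + 1):
        report.attempts = attempt
        store = _new_store(config, n_slots, seed)
        ok = True
        for codes in chunks:
            if store.insert_many(codes) < codes.shape[0]:
                ok = False
                break
        if ok and store.load <= config.fill_limit:
            report.n_keys = store.n_keys
            report.load = store.load
            return store, report
        if ok:  # built but fuller than the fill limit: grow and retry
            logger.warning("index load %.3f exceeds fill limit %.3f; growing",
                           store.load, config.fill_limit)
            n_slots = int(n_slots * GROWTH_FACTOR)
            continue
        if attempt == 1:
            n_slots = int(n_slots * GROWTH_FACTOR)  # grow first
        else:
            seed += 7_654_321  # then try different hash functions
        logger.warning("insertion failed (attempt %d); rebuilding", attempt)
    raise IndexBuildError(
        f"index build failed after {MAX_BUILD_ATTEMPTS} attempts "
        f"(last size {n_slots} slots)"
    )


def index_stats(store) -> dict:
    """Summary of a store: structure kind, mask shape, keys, slots, load,
    and payload bits per key (slot width / load)."""
    mask = parse_mask(store.mask) if store.mask else None
    load = store.load
    return {
        "structure": store.kind,
        "k": mask.weight_k if mask else None,
        "w": mask.width_w if mask else None,
        "keys": store.n_keys,
        "slots": store.n_slots,
        "load": load,
        "bits_per_key": (store.slot_bits / load) if load > 0 else float("inf"),
    }


def save_index(store, path: str | os.PathLike) -> None:
    with open(path, "wb") as fh:
        fh.write(cuckoo.serialize(store))


def load_index(path: str | os.PathLike):
    with open(path, "rb") as fh:
        return cuckoo.deserialize(fh.read())
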