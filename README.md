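# readsieve

Alignment-free removal of host-derived reads from sequencing data using
spaced seeds (gapped k-mers) and Cuckoo hash structures.

Microbiome samples taken from a host organism inevitably contain host DNA.
Host reads must be depleted before publication (privacy regulations for
human subjects) and before downstream analysis (host contamination skews
profiling, binning, and assembly). `readsieve` addresses this for
bioinformaticians who need a fast, memory-frugal filter that runs from the
shell: index a host (pan)genome once, then stream FASTQ files through a
per-read classifier.

## Method

A *(k, w)-mask* is a string over `{#, _}` of width *w* with *k* significant
positions (`#`), e.g. the default (29, 33) mask

```
######_#######_###_#######_######
```

Every length-*w* window *x* of a sequence yields a gapped k-mer: the *k*
characters at significant positions, encoded base-4 with **A=0, C=1, T=2,
G=3** (note: not the common A,C,G,T order; the complement of a digit is
`digit XOR 2`). Forward and reverse strands are identified through the
canonical code

```
cc(x) = max( enc(x), enc(rc(x)) )
```

which is well defined for symmetric masks. The index is the set of
canonical codes of all windows of the reference, stored either

* **exactly**, in a (d=3, l=4) bucketed Cuckoo hash table (full codes,
  zero false positives, usable up to ~98% load), or
* **probabilistically**, in a (d=2, l=2) *windowed* Cuckoo filter holding
  16-bit fingerprints in overlapping windows (false positive rate below
  `d*l*2^-16 = 2^-14 < 1/16000`, ~16.8 = 16/0.95 bits per key at its 95%
  operating load).

A read *s* is classified by covered bases: in **sensitive** mode every
window is queried and a hit marks its significant positions as covered; in
**sampling** mode only every `floor(w/2)+1`-th window is queried and a hit
marks all *w* window positions. The read is called host iff at least
`T*|s|` positions are covered (default `T = 0.5`). For paired-end data the
pair is removed if either mate is host. The default mask guarantees at
least 50 covered positions in any 100 bp stretch that matches the
reference with up to three substitutions — `readsieve` certifies this by
exhaustive enumeration (`min_coverage`).

A reference index can be augmented into a pangenome index: common variants
(INFO/AF at least 1% by default) from a VCF are applied to the reference
individually, and the gapped k-mers of the alternative allele plus or minus
50 bp of context are added; extra FASTA collections (e.g. alternative
assemblies, gene variant sets, cDNA) are simply further inputs.

## Worked example

Synthetic fixture: a 5 kb host genome, 100 host reads (100 bp, 1%
substitution errors) mixed with 100 reads from an unrelated genome.

```sh
readsieve fixtures --preset small --out demo --seed 1
readsieve index --size-estimate 6000 --seed 1 --out demo/host.idx demo/genome.fa
readsieve filter --index demo/host.idx --reads demo/reads.fq \
    --out demo/clean.fq --json-summary demo/summary.json
```

prints

```
indexed 1 sequence(s), 4968 windows, 4968 keys (load 0.728) -> demo/host.idx
200 reads: removed 100, retained 100 (0 shorter than the mask)
```

All 100 host reads are removed (their seed coverage exceeds half the read
length despite the substitutions) and all 100 foreign reads are retained
(an exact index yields no spurious seed hits). `readsieve stats
demo/host.idx` reports the structure, mask shape (k=29, w=33), key count,
load, and payload bits per key. The library API mirrors the CLI:
`encode("TACGC") == 541`, `canonical_code(541, 5) == 888`, and
`extract_gapped("TACGCGTAAG", parse_mask("##_#_##"))` yields canonical
gapped codes 574, 574, 663, ... per window.

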