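"""Selection of repeat protospacers suitable for PAM profiling.

A good repeat protospacer occurs thousands of times in the genome with
near-random 10-nt flanks, so that the flank population spans the whole
PAM candidate space.  This module provides the k-mer census over both
strands, the candidate filters (5' G start, no homopolymer triple),
strand-aware flank extraction, flank-diversity summaries, and
Hamming-neighborhood counting of mismatch targets.

Strand convention: the occurrence count of a k-mer w is the number of
forward occurrences of w plus the forward occurrences of its reverse
complement — i.e. one count per strand per locus, so a palindromic k-mer
at one locus counts twice.  Windows containing N are skipped entirely.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import _scan
from .io_core import GenomeSequence, revcomp

log = logging.getLogger("genomepam")

HOMOPOLYMER_TRIPLES = ("AAA", "TTT", "CCC", "GGG")


@dataclass
class KmerCensus:
    """Occurrence counts of all k-mers over both strands of a genome."""

    k: int
    counts: dict[str, int]
    genome_label: str = ""

    def occurrences(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


@dataclass
class RepeatCandidate:
    kmer: str
    occurrences: int
    flank3_pfm: np.ndarray | None = None
    flank5_pfm: np.ndarray | None = None
    flank_entropy_3p: float | None = None
    flank_entropy_5p: float | None = None
    passes_filters: dict[str, bool] = field(default_factory=dict)


@dataclass
class MismatchCensus:
    """Numbers of genomic sites at each exact Hamming distance from a protospacer."""

    protospacer: str
    max_d: int
    counts_by_distance: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts_by_distance.values())


def _forward_kmer_counts(genome: GenomeSequence, k: int) -> Counter:
    counts: Counter = Counter()
    for name, seq in genome:
        if len(seq) < k:
            continue
        if "N" in seq:
            codes = _scan.encode(seq)
            bad = _scan.window_has_n(codes, k)
            counts.update(
                seq[i : i + k] for i in range(len(seq) - k + 1) if not bad[i]
            )
        else:
            counts.update(seq[i : i + k] for i in range(len(seq) - k + 1))
    return counts


def count_kmers(genome: GenomeSequence, k: int, genome_label: str = "") -> KmerCensus:
    """Census of all k-mers counting both strands.

    ``counts[w] = fwd(w) + fwd(revcomp(w))``; overlapping occurrences all
    count, and windows containing N are skipped.
    """
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in 1..32, got {k}")
    if genome.total_length == 0:
        raise ValueError("genome is empty")
    fwd = _forward_kmer_counts(genome, k)
    if not fwd:
        log.warning("count_kmers: k=%d exceeds every chromosome length — empty census", k)
        return KmerCensus(k=k, counts={}, genome_label=genome_label)
    counts: dict[str, int] = {}
    for w, c in fwd.items():
        counts[w] = c + fwd.get(revcomp(w), 0)
        rc = revcomp(w)
        if rc not in fwd:
            counts[rc] = c  # target exists on the other strand too
    log.info("count_kmers: k=%d, %d distinct k-mers", k, len(counts))
    return KmerCensus(k=k, counts=counts, genome_label=genome_label)


def passes_candidate_filters(kmer: str) -> dict[str, bool]:
    """The repeat-protospacer filters: 5' G start, no AAA/TTT/CCC/GGG run."""
    return {
        "starts_with_G": kmer.startswith("G"),
        "no_homopolymer_triple": not any(t in kmer for t in HOMOPOLYMER_TRIPLES),
    }


def filter_candidates(census: KmerCensus, min_occurrences: int = 1000) -> list[RepeatCandidate]:
    """Repeat candidates passing all filters with at least ``min_occurrences``.

    Sorted by descending occurrence count (ties broken lexicographically
    for determinism).
    """
    kept = []
    for kmer, occ in census.counts.items():
        flags = passes_candidate_filters(kmer)
        if all(flags.values()) and occ >= min_occurrences:
            kept.append(RepeatCandidate(kmer=kmer, occurrences=occ, passes_filters=flags))
    kept.sort(key=lambda c: (-c.occurrences, c.kmer))
    log.info(
        "filter_candidates: %d/%d k-mers kept (min_occurrences=%d)",
        len(kept), len(census.counts), min_occurrences,
    )
    return kept


def _occurrence_intervals(genome: GenomeSequence, kmer: str):
    """Yield (chrom, start, strand) for every double-strand occurrence."""
    rc = revcomp(kmer)
    for name, seq in genome:
        for query, strand in ((kmer, "+"), (rc, "-")):
            i = seq.find(query)
            while i != -1:
                yield name, i, strand
                i = seq.find(query, i + 1)


def extract_flanks(
    genome: GenomeSequence,
    kmer: str,
    side: str,
    flank_len: int = 10,
) -> list[str]:
    """Flanks of every occurrence of ``kmer``, in protospacer orientation.

    ``side`` is ``"five_prime"`` or ``"three_prime"``.  For a minus-strand
    hit the 3' flank is the reverse complement of the genomic bases
    immediately 5' of the hit interval (and vice versa).  Flank windows
    that run off the chromosome or contain N are dropped (counted in the
    log).
    """
    if side not in ("five_prime", "three_prime"):
        raise ValueError(f"side must be five_prime or three_prime, got {side!r}")
    k = len(kmer)
    flanks: list[str] = []
    dropped = 0
    found = False
    for chrom, start, strand in _occurrence_intervals(genome, kmer):
        found = True
        seq = genome.records[chrom]
        # genomic side of the requested protospacer side
        if (side == "three_prime") == (strand == "+"):
            lo, hi = start + k, start + k + flank_len
        else:
            lo, hi = start - flank_len, start
        if lo < 0 or hi > len(seq):
            dropped += 1
            continue
        flank = seq[lo:hi]
        if "N" in flank:
            dropped += 1
            continue
        flanks.append(flank if strand == "+" else revcomp(flank))
    if not found:
        log.warning("extract_flanks: %r not found in genome", kmer)
    if dropped:
        log.info("extract_flanks: dropped %d flank(s) (boundary or N)", dropped)
    return flanks


def flank_diversity(flanks: list[str]) -> tuple[np.ndarray, float]:
    """Position frequency matrix (4 x W, rows A,C,G,T) and mean Shannon entropy.

    Entropy is in bits, averaged over positions; 2 bits means a uniform
    base composition, 0 a fixed base.
    """
    if not flanks:
        raise ValueError("no flanks given")
    widths = {len(f) for f in flanks}
    if len(widths) != 1:
        raise ValueError(f"ragged flank lengths: {sorted(widths)}")
    (w,) = widths
    mat = np.zeros((4, w), dtype=float)
    codes = np.vstack([_scan.encode(f) for f in flanks])
    if (codes > 3).any():
        raise ValueError("flanks must be over ACGT")
    for b in range(4):
        mat[b] = (codes == b).sum(axis=0)
    pfm = mat / mat.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    entropy = float(-plogp.sum(axis=0).mean())
    return pfm, entropy


def mismatch_neighborhood(
    genome: GenomeSequence, protospacer: str, max_d: int = 4
) -> MismatchCensus:
    """Count genomic windows at each exact Hamming distance from the protospacer.

    Both strands are scanned (a minus-strand target is a forward occurrence
    of the reverse complement); windows containing N are skipped; the d=0
    bin reproduces :func:`count_kmers` for the protospacer.
    """
    protospacer = protospacer.upper()
    if set(protospacer) - set("ACGT"):
        raise ValueError("protospacer must be over ACGT")
    if max_d > len(protospacer):
        raise ValueError("max_d exceeds protospacer length")
    k = len(protospacer)
    bins = np.zeros(max_d + 1, dtype=np.int64)
    for query in (protospacer, revcomp(protospacer)):
        allowed = _scan.exact_allowed(query)
        for _, seq in genome:
            if len(seq) < k:
                continue
            codes = _scan.encode(seq)
            mm = _scan.mismatch_counts(codes, allowed)
            ok = ~_scan.window_has_n(codes, k)
            mm = mm[ok]
            hits = mm[mm <= max_d]
            if hits.size:
                bins += np.bincount(hits, minlength=max_d + 1)
    return MismatchCensus(
        protospacer=protospacer,
        max_d=max_d,
        counts_by_distance={d: int(bins[d]) for d in range(max_d + 1)},
    )
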