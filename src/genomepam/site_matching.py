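"""Matching cleavage evidence to protospacer-aligned genomic targets.

The matcher enumerates every genomic window within a mismatch budget of
the spacer (substitutions only, both strands; the PAM-side flank is left
entirely unconstrained), then assigns dsODN-style integration events to
the nearest candidate target.  Spacers of 21-22 nt may carry IUPAC
degenerate bases (e.g. Y) at their 5' extension; a genomic base inside
the degenerate set is a match, not a mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from . import _scan
from .io_core import CleavageSite, GenomeSequence, SiteTable, revcomp

log = logging.getLogger("genomepam")

FLANK_LEN = 10


@dataclass(frozen=True)
class PamOrientation:
    """Which side of the spacer carries the PAM.

    ``three_prime`` (Cas9-like) reads the PAM from flank3, positions 1..10
    with 1 adjacent to the spacer; ``five_prime`` (Cas12a-like) reads it
    from flank5, positions -10..-1 with -1 adjacent.
    """

    value: str

    def __post_init__(self):
        if self.value not in ("three_prime", "five_prime"):
            raise ValueError(f"orientation must be three_prime or five_prime, got {self.value!r}")


THREE_PRIME = PamOrientation("three_prime")
FIVE_PRIME = PamOrientation("five_prime")


def parse_orientation(text: str | PamOrientation) -> PamOrientation:
    if isinstance(text, PamOrientation):
        return text
    aliases = {
        "3p": THREE_PRIME, "three_prime": THREE_PRIME, "3": THREE_PRIME,
        "5p": FIVE_PRIME, "five_prime": FIVE_PRIME, "5": FIVE_PRIME,
    }
    try:
        return aliases[text.lower()]
    except KeyError:
        raise ValueError(f"unknown PAM orientation {text!r}") from None


def _iupac_allowed(spacer: str) -> list[np.ndarray]:
    """Per-position genome-code match tables honouring IUPAC degeneracy."""
    tables = []
    for ch in spacer:
        lut = np.zeros(5, dtype=bool)
        for b in ambiguous_dna_values[ch]:
            lut["ACGT".index(b)] = True
        tables.append(lut)
    return tables


def find_genomic_targets(
    genome: GenomeSequence,
    protospacer: str,
    max_mm: int = 6,
    flank_len: int = FLANK_LEN,
) -> list[CleavageSite]:
    """All genomic windows within ``max_mm`` substitutions of the spacer.

    Returns site templates (read_count 1, unassigned) with both 10-mer
    flanks populated in protospacer orientation.  Degenerate spacer bases
    match their IUPAC set at zero cost.  Windows containing N, or whose
    flank windows run off the chromosome or contain N, are dropped and
    counted in the log.
    """
    protospacer = protospacer.upper()
    unsupported = set(protospacer) - set("ACGTRYSWKMBDHV")
    if unsupported:
        raise ValueError(f"spacer contains unsupported characters: {sorted(unsupported)}")
    k = len(protospacer)
    templates: list[CleavageSite] = []
    dropped_flanks = 0
    for query, strand in ((protospacer, "+"), (revcomp(protospacer), "-")):
        allowed = _iupac_allowed(query)
        for chrom, seq in genome:
            if len(seq) < k:
                continue
            codes = _scan.encode(seq)
            mm = _scan.mismatch_counts(codes, allowed)
            ok = ~_scan.window_has_n(codes, k)
            starts = np.nonzero((mm <= max_mm) & ok)[0]
            for start in starts.tolist():
                end = start + k
                lo5, hi5 = start - flank_len, start
                lo3, hi3 = end, end + flank_len
                if lo5 < 0 or hi3 > len(seq):
                    dropped_flanks += 1
                    continue
                up, down = seq[lo5:hi5], seq[lo3:hi3]
                if "N" in up or "N" in down:
                    dropped_flanks += 1
                    continue
                window = seq[start:end]
                if strand == "+":
                    aligned, flank5, flank3 = window, up, down
                else:
                    aligned, flank5, flank3 = revcomp(window), revcomp(down), revcomp(up)
                positions = tuple(
                    j + 1
                    for j, (a, s) in enumerate(zip(aligned, protospacer))
                    if a not in ambiguous_dna_values[s]
                )
                templates.append(
                    CleavageSite(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        aligned_seq=aligned,
                        n_mismatch=len(positions),
                        mismatch_positions=positions,
                        flank5=flank5,
                        flank3=flank3,
                    )
                )
    if dropped_flanks:
        log.info("find_genomic_targets: dropped %d window(s) (flank boundary or N)", dropped_flanks)
    templates.sort(key=lambda t: (t.chrom, t.start, t.strand))
    log.info(
        "find_genomic_targets: %d template(s) within %d mismatch(es)", len(templates), max_mm
    )
    return templates


def _distance_to_interval(pos: int, start: int, end: int) -> int:
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - end + 1


def assign_integrations(
    templates: list[CleavageSite],
    integration_events: list[tuple[str, int, int]],
    window: int = 25,
    provenance: str = "",
) -> tuple[SiteTable, list[tuple[str, int, int]]]:
    """Assign (chrom, pos, read_count) events to the nearest target template.

    An event is assigned when its position is within ``window`` bases of
    the template's protospacer interval; read counts are summed per
    template; templates with no events are dropped.  Returns the resulting
    table and the list of unassigned events.  Equidistant ties break to
    the lowest (chrom, start, strand).
    """
    by_chrom: dict[str, list[CleavageSite]] = {}
    for t in templates:
        by_chrom.setdefault(t.chrom, []).append(t)
    reads: dict[tuple[str, int, str], int] = {}
    unassigned: list[tuple[str, int, int]] = []
    for chrom, pos, rc in integration_events:
        if rc <= 0:
            raise ValueError(f"integration event at {chrom}:{pos} has non-positive read count")
        best: CleavageSite | None = None
        best_d: int | None = None
        tie = False
        for t in by_chrom.get(chrom, []):
            d = _distance_to_interval(pos, t.start, t.end)
            if d > window:
                continue
            if best is None or d < best_d:
                best, best_d, tie = t, d, False
            elif d == best_d:
                tie = True
                if (t.chrom, t.start, t.strand) < (best.chrom, best.start, best.strand):
                    best = t
        if best is None:
            unassigned.append((chrom, pos, rc))
            continue
        if tie:
            log.warning(
                "assign_integrations: tie at %s:%d broken to %s:%d%s",
                chrom, pos, best.chrom, best.start, best.strand,
            )
        key = (best.chrom, best.start, best.strand)
        reads[key] = reads.get(key, 0) + rc
    sites = [
        t.with_reads(reads[(t.chrom, t.start, t.strand)])
        for t in templates
        if (t.chrom, t.start, t.strand) in reads
    ]
    if unassigned:
        log.info("assign_integrations: %d unassigned event(s)", len(unassigned))
    return SiteTable(sites, provenance=provenance), unassigned


def pam_flank(site: CleavageSite, orientation: PamOrientation) -> str:
    """The 10-mer PAM-side flank for the given orientation."""
    return site.flank3 if orientation.value == "three_prime" else site.flank5


def pam_position_index(position: int, orientation: PamOrientation) -> int:
    """String index into the PAM flank for a 1-based (3') or negative (5') position.

    Three-prime positions run 1..10 with 1 adjacent to the spacer;
    five-prime positions run -10..-1 with -1 adjacent (the last character
    of flank5 in protospacer orientation).
    """
    if orientation.value == "three_prime":
        if not 1 <= position <= FLANK_LEN:
            raise ValueError(f"3' PAM position must be 1..10, got {position}")
        return position - 1
    if not -FLANK_LEN <= position <= -1:
        raise ValueError(f"5' PAM position must be -10..-1, got {position}")
    return FLANK_LEN + position
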