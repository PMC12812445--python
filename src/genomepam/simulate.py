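"""Synthetic genomes with planted repeat targets and PAM-dependent capture.

The generator emulates what the assay sees: a repeat protospacer planted
many times in a background genome, each copy with an independent random
10-nt flank on both sides, a subset of copies carrying 1-6 spacer
substitutions (biased towards spacer positions 8-11), and cleavage
capture in which a site's read count follows an overdispersed
negative-binomial law whose mean scales with the activity its PAM flank
earns under a planted IUPAC activity model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from .io_core import CleavageSite, GenomeSequence, SiteTable, revcomp
from .site_matching import PamOrientation, pam_flank, parse_orientation

log = logging.getLogger("genomepam")

REP1 = "GTGAGCCACTGTGCCTGGCC"  # the canonical Alu-derived repeat protospacer
FLANK_LEN = 10
BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for one simulated capture experiment."""

    seed: int = 0
    spacer: str = REP1
    genome_length: int | None = None  # default: 3x the planted footprint
    n_perfect_targets: int = 2000
    n_mismatch_targets: int = 400
    max_planted_mismatches: int = 6
    mismatch_hotspot: tuple[int, int] = (8, 11)  # 1-based spacer positions
    mismatch_hotspot_prob: float = 0.6
    pam_model: dict[str, float] = field(default_factory=lambda: {"NGG": 1.0})
    pam_orientation: str = "three_prime"
    mean_depth: float = 100.0
    dispersion: float = 2.0  # negative-binomial size; larger -> closer to Poisson
    capture_rate: float = 0.9
    mismatch_penalty: float = 0.3  # activity multiplier per planted mismatch
    wobble_enrichment: dict | None = None  # {"position": int, "base": str, "prob": float}

    def __post_init__(self):
        for pattern, act in self.pam_model.items():
            if not 0.0 <= act <= 1.0:
                raise ValueError(f"activity for {pattern!r} must be in [0, 1]")
            if set(pattern) - set(ambiguous_dna_values):
                raise ValueError(f"PAM pattern {pattern!r} is not IUPAC")
            if len(pattern) > FLANK_LEN:
                raise ValueError(f"PAM pattern {pattern!r} longer than the flank")

    @property
    def n_targets(self) -> int:
        return self.n_perfect_targets + self.n_mismatch_targets

    @property
    def footprint(self) -> int:
        return len(self.spacer) + 2 * FLANK_LEN

    def resolved_genome_length(self) -> int:
        if self.genome_length is not None:
            if self.genome_length < self.n_targets * self.footprint * 3:
                raise ValueError(
                    "genome_length too small: need >= 3x the planted footprint "
                    f"({self.n_targets * self.footprint * 3} bases)"
                )
            return self.genome_length
        return self.n_targets * self.footprint * 3


@dataclass
class PlantedSite:
    """Ground truth for one planted target."""

    template: CleavageSite
    activity: float = 0.0
    expected_reads: float = 0.0
    realized_reads: int = 0


@dataclass
class SimTruth:
    spacer: str
    pam_orientation: str
    sites: list[PlantedSite] = field(default_factory=list)

    def templates(self) -> list[CleavageSite]:
        return [p.template for p in self.sites]


def pam_activity(
    flank: str, pam_model: dict[str, float], orientation: str | PamOrientation
) -> float:
    """Activity of a PAM flank under an IUPAC pattern -> activity map.

    A 3' pattern is anchored at the spacer-proximal start of flank3; a 5'
    pattern at the spacer-proximal end of flank5.  When several patterns
    match, the most specific one (fewest-N, i.e. smallest IUPAC expansion)
    wins; no match means activity 0.
    """
    orientation = parse_orientation(orientation)
    best: tuple[float, float] | None = None  # (specificity, activity)
    for pattern, act in pam_model.items():
        window = (
            flank[: len(pattern)]
            if orientation.value == "three_prime"
            else flank[len(flank) - len(pattern) :]
        )
        if all(b in ambiguous_dna_values[p] for b, p in zip(window, pattern)):
            spec = sum(1.0 / len(ambiguous_dna_values[p]) for p in pattern)
            if best is None or spec > best[0]:
                best = (spec, act)
    return best[1] if best else 0.0


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def planted_motif_spec(
    pattern: str, orientation: str | PamOrientation
) -> dict[int, set[str]]:
    """Display position -> allowed bases for the defined (non-N) pattern positions.

    Uses the same anchoring as :func:`pam_activity`: a 3' pattern starts at
    PAM position 1, a 5' pattern ends at position -1.  Useful for checking
    that a recovered motif matches the planted model.
    """
    orientation = parse_orientation(orientation)
    spec: dict[int, set[str]] = {}
    for i, ch in enumerate(pattern):
        if ch == "N":
            continue
        pos = i + 1 if orientation.value == "three_prime" else i - len(pattern)
        spec[pos] = set(ambiguous_dna_values[ch])
    return spec


def motif_matches_planted(
    positions: tuple[int, ...], motif: str, pattern: str, orientation: str | PamOrientation
) -> bool:
    """True when a recovered motif covers exactly the planted defined positions
    and every base falls inside the planted IUPAC set."""
    spec = planted_motif_spec(pattern, orientation)
    if set(positions) != set(spec):
        return False
    return all(b in spec[p] for p, b in zip(positions, motif))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate_spacer(rng: np.random.Generator, spacer: str, cfg: SimConfig) -> tuple[str, tuple[int, ...]]:
    n_mm = int(rng.integers(1, cfg.max_planted_mismatches + 1))
    lo, hi = cfg.mismatch_hotspot
    hotspot = [p for p in range(lo, hi + 1) if p <= len(spacer)]
    other = [p for p in range(1, len(spacer) + 1) if p not in hotspot]
    positions: set[int] = set()
    while len(positions) < n_mm:
        pool = hotspot if (hotspot and rng.random() < cfg.mismatch_hotspot_prob) else other
        positions.add(int(rng.choice(pool)))
    seq = list(spacer)
    for p in sorted(positions):
        seq[p - 1] = rng.choice([b for b in BASES if b != spacer[p - 1]])
    return "".join(seq), tuple(sorted(positions))


def make_genome(config: SimConfig) -> tuple[GenomeSequence, SimTruth]:
    """Background genome with planted perfect and mismatch targets.

    Targets are placed in non-overlapping slots on random strands; each
    carries independent uniform-random 10-nt flanks.  Deterministic for a
    given config (byte-identical FASTA across runs).
    """
    rng = np.random.default_rng(config.seed)
    length = config.resolved_genome_length()
    spacer = config.spacer.upper()
    footprint = config.footprint
    slot = footprint + 10  # spacing margin between planted fragments

    n_slots = length // slot
    if n_slots < config.n_targets:
        raise ValueError("cannot place targets without overlap")
    genome_arr = bytearray(_random_dna(rng, length), "ascii")

    chosen = rng.choice(n_slots, size=config.n_targets, replace=False)
    chosen.sort()
    orientation = parse_orientation(config.pam_orientation)
    truth = SimTruth(spacer=spacer, pam_orientation=orientation.value)
    is_mismatch = np.zeros(config.n_targets, dtype=bool)
    if config.n_mismatch_targets:
        is_mismatch[
            rng.choice(config.n_targets, size=config.n_mismatch_targets, replace=False)
        ] = True

    for i, slot_idx in enumerate(chosen.tolist()):
        if is_mismatch[i]:
            aligned, positions = _mutate_spacer(rng, spacer, config)
        else:
            aligned, positions = spacer, ()
        flank5 = _random_dna(rng, FLANK_LEN)
        flank3 = _random_dna(rng, FLANK_LEN)
        if config.wobble_enrichment and positions:
            we = config.wobble_enrichment
            if rng.random() < we["prob"]:
                pos = we["position"]
                if orientation.value == "three_prime":
                    flank3 = flank3[: pos - 1] + we["base"] + flank3[pos:]
                else:
                    idx = FLANK_LEN + pos  # pos is negative
                    flank5 = flank5[:idx] + we["base"] + flank5[idx + 1 :]
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = flank5 + aligned + flank3
        pos0 = slot_idx * slot + 5
        start = pos0 + FLANK_LEN
        placed = fragment if strand == "+" else revcomp(fragment)
        genome_arr[pos0 : pos0 + footprint] = placed.encode("ascii")
        truth.sites.append(
            PlantedSite(
                template=CleavageSite(
                    chrom="chrSim",
                    start=start,
                    end=start + len(spacer),
                    strand=strand,
                    aligned_seq=aligned,
                    n_mismatch=len(positions),
                    mismatch_positions=positions,
                    flank5=flank5,
                    flank3=flank3,
                )
            )
        )
    genome = GenomeSequence({"chrSim": genome_arr.decode("ascii")})
    log.info(
        "make_genome: %d bases, %d perfect + %d mismatch targets planted",
        length, config.n_perfect_targets, config.n_mismatch_targets,
    )
    return genome, truth


def simulate_capture(
    truth: SimTruth,
    pam_model: dict[str, float],
    mean_depth: float = 100.0,
    dispersion: float = 2.0,
    capture_rate: float = 0.9,
    seed: int = 0,
    mismatch_penalty: float = 0.3,
    provenance: str = "simulated",
) -> SiteTable:
    """Capture simulation: which planted sites are detected and with how many reads.

    A site's activity is its PAM-flank activity under ``pam_model`` times
    ``mismatch_penalty`` per planted spacer mismatch; active sites are
    detected with probability ``capture_rate``, and detected sites draw
    reads from a negative binomial (mean = activity x mean_depth, size =
    ``dispersion``) conditioned on being >= 1.
    """
    rng = np.random.default_rng(seed)
    orientation = parse_orientation(truth.pam_orientation)
    captured: list[CleavageSite] = []
    for planted in truth.sites:
        t = planted.template
        act = pam_activity(pam_flank(t, orientation), pam_model, orientation)
        act *= mismatch_penalty**t.n_mismatch
        planted.activity = act
        planted.expected_reads = act * mean_depth
        planted.realized_reads = 0
        if act <= 0 or rng.random() >= capture_rate:
            continue
        mean = act * mean_depth
        p = dispersion / (dispersion + mean)
        reads = 0
        for _ in range(10_000):  # draw conditioned on >= 1
            reads = int(rng.negative_binomial(dispersion, p))
            if reads >= 1:
                break
        else:
            reads = 1
        planted.realized_reads = reads
        captured.append(t.with_reads(reads))
    log.info(
        "simulate_capture: %d/%d planted site(s) captured, %d reads",
        len(captured), len(truth.sites), sum(s.read_count for s in captured),
    )
    return SiteTable(captured, provenance=provenance)


def pattern_match_probability(pattern: str) -> float:
    """Probability a uniform random flank matches an IUPAC PAM pattern."""
    p = 1.0
    for ch in pattern:
        p *= len(ambiguous_dna_values[ch]) / 4.0
    return p


def recovery_experiment(
    pattern: str,
    orientation: str | PamOrientation,
    seed: int,
    target_edited_sites: int = 500,
    max_mm: int = 6,
    mismatch_fraction: float = 0.2,
):
    """One full simulate -> match -> motif-table run against a planted PAM model.

    The number of planted targets is sized so that roughly
    ``target_edited_sites`` end up captured under the pattern's match
    probability and the default capture rate.  Returns the fitted
    :class:`~genomepam.genomepam_table.GenomePamTable` together with a
    boolean saying whether the retained motif recovers the planted model
    (for the PAM-less pattern ``"N"``: whether nothing beyond the seed
    step is retained).
    """
    from .genomepam_table import seed_extend
    from .site_matching import find_genomic_targets

    orientation = parse_orientation(orientation)
    p_match = pattern_match_probability(pattern)
    capture_rate = 0.9
    n_total = int(np.ceil(target_edited_sites / (p_match * capture_rate)))
    n_mismatch = int(round(n_total * mismatch_fraction))
    cfg = SimConfig(
        seed=seed,
        n_perfect_targets=n_total - n_mismatch,
        n_mismatch_targets=n_mismatch,
        pam_model={pattern: 1.0},
        pam_orientation=orientation.value,
        capture_rate=capture_rate,
    )
    genome, truth, sites = run_simulation(cfg)
    templates = find_genomic_targets(genome, cfg.spacer, max_mm=max_mm)
    table = seed_extend(sites, templates, orientation=orientation)
    if set(pattern) == {"N"}:  # PAM-less: nothing beyond the seed step retained
        recovered = len(table.retained) <= 1
    else:
        final = table.final_motif
        recovered = final is not None and motif_matches_planted(
            final.positions, final.motif, pattern, orientation
        )
    return table, recovered


def run_simulation(config: SimConfig) -> tuple[GenomeSequence, SimTruth, SiteTable]:
    """Convenience wrapper: genome + truth + captured site table."""
    genome, truth = make_genome(config)
    sites = simulate_capture(
        truth,
        pam_model=config.pam_model,
        mean_depth=config.mean_depth,
        dispersion=config.dispersion,
        capture_rate=config.capture_rate,
        seed=config.seed + 1,
        mismatch_penalty=config.mismatch_penalty,
        provenance=f"sim(seed={config.seed})",
    )
    return genome, truth, sites
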