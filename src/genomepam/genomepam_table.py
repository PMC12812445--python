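"""Iterative seed-extension PAM-motif enrichment (the GenomePAM Table).

The enrichment statistic for a motif is its *edited value*: the number of
edited (captured) genomic sites matching the motif plus the summed read
counts of those sites, the reads linearly rescaled so that their maximum
over the motifs under comparison equals the maximum site count.  Within a
motif window the edited values are compared against the genomic
background target counts by a two-sided Pearson chi-square test.

The search seeds at the single most significant base over all PAM window
positions, then grows the motif one base at a time towards the 5' or 3'
end, at each round keeping the more significant of the two directions,
until the window boundaries are reached.  The reported (retained) motifs
are those that both pass a Bonferroni-corrected significance gate and
strictly increase the percentage of background targets edited.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _scan
from .io_core import CleavageSite, SiteTable
from .site_matching import PamOrientation, pam_flank, parse_orientation

log = logging.getLogger("genomepam")


@dataclass(frozen=True)
class EditedValue:
    """Site count plus range-scaled read count for one motif."""

    site_count: int
    read_count: int
    scale_factor: float

    @property
    def scaled_reads(self) -> float:
        return self.read_count * self.scale_factor

    @property
    def value(self) -> float:
        return self.site_count + self.scaled_reads


def edited_value(
    site_counts: Sequence[int], read_counts: Sequence[int]
) -> list[EditedValue]:
    """Edited values for the motifs of one comparison window.

    The read counts are scaled by max(site_counts)/max(read_counts) so
    the largest scaled read total equals the largest site count; with
    all-zero reads the scale is 0 and the values reduce to site counts.
    """
    sc = np.asarray(site_counts)
    rc = np.asarray(read_counts)
    if sc.shape != rc.shape:
        raise ValueError("site_counts and read_counts must have equal length")
    if (sc < 0).any() or (rc < 0).any():
        raise ValueError("counts must be nonnegative")
    if rc.max(initial=0) == 0:
        log.warning("edited_value: all read counts zero; values fall back to site counts")
        scale = 0.0
    else:
        scale = float(sc.max()) / float(rc.max())
    return [EditedValue(int(s), int(r), scale) for s, r in zip(sc, rc)]


class ChiSquareResult(NamedTuple):
    chi2: float
    p: float
    df: int


def window_chi_square(
    edited_values: Sequence[float], background_counts: Sequence[int]
) -> ChiSquareResult:
    """Pearson chi-square of edited values against background counts.

    The edited values (rounded to integers) are the observed counts over
    the k motifs of one window; the expected counts are proportional to
    the genomic background counts (goodness of fit, df = k - 1, two-sided
    p).  Motifs with zero background are dropped with a warning (their
    expected count would be undefined); with fewer than two informative
    motifs, or no edited signal at all, the p-value is undefined (NaN).
    """
    ev = np.rint(np.asarray(edited_values, dtype=float)).astype(np.int64)
    bg = np.asarray(background_counts, dtype=np.int64)
    if ev.shape != bg.shape:
        raise ValueError("edited_values and background_counts must have equal length")
    if (ev < 0).any():
        raise ValueError("edited values must be nonnegative")
    if (bg < 0).any():
        raise ValueError("background counts must be nonnegative")
    keep = bg > 0
    if not keep.all():
        log.warning(
            "window_chi_square: dropped %d motif(s) with empty background", int((~keep).sum())
        )
    ev, bg = ev[keep], bg[keep]
    k = ev.size
    if k < 2 or ev.sum() == 0:
        return ChiSquareResult(math.nan, math.nan, 0)
    expected = bg * ev.sum() / bg.sum()
    chi2, p = stats.chisquare(ev, f_exp=expected)
    return ChiSquareResult(float(chi2), float(p), k - 1)


def percent_edited(edited_sites: int, total_sites: int) -> float:
    """Percentage of background targets edited, rounded half-up to 1 decimal."""
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    if not 0 <= edited_sites <= total_sites:
        raise ValueError("need 0 <= edited_sites <= total_sites")
    pct = Decimal(100 * edited_sites) / Decimal(total_sites)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class MotifStep:
    """One seed-extension iteration of the GenomePAM Table."""

    motif: str
    positions: tuple[int, ...]  # display positions (1..10 for 3', -10..-1 for 5')
    start: int  # 0-based index into the PAM window
    edited_sites: int
    total_sites: int
    edited_value: float
    chi2_stat: float
    p_value: float
    step_index: int
    n_candidates: int  # motifs tested in this round (Bonferroni denominator)

    @property
    def percent_edited(self) -> float:
        return percent_edited(self.edited_sites, self.total_sites)

    @property
    def edited_fraction(self) -> float:
        return self.edited_sites / self.total_sites

    def as_dict(self) -> dict:
        return {
            "motif": self.motif,
            "positions": list(self.positions),
            "edited_sites": self.edited_sites,
            "total_sites": self.total_sites,
            "percent_edited": self.percent_edited,
            "edited_value": self.edited_value,
            "chi2": None if math.isnan(self.chi2_stat) else self.chi2_stat,
            "p_value": None if math.isnan(self.p_value) else self.p_value,
            "step_index": self.step_index,
            "n_candidates": self.n_candidates,
        }


@dataclass
class GenomePamTable:
    """Full seed-extension trace plus the retained (reported) motifs."""

    steps: list[MotifStep] = field(default_factory=list)
    retained: list[MotifStep] = field(default_factory=list)
    alpha: float = 0.01
    orientation: str = "three_prime"

    @property
    def final_motif(self) -> MotifStep | None:
        return self.retained[-1] if self.retained else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_dict() for s in self.steps])

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "alpha": self.alpha,
            "orientation": self.orientation,
            "steps": [s.as_dict() for s in self.steps],
            "retained": [s.as_dict() for s in self.retained],
        }
        text = json.dumps(payload, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _display_positions(start: int, length: int, orientation: PamOrientation, window: int):
    if orientation.value == "three_prime":
        return tuple(range(start + 1, start + length + 1))
    return tuple(range(start - window, start + length - window))


def _motif_stats(codes: np.ndarray, reads: np.ndarray, tcodes: np.ndarray, start: int, motif: str):
    """(edited site count, edited read sum, background target count) for a motif."""
    smask = np.ones(codes.shape[0], dtype=bool)
    tmask = np.ones(tcodes.shape[0], dtype=bool)
    for j, ch in enumerate(motif):
        c = "ACGT".index(ch)
        smask &= codes[:, start + j] == c
        tmask &= tcodes[:, start + j] == c
    return int(smask.sum()), int(reads[smask].sum()), int(tmask.sum())


def seed_extend(
    sites: SiteTable,
    targets: Sequence[CleavageSite],
    orientation: str | PamOrientation = "three_prime",
    pam_window: int = 10,
    alpha: float = 0.01,
) -> GenomePamTable:
    """Run the iterative seed-extension motif search.

    ``targets`` is the candidate genomic target set (the background); the
    edited sites are the rows of ``sites``.  Deterministic: ties in
    p-value break to higher percent edited, then lexicographic motif.
    """
    orientation = parse_orientation(orientation)
    if len(sites) == 0:
        raise ValueError("no edited sites")
    if not targets:
        raise ValueError("no background targets")

    codes = np.vstack([_scan.encode(pam_flank(s, orientation)[:pam_window]) for s in sites])
    reads = np.array([s.read_count for s in sites], dtype=np.int64)
    tcodes = np.vstack([_scan.encode(pam_flank(t, orientation)[:pam_window]) for t in targets])
    W = pam_window
    if codes.shape[1] < W or tcodes.shape[1] < W:
        raise ValueError("PAM flanks narrower than the requested window")

    def evaluate(start: int, motifs: list[str]):
        """Window comparison over sibling motifs; returns per-motif stats + test."""
        stats_ = [_motif_stats(codes, reads, tcodes, start, m) for m in motifs]
        evs = edited_value([s for s, _, _ in stats_], [r for _, r, _ in stats_])
        bg = [b for _, _, b in stats_]
        test = window_chi_square([e.value for e in evs], bg)
        return stats_, evs, bg, test

    def pick_motif(motifs, stats_, evs, bg):
        """The enriched motif within a window: largest edited value per background target."""
        best = None  # (enrich, frac, motif, sites, background, ev)
        for m, (s, _r, b), e in zip(motifs, stats_, evs):
            if b == 0:
                continue
            cand = (e.value / b, s / b, m, s, b, e)
            if (
                best is None
                or (cand[0], cand[1]) > (best[0], best[1])
                or ((cand[0], cand[1]) == (best[0], best[1]) and m < best[2])
            ):
                best = cand
        if best is None:
            return None
        return best[2], best[3], best[4], best[5]

    steps: list[MotifStep] = []

    # --- step 1: best single base over every window position
    n_candidates = 4 * W
    best_step: MotifStep | None = None
    for pos in range(W):
        motifs = list("ACGT")
        stats_, evs, bg, test = evaluate(pos, motifs)
        picked = pick_motif(motifs, stats_, evs, bg)
        if picked is None:
            continue
        m, s, b, e = picked
        cand = MotifStep(
            motif=m,
            positions=_display_positions(pos, 1, orientation, W),
            start=pos,
            edited_sites=s,
            total_sites=b,
            edited_value=e.value,
            chi2_stat=test.chi2,
            p_value=test.p,
            step_index=1,
            n_candidates=n_candidates,
        )
        if best_step is None or _step_key(cand) < _step_key(best_step):
            best_step = cand
    if best_step is None:
        raise ValueError("no informative PAM position (empty background everywhere)")
    steps.append(best_step)

    # --- bidirectional extension
    lo, hi = best_step.start, best_step.start + len(best_step.motif) - 1
    motif = best_step.motif
    step_index = 1
    while lo > 0 or hi < W - 1:
        step_index += 1
        candidates: list[MotifStep] = []
        sides = []
        if lo > 0:
            sides.append(("five", lo - 1))
        if hi < W - 1:
            sides.append(("three", hi + 1))
        n_cand = 4 * len(sides)
        for side, _pos in sides:
            if side == "five":
                start = lo - 1
                motifs = [b + motif for b in "ACGT"]
            else:
                start = lo
                motifs = [motif + b for b in "ACGT"]
            stats_, evs, bg, test = evaluate(start, motifs)
            picked = pick_motif(motifs, stats_, evs, bg)
            if picked is None:
                continue
            m, s, b, e = picked
            candidates.append(
                MotifStep(
                    motif=m,
                    positions=_display_positions(start, len(m), orientation, W),
                    start=start,
                    edited_sites=s,
                    total_sites=b,
                    edited_value=e.value,
                    chi2_stat=test.chi2,
                    p_value=test.p,
                    step_index=step_index,
                    n_candidates=n_cand,
                )
            )
        if not candidates:
            break
        chosen = min(candidates, key=_step_key)
        steps.append(chosen)
        lo, hi = chosen.start, chosen.start + len(chosen.motif) - 1
        motif = chosen.motif

    retained: list[MotifStep] = []
    last_frac = 0.0
    for s in steps:
        significant = (not math.isnan(s.p_value)) and s.p_value <= alpha / s.n_candidates
        if significant and s.edited_fraction > last_frac:
            retained.append(s)
            last_frac = s.edited_fraction
    table = GenomePamTable(
        steps=steps, retained=retained, alpha=alpha, orientation=orientation.value
    )
    log.info(
        "seed_extend: %d step(s), retained %s",
        len(steps),
        [f"{s.motif}@{s.positions}" for s in retained] or "none",
    )
    return table


def _step_key(step: MotifStep):
    """Ordering for step selection: smaller p, then higher percent, then motif."""
    p = step.p_value if not math.isnan(step.p_value) else math.inf
    return (p, -step.edited_fraction, step.motif)
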