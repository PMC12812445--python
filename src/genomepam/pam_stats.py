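"""PAM-preference summaries: weighted frequency matrices, PCV, heat maps.

The PAM cleavage value (PCV) of an L-mer is the fraction it represents
among captured PAM-window sequences (read-weighted by default) divided by
its fraction among the background population of candidate genomic target
flanks.  The relative PCV is log2(PCV) normalized so the top PAM is 0.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _scan
from .io_core import SiteTable
from .site_matching import PamOrientation, pam_flank, pam_position_index, parse_orientation

log = logging.getLogger("genomepam")

BASES = "ACGT"


@dataclass
class WeightedPfm:
    """Read-weighted position frequency matrix over the PAM-side flank."""

    matrix: np.ndarray  # 4 x W, rows A,C,G,T; columns sum to 1
    weights_used: str  # "reads" or "sites"
    stratum: str  # "perfect", "mismatch" or "all"
    n_sites: int
    total_reads: int

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (for logo scaling)."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=0)
        return 2.0 - h


def weighted_pfm(
    sites: SiteTable,
    orientation: str | PamOrientation,
    stratum: str = "all",
    weight_mode: str = "reads",
) -> WeightedPfm:
    """PAM-flank base frequencies weighted by read counts (or site counts)."""
    orientation = parse_orientation(orientation)
    if weight_mode not in ("reads", "sites"):
        raise ValueError(f"weight_mode must be 'reads' or 'sites', got {weight_mode!r}")
    sub = sites.subset(stratum)
    if len(sub) == 0:
        raise ValueError(f"stratum {stratum!r} contains no sites")
    flanks = [pam_flank(s, orientation) for s in sub]
    w = np.array(
        [s.read_count for s in sub] if weight_mode == "reads" else [1] * len(sub),
        dtype=float,
    )
    codes = np.vstack([_scan.encode(f) for f in flanks])
    width = codes.shape[1]
    mat = np.zeros((4, width), dtype=float)
    for b in range(4):
        mat[b] = ((codes == b) * w[:, None]).sum(axis=0)
    mat /= mat.sum(axis=0, keepdims=True)
    return WeightedPfm(
        matrix=mat,
        weights_used=weight_mode,
        stratum=stratum,
        n_sites=len(sub),
        total_reads=sub.total_reads,
    )


def pam_window_slice(flank: str, L: int, window_offset: int, orientation: PamOrientation) -> str:
    """The L consecutive PAM positions starting ``window_offset`` bases from the spacer.

    For a 3' PAM this is flank positions 1+offset .. L+offset; for a 5'
    PAM, positions -(offset+L) .. -(offset+1) — in both cases counted
    outward from the spacer-proximal flank end.
    """
    if window_offset + L > len(flank):
        raise ValueError("PAM window exceeds flank width")
    if orientation.value == "three_prime":
        return flank[window_offset : window_offset + L]
    n = len(flank)
    return flank[n - window_offset - L : n - window_offset]


@dataclass
class PcvTable:
    """Per-PAM captured/background fractions, PCV and relative PCV."""

    pam_len: int
    table: pd.DataFrame  # columns: pam, captured_fraction, background_fraction, pcv, relative_pcv
    orientation: str
    window_offset: int

    def pcv(self, pam: str) -> float:
        row = self.table.loc[self.table["pam"] == pam, "pcv"]
        if row.empty:
            raise KeyError(pam)
        return float(row.iloc[0])

    def top_pams(self, n: int = 1) -> list[str]:
        defined = self.table.dropna(subset=["pcv"])
        return defined.sort_values(["pcv", "pam"], ascending=[False, True])["pam"].head(n).tolist()


def pcv_table(
    sites: SiteTable,
    background_pams: list[str] | Counter,
    L: int,
    orientation: str | PamOrientation = "three_prime",
    window_offset: int = 0,
    weight_mode: str = "reads",
    pseudocount: float = 0.0,
) -> PcvTable:
    """PCV of every observed L-mer PAM against the genomic background.

    ``background_pams`` is the multiset of L-mers at the same window
    offset in the PAM flanks of all candidate genomic targets.  PAMs
    absent from the background get an undefined (NaN) PCV; PAMs captured
    with zero weight get relative PCV -inf (rendered as missing on
    export).
    """
    orientation = parse_orientation(orientation)
    if L > 10:
        raise ValueError("PAM length must be <= flank width (10)")
    bg = Counter(background_pams)
    if not bg:
        raise ValueError("background PAM population is empty")
    if any(len(p) != L for p in bg):
        raise ValueError("background L-mers have wrong length")

    cap: Counter = Counter()
    for s in sites:
        pam = pam_window_slice(pam_flank(s, orientation), L, window_offset, orientation)
        cap[pam] += s.read_count if weight_mode == "reads" else 1

    if pseudocount:
        for p in bg:
            cap[p] += pseudocount

    cap_total = sum(cap.values())
    bg_total = sum(bg.values())
    pams = sorted(set(bg) | set(cap))
    rows = []
    for p in pams:
        cf = cap.get(p, 0) / cap_total
        bf = bg.get(p, 0) / bg_total
        pcv = cf / bf if bf > 0 else np.nan  # undefined, not infinite
        rows.append({"pam": p, "captured_fraction": cf, "background_fraction": bf, "pcv": pcv})
        if bf == 0 and cf > 0:
            log.warning("pcv_table: PAM %s captured but absent from background", p)
    df = pd.DataFrame(rows)
    max_pcv = df["pcv"].max(skipna=True)
    with np.errstate(divide="ignore"):
        df["relative_pcv"] = np.log2(df["pcv"] / max_pcv)
    return PcvTable(pam_len=L, table=df, orientation=orientation.value, window_offset=window_offset)


def heatmap_matrix(pcv: PcvTable) -> pd.DataFrame:
    """16 x 16 grid of relative PCV for a 4-base PAM window.

    Rows are PAM positions 1-2, columns positions 3-4, both lexicographic
    AA..TT; undefined cells are NaN.
    """
    if pcv.pam_len != 4:
        raise ValueError("heat map requires a 4-base PAM table")
    dimers = [a + b for a in BASES for b in BASES]
    grid = pd.DataFrame(np.nan, index=dimers, columns=dimers)
    for row in pcv.table.itertuples(index=False):
        val = row.relative_pcv
        if np.isfinite(val):
            grid.loc[row.pam[:2], row.pam[2:]] = val
    return grid


def wobble_comparison(
    sites: SiteTable,
    position: int,
    base: str,
    orientation: str | PamOrientation = "three_prime",
) -> dict[str, float]:
    """Compare a PAM base's prevalence between perfect and mismatch strata.

    Returns the read-weighted fraction of ``base`` at the given PAM
    position in each stratum and the two-sided Pearson chi-square p-value
    on the 2x2 site-count table (base vs not-base x perfect vs mismatch).
    """
    orientation = parse_orientation(orientation)
    idx = pam_position_index(position, orientation)
    base = base.upper()
    counts = np.zeros((2, 2), dtype=float)  # rows: stratum; cols: base / not-base
    frac = {}
    for si, stratum in enumerate(("perfect", "mismatch")):
        sub = sites.subset(stratum)
        if len(sub) == 0:
            raise ValueError(f"stratum {stratum!r} contains no sites")
        hits = np.array([pam_flank(s, orientation)[idx] == base for s in sub])
        reads = np.array([s.read_count for s in sub], dtype=float)
        frac[f"{stratum}_frac"] = float(reads[hits].sum() / reads.sum())
        counts[si, 0] = hits.sum()
        counts[si, 1] = (~hits).sum()
    if counts.any(axis=0).all():
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    else:  # one column empty: no information
        chi2, p = 0.0, 1.0
    return {**frac, "chi2": float(chi2), "p_value": float(p)}


def plot_logo(pfm: WeightedPfm, path: str, title: str = "") -> None:
    """Render an information-content-scaled sequence logo (thin display layer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    ic = pfm.information_content()
    fig, ax = plt.subplots(figsize=(max(4, pfm.width * 0.6), 2.5))
    for j in range(pfm.width):
        heights = sorted(
            ((pfm.matrix[b, j] * ic[j], BASES[b]) for b in range(4)), key=lambda t: t[0]
        )
        y = 0.0
        for h, letter in heights:
            if h <= 0:
                continue
            tp = TextPath((0, 0), letter, size=1.0, prop=fp)
            bb = tp.get_extents()
            tr = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(j + 0.05, y)
            )
            ax.add_patch(PathPatch(tp.transformed(tr), color=colors[letter], lw=0))
            y += h
    ax.set_xlim(0, pfm.width)
    ax.set_ylim(0, 2)
    ax.set_xticks(np.arange(pfm.width) + 0.5)
    ax.set_xticklabels(range(1, pfm.width + 1))
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
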