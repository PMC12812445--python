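"""Cross-enzyme and cross-cell-line comparisons.

On/off-target site and read ratios, read-downsampling discovery curves
(multivariate hypergeometric draws from the site x read-count table),
relative activity/specificity against reference enzymes, and 5-Mb-window
read-proportion profiles with log2 ratios against a reference cell line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import SiteTable

log = logging.getLogger("genomepam")


@dataclass
class EnzymeSummary:
    """Perfect/mismatch site and read totals with their ratios.

    Ratios are NaN (undefined, not infinite) when the denominator is 0.
    """

    label: str
    n_on_sites: int
    n_off_sites: int
    on_reads: int
    off_reads: int

    @property
    def site_ratio(self) -> float:
        return self.n_on_sites / self.n_off_sites if self.n_off_sites else math.nan

    @property
    def read_ratio(self) -> float:
        return self.on_reads / self.off_reads if self.off_reads else math.nan


def enzyme_summary(sites: SiteTable, label: str | None = None) -> EnzymeSummary:
    """On/off-target site and read totals of one cleavage-site table."""
    if len(sites) == 0:
        raise ValueError("empty site table")
    on = [s for s in sites if s.match_class == "perfect"]
    off = [s for s in sites if s.match_class == "mismatch"]
    summ = EnzymeSummary(
        label=label if label is not None else sites.provenance,
        n_on_sites=len(on),
        n_off_sites=len(off),
        on_reads=sum(s.read_count for s in on),
        off_reads=sum(s.read_count for s in off),
    )
    if summ.n_off_sites == 0:
        log.warning("enzyme_summary[%s]: no mismatch sites — ratios undefined", summ.label)
    return summ


def downsample_curve(
    sites: SiteTable,
    depths: list[int],
    n_reps: int = 100,
    seed: int = 0,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Mean on/off-target site discovery at each sequencing depth.

    Reads are drawn without replacement from the pooled site-read multiset
    (multivariate hypergeometric); a site is detected at a depth when its
    sampled reads reach ``min_reads``.  Returns a frame with columns
    depth, mean_on_sites, mean_off_sites, mean_total_sites.
    """
    total = sites.total_reads
    if any(d > total for d in depths):
        raise ValueError(f"depth exceeds total reads ({total}) for without-replacement sampling")
    if any(d < 0 for d in depths):
        raise ValueError("depths must be nonnegative")
    colors = np.array([s.read_count for s in sites], dtype=np.int64)
    is_on = np.array([s.match_class == "perfect" for s in sites])
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        on_counts = np.empty(n_reps)
        off_counts = np.empty(n_reps)
        for rep in range(n_reps):
            drawn = rng.multivariate_hypergeometric(colors, depth)
            detected = drawn >= min_reads
            on_counts[rep] = (detected & is_on).sum()
            off_counts[rep] = (detected & ~is_on).sum()
        rows.append(
            {
                "depth": depth,
                "mean_on_sites": float(on_counts.mean()),
                "mean_off_sites": float(off_counts.mean()),
                "mean_total_sites": float((on_counts + off_counts).mean()),
            }
        )
    return pd.DataFrame(rows)


def activity_specificity(
    summaries: list[EnzymeSummary], wt_label: str, specificity_ref_label: str
) -> pd.DataFrame:
    """Relative activity and specificity per enzyme.

    Relative activity is the perfect-match site count over that of the
    wild-type reference; relative specificity is the perfect/mismatch
    site-count ratio over that of the high-fidelity reference.
    """
    by_label = {s.label: s for s in summaries}
    for ref in (wt_label, specificity_ref_label):
        if ref not in by_label:
            raise ValueError(f"reference enzyme {ref!r} not among summaries")
    wt = by_label[wt_label]
    spec_ref = by_label[specificity_ref_label]
    if wt.n_on_sites == 0:
        raise ValueError(f"{wt_label!r} has zero perfect-match sites")
    if not math.isfinite(spec_ref.site_ratio) or spec_ref.site_ratio == 0:
        raise ValueError(f"{specificity_ref_label!r} has an undefined on/off ratio")
    rows = []
    for s in summaries:
        rows.append(
            {
                "label": s.label,
                "n_on_sites": s.n_on_sites,
                "n_off_sites": s.n_off_sites,
                "site_ratio": s.site_ratio,
                "read_ratio": s.read_ratio,
                "relative_activity": s.n_on_sites / wt.n_on_sites,
                "relative_specificity": s.site_ratio / spec_ref.site_ratio,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class WindowProfile:
    """Per-window cleavage-read proportions of one sample."""

    label: str
    window_size: int
    windows: pd.DataFrame  # columns: chrom, window_start, reads, proportion

    @property
    def proportions(self) -> np.ndarray:
        return self.windows["proportion"].to_numpy()


def window_profile(
    sites: SiteTable,
    genome_lengths: dict[str, int],
    window: int = 5_000_000,
    label: str | None = None,
) -> WindowProfile:
    """Read proportion per fixed-size chromosomal window.

    Every window of every chromosome appears (the last one may be short);
    a site's reads all fall in the window containing its protospacer
    start; proportions are normalized to sum to 1 over the genome.
    """
    window = int(window)
    rows = []
    index: dict[tuple[str, int], int] = {}
    for chrom, length in genome_lengths.items():
        for wstart in range(0, max(length, 1), window):
            index[(chrom, wstart)] = len(rows)
            rows.append({"chrom": chrom, "window_start": wstart, "reads": 0})
    for s in sites:
        if s.chrom not in genome_lengths:
            raise ValueError(f"site chromosome {s.chrom!r} missing from genome_lengths")
        wstart = (s.start // window) * window
        rows[index[(s.chrom, wstart)]]["reads"] += s.read_count
    df = pd.DataFrame(rows)
    total = df["reads"].sum()
    if total == 0:
        raise ValueError("no reads in any window")
    df["proportion"] = df["reads"] / total
    return WindowProfile(
        label=label if label is not None else sites.provenance,
        window_size=window,
        windows=df,
    )


def profile_ratio(
    sample: WindowProfile, reference_replicates: list[WindowProfile]
) -> pd.DataFrame:
    """log2 of sample window proportions over the mean reference proportions.

    Windows where the reference mean is 0 come out as NaN (missing).
    Returns columns chrom, window_start, proportion, reference_proportion,
    log2_ratio.
    """
    if not reference_replicates:
        raise ValueError("need at least one reference replicate")
    base = sample.windows[["chrom", "window_start", "proportion"]].copy()
    ref = np.mean([r.proportions for r in reference_replicates], axis=0)
    if len(ref) != len(base):
        raise ValueError("reference profiles have different windowing than the sample")
    base["reference_proportion"] = ref
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref > 0, base["proportion"].to_numpy() / ref, np.nan)
        base["log2_ratio"] = np.log2(ratio, out=np.full(len(ref), np.nan), where=ratio > 0)
    # a window with zero sample reads over a nonzero reference is -inf; keep NaN for ref==0 only
    zero_over_ref = (base["proportion"] == 0) & (base["reference_proportion"] > 0)
    base.loc[zero_over_ref, "log2_ratio"] = -np.inf
    return base
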