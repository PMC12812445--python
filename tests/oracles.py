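"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's scanning code paths: plain string
slicing over both strands, and a hand-written Pearson chi-square.
"""

from collections import Counter

from scipy.stats import chi2 as chi2_dist

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def naive_kmer_census(records: dict[str, str], k: int) -> dict[str, int]:
    """counts[w] = windows reading w on either strand (N windows skipped)."""
    counts: Counter = Counter()
    for seq in records.values():
        for strand_seq in (seq, rc(seq)):
            for i in range(len(strand_seq) - k + 1):
                w = strand_seq[i : i + k]
                if "N" not in w:
                    counts[w] += 1
    return dict(counts)


def naive_mismatch_census(records: dict[str, str], spacer: str, max_d: int) -> dict[int, int]:
    """Window counts by exact Hamming distance, both strands, N skipped."""
    k = len(spacer)
    bins = {d: 0 for d in range(max_d + 1)}
    for seq in records.values():
        for strand_seq in (seq, rc(seq)):
            for i in range(len(strand_seq) - k + 1):
                w = strand_seq[i : i + k]
                if "N" in w:
                    continue
                d = sum(a != b for a, b in zip(w, spacer))
                if d <= max_d:
                    bins[d] += 1
    return bins


def naive_gof_chi_square(observed: list[int], background: list[int]) -> tuple[float, float, int]:
    """Textbook goodness-of-fit chi-square: expected proportional to background."""
    total_obs = sum(observed)
    total_bg = sum(background)
    stat = 0.0
    for o, b in zip(observed, background):
        e = total_obs * b / total_bg
        stat += (o - e) ** 2 / e
    df = len(observed) - 1
    return stat, float(chi2_dist.sf(stat, df)), df


def naive_chi_square(table: list[list[int]]) -> tuple[float, float, int]:
    """Textbook Pearson chi-square on an r x c count table."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    row_sums = [sum(r) for r in table]
    col_sums = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sums[i] * col_sums[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    df = (rows - 1) * (cols - 1)
    p = float(chi2_dist.sf(stat, df))
    return stat, p, df
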