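import numpy as np
import pytest

from genomepam import (
    FIVE_PRIME,
    THREE_PRIME,
    GenomeSequence,
    assign_integrations,
    find_genomic_targets,
    pam_flank,
    revcomp,
)
from genomepam.site_matching import pam_position_index, parse_orientation

from .conftest import random_genome

SPACER = "GTGAGCCACTGTGCCTGGCC"


def plant(rng, n_perfect, n_mismatch, mm_positions=(8, 9, 10, 11)):
    """Background genome with planted exact/variant spacer copies + flanks."""
    pieces = []
    truth = []
    cursor = 0
    for i in range(n_perfect + n_mismatch):
        gap = "".join(rng.choice(list("ACGT"), 60))
        aligned = SPACER
        n_mm = 0
        if i >= n_perfect:
            n_mm = int(rng.integers(1, 3))
            chosen = rng.choice(mm_positions, size=n_mm, replace=False)
            s = list(SPACER)
            for p in chosen:
                s[p - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p - 1]]
            aligned = "".join(s)
        flank5 = "".join(rng.choice(list("ACGT"), 10))
        flank3 = "".join(rng.choice(list("ACGT"), 10))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = flank5 + aligned + flank3
        pieces.append(gap)
        cursor += len(gap)
        start = cursor + 10
        truth.append((start, strand, aligned, n_mm, flank5, flank3))
        pieces.append(frag if strand == "+" else revcomp(frag))
        cursor += len(frag)
    pieces.append("".join(rng.choice(list("ACGT"), 60)))
    return GenomeSequence({"chrP": "".join(pieces)}), truth


class TestFindGenomicTargets:
    def test_planted_truth_recovered(self):
        rng = np.random.default_rng(41)
        genome, truth = plant(rng, n_perfect=5, n_mismatch=3)
        hits = find_genomic_targets(genome, SPACER, max_mm=2)
        assert len(hits) == 8
        classes = [h.match_class for h in hits]
        assert classes.count("perfect") == 5
        assert classes.count("mismatch") == 3
        by_start = {h.start: h for h in hits}
        for start, strand, aligned, n_mm, flank5, flank3 in truth:
            h = by_start[start]
            assert (h.strand, h.aligned_seq, h.n_mismatch) == (strand, aligned, n_mm)
            assert (h.flank5, h.flank3) == (flank5, flank3)

    def test_max_mm_zero_only_exact(self):
        rng = np.random.default_rng(43)
        genome, _ = plant(rng, n_perfect=4, n_mismatch=4)
        hits = find_genomic_targets(genome, SPACER, max_mm=0)
        assert len(hits) == 4
        assert all(h.n_mismatch == 0 for h in hits)

    def test_self_consistency_hamming_from_genome(self):
        rng = np.random.default_rng(47)
        genome, _ = plant(rng, n_perfect=3, n_mismatch=5)
        for h in find_genomic_targets(genome, SPACER, max_mm=6):
            window = genome.records[h.chrom][h.start : h.end]
            if h.strand == "-":
                window = revcomp(window)
            assert window == h.aligned_seq
            d = sum(a != b for a, b in zip(window, SPACER))
            assert d == h.n_mismatch
            assert len(h.mismatch_positions) == d

    def test_iupac_y_never_counts_as_mismatch(self):
        # 21-nt spacer with a 5' Y: genomic C or T at position 1 is a match
        for first in "CT":
            genome = GenomeSequence(
                {"c": "A" * 12 + first + SPACER + "G" * 12}
            )
            hits = find_genomic_targets(genome, "Y" + SPACER, max_mm=0)
            assert len(hits) == 1
            assert hits[0].n_mismatch == 0
        genome = GenomeSequence({"c": "A" * 12 + "G" + SPACER + "G" * 12})
        hits = find_genomic_targets(genome, "Y" + SPACER, max_mm=1)
        assert hits and hits[0].n_mismatch == 1 and hits[0].mismatch_positions == (1,)

    def test_rc_genome_swaps_strands_only(self):
        rng = np.random.default_rng(53)
        genome, _ = plant(rng, n_perfect=4, n_mismatch=2)
        fwd = find_genomic_targets(genome, SPACER, max_mm=2)
        rc = find_genomic_targets(genome.reverse_complement(), SPACER, max_mm=2)
        a = sorted((h.aligned_seq, h.flank5, h.flank3, h.n_mismatch) for h in fwd)
        b = sorted((h.aligned_seq, h.flank5, h.flank3, h.n_mismatch) for h in rc)
        assert a == b
        assert sorted(h.strand for h in fwd) == sorted(
            {"+": "-", "-": "+"}[h.strand] for h in rc
        )

    def test_non_iupac_spacer_rejected(self, tiny_genome):
        with pytest.raises(ValueError, match="unsupported"):
            find_genomic_targets(tiny_genome, "ACGX", max_mm=0)

    def test_n_window_skipped(self):
        genome = GenomeSequence({"c": "A" * 12 + SPACER[:10] + "N" + SPACER[11:] + "G" * 12})
        assert find_genomic_targets(genome, SPACER, max_mm=6) == []


class TestAssignIntegrations:
    def test_basic_assignment_and_additivity(self):
        rng = np.random.default_rng(59)
        genome, _ = plant(rng, n_perfect=2, n_mismatch=0)
        templates = find_genomic_targets(genome, SPACER, max_mm=0)
        t0 = templates[0]
        events = [(t0.chrom, t0.start + 5, 3), (t0.chrom, t0.end + 10, 7)]
        table, unassigned = assign_integrations(templates, events, window=25)
        assert len(table) == 1
        assert table.sites[0].read_count == 10
        assert unassigned == []
        assert table.total_reads == 10  # read conservation

    def test_far_event_unassigned(self):
        rng = np.random.default_rng(61)
        genome, _ = plant(rng, n_perfect=1, n_mismatch=0)
        templates = find_genomic_targets(genome, SPACER, max_mm=0)
        ev = (templates[0].chrom, templates[0].start + 500, 4)
        table, unassigned = assign_integrations(templates, [ev], window=25)
        assert len(table) == 0
        assert unassigned == [ev]

    def test_zero_event_templates_dropped(self):
        rng = np.random.default_rng(67)
        genome, _ = plant(rng, n_perfect=3, n_mismatch=0)
        templates = find_genomic_targets(genome, SPACER, max_mm=0)
        t = templates[1]
        table, _ = assign_integrations(templates, [(t.chrom, t.start, 2)], window=25)
        assert [s.start for s in table] == [t.start]

    def test_nonpositive_reads_rejected(self):
        with pytest.raises(ValueError, match="read count"):
            assign_integrations([], [("chr1", 5, 0)], window=25)


class TestPamFlank:
    def test_orientation_selects_flank(self, ngg_run):
        _, _, _, sites, _ = ngg_run
        s = sites.sites[0]
        assert pam_flank(s, THREE_PRIME) == s.flank3
        assert pam_flank(s, FIVE_PRIME) == s.flank5

    def test_position_numbering_contract(self):
        # 3' position 1 is adjacent to the spacer; 5' position -1 is adjacent
        assert pam_position_index(1, THREE_PRIME) == 0
        assert pam_position_index(10, THREE_PRIME) == 9
        assert pam_position_index(-1, FIVE_PRIME) == 9
        assert pam_position_index(-3, FIVE_PRIME) == 7
        assert pam_position_index(-10, FIVE_PRIME) == 0
        with pytest.raises(ValueError):
            pam_position_index(0, THREE_PRIME)
        with pytest.raises(ValueError):
            pam_position_index(1, FIVE_PRIME)

    def test_parse_orientation_aliases(self):
        assert parse_orientation("3p") is THREE_PRIME
        assert parse_orientation("five_prime") is FIVE_PRIME
        with pytest.raises(ValueError):
            parse_orientation("sideways")
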