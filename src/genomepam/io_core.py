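"""Readers/writers for the formats the pipeline touches, plus core containers.

Coordinates are 0-based half-open everywhere; any 1-based display is
formatting only.  Genome sequences are uppercase over {A, C, G, T, N};
other IUPAC ambiguity codes are collapsed to N on load.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("genomepam")

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")
_AMBIGUITY_TO_N = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNN")

#: canonical site-table column order
SITE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "aligned_seq",
    "n_mismatch",
    "mismatch_positions",
    "flank5",
    "flank3",
    "read_count",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Named chromosome sequences with uppercase ACGTN content."""

    records: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records.items())

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence({name: revcomp(seq) for name, seq in self.records.items()})


def _clean_sequence(raw: str, name: str) -> str:
    seq = raw.upper().translate(_AMBIGUITY_TO_N)
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"record {name!r} contains non-IUPAC characters: {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Lowercase is uppercased; IUPAC ambiguity codes become N; duplicate
    record names and empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ValueError(f"{path}: line 1 is not a FASTA header: {first.strip()!r}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record name {rec.id!r}")
        records[rec.id] = _clean_sequence(str(rec.seq), rec.id)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    genome = GenomeSequence(records)
    log.info("read_fasta: %s — %d record(s), %d bases", path, len(records), genome.total_length)
    return genome


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class CleavageSite:
    """One protospacer-aligned genomic target with its cleavage evidence.

    ``start``/``end`` bound the protospacer interval (0-based half-open);
    ``aligned_seq`` and the two 10-mer flanks are reported in protospacer
    orientation.  ``mismatch_positions`` are 1-based spacer positions.
    """

    chrom: str
    start: int
    end: int
    strand: str
    aligned_seq: str
    n_mismatch: int
    mismatch_positions: tuple[int, ...]
    flank5: str
    flank3: str
    read_count: int = 1

    @property
    def match_class(self) -> str:
        return "perfect" if self.n_mismatch == 0 else "mismatch"

    def with_reads(self, read_count: int) -> "CleavageSite":
        return replace(self, read_count=read_count)


class SiteTable:
    """Ordered collection of :class:`CleavageSite` rows with a provenance label.

    Invariants: every read_count >= 1 and (chrom, start, strand) unique.
    """

    def __init__(self, sites: Iterable[CleavageSite], provenance: str = ""):
        self.sites: list[CleavageSite] = list(sites)
        self.provenance = provenance
        self._validate()

    def _validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for s in self.sites:
            if s.read_count < 1:
                raise ValueError(
                    f"read_count must be >= 1, got {s.read_count} at {s.chrom}:{s.start}"
                )
            key = (s.chrom, s.start, s.strand)
            if key in seen:
                raise ValueError(f"duplicate site {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[CleavageSite]:
        return iter(self.sites)

    @property
    def total_reads(self) -> int:
        return sum(s.read_count for s in self.sites)

    def subset(self, stratum: str) -> "SiteTable":
        """Rows of one match class: 'perfect', 'mismatch' or 'all'."""
        if stratum == "all":
            return self
        if stratum not in ("perfect", "mismatch"):
            raise ValueError(f"unknown stratum {stratum!r}")
        return SiteTable(
            [s for s in self.sites if s.match_class == stratum],
            provenance=f"{self.provenance}[{stratum}]",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "strand": s.strand,
                    "aligned_seq": s.aligned_seq,
                    "n_mismatch": s.n_mismatch,
                    "mismatch_positions": ",".join(str(p) for p in s.mismatch_positions),
                    "flank5": s.flank5,
                    "flank3": s.flank3,
                    "read_count": s.read_count,
                }
            )
        return pd.DataFrame(rows, columns=SITE_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "SiteTable":
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"site table missing required column(s): {missing}")
        sites = []
        for row in df.itertuples(index=False):
            rc = row.read_count
            if isinstance(rc, float) and not float(rc).is_integer():
                raise ValueError(f"read_count must be an integer, got {rc!r}")
            mp = row.mismatch_positions
            if pd.isna(mp) or mp == "":
                positions: tuple[int, ...] = ()
            else:
                positions = tuple(int(p) for p in str(mp).split(","))
            sites.append(
                CleavageSite(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    aligned_seq=str(row.aligned_seq),
                    n_mismatch=int(row.n_mismatch),
                    mismatch_positions=positions,
                    flank5=str(row.flank5),
                    flank3=str(row.flank3),
                    read_count=int(rc),
                )
            )
        return cls(sites, provenance=provenance)


def read_site_table(path: str | Path, provenance: str | None = None) -> SiteTable:
    """Read the canonical tab-separated site table (``#`` lines are comments)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"mismatch_positions": str},
        keep_default_na=False,
        na_values=[],
    )
    table = SiteTable.from_frame(df, provenance=provenance if provenance is not None else path.stem)
    log.info("read_site_table: %s — %d site(s), %d reads", path, len(table), table.total_reads)
    return table


def write_site_table(table: SiteTable, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a site table as TSV; optional ``header_lines`` become # comments."""
    buf = io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    table.to_frame().to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
    log.info("write_site_table: %s — %d site(s)", path, len(table))
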