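"""Sequence/site I/O and the site-relative coordinate convention.

Every downstream analysis works on fixed-length genomic windows anchored at a
poly(A) site: 300 nt upstream and 100 nt downstream of the cleavage position,
which is position -1 of the window.  There is no position 0; position +1 is
the first base downstream of the cleavage site.  Array index ``i`` of a
window maps to position ``i - 300`` for ``i < 300`` and ``i - 299`` for
``i >= 300``, so index 299 is position -1 and index 300 is position +1.

Sequences are held as DNA (T) internally; motifs and reports use the RNA
alphabet (U), matching how polyadenylation signals are written in the
literature.  :func:`to_rna` / :func:`to_dna` convert between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

UPSTREAM = 300
DOWNSTREAM = 100
WINDOW_LENGTH = UPSTREAM + DOWNSTREAM

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PolyasigError(ValueError):
    """Base class for user-facing errors raised by this package."""


def to_dna(s: str) -> str:
    """Normalize a nucleotide string to uppercase DNA (U -> T)."""
    return s.upper().replace("U", "T")


def to_rna(s: str) -> str:
    """Convert an internal DNA string to the RNA alphabet used in reports."""
    return s.upper().replace("T", "U")


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def normalize_sequence(s: str, *, context: str = "") -> str:
    """Uppercase, map U->T and any other IUPAC/unknown letter to N."""
    s = to_dna(s)
    if set(s) <= _DNA_ALPHABET:
        return s
    cleaned = "".join(c if c in _DNA_ALPHABET else "N" for c in s)
    n_mapped = sum(1 for a, b in zip(s, cleaned) if a != b)
    logger.warning(
        "%s: %d non-ACGTN character(s) mapped to N", context or "sequence", n_mapped
    )
    return cleaned


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: id plus DNA sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PolyasigError(f"contig {self.contig_id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class PolyASite:
    """A cleavage site: 1-based genomic coordinate of the base at position -1."""

    contig_id: str
    coord: int
    strand: str
    support: int = 1

    def __post_init__(self) -> None:
        if self.coord < 1:
            raise PolyasigError(f"site coordinate must be >= 1, got {self.coord}")
        if self.strand not in ("+", "-"):
            raise PolyasigError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.support < 1:
            raise PolyasigError(f"support must be >= 1, got {self.support}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig_id, self.coord, self.strand)


@dataclass(frozen=True)
class SiteWindow:
    """A 400-nt strand-corrected window around one poly(A) site.

    ``sequence`` reads 5'->3' of the transcript; the cleavage base (position
    -1) sits at index 299.
    """

    site: PolyASite
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise PolyasigError(
                f"window must be {WINDOW_LENGTH} nt, got {len(self.sequence)}"
            )

    def at(self, pos: int) -> str:
        """Base at a site-relative position (no position 0)."""
        return self.sequence[pos_to_index(pos)]

    def slice(self, region: "Region") -> str:
        i0, i1 = region.index_span()
        return self.sequence[i0 : i1 + 1]


def pos_to_index(pos: int) -> int:
    """Site-relative position -> window index (-300..-1,+1..+100 -> 0..399)."""
    if -UPSTREAM <= pos <= -1:
        return pos + UPSTREAM
    if 1 <= pos <= DOWNSTREAM:
        return pos + UPSTREAM - 1
    raise PolyasigError(
        f"position {pos} outside [-{UPSTREAM},-1] U [+1,+{DOWNSTREAM}] (no position 0)"
    )


def index_to_pos(index: int) -> int:
    """Window index -> site-relative position (inverse of :func:`pos_to_index`)."""
    if not 0 <= index < WINDOW_LENGTH:
        raise PolyasigError(f"index {index} outside [0,{WINDOW_LENGTH})")
    return index - UPSTREAM if index < UPSTREAM else index - UPSTREAM + 1


@dataclass(frozen=True)
class Region:
    """A labeled inclusive site-relative interval (start <= end, neither 0)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        for p in (self.start, self.end):
            if p == 0 or not (-UPSTREAM <= p <= DOWNSTREAM):
                raise PolyasigError(f"region bound {p} invalid (no 0; within window)")
        if self.start > self.end:
            raise PolyasigError(f"region start {self.start} > end {self.end}")

    def index_span(self) -> tuple[int, int]:
        return pos_to_index(self.start), pos_to_index(self.end)

    def __len__(self) -> int:
        i0, i1 = self.index_span()
        return i1 - i0 + 1

    def positions(self) -> list[int]:
        i0, i1 = self.index_span()
        return [index_to_pos(i) for i in range(i0, i1 + 1)]

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end and pos != 0


CE_DEFAULT = Region("CE", -10, 10)


# ---------------------------------------------------------------------------
# readers / writers


def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a FASTA genome into a dict keyed by contig id.

    Contig ids are the first whitespace-delimited header token.  Lowercase is
    uppercased; IUPAC codes other than ACGT become N (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise PolyasigError(f"genome file not found: {path}")
    genomes: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genomes:
            raise PolyasigError(f"duplicate contig ID in {path}: {rec.id!r}")
        seq = normalize_sequence(str(rec.seq), context=f"contig {rec.id}")
        genomes[rec.id] = GenomeSequence(rec.id, seq)
    if not genomes:
        raise PolyasigError(f"no FASTA records in {path}")
    return genomes


def read_sites(path: str | Path, dialect: str = "tsv") -> list[PolyASite]:
    """Read a poly(A)-site table.

    ``dialect="tsv"``: whitespace-delimited columns contig, 1-based cleavage
    coordinate, strand, optional EST support count.  ``dialect="bed"``: BED6
    (0-based half-open); the cleavage coordinate is the interval end, i.e. the
    last covered base in 1-based terms, with strand in column 6 and the score
    column ignored.
    """
    path = Path(path)
    if not path.exists():
        raise PolyasigError(f"site table not found: {path}")
    if dialect not in ("tsv", "bed"):
        raise PolyasigError(f"unknown site-table dialect {dialect!r}")
    sites: list[PolyASite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if lineno == 1 and line.split()[:3] == ["contig", "coord", "strand"]:
                continue  # header written by write_sites
            fields = line.split()
            try:
                if dialect == "bed":
                    if len(fields) < 6:
                        raise PolyasigError("BED dialect needs 6 columns")
                    contig, _start, end, _name, _score, strand = fields[:6]
                    coord = int(end)
                    support = 1
                else:
                    contig, coord_s, strand = fields[:3]
                    coord = int(coord_s)
                    support = int(fields[3]) if len(fields) > 3 else 1
            except (ValueError, IndexError) as exc:
                raise PolyasigError(f"{path}:{lineno}: malformed site row: {exc}")
            sites.append(PolyASite(contig, coord, strand, support))
    return sites


def write_sites(sites: Iterable[PolyASite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tcoord\tstrand\tsupport\n")
        for s in sites:
            fh.write(f"{s.contig_id}\t{s.coord}\t{s.strand}\t{s.support}\n")


# ---------------------------------------------------------------------------
# window extraction


def extract_window(
    genome: GenomeSequence,
    site: PolyASite,
    up: int = UPSTREAM,
    down: int = DOWNSTREAM,
) -> SiteWindow:
    """Extract the strand-corrected window around one site.

    For strand '+' the window covers genomic 1-based bases
    ``[coord-up+1, coord+down]``; for strand '-' it covers
    ``[coord-down, coord+up-1]`` reverse-complemented, so that in both cases
    the returned sequence reads 5'->3' of the transcript with the cleavage
    base at position -1.  Windows running past a contig end raise; batch
    extraction drops and logs them instead.
    """
    if up != UPSTREAM or down != DOWNSTREAM:
        raise PolyasigError("window geometry is fixed at 300 upstream / 100 downstream")
    if site.contig_id != genome.contig_id:
        raise PolyasigError(
            f"site contig {site.contig_id!r} != genome contig {genome.contig_id!r}"
        )
    L = len(genome.sequence)
    if site.strand == "+":
        lo, hi = site.coord - up + 1, site.coord + down  # 1-based inclusive
    else:
        lo, hi = site.coord - down, site.coord + up - 1
    if lo < 1 or hi > L:
        raise WindowOutOfBounds(
            f"window [{lo},{hi}] outside contig {genome.contig_id} (length {L})"
        )
    seg = genome.sequence[lo - 1 : hi]
    if site.strand == "-":
        seg = reverse_complement(seg)
    return SiteWindow(site, seg)


class WindowOutOfBounds(PolyasigError):
    pass


@dataclass
class ExtractionLog:
    """Per-reason counts of sites dropped during batch extraction."""

    n_input: int = 0
    n_extracted: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def extract_windows(
    genomes: dict[str, GenomeSequence], sites: Sequence[PolyASite]
) -> tuple[list[SiteWindow], ExtractionLog]:
    """Extract windows for many sites; unknown contigs and out-of-bounds
    windows are dropped with counted reasons (counts conserve)."""
    log = ExtractionLog(n_input=len(sites))
    windows: list[SiteWindow] = []
    for site in sites:
        genome = genomes.get(site.contig_id)
        if genome is None:
            log.drop("unknown_contig")
            logger.info("dropped site %s: unknown contig", site.key)
            continue
        try:
            windows.append(extract_window(genome, site))
        except WindowOutOfBounds:
            log.drop("out_of_bounds")
            logger.info("dropped site %s: out_of_bounds", site.key)
    log.n_extracted = len(windows)
    return windows, log


def _header(site: PolyASite) -> str:
    return f"{site.contig_id}:{site.coord}:{site.strand} support={site.support}"


def write_windows(windows: Iterable[SiteWindow], path: str | Path) -> None:
    """Serialize windows as FASTA with headers encoding contig:coord:strand."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{_header(w.site)}\n{w.sequence}\n")


def read_windows(path: str | Path) -> list[SiteWindow]:
    """Read a window FASTA written by :func:`write_windows`."""
    path = Path(path)
    if not path.exists():
        raise PolyasigError(f"window file not found: {path}")
    windows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            contig, coord, strand = rec.id.split(":")
            support = 1
            for tok in rec.description.split()[1:]:
                if tok.startswith("support="):
                    support = int(tok.split("=", 1)[1])
            site = PolyASite(contig, int(coord), strand, support)
        except (ValueError, PolyasigError) as exc:
            raise PolyasigError(f"malformed window header {rec.description!r}: {exc}")
        seq = normalize_sequence(str(rec.seq), context=rec.id)
        windows.append(SiteWindow(site, seq))
    if not windows:
        raise PolyasigError(f"no windows in {path}")
    return windows
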