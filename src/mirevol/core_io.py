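"""Domain types and readers/writers for the formats the pipeline touches.

The internal sequence alphabet is DNA (``T``, never ``U``); RNA input is
converted at the I/O boundary.  All internal coordinates are 0-based
half-open intervals; report output uses 1-based positions (the convention
of the mature-miRNA literature, where position 1 is the 5' end of the
mature strand).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A malformed input file (names the offending record)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert to the internal DNA alphabet (U -> T)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise FormatError(f"invalid characters {sorted(bad)} in sequence {seq!r}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureRecord:
    """One species' experimentally supported mature miRNA (~22 nt)."""

    id: str
    species: str
    sequence: str
    read_depth: int = 0
    source: Optional[tuple] = None  # (hairpin id, start offset in hairpin)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for mature record {self.id}")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.read_depth < 0:
            raise ValueError(f"negative read depth for {self.id}")


@dataclass(frozen=True)
class HairpinRecord:
    """An excised precursor sequence with located mature/loop/star segments.

    ``sequence`` is the excision product: the pre-miRNA hairpin plus a
    short stretch of flanking sequence on each side.  Spans are 0-based
    half-open intervals into ``sequence``.
    """

    id: str
    species: str
    sequence: str
    mature_span: tuple[int, int]
    loop_span: tuple[int, int]
    star_span: tuple[int, int]
    score: float = 0.0
    read_depth: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        n = len(self.sequence)
        for name, (a, b) in (
            ("mature", self.mature_span),
            ("loop", self.loop_span),
            ("star", self.star_span),
        ):
            if not (0 <= a <= b <= n):
                raise ValueError(f"{name} span {(a, b)} outside hairpin {self.id} (len {n})")
        ma, mb = self.mature_span
        sa, sb = self.star_span
        if max(ma, sa) < min(mb, sb):
            raise ValueError(f"mature and star spans overlap in {self.id}")

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_span[0]:self.mature_span[1]]

    @property
    def star(self) -> str:
        return self.sequence[self.star_span[0]:self.star_span[1]]

    @property
    def premirna_span(self) -> tuple[int, int]:
        """Span of the pre-miRNA (mature arm through star arm, incl. loop)."""
        a = min(self.mature_span[0], self.star_span[0])
        b = max(self.mature_span[1], self.star_span[1])
        return (a, b)

    @property
    def premirna(self) -> str:
        a, b = self.premirna_span
        return self.sequence[a:b]


@dataclass(frozen=True)
class PredictionFilter:
    """Inclusion filter for hairpin-prediction rows (score and read depth)."""

    min_score: float = 0.0
    min_depth: int = 3

    def __post_init__(self):
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass(frozen=True)
class RegionScheme:
    """Functional regions of the mature miRNA, 1-based inclusive bounds.

    seed 1-8 (target-recognition core), central 9-12, 3' supplementary
    13-16, tail 17..L.
    """

    seed_end: int = 8
    central_end: int = 12
    supplementary_end: int = 16

    REGIONS = ("seed", "central", "supplementary", "tail")

    def classify(self, position: int) -> str:
        if position < 1:
            raise ValueError(f"position {position} is not 1-based")
        if position <= self.seed_end:
            return "seed"
        if position <= self.central_end:
            return "central"
        if position <= self.supplementary_end:
            return "supplementary"
        return "tail"


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs, order preserved.

    Sequences are uppercased and U->T normalized.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for FASTA record {rec.id!r} in {path}")
        out.append((rec.id, normalize_sequence(seq)))
    return out


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


PREDICTION_COLUMNS = ["id", "species", "score", "depth", "mature", "star", "hairpin"]


def parse_prediction_table(path, filt: PredictionFilter = PredictionFilter()) -> list[HairpinRecord]:
    """Parse a hairpin-prediction TSV into :class:`HairpinRecord` objects.

    Expected columns: id, species, score, depth, mature, star, hairpin.
    Rows failing the score/depth filter are dropped.  The mature and star
    spans are located by exact substring search within the hairpin; on
    multiple occurrences the leftmost is used (with a warning).  Rows whose
    mature is not a substring of the hairpin are skipped and logged.
    """
    records: list[HairpinRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(PREDICTION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"prediction table {path} missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            score = float(row["score"])
            depth = int(row["depth"])
            if score < filt.min_score or depth < filt.min_depth:
                continue
            hairpin = normalize_sequence(row["hairpin"])
            mature = normalize_sequence(row["mature"])
            star = normalize_sequence(row["star"])
            m0 = hairpin.find(mature)
            if m0 < 0:
                logger.error(
                    "row %d (%s): mature not found in hairpin; row skipped", i, row["id"]
                )
                continue
            if hairpin.find(mature, m0 + 1) >= 0:
                logger.warning(
                    "row %d (%s): mature occurs more than once in hairpin; using leftmost",
                    i, row["id"],
                )
            s0 = hairpin.find(star)
            if s0 < 0:
                logger.error(
                    "row %d (%s): star not found in hairpin; row skipped", i, row["id"]
                )
                continue
            mature_span = (m0, m0 + len(mature))
            star_span = (s0, s0 + len(star))
            if mature_span[0] < star_span[0]:
                loop_span = (mature_span[1], star_span[0])
            else:
                loop_span = (star_span[1], mature_span[0])
            if loop_span[0] > loop_span[1]:
                logger.error(
                    "row %d (%s): mature and star spans overlap; row skipped", i, row["id"]
                )
                continue
            records.append(
                HairpinRecord(
                    id=row["id"],
                    species=row["species"],
                    sequence=hairpin,
                    mature_span=mature_span,
                    loop_span=loop_span,
                    star_span=star_span,
                    score=score,
                    read_depth=depth,
                )
            )
    return records


def matures_from_hairpins(hairpins: Sequence[HairpinRecord]) -> list[MatureRecord]:
    """Extract one MatureRecord per hairpin prediction."""
    return [
        MatureRecord(
            id=h.id,
            species=h.species,
            sequence=h.mature,
            read_depth=h.read_depth,
            source=(h.id, h.mature_span[0]),
        )
        for h in hairpins
    ]


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)
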