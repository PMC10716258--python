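"""Read-pair and contact-list I/O.

Implements the 4DN pairs format (plain text or BGZF-compressed) with a JSON
tile index for random access, and the UCSC interact track format for contact
lists.

Coordinate conventions
----------------------
Positions in pairs files are 1-based, per the pairs standard, and
:class:`ContactRecord` stores them as such.  Every other interval in this
package (regions, viewports, bins) is 0-based half-open; the conversion
happens exactly once, at this module's boundary: a record with position ``p``
lies at 0-based coordinate ``p - 1``.
"""

from __future__ import annotations

import gzip
import io
import json
import warnings
from dataclasses import dataclass, field, replace

import pysam

PAIRS_FORMAT_LINE = "## pairs format v1.0"
INDEX_VERSION = 1
GZIP_MAGIC = b"\x1f\x8b"


class PairsFormatError(ValueError):
    """The file is not a recognizable pairs file (missing/garbled header)."""


class PairsParseError(ValueError):
    """A body line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class UnsortedInputError(ValueError):
    """Input was declared sorted but is not; names the offending line."""


@dataclass(frozen=True)
class ContactRecord:
    """One read pair; positions are 1-based as in the pairs standard."""

    read_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str = "."
    strand2: str = "."
    extra: tuple = ()

    def __post_init__(self):
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError("pairs positions are 1-based and must be >= 1")

    @property
    def is_intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def distance(self) -> int:
        """Genomic separation |pos2 - pos1| (intrachromosomal only)."""
        if not self.is_intra:
            raise ValueError("distance is undefined for interchromosomal pairs")
        return abs(self.pos2 - self.pos1)

    def point(self) -> tuple:
        """0-based (x, y) plane coordinates of this pair."""
        return (float(self.pos1 - 1), float(self.pos2 - 1))

    def to_line(self) -> str:
        fields = [self.read_id, self.chrom1, str(self.pos1), self.chrom2,
                  str(self.pos2), self.strand1, self.strand2, *self.extra]
        return "\t".join(fields)


@dataclass
class PairsHeader:
    lines: list = field(default_factory=list)
    chromsizes: dict = field(default_factory=dict)  # name -> length, in order

    @property
    def chrom_order(self) -> dict:
        return {name: i for i, name in enumerate(self.chromsizes)}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def contains_position(self, pos: int) -> bool:
        """Whether a 1-based pairs position falls in this interval."""
        return self.start <= pos - 1 < self.end


def _open_pairs(path):
    """Open plain-text or BGZF pairs file for binary line reading."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        try:
            return pysam.BGZFile(str(path), "rb")
        except (OSError, ValueError):  # plain gzip, no BGZF blocks
            return gzip.open(path, "rb")
    return open(path, "rb")


def read_header(fh) -> tuple:
    """Parse the '#' header; returns (header, offset_of_first_body_line)."""
    header = PairsHeader()
    saw_format = False
    while True:
        offset = fh.tell()
        raw = fh.readline()
        if not raw:
            break
        line = raw.decode().rstrip("\n")
        if not line.startswith("#"):
            fh.seek(offset)
            break
        header.lines.append(line)
        if line.startswith("## pairs format"):
            saw_format = True
        elif line.startswith("#chromsize:"):
            parts = line.split(None, 2)[1:]
            if len(parts) != 2:
                raise PairsFormatError(f"garbled chromsize line: {line!r}")
            header.chromsizes[parts[0]] = int(parts[1])
    if not saw_format:
        raise PairsFormatError('missing "## pairs format" header line')
    return header, fh.tell()


def parse_record(line: str, line_number: int) -> ContactRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 7:
        raise PairsParseError(f"expected >= 7 tab-separated columns, got {len(cols)}", line_number)
    try:
        pos1, pos2 = int(cols[2]), int(cols[4])
    except ValueError:
        raise PairsParseError(f"non-integer position in {cols[2]!r}/{cols[4]!r}", line_number) from None
    return ContactRecord(cols[0], cols[1], pos1, cols[3], pos2,
                         cols[5], cols[6], tuple(cols[7:]))


def normalize_record(rec: ContactRecord, chrom_order: dict) -> ContactRecord:
    """Upper-triangle normalization under (chromosome order, position)."""
    o1 = chrom_order.get(rec.chrom1, len(chrom_order))
    o2 = chrom_order.get(rec.chrom2, len(chrom_order))
    if (o2, rec.chrom2, rec.pos2) < (o1, rec.chrom1, rec.pos1):
        return replace(rec, chrom1=rec.chrom2, pos1=rec.pos2, strand1=rec.strand2,
                       chrom2=rec.chrom1, pos2=rec.pos1, strand2=rec.strand1)
    return rec


def _region_match(rec, region_a, region_b) -> bool:
    if region_a is not None:
        if rec.chrom1 != region_a.chrom or not region_a.contains_position(rec.pos1):
            return False
    if region_b is not None:
        if rec.chrom2 != region_b.chrom or not region_b.contains_position(rec.pos2):
            return False
    return True


def _warn_unknown_chroms(header, regions):
    known = set(header.chromsizes)
    if not known:
        return
    for region in regions:
        if region is not None and region.chrom not in known:
            warnings.warn(f"chromosome {region.chrom!r} not in pairs header; "
                          "query returns no records", stacklevel=3)


def read_pairs(path, region_a: GenomicInterval = None,
               region_b: GenomicInterval = None, index: "GenomeIndex" = None):
    """Yield :class:`ContactRecord` from a pairs file.

    With no regions, records come back in file order exactly as stored.  With
    regions, records are upper-triangle normalized first and exactly those
    whose (pos1, pos2) fall in ``region_a`` x ``region_b`` are yielded.  When
    a sorted :class:`GenomeIndex` is supplied, only the byte ranges that can
    hold matching records are scanned.
    """
    filtering = region_a is not None or region_b is not None
    fh = _open_pairs(path)
    try:
        header, body_offset = read_header(fh)
        if filtering:
            _warn_unknown_chroms(header, (region_a, region_b))
        chrom_order = header.chrom_order
        if index is not None and index.sorted and filtering and region_a is not None:
            byte_ranges = index.block_ranges(region_a)
        else:
            byte_ranges = [(body_offset, None)]
        line_number = len(header.lines)
        for start, end in byte_ranges:
            fh.seek(start)
            while end is None or fh.tell() < end:
                raw = fh.readline()
                if not raw:
                    break
                line_number += 1
                line = raw.decode()
                if not line.strip():
                    continue
                if line.startswith("#"):
                    continue
                rec = parse_record(line, line_number)
                if filtering:
                    rec = normalize_record(rec, chrom_order)
                    if not _region_match(rec, region_a, region_b):
                        continue
                yield rec
    finally:
        fh.close()


def write_pairs(records, path, chromsizes: dict = None, bgzf: bool = False,
                extra_header_lines=()):
    """Write records as a pairs file (canonical 7+ column layout)."""
    lines = [PAIRS_FORMAT_LINE]
    for name, length in (chromsizes or {}).items():
        lines.append(f"#chromsize: {name} {length}")
    lines.extend(extra_header_lines)
    lines.append("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2")
    body = "".join(rec.to_line() + "\n" for rec in records)
    payload = "\n".join(lines) + "\n" + body
    if bgzf:
        with pysam.BGZFile(str(path), "wb") as fh:
            fh.write(payload.encode())
    else:
        with open(path, "w") as fh:
            fh.write(payload)
    return path


# ---------------------------------------------------------------------------
# Tile index
# ---------------------------------------------------------------------------

@dataclass
class GenomeIndex:
    """Coarse tile index over (chrom1, pos1) byte ranges.

    ``blocks`` maps "chrom,tile" to ``[start, end]`` file offsets (BGZF
    virtual offsets for compressed files).  Only usable for region queries
    when the underlying file is sorted by (chrom1, pos1).
    """

    tile_size: int
    chromosomes: list  # [(name, length or None), ...]
    blocks: dict
    sorted: bool = True
    version: int = INDEX_VERSION

    def block_ranges(self, region: GenomicInterval):
        """Merged byte ranges covering all tiles that overlap ``region``."""
        first = region.start // self.tile_size
        last = (region.end - 1) // self.tile_size
        ranges = []
        for tile in range(first, last + 1):
            block = self.blocks.get(f"{region.chrom},{tile}")
            if block is not None:
                ranges.append(tuple(block))
        ranges.sort()
        merged = []
        for start, end in ranges:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        return [tuple(r) for r in merged]

    def save(self, path) -> str:
        path = str(path)
        payload = {"format": "voronoi3c-tile-index", "version": self.version,
                   "tile_size": self.tile_size, "sorted": self.sorted,
                   "chromosomes": self.chromosomes, "blocks": self.blocks}
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def load(cls, path) -> "GenomeIndex":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(tile_size=payload["tile_size"],
                   chromosomes=[tuple(c) for c in payload["chromosomes"]],
                   blocks=payload["blocks"], sorted=payload["sorted"],
                   version=payload["version"])


def index_path_for(pairs_path) -> str:
    return str(pairs_path) + ".tiles.json"


def build_index(path, tile_size: int = 1_000_000, unsorted_ok: bool = False) -> GenomeIndex:
    """Scan a pairs file once and build the tile index.

    Requires input sorted by (chrom1, pos1) under the header's chromosome
    order; pass ``unsorted_ok=True`` to accept unsorted input, producing an
    index that forces linear scans.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    fh = _open_pairs(path)
    try:
        header, _ = read_header(fh)
        chrom_order = dict(header.chrom_order)
        chromosomes = [(name, length) for name, length in header.chromsizes.items()]
        known = set(header.chromsizes)
        blocks = {}
        current_key = None
        current_start = None
        last_sort_key = None
        line_number = len(header.lines)
        while True:
            offset = fh.tell()
            raw = fh.readline()
            if not raw:
                break
            line_number += 1
            line = raw.decode()
            if not line.strip() or line.startswith("#"):
                continue
            rec = parse_record(line, line_number)
            if rec.chrom1 not in chrom_order:
                chrom_order[rec.chrom1] = len(chrom_order)
                if rec.chrom1 not in known:
                    chromosomes.append((rec.chrom1, None))
                    known.add(rec.chrom1)
            sort_key = (chrom_order[rec.chrom1], rec.pos1)
            if last_sort_key is not None and sort_key < last_sort_key:
                if not unsorted_ok:
                    raise UnsortedInputError(
                        f"input not sorted by (chrom1, pos1) at line {line_number}")
                return GenomeIndex(tile_size, chromosomes, {}, sorted=False)
            last_sort_key = sort_key
            key = f"{rec.chrom1},{(rec.pos1 - 1) // tile_size}"
            if key != current_key:
                if current_key is not None:
                    blocks[current_key] = [current_start, offset]
                current_key, current_start = key, offset
            end_offset = fh.tell()
        if current_key is not None:
            blocks[current_key] = [current_start, end_offset]
        return GenomeIndex(tile_size, chromosomes, blocks, sorted=True)
    finally:
        fh.close()


# ---------------------------------------------------------------------------
# interact track format
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractRecord:
    """One pairwise interaction; intervals are 0-based half-open on disk."""

    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self):
        if self.source_start >= self.source_end:
            raise ValueError("source interval must satisfy start < end")
        if self.target_start >= self.target_end:
            raise ValueError("target interval must satisfy start < end")
        if self.score < 0:
            raise ValueError("score must be non-negative")


def write_interact(records, path) -> str:
    """Write the 18-column UCSC interact layout.

    The exact score is carried in the ``value`` column; the integer ``score``
    column is clamped to the browser's 0-1000 range.
    """
    with open(path, "w") as fh:
        for rec in records:
            if rec.source_chrom == rec.target_chrom:
                chrom = rec.source_chrom
                lo = min(rec.source_start, rec.target_start)
                hi = max(rec.source_end, rec.target_end)
            else:
                chrom, lo, hi = rec.source_chrom, rec.source_start, rec.source_end
            cols = [chrom, lo, hi, rec.name, min(1000, int(rec.score)),
                    repr(float(rec.score)), ".", "0",
                    rec.source_chrom, rec.source_start, rec.source_end, ".", ".",
                    rec.target_chrom, rec.target_start, rec.target_end, ".", "."]
            fh.write("\t".join(str(c) for c in cols) + "\n")
    return str(path)


def read_interact(path):
    """Read interact records (18-column layout, or the minimal 5-column
    ``chrom source_start source_end target_start target_end`` subset)."""
    records = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if len(cols) >= 18:
                    records.append(InteractRecord(
                        source_chrom=cols[8], source_start=int(cols[9]),
                        source_end=int(cols[10]), target_chrom=cols[13],
                        target_start=int(cols[14]), target_end=int(cols[15]),
                        score=float(cols[5]), name=cols[3]))
                elif len(cols) == 5:
                    records.append(InteractRecord(
                        source_chrom=cols[0], source_start=int(cols[1]),
                        source_end=int(cols[2]), target_chrom=cols[0],
                        target_start=int(cols[3]), target_end=int(cols[4])))
                else:
                    raise ValueError(f"expected 18 or 5 columns, got {len(cols)}")
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_number}: {exc}") from None
    return records
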