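"""Gene-structure handling for nascent-transcription analysis.

Reads GTF gene models, collapses transcripts that share both their
transcription start site (TSS) and termination site (TTS) into a single
transcript group, and derives the strand-aware regions (gene span, last
exon, downstream windows) that the quantification modules consume.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open intervals; GTF input/output
converts from/to 1-based inclusive at the boundary.  ``tss`` and ``tts``
are single base positions in *biological* orientation: for a plus-strand
transcript the TSS is its leftmost base and the TTS its rightmost base;
for a minus-strand transcript the TSS is the rightmost base and the TTS
the leftmost.  Hence ``tss < tts`` on ``+`` and ``tss > tts`` on ``-``.
"All "upstream"/"downstream" language follows the direction of
transcription.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DataError

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class TranscriptModel:
    """A single annotated transcript with its exon structure."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DataError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        if not self.exons:
            raise DataError(f"{self.transcript_id}: no exons")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise DataError(f"{self.transcript_id}: overlapping exons")
        if self.end <= self.start:
            raise DataError(f"{self.transcript_id}: empty span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def terminal_exon(self) -> Interval:
        """Exon adjacent to the TTS (last exon in transcription order)."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]


@dataclass
class TranscriptGroup:
    """Transcripts of one gene sharing identical TSS and TTS.

    Collapsing TSS/TTS-identical transcripts avoids quantifying the same
    promoter or termination region repeatedly; members may still differ in
    internal exon structure.  The group's ``last_exon`` is taken from the
    member with the longest terminal exon (an inclusive choice that gives
    readthrough denominators the largest annotated support).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    members: list[str]
    last_exon: Interval

    @property
    def span(self) -> Interval:
        """Genomic interval (0-based half-open) covered by the group."""
        lo, hi = sorted((self.tss, self.tts))
        return (lo, hi + 1)

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    groups: list[TranscriptGroup]
    major: TranscriptGroup | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise DataError(f"{self.gene_id}: gene with no transcript groups")

    @property
    def span(self) -> Interval:
        lo = min(g.span[0] for g in self.groups)
        hi = max(g.span[1] for g in self.groups)
        return (lo, hi)


@dataclass
class GtfParseResult:
    """Parsed genes plus the permissive parser's bookkeeping counters."""

    genes: list[GeneModel]
    n_transcripts: int = 0
    n_malformed: int = 0
    n_no_exon_transcripts: int = 0
    n_split_loci: int = 0
    warnings: list[str] = field(default_factory=list)


def group_transcripts(transcripts: list[TranscriptModel]) -> list[TranscriptGroup]:
    """Partition one gene's transcripts by identical (TSS, TTS).

    All inputs must share gene_id, chromosome and strand (the caller splits
    multi-locus gene_ids first).  Groups come back sorted by (tss, tts) so
    downstream processing is order-independent.
    """
    if not transcripts:
        return []
    gid = transcripts[0].gene_id
    chrom = transcripts[0].chrom
    strand = transcripts[0].strand
    for t in transcripts:
        if (t.gene_id, t.chrom, t.strand) != (gid, chrom, strand):
            raise DataError(f"{gid}: group_transcripts needs a single locus")
    by_key: dict[tuple[int, int], list[TranscriptModel]] = {}
    for t in transcripts:
        by_key.setdefault((t.tss, t.tts), []).append(t)
    groups = []
    for (tss, tts), members in sorted(by_key.items()):
        # last exon from the member whose terminal exon is longest
        last = max(
            (m.terminal_exon for m in members), key=lambda iv: (iv[1] - iv[0], iv)
        )
        groups.append(
            TranscriptGroup(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                tss=tss,
                tts=tts,
                members=[m.transcript_id for m in members],
                last_exon=last,
            )
        )
    return groups


def build_gene_models(transcripts: list[TranscriptModel]) -> tuple[list[GeneModel], int]:
    """Assemble GeneModels from transcripts, splitting multi-locus gene_ids.

    A gene_id whose transcripts sit on several chromosomes or strands is
    emitted as one GeneModel per locus with ``_locus<i>`` suffixes; returns
    (genes, number of split loci).
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes: list[GeneModel] = []
    n_split = 0
    for gid in sorted(by_gene):
        ts = by_gene[gid]
        loci: dict[tuple[str, str], list[TranscriptModel]] = {}
        for t in ts:
            loci.setdefault((t.chrom, t.strand), []).append(t)
        multi = len(loci) > 1
        if multi:
            n_split += len(loci)
        for i, key in enumerate(sorted(loci), start=1):
            sub = loci[key]
            out_id = f"{gid}_locus{i}" if multi else gid
            for t in sub:
                t = t  # gene_id on the transcript is left untouched
            groups = group_transcripts(sub)
            if multi:
                groups = [
                    TranscriptGroup(out_id, g.chrom, g.strand, g.tss, g.tts,
                                    g.members, g.last_exon)
                    for g in groups
                ]
            genes.append(
                GeneModel(
                    gene_id=out_id,
                    gene_name=sub[0].gene_name,
                    chrom=key[0],
                    strand=key[1],
                    groups=groups,
                )
            )
    return genes, n_split


def read_gtf(path: str | Path) -> GtfParseResult:
    """Permissively parse a GTF (Ensembl or RefGene dialect) into GeneModels.

    Only ``exon`` feature lines are used; a transcript's span is the hull of
    its exons.  Malformed lines are skipped and counted; transcripts whose
    records carry no exon line are dropped and counted.  1-based inclusive
    GTF coordinates become 0-based half-open internally.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"GTF not found: {path}")
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> gene_id, name, chrom, strand
    seen_tids: set[str] = set()
    n_malformed = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                n_malformed += 1
                continue
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if tid is None or gid is None:
                n_malformed += 1
                continue
            try:
                s0, e0 = int(start) - 1, int(end)
            except ValueError:
                n_malformed += 1
                continue
            if strand not in "+-" or e0 <= s0:
                n_malformed += 1
                continue
            if tid not in meta:
                meta[tid] = (gid, attr.get("gene_name", gid), chrom, strand)
            seen_tids.add(tid)
            if feature == "exon":
                exons.setdefault(tid, []).append((s0, e0))
    transcripts: list[TranscriptModel] = []
    n_no_exon = 0
    for tid in sorted(seen_tids):
        gid, gname, chrom, strand = meta[tid]
        ivs = exons.get(tid)
        if not ivs:
            n_no_exon += 1
            continue
        ivs = _merge_touching(sorted(ivs))
        transcripts.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gid, gene_name=gname, chrom=chrom,
                strand=strand, start=min(s for s, _ in ivs),
                end=max(e for _, e in ivs), exons=ivs,
            )
        )
    genes, n_split = build_gene_models(transcripts)
    res = GtfParseResult(
        genes=genes,
        n_transcripts=len(transcripts),
        n_malformed=n_malformed,
        n_no_exon_transcripts=n_no_exon,
        n_split_loci=n_split,
    )
    if n_malformed:
        res.warnings.append(f"skipped {n_malformed} malformed GTF line(s)")
    if n_no_exon:
        res.warnings.append(f"dropped {n_no_exon} transcript(s) without exon records")
    for w in res.warnings:
        logger.warning("%s: %s", path.name, w)
    return res


def _merge_touching(ivs: list[Interval]) -> list[Interval]:
    """Merge duplicated/overlapping exon records (tolerant of dialects)."""
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = out[-1]
        if s <= pe:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF; fatal if no genes survive parsing."""
    res = read_gtf(path)
    if not res.genes:
        raise DataError(f"no genes parsed from {path}")
    return res.genes


def downstream_window(
    group: TranscriptGroup, length: int, chrom_size: int | None = None
) -> Interval:
    """Interval starting immediately past the TTS, extending ``length`` bp
    in the direction of transcription, clipped at chromosome bounds.

    May come back empty (start == end) when the TTS sits at a chromosome
    edge; callers treat an empty window as zero signal.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if group.strand == "+":
        start = group.tts + 1
        end = start + length
        if chrom_size is not None:
            end = min(end, chrom_size)
            start = min(start, end)
    else:
        end = group.tts
        start = max(0, end - length)
    return (start, end)


def transcription_interval(
    anchor: int, strand: str, offset5: int, offset3: int
) -> Interval:
    """Genomic half-open interval for transcription-coordinate offsets
    ``[offset5, offset3)`` relative to ``anchor`` (negative = upstream)."""
    if strand == "+":
        return (anchor + offset5, anchor + offset3)
    return (anchor - offset3 + 1, anchor - offset5 + 1)


def write_gtf(genes: list[GeneModel], path: str | Path, source: str = "nascentq") -> None:
    """Write groups back out as single-exon-per-member GTF records.

    Exon structure beyond the group's span and last exon is not retained by
    TranscriptGroup, so each member is emitted with its group span as one
    exon; round-trips preserve (tss, tts) exactly.
    """
    with open(path, "w") as fh:
        for g in genes:
            for grp in g.groups:
                s, e = grp.span
                for tid in grp.members:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                        f'gene_name "{g.gene_name}";'
                    )
                    fh.write(
                        f"{g.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )


def dump_bed12(genes: list[GeneModel], path: str | Path) -> None:
    """Debug dump: one BED12 line per transcript group."""
    with open(path, "w") as fh:
        for g in genes:
            for grp in g.groups:
                s, e = grp.span
                les, lee = grp.last_exon
                fh.write(
                    "\t".join(
                        [
                            g.chrom, str(s), str(e),
                            f"{g.gene_id}|{','.join(grp.members)}",
                            "0", g.strand, str(les), str(lee), "0", "1",
                            str(e - s), "0",
                        ]
                    )
                    + "\n"
                )
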