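"""Promoter/gene-body definition, major-transcript selection, pausing.

The promoter-proximal region of a TSS is found by scanning 50-bp windows
at a 5-bp step across ±500 bp of the TSS along the coding strand and
keeping the window with the most sense-strand reads, pooled over every
sample so all conditions share one region per gene.  The gene body runs
from +1 kb downstream of the TSS to the TTS; genes shorter than 1 kb have
no body and are excluded from body-based statistics.

A gene's *major transcript* is chosen from its TSS/TTS-identical
transcript groups by highest pooled promoter-proximal count, breaking
ties by gene-body count and then by span length; this replaces
longest-transcript preselection with a data-driven choice.

The pausing index is the promoter read density divided by the gene-body
read density (both in reads/bp), undefined when the body has no reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel, Interval, TranscriptGroup, transcription_interval
from .counts import CountCache, check_compatible

PROMOTER_WIDTH = 50
PROMOTER_STEP = 5
PROMOTER_SPAN = 500
BODY_OFFSET = 1000


@dataclass
class PromoterWindow:
    """Selected 50-bp promoter-proximal window for one TSS."""

    tss: int
    strand: str
    interval: Interval  # genomic, 0-based half-open
    offset: int  # transcription-coordinate offset of the window start
    pooled_count: int
    zero_signal: bool = False


@dataclass
class PausingRecord:
    gene_id: str
    sample_id: str
    index: float | None  # None = undefined (zero body signal)

    @property
    def defined(self) -> bool:
        return self.index is not None


def _window_interval(tss: int, strand: str, offset: int, width: int = PROMOTER_WIDTH) -> Interval:
    return transcription_interval(tss, strand, offset, offset + width)


def candidate_offsets(
    span: int = PROMOTER_SPAN, width: int = PROMOTER_WIDTH, step: int = PROMOTER_STEP
) -> list[int]:
    """Transcription-coordinate start offsets of all candidate windows
    covering [TSS - span, TSS + span]."""
    return list(range(-span, span - width + 1, step))


def promoter_window(
    tss: int,
    strand: str,
    chrom: str,
    caches: list[CountCache],
    span: int = PROMOTER_SPAN,
    width: int = PROMOTER_WIDTH,
    step: int = PROMOTER_STEP,
) -> PromoterWindow:
    """Pick the maximal-count 50-bp window around a TSS.

    Counts are sense-strand reads summed over all caches.  Ties prefer
    the window whose start offset is nearest the TSS, then the more
    upstream one; a fully silent span returns the TSS-centred window
    flagged ``zero_signal``.
    """
    check_compatible(caches)
    best = None
    for off in candidate_offsets(span, width, step):
        iv = _window_interval(tss, strand, off, width)
        n = sum(c.count(chrom, iv[0], iv[1], strand) for c in caches)
        key = (-n, abs(off), off)
        if best is None or key < best[0]:
            best = (key, off, n)
    _, off, n = best
    if n == 0:
        off = -(width // 2)
        return PromoterWindow(
            tss, strand, _window_interval(tss, strand, off, width), off, 0, True
        )
    return PromoterWindow(tss, strand, _window_interval(tss, strand, off, width), off, n)


def gene_body(group: TranscriptGroup, offset: int = BODY_OFFSET) -> Interval | None:
    """[TSS + offset, TTS] in transcription direction, or None when the
    transcript group is shorter than ``offset``."""
    if group.length <= offset:
        return None
    if group.strand == "+":
        return (group.tss + offset, group.tts + 1)
    return (group.tts, group.tss - offset + 1)


def select_major_transcript(
    gene: GeneModel, caches: list[CountCache]
) -> TranscriptGroup:
    """Mark and return the gene's major transcript group.

    Highest pooled promoter-proximal count wins; groups sharing a TSS
    (equal promoter counts) are separated by gene-body count, then by
    span length (longest), then by coordinates for full determinism.
    Selection uses pooled counts so it is invariant to uniform scaling.
    """
    scored = []
    win_by_tss: dict[int, PromoterWindow] = {}
    for grp in gene.groups:
        if grp.tss not in win_by_tss:
            win_by_tss[grp.tss] = promoter_window(grp.tss, gene.strand, gene.chrom, caches)
        win = win_by_tss[grp.tss]
        p = win.pooled_count
        body = gene_body(grp)
        b = (
            sum(c.count(gene.chrom, body[0], body[1], gene.strand) for c in caches)
            if body is not None
            else 0
        )
        scored.append(((-p, -b, -grp.length, grp.tss, grp.tts), grp))
    scored.sort(key=lambda t: t[0])
    gene.major = scored[0][1]
    return gene.major


def pausing_index(
    promoter_count: float,
    promoter_len: int,
    body_count: float,
    body_len: int,
) -> float | None:
    """Density ratio (promoter reads/bp) / (body reads/bp); None when the
    body has zero reads (undefined, never encoded as 0)."""
    if body_len <= 0 or promoter_len <= 0:
        return None
    if body_count == 0:
        return None
    return (promoter_count / promoter_len) / (body_count / body_len)


@dataclass
class GeneQuant:
    """Per-gene quantification over all samples (major transcript group)."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    tts: int
    promoter: PromoterWindow
    body: Interval | None
    promoter_counts: dict[str, int]
    body_counts: dict[str, int]
    pausing: dict[str, float | None]


def quantify_genes(
    genes: list[GeneModel],
    caches: list[CountCache],
    select_major: bool = True,
) -> list[GeneQuant]:
    """Select major transcripts and quantify promoter/body per sample."""
    check_compatible(caches)
    out: list[GeneQuant] = []
    for gene in genes:
        grp = select_major_transcript(gene, caches) if select_major else gene.groups[0]
        win = promoter_window(grp.tss, gene.strand, gene.chrom, caches)
        body = gene_body(grp)
        pc: dict[str, int] = {}
        bc: dict[str, int] = {}
        pi: dict[str, float | None] = {}
        for c in caches:
            p = c.count(gene.chrom, win.interval[0], win.interval[1], gene.strand)
            b = (
                c.count(gene.chrom, body[0], body[1], gene.strand)
                if body is not None
                else 0
            )
            pc[c.sample_id] = p
            bc[c.sample_id] = b
            pi[c.sample_id] = (
                pausing_index(p, win.interval[1] - win.interval[0], b, body[1] - body[0])
                if body is not None
                else None
            )
        out.append(
            GeneQuant(
                gene_id=gene.gene_id,
                gene_name=gene.gene_name,
                chrom=gene.chrom,
                strand=gene.strand,
                tss=grp.tss,
                tts=grp.tts,
                promoter=win,
                body=body,
                promoter_counts=pc,
                body_counts=bc,
                pausing=pi,
            )
        )
    return out


def quant_frames(
    quants: list[GeneQuant], caches: list[CountCache]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(summary, promoter counts, body counts) DataFrames from GeneQuants.

    Count frames are genes x samples and feed the differential module;
    the summary carries intervals, densities and pausing indices.
    """
    samples = [c.sample_id for c in caches]
    pmat = pd.DataFrame(
        {s: [q.promoter_counts[s] for q in quants] for s in samples},
        index=[q.gene_id for q in quants],
    )
    bmat = pd.DataFrame(
        {s: [q.body_counts[s] for q in quants] for s in samples},
        index=[q.gene_id for q in quants],
    )
    rows = []
    for q in quants:
        row: dict = {
            "gene_id": q.gene_id,
            "gene_name": q.gene_name,
            "chrom": q.chrom,
            "strand": q.strand,
            "tss": q.tss,
            "tts": q.tts,
            "promoter_start": q.promoter.interval[0],
            "promoter_end": q.promoter.interval[1],
            "promoter_zero_signal": q.promoter.zero_signal,
            "body_start": q.body[0] if q.body else np.nan,
            "body_end": q.body[1] if q.body else np.nan,
            "body_defined": q.body is not None,
        }
        for s in samples:
            row[f"promoter_count:{s}"] = q.promoter_counts[s]
            row[f"body_count:{s}"] = q.body_counts[s]
            pi = q.pausing[s]
            row[f"pausing_index:{s}"] = np.nan if pi is None else pi
        rows.append(row)
    return pd.DataFrame(rows), pmat, bmat
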