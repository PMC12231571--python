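"""Transcriptional readthrough quantification and dysregulation calls.

Readthrough — polymerase signal continuing past the cleavage and
polyadenylation site — is scored per gene as the ratio of reads in a
fixed 50-kb window downstream of the TTS to reads in the last exon
(raw counts; the ratio is scale-free within a sample).  Only *active*
genes are considered: promoter-proximal reads > 0 and gene-body density
above 4 reads/kb once the sample's total is normalized to 10 million
(strict inequality; a density of exactly 4.0 is inactive).  Genes with
another active gene within 50 kb downstream are excluded, since that
neighbor's transcription would masquerade as readthrough.

Condition differences in the ratio are tested with the same stratified
CMH machinery used for alternative TSS/TTS detection: one 2x2 table per
cross-condition sample pair with rows = (downstream count, last-exon
count), BH FDR across tested genes, direction = sign of
log2(mean ratio B / mean ratio A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel, Interval, downstream_window
from .altsites import CMHResult, _strata_from_counts, bh_fdr, cmh_test
from .counts import CountCache, check_compatible
from .regions import GeneQuant

READTHROUGH_WINDOW = 50_000
ACTIVITY_BODY_DENSITY = 4.0  # reads per kb, after normalizing totals to 1e7
ACTIVITY_NORM_TOTAL = 1e7


def is_active(
    promoter_count: int,
    body_count: int,
    body_len: int,
    total_mapped: int,
    norm_to: float = ACTIVITY_NORM_TOTAL,
    min_density: float = ACTIVITY_BODY_DENSITY,
) -> bool:
    """Activity rule: promoter reads > 0 AND normalized body density
    strictly above ``min_density`` reads/kb at ``norm_to`` total reads.

    An undefined gene body (length <= 0) makes the gene inactive.
    """
    if promoter_count <= 0 or body_len <= 0 or total_mapped <= 0:
        return False
    density = (body_count * (norm_to / total_mapped)) / (body_len / 1000.0)
    return density > min_density


@dataclass
class ReadthroughRecord:
    gene_id: str
    chrom: str
    strand: str
    last_exon: Interval
    downstream: Interval
    last_exon_counts: dict[str, int]
    downstream_counts: dict[str, int]
    ratios: dict[str, float | None]  # None = undefined (zero last-exon count)
    cmh: CMHResult
    fdr: float | None = None
    direction: str | None = None  # increased | decreased
    reason: str | None = None


def readthrough_ratio(downstream_count: int, last_exon_count: int) -> float | None:
    """Downstream-to-last-exon read ratio; None when the last exon has no
    reads (undefined, excluded from testing, never reported as 0)."""
    if last_exon_count <= 0:
        return None
    return downstream_count / last_exon_count


def _gene_activity(
    q: GeneQuant, caches: list[CountCache]
) -> dict[str, bool]:
    body_len = int(q.body[1] - q.body[0]) if q.body else 0
    return {
        c.sample_id: is_active(
            q.promoter_counts[c.sample_id],
            q.body_counts[c.sample_id],
            body_len,
            c.total_mapped,
        )
        for c in caches
    }


def detect_readthrough_change(
    genes: list[GeneModel],
    quants: list[GeneQuant],
    caches: list[CountCache],
    samples_a: list[str],
    samples_b: list[str],
    chrom_sizes: dict[str, int] | None = None,
    window: int = READTHROUGH_WINDOW,
    activity: str = "all",
    pairing: str = "auto",
) -> list[ReadthroughRecord]:
    """Score readthrough change for every eligible gene.

    ``activity='all'`` (default) requires the gene to be active in every
    sample; ``'pooled'`` requires activity of the pooled counts only.
    The downstream-neighbor exclusion drops genes with another gene that
    is active in at least one sample within ``window`` bp downstream of
    the TTS, on either strand.
    """
    check_compatible(caches)
    by_sample = {c.sample_id: c for c in caches}
    gene_by_id = {g.gene_id: g for g in genes}
    active_map: dict[str, dict[str, bool]] = {
        q.gene_id: _gene_activity(q, caches) for q in quants
    }
    records: list[ReadthroughRecord] = []
    for q in quants:
        gene = gene_by_id.get(q.gene_id)
        if gene is None or gene.major is None:
            continue
        grp = gene.major
        size = chrom_sizes.get(gene.chrom) if chrom_sizes else None
        down = downstream_window(grp, window, size)
        rec = ReadthroughRecord(
            gene_id=q.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            last_exon=grp.last_exon,
            downstream=down,
            last_exon_counts={},
            downstream_counts={},
            ratios={},
            cmh=CMHResult(None, None, None, 0, 0),
        )
        acts = active_map[q.gene_id]
        if activity == "pooled":
            ok = sum(q.promoter_counts.values()) > 0 and any(acts.values())
        else:
            ok = all(acts.values())
        if not ok:
            rec.reason = "inactive"
            records.append(rec)
            continue
        if _active_neighbor_downstream(gene, down, genes, active_map):
            rec.reason = "active_downstream_neighbor"
            records.append(rec)
            continue
        le = grp.last_exon
        for sid, cache in by_sample.items():
            lec = cache.count(gene.chrom, le[0], le[1], gene.strand)
            dnc = cache.count(gene.chrom, down[0], down[1], gene.strand)
            rec.last_exon_counts[sid] = lec
            rec.downstream_counts[sid] = dnc
            rec.ratios[sid] = readthrough_ratio(dnc, lec)
        if any(rec.ratios[s] is None for s in by_sample):
            rec.reason = "undefined_ratio"
            records.append(rec)
            continue
        strata = _strata_from_counts(
            rec.downstream_counts, rec.last_exon_counts, samples_a, samples_b, pairing
        )
        rec.cmh = cmh_test(strata)
        if rec.cmh.defined:
            mean_a = float(np.mean([rec.ratios[s] for s in samples_a]))
            mean_b = float(np.mean([rec.ratios[s] for s in samples_b]))
            if mean_b > mean_a:
                rec.direction = "increased"
            elif mean_b < mean_a:
                rec.direction = "decreased"
            else:
                rec.direction = "unchanged"
        else:
            rec.reason = "degenerate_strata"
        records.append(rec)
    tested = [r for r in records if r.cmh.defined]
    if tested:
        fdrs = bh_fdr(np.array([r.cmh.pvalue for r in tested]))
        for r, qv in zip(tested, fdrs):
            r.fdr = float(qv)
    return records


def _active_neighbor_downstream(
    gene: GeneModel,
    down: Interval,
    genes: list[GeneModel],
    active_map: dict[str, dict[str, bool]],
) -> bool:
    """Any gene active in >=1 sample whose span intersects the downstream
    window (strand-agnostic: convergent neighbors contaminate too)."""
    for other in genes:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        if not any(active_map.get(other.gene_id, {}).values()):
            continue
        s, e = other.span
        if s < down[1] and down[0] < e:
            return True
    return False


def readthrough_table(records: list[ReadthroughRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "strand": r.strand,
            "last_exon": f"{r.last_exon[0]}-{r.last_exon[1]}",
            "downstream": f"{r.downstream[0]}-{r.downstream[1]}",
            "statistic": r.cmh.statistic if r.cmh.defined else np.nan,
            "pvalue": r.cmh.pvalue if r.cmh.defined else np.nan,
            "fdr": r.fdr if r.fdr is not None else np.nan,
            "direction": r.direction or "",
            "reason": r.reason or "",
        }
        for sid, ratio in r.ratios.items():
            row[f"ratio:{sid}"] = np.nan if ratio is None else ratio
        rows.append(row)
    return pd.DataFrame(rows)
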