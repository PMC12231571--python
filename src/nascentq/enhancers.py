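"""Active-enhancer definition from externally called de-novo transcripts.

Enhancer candidates come from a de-novo transcript caller (e.g. HOMER
with its default tssFold/bodyFold thresholds) run on pooled reads; this
module applies the genic-proximity exclusion — any transcript within
-2 kb (upstream) to +20 kb (downstream) of an annotated gene, in that
gene's transcription coordinates, is dropped — and pairs the surviving
divergent plus/minus transcripts into active enhancers, quantified by
reads on both strands over the pair's union span.

Pair geometry (the upstream caller does not define one): a minus-strand
transcript whose 5' end lies at most ``max_gap`` bp (default 1,000)
upstream of a plus-strand transcript's 5' end forms a divergent pair;
matching is greedy by closest 5'-to-5' distance, each transcript joining
at most one pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import GeneModel, Interval
from .counts import CountCache
from .errors import DataError

GENIC_UPSTREAM = 2_000
GENIC_DOWNSTREAM = 20_000
DEFAULT_MAX_GAP = 1_000


@dataclass(frozen=True)
class StrandedInterval:
    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class EnhancerCandidate:
    """A divergent transcript pair defining one active enhancer."""

    chrom: str
    plus: StrandedInterval
    minus: StrandedInterval
    counts: dict[str, int] | None = None  # both strands summed, per sample
    normalized: dict[str, float] | None = None

    @property
    def region(self) -> Interval:
        return (
            min(self.plus.start, self.minus.start),
            max(self.plus.end, self.minus.end),
        )


def read_bed6(path: str | Path) -> list[StrandedInterval]:
    """Read stranded intervals from a BED6 (or BED6+) file."""
    out = []
    path = Path(path)
    if not path.exists():
        raise DataError(f"transcript BED not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6 or f[5] not in "+-":
                raise DataError(f"{path}:{lineno}: need BED6 with strand")
            out.append(StrandedInterval(f[0], int(f[1]), int(f[2]), f[5], f[3]))
    return out


def genic_exclusion_window(gene: GeneModel) -> Interval:
    """[TSS - 2 kb, TTS + 20 kb] in the gene's transcription direction,
    as a genomic half-open interval."""
    lo, hi = gene.span
    if gene.strand == "+":
        return (lo - GENIC_UPSTREAM, hi + GENIC_DOWNSTREAM)
    return (lo - GENIC_DOWNSTREAM, hi + GENIC_UPSTREAM)


def filter_genic(
    transcripts: list[StrandedInterval], genes: list[GeneModel]
) -> list[StrandedInterval]:
    """Drop transcripts overlapping any gene's -2 kb/+20 kb window."""
    windows: dict[str, list[Interval]] = {}
    for g in genes:
        windows.setdefault(g.chrom, []).append(genic_exclusion_window(g))
    survivors = []
    for t in transcripts:
        hit = any(
            t.start < e and s < t.end for s, e in windows.get(t.chrom, ())
        )
        if not hit:
            survivors.append(t)
    return survivors


def pair_bidirectional(
    transcripts: list[StrandedInterval], max_gap: int = DEFAULT_MAX_GAP
) -> list[EnhancerCandidate]:
    """Greedily pair divergent plus/minus transcripts by 5' proximity.

    A (minus, plus) pair is divergent when the minus transcript's 5' end
    is not downstream of the plus transcript's 5' end and the two 5' ends
    are within ``max_gap`` bp.  Candidates are ranked by 5' distance and
    matched greedily, each transcript used at most once; input order does
    not matter (everything is sorted first).
    """
    plus = sorted(
        (t for t in transcripts if t.strand == "+"), key=lambda t: (t.chrom, t.start)
    )
    minus = sorted(
        (t for t in transcripts if t.strand == "-"), key=lambda t: (t.chrom, t.start)
    )
    candidates = []
    for m in minus:
        for p in plus:
            if p.chrom != m.chrom:
                continue
            dist = p.five_prime - m.five_prime
            if 0 <= dist <= max_gap:
                candidates.append((dist, m.chrom, m.five_prime, p.five_prime, m, p))
    candidates.sort(key=lambda t: t[:4])
    used: set[StrandedInterval] = set()
    pairs = []
    for _, _, _, _, m, p in candidates:
        if m in used or p in used:
            continue
        used.update((m, p))
        pairs.append(EnhancerCandidate(chrom=m.chrom, plus=p, minus=m))
    pairs.sort(key=lambda c: (c.chrom, c.region))
    return pairs


def naive_transcript_calls(
    cache: CountCache,
    min_bin_count: int = 5,
    min_length: int = 400,
) -> list[StrandedInterval]:
    """Crude transcript caller for tests and fixtures only — NOT a
    production substitute for a real de-novo caller.

    Merges runs of contiguous 200-bp bins whose pooled count reaches
    ``min_bin_count`` into stranded intervals and keeps those at least
    ``min_length`` long.  Useful to fabricate plausible BED input for
    the enhancer pipeline from simulated data.
    """
    calls: list[StrandedInterval] = []
    bw = cache.bin_width
    for (chrom, strand), tr in sorted(cache.tracks.items()):
        run_start = None
        for i, v in enumerate(tr.bins.tolist() + [0]):
            if v >= min_bin_count and run_start is None:
                run_start = i
            elif v < min_bin_count and run_start is not None:
                start, end = run_start * bw, i * bw
                if end - start >= min_length:
                    calls.append(
                        StrandedInterval(chrom, start, end, strand, f"call{len(calls)}")
                    )
                run_start = None
    return calls


def quantify_enhancers(
    pairs: list[EnhancerCandidate],
    caches: list[CountCache],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Count both-strand reads in each enhancer region per sample; apply
    the shared gene-body normalization factors when provided."""
    rows = []
    for enh in pairs:
        s, e = enh.region
        enh.counts = {
            c.sample_id: c.count(enh.chrom, s, e, strand="both") for c in caches
        }
        if factors is not None:
            enh.normalized = {
                sid: cnt / float(factors[sid]) for sid, cnt in enh.counts.items()
            }
        row = {
            "chrom": enh.chrom,
            "start": s,
            "end": e,
            "plus_tx": f"{enh.plus.start}-{enh.plus.end}",
            "minus_tx": f"{enh.minus.start}-{enh.minus.end}",
        }
        for sid, cnt in enh.counts.items():
            row[f"count:{sid}"] = cnt
        if enh.normalized:
            for sid, val in enh.normalized.items():
                row[f"normalized:{sid}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def enhancer_count_matrix(pairs: list[EnhancerCandidate]) -> pd.DataFrame:
    """Enhancers x samples raw count matrix for the differential module."""
    ids = [f"{p.chrom}:{p.region[0]}-{p.region[1]}" for p in pairs]
    if not pairs:
        return pd.DataFrame()
    samples = list(pairs[0].counts)
    return pd.DataFrame(
        {s: [p.counts[s] for p in pairs] for s in samples}, index=ids
    )
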