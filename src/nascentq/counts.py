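"""Single-pass, two-resolution read counting over nascent-RNA alignments.

Each alignment file (coordinate BAM or a plus/minus bedGraph pair) is
streamed exactly once.  Every usable read contributes one count at a
single representative base — by default its 3' end, the position of the
engaged polymerase in PRO-seq — recorded per (chromosome, strand) at two
resolutions:

* site resolution: sorted position/count arrays, and
* 200-bp bins: dense per-chromosome arrays tiled from coordinate 0.

Region queries sum whole interior bins and fall back to site counts only
in the partial edge bins, which is exactly equal to summing sites alone
(each read lives in exactly one site and one bin).  Caches persist as
versioned pickles; a version mismatch raises CacheVersionError rather
than silently mixing incompatible layouts.
"""

from __future__ import annotations

import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .errors import CacheVersionError, DataError

CACHE_VERSION = 1
BIN_WIDTH = 200

READ_RULES = ("three_prime", "five_prime")


@dataclass
class StrandTrack:
    """Counts for one (chromosome, strand): sites plus bin sums."""

    positions: np.ndarray  # sorted int64 site positions
    site_counts: np.ndarray  # int64, parallel to positions
    bins: np.ndarray  # int64 bin sums, index = position // bin_width

    @property
    def total(self) -> int:
        return int(self.site_counts.sum())


@dataclass
class RegionQuery:
    """A strand-aware counting request on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str  # the strand of interest, e.g. the gene's strand
    orientation: str = "sense"  # sense | antisense | both

    def resolved_strands(self) -> tuple[str, ...]:
        if self.orientation == "both":
            return ("+", "-")
        flip = {"+": "-", "-": "+"}
        if self.orientation == "sense":
            return (self.strand,)
        return (flip[self.strand],)


@dataclass
class CountCache:
    """Per-sample, per-(chrom, strand) counts at site and bin resolution."""

    sample_id: str
    read_rule: str
    bin_width: int = BIN_WIDTH
    tracks: dict[tuple[str, str], StrandTrack] = field(default_factory=dict)
    total_mapped: int = 0
    metadata: dict = field(default_factory=dict)

    # -- queries ---------------------------------------------------------

    def count(self, chrom: str, start: int, end: int, strand: str = "both") -> int:
        """Exact read count in [start, end) on the requested strand(s).

        Interior whole bins are answered from bin sums, the partial edge
        bins from site arrays; by conservation the result equals a pure
        site-level summation.
        """
        if end <= start:
            return 0
        strands = ("+", "-") if strand == "both" else (strand,)
        total = 0
        for s in strands:
            tr = self.tracks.get((chrom, s))
            if tr is None:
                continue
            total += self._count_track(tr, max(0, start), end)
        return total

    def _count_track(self, tr: StrandTrack, start: int, end: int) -> int:
        bw = self.bin_width
        first_full = -(-start // bw)  # ceil division: first fully covered bin
        last_full = end // bw  # one past the last fully covered bin
        if first_full >= last_full:
            # interval inside one or two bins: sites only
            return self._site_sum(tr, start, end)
        interior = int(tr.bins[first_full:min(last_full, len(tr.bins))].sum())
        left = self._site_sum(tr, start, first_full * bw)
        right = self._site_sum(tr, last_full * bw, end)
        return interior + left + right

    @staticmethod
    def _site_sum(tr: StrandTrack, start: int, end: int) -> int:
        if end <= start:
            return 0
        i = np.searchsorted(tr.positions, start, side="left")
        j = np.searchsorted(tr.positions, end, side="left")
        return int(tr.site_counts[i:j].sum())

    def region_count(self, query: RegionQuery) -> int:
        total = 0
        for s in query.resolved_strands():
            tr = self.tracks.get((query.chrom, s))
            if tr is None:
                continue
            total += self._count_track(tr, max(0, query.start), query.end)
        return total

    def chrom_total(self, chrom: str, strand: str) -> int:
        tr = self.tracks.get((chrom, strand))
        return 0 if tr is None else tr.total

    def chroms(self) -> set[str]:
        return {c for c, _ in self.tracks}

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "version": CACHE_VERSION,
            "sample_id": self.sample_id,
            "read_rule": self.read_rule,
            "bin_width": self.bin_width,
            "total_mapped": self.total_mapped,
            "metadata": self.metadata,
            "tracks": {
                key: (tr.positions, tr.site_counts, tr.bins)
                for key, tr in self.tracks.items()
            },
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh, protocol=4)

    @classmethod
    def load(cls, path: str | Path) -> "CountCache":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if not isinstance(payload, dict) or payload.get("version") != CACHE_VERSION:
            raise CacheVersionError(
                f"{path}: cache version {payload.get('version')!r} != {CACHE_VERSION}; rebuild"
            )
        cache = cls(
            sample_id=payload["sample_id"],
            read_rule=payload["read_rule"],
            bin_width=payload["bin_width"],
            total_mapped=payload["total_mapped"],
            metadata=payload["metadata"],
        )
        cache.tracks = {
            key: StrandTrack(pos, cnt, bins)
            for key, (pos, cnt, bins) in payload["tracks"].items()
        }
        return cache

    def validate(self) -> None:
        """Conservation invariant: site sums == bin sums == total, per track."""
        total = 0
        for (chrom, strand), tr in self.tracks.items():
            s_sum = int(tr.site_counts.sum())
            b_sum = int(tr.bins.sum())
            if s_sum != b_sum:
                raise DataError(
                    f"{self.sample_id} {chrom}{strand}: site sum {s_sum} != bin sum {b_sum}"
                )
            total += s_sum
        if total != self.total_mapped:
            raise DataError(
                f"{self.sample_id}: track totals {total} != total_mapped {self.total_mapped}"
            )


def check_compatible(caches: list[CountCache]) -> None:
    """Refuse to compare caches built under different counting dialects."""
    rules = {c.read_rule for c in caches}
    widths = {c.bin_width for c in caches}
    if len(rules) > 1:
        raise DataError(f"mixed read rules across caches: {sorted(rules)}")
    if len(widths) > 1:
        raise DataError(f"mixed bin widths across caches: {sorted(widths)}")


def _finalize(
    acc: dict[tuple[str, str], dict[int, int]],
    sample_id: str,
    read_rule: str,
    source: str,
) -> CountCache:
    cache = CountCache(sample_id=sample_id, read_rule=read_rule)
    total = 0
    for key, sitemap in acc.items():
        if not sitemap:
            continue
        positions = np.fromiter(sitemap.keys(), dtype=np.int64, count=len(sitemap))
        cnts = np.fromiter(sitemap.values(), dtype=np.int64, count=len(sitemap))
        order = np.argsort(positions, kind="stable")
        positions, cnts = positions[order], cnts[order]
        nbins = int(positions[-1] // BIN_WIDTH) + 1
        bins = np.zeros(nbins, dtype=np.int64)
        np.add.at(bins, positions // BIN_WIDTH, cnts)
        cache.tracks[key] = StrandTrack(positions, cnts, bins)
        total += int(cnts.sum())
    cache.total_mapped = total
    cache.metadata = {
        "read_rule": read_rule,
        "source": source,
        "built_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    cache.validate()
    return cache


def build_cache(
    alignments: str | Path | tuple[str | Path, str | Path],
    read_rule: str = "three_prime",
    sample_id: str | None = None,
    include_duplicates: bool = False,
    include_secondary: bool = False,
    allow_noninteger: bool = False,
) -> CountCache:
    """Stream one alignment source once into a CountCache.

    ``alignments`` is a BAM/SAM path, or a (plus, minus) pair of bedGraph
    paths.  Each primary, mapped, non-duplicate alignment contributes one
    count at its representative base (``read_rule``: ``three_prime`` for
    PRO-seq polymerase position, ``five_prime`` for GRO-seq-style 5' ends)
    on its alignment strand.
    """
    if read_rule not in READ_RULES:
        raise DataError(f"unknown read rule {read_rule!r}; choose from {READ_RULES}")
    if isinstance(alignments, (tuple, list)):
        plus, minus = alignments
        sid = sample_id or Path(plus).stem
        acc = _accumulate_bedgraph_pair(Path(plus), Path(minus), allow_noninteger)
        return _finalize(acc, sid, read_rule, f"bedGraph:{plus},{minus}")
    path = Path(alignments)
    sid = sample_id or path.stem
    acc = _accumulate_bam(path, read_rule, include_duplicates, include_secondary)
    return _finalize(acc, sid, read_rule, f"bam:{path}")


def cache_from_site_counts(
    site_counts: dict[tuple[str, str], dict[int, int]],
    sample_id: str = "sample",
    read_rule: str = "three_prime",
) -> CountCache:
    """Build a cache directly from per-(chrom, strand) position->count maps
    (e.g. precomputed 3'-end tallies), bypassing alignment streaming."""
    acc = {key: dict(v) for key, v in site_counts.items()}
    return _finalize(acc, sample_id, read_rule, "site_counts")


def _accumulate_bam(
    path: Path,
    read_rule: str,
    include_duplicates: bool,
    include_secondary: bool,
) -> dict[tuple[str, str], dict[int, int]]:
    if not path.exists():
        raise DataError(f"alignment file not found: {path}")
    acc: dict[tuple[str, str], dict[int, int]] = {}
    mode = "r" if path.suffix == ".sam" else "rb"
    try:
        bam = pysam.AlignmentFile(str(path), mode, check_sq=False)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    with bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if not include_secondary and (read.is_secondary or read.is_supplementary):
                continue
            if not include_duplicates and read.is_duplicate:
                continue
            strand = "-" if read.is_reverse else "+"
            if read_rule == "three_prime":
                pos = read.reference_end - 1 if strand == "+" else read.reference_start
            else:
                pos = read.reference_start if strand == "+" else read.reference_end - 1
            sitemap = acc.setdefault((read.reference_name, strand), {})
            sitemap[pos] = sitemap.get(pos, 0) + 1
    return acc


def _accumulate_bedgraph_pair(
    plus: Path, minus: Path, allow_noninteger: bool
) -> dict[tuple[str, str], dict[int, int]]:
    acc: dict[tuple[str, str], dict[int, int]] = {}
    for path, strand in ((plus, "+"), (minus, "-")):
        if not path.exists():
            raise DataError(f"bedGraph not found: {path}")
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise DataError(f"{path}:{lineno}: malformed bedGraph line")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                value = abs(value)  # minus-strand tracks often carry negative values
                if value == 0:
                    continue
                if value != int(value):
                    if not allow_noninteger:
                        raise DataError(
                            f"{path}:{lineno}: non-integer value {value}; counts must "
                            "be integral (pass allow_noninteger to round)"
                        )
                    value = round(value)
                sitemap = acc.setdefault((chrom, strand), {})
                v = int(value)
                for pos in range(start, end):
                    sitemap[pos] = sitemap.get(pos, 0) + v
    return acc


def export_bedgraph(cache: CountCache, plus_path: str | Path, minus_path: str | Path) -> None:
    """Write site counts as a plus/minus bedGraph pair (minus values negated)."""
    for path, strand, sign in ((plus_path, "+", 1), (minus_path, "-", -1)):
        with open(path, "w") as fh:
            for (chrom, s), tr in sorted(cache.tracks.items()):
                if s != strand:
                    continue
                for pos, cnt in zip(tr.positions, tr.site_counts):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sign * cnt}\n")


def size_factors(body_counts, user_factors=None):
    """Per-sample scale factors for normalization.

    Returns user-supplied factors verbatim when given (e.g. spike-in
    derived); otherwise computes DESeq2 median-of-ratios factors on the
    gene-body count matrix.  The same factors are applied to promoter and
    enhancer counts downstream so all regions share one scale.

    Parameters
    ----------
    body_counts : pandas.DataFrame
        Genes x samples raw gene-body counts.
    user_factors : sequence of float, optional
        One positive factor per sample (column order).
    """
    import pandas as pd

    samples = list(body_counts.columns)
    if user_factors is not None:
        factors = np.asarray(user_factors, dtype=float)
        if factors.shape != (len(samples),):
            raise DataError(
                f"expected {len(samples)} normalization factors, got {factors.shape}"
            )
        if (factors <= 0).any():
            raise DataError("user normalization factors must all be > 0")
        return pd.Series(factors, index=samples, name="size_factor")
    mat = body_counts.to_numpy(dtype=float)
    if mat.size == 0 or not np.any(mat > 0):
        raise DataError("gene-body count matrix is all zero; cannot normalize")
    if (mat.sum(axis=0) == 0).any():
        zero = [s for s, tot in zip(samples, mat.sum(axis=0)) if tot == 0]
        raise DataError(f"sample(s) with zero gene-body counts: {zero}")
    from pydeseq2.preprocessing import deseq2_norm

    _, sf = deseq2_norm(body_counts.T)  # pydeseq2 wants samples x genes
    factors = np.asarray(sf, dtype=float).ravel()
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise DataError(
            "median-of-ratios normalization failed (no gene positive in all "
            "samples?); provide user factors"
        )
    return pd.Series(factors, index=samples, name="size_factor")
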