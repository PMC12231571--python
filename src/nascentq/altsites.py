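"""Alternative TSS / TTS usage detection via stratified 2x2 CMH tests.

A condition-dependent shift of nascent-read mass between two start (or
termination) sites of one gene is tested with the Cochran–Mantel–Haenszel
statistic.  For every cross-condition sample pair (one sample from each
condition) a 2x2 table is formed with rows = the two sites' read counts
and columns = the two samples; the CMH test then asks whether site usage
is consistently associated with condition across those strata, assuming
a common odds ratio:

    chi2 = (sum_k (a_k - E[a_k]))^2 / sum_k Var(a_k),   1 df,

with E and Var the hypergeometric mean/variance of the top-left cell
given the table margins, and the Mantel–Haenszel common odds ratio
OR = (sum_k a_k d_k / N_k) / (sum_k b_k c_k / N_k).  No continuity
correction is applied by default.

TSS pairs closer than 1 kb are not tested (their promoter windows would
mix signal); each TSS is quantified by its own data-driven 50-bp promoter
window.  TTS sites are quantified over [-1 kb, +2 kb) around the TTS in
transcription coordinates, after excluding TTS sites that fall inside
another gene or have a gene within 3 kb downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, Interval, transcription_interval
from .counts import CountCache, check_compatible
from .regions import promoter_window

MIN_TSS_SEPARATION = 1000
TTS_WINDOW_UP = 1000  # bp upstream of the TTS
TTS_WINDOW_DOWN = 2000  # bp downstream of the TTS
TTS_NEIGHBOR_GAP = 3000
MIN_TOTAL_READS = 20  # combined total across strata required to test a pair


@dataclass
class Stratum2x2:
    """One cross-condition sample pair's 2x2 table.

    Rows are the two sites' read counts, columns the sample from condition
    A and the sample from condition B: a = site1/A, b = site1/B,
    c = site2/A, d = site2/B.
    """

    a: int
    b: int
    c: int
    d: int
    pair: tuple[str, str] = ("", "")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins_ok(self) -> bool:
        return (
            min(self.a + self.b, self.c + self.d) >= 0
            and (self.a + self.b) > 0
            and (self.c + self.d) > 0
            and (self.a + self.c) > 0
            and (self.b + self.d) > 0
        )


@dataclass
class CMHResult:
    statistic: float | None
    pvalue: float | None
    odds_ratio: float | None
    n_strata: int
    n_skipped: int

    @property
    def defined(self) -> bool:
        return self.statistic is not None


def cmh_test(strata: list[Stratum2x2], continuity: bool = False) -> CMHResult:
    """Cochran–Mantel–Haenszel chi-square (1 df) over 2x2 strata.

    Strata with a zero row or column margin carry no information about
    the odds ratio and are skipped (counted in ``n_skipped``).  When every
    stratum is degenerate the result is flagged undefined and the caller
    excludes it from FDR.
    """
    used = [s for s in strata if s.margins_ok()]
    skipped = len(strata) - len(used)
    if not used:
        return CMHResult(None, None, None, 0, skipped)
    num = 0.0
    var = 0.0
    or_num = 0.0
    or_den = 0.0
    for s in used:
        n = s.n
        r1, r2 = s.a + s.b, s.c + s.d
        c1, c2 = s.a + s.c, s.b + s.d
        num += s.a - r1 * c1 / n
        if n > 1:
            var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        or_num += s.a * s.d / n
        or_den += s.b * s.c / n
    if var == 0:
        return CMHResult(None, None, None, len(used), skipped)
    delta = abs(num)
    if continuity:
        delta = max(0.0, delta - 0.5)
    statistic = delta * delta / var
    pvalue = float(stats.chi2.sf(statistic, df=1))
    if or_den > 0:
        odds_ratio = or_num / or_den
    elif or_num > 0:
        odds_ratio = float("inf")
    else:
        odds_ratio = None
    return CMHResult(float(statistic), pvalue, odds_ratio, len(used), skipped)


@dataclass
class AltSiteRecord:
    gene_id: str
    kind: str  # "ATSS" or "ATTS"
    chrom: str
    strand: str
    site1: int
    site2: int
    window1: Interval
    window2: Interval
    strata: list[Stratum2x2]
    cmh: CMHResult
    usage_a: float | None  # mean site1 fraction, condition A
    usage_b: float | None
    fdr: float | None = None
    reason: str | None = None  # set when the pair was not testable


def _strata_from_counts(
    counts1: dict[str, int],
    counts2: dict[str, int],
    samples_a: list[str],
    samples_b: list[str],
    pairing: str = "auto",
) -> list[Stratum2x2]:
    """Cross-condition strata from per-sample counts at two sites.

    ``pairing='matched'`` zips samples positionally (one stratum per
    replicate pair, requires equal group sizes); ``'all'`` uses every
    (A-sample, B-sample) combination.  The default ``'auto'`` picks
    matched pairing for balanced designs: strata built from all
    combinations share samples and are therefore positively correlated,
    which inflates the CMH test's false-positive rate well above its
    nominal level, whereas disjoint matched pairs keep it calibrated.
    """
    if pairing == "auto":
        pairing = "matched" if len(samples_a) == len(samples_b) else "all"
    if pairing == "matched":
        if len(samples_a) != len(samples_b):
            raise ValueError("matched pairing requires equal group sizes")
        pairs = list(zip(samples_a, samples_b))
    else:
        pairs = [(sa, sb) for sa in samples_a for sb in samples_b]
    return [
        Stratum2x2(counts1[sa], counts1[sb], counts2[sa], counts2[sb], (sa, sb))
        for sa, sb in pairs
    ]


def _usage_fraction(
    counts1: dict[str, int], counts2: dict[str, int], samples: list[str]
) -> float | None:
    fracs = []
    for s in samples:
        tot = counts1[s] + counts2[s]
        if tot > 0:
            fracs.append(counts1[s] / tot)
    return float(np.mean(fracs)) if fracs else None


def detect_atss(
    gene: GeneModel,
    caches: list[CountCache],
    samples_a: list[str],
    samples_b: list[str],
    min_sep: int = MIN_TSS_SEPARATION,
    min_total: int = MIN_TOTAL_READS,
    pairing: str = "auto",
    continuity: bool = False,
) -> list[AltSiteRecord]:
    """Test every sufficiently separated TSS pair of one gene.

    Each TSS is quantified with its own pooled 50-bp promoter window;
    pairs whose combined count across strata falls below ``min_total``
    are reported untested with a reason code.
    """
    check_compatible(caches)
    by_sample = {c.sample_id: c for c in caches}
    tss_list = sorted({g.tss for g in gene.groups})
    if len(tss_list) < 2:
        return []
    windows = {
        t: promoter_window(t, gene.strand, gene.chrom, caches) for t in tss_list
    }
    counts = {
        t: {
            sid: by_sample[sid].count(
                gene.chrom, windows[t].interval[0], windows[t].interval[1], gene.strand
            )
            for sid in by_sample
        }
        for t in tss_list
    }
    records = []
    for i, t1 in enumerate(tss_list):
        for t2 in tss_list[i + 1:]:
            if abs(t2 - t1) < min_sep:
                continue
            records.append(
                _test_pair(
                    gene, "ATSS", t1, t2,
                    windows[t1].interval, windows[t2].interval,
                    counts[t1], counts[t2],
                    samples_a, samples_b, min_total, pairing, continuity,
                )
            )
    return records


def tts_window(tts: int, strand: str) -> Interval:
    """[-1 kb, +2 kb) around a TTS in transcription coordinates."""
    return transcription_interval(tts, strand, -TTS_WINDOW_UP, TTS_WINDOW_DOWN)


def tts_excluded(
    tts: int, gene: GeneModel, all_genes: list[GeneModel], gap: int = TTS_NEIGHBOR_GAP
) -> bool:
    """True when a TTS is contaminated by a neighboring gene: it overlaps
    another gene's span, or another gene starts within ``gap`` bp
    downstream of it (transcription direction)."""
    if gene.strand == "+":
        down = (tts, tts + gap + 1)
    else:
        down = (tts - gap, tts + 1)
    for other in all_genes:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        s, e = other.span
        if s <= tts < e:
            return True
        if s < down[1] and down[0] < e:
            return True
    return False


def detect_atts(
    gene: GeneModel,
    caches: list[CountCache],
    samples_a: list[str],
    samples_b: list[str],
    all_genes: list[GeneModel] | None = None,
    min_total: int = MIN_TOTAL_READS,
    pairing: str = "auto",
    continuity: bool = False,
) -> list[AltSiteRecord]:
    """Test alternative TTS usage between distinct TTS sites of one gene.

    TTS sites failing the neighbor-exclusion screen are dropped before
    pairing; pairs are only tested when their [-1 kb, +2 kb) windows are
    disjoint, so a shared read cannot sit in both windows.
    """
    check_compatible(caches)
    by_sample = {c.sample_id: c for c in caches}
    tts_list = sorted({g.tts for g in gene.groups})
    if len(tts_list) < 2:
        return []
    if all_genes is not None:
        tts_list = [t for t in tts_list if not tts_excluded(t, gene, all_genes)]
    if len(tts_list) < 2:
        return []
    windows = {t: tts_window(t, gene.strand) for t in tts_list}
    counts = {
        t: {
            sid: by_sample[sid].count(
                gene.chrom, windows[t][0], windows[t][1], gene.strand
            )
            for sid in by_sample
        }
        for t in tts_list
    }
    records = []
    for i, t1 in enumerate(tts_list):
        for t2 in tts_list[i + 1:]:
            w1, w2 = windows[t1], windows[t2]
            if w1[0] < w2[1] and w2[0] < w1[1]:  # overlapping windows
                continue
            records.append(
                _test_pair(
                    gene, "ATTS", t1, t2, w1, w2,
                    counts[t1], counts[t2],
                    samples_a, samples_b, min_total, pairing, continuity,
                )
            )
    return records


def _test_pair(
    gene: GeneModel,
    kind: str,
    s1: int,
    s2: int,
    w1: Interval,
    w2: Interval,
    counts1: dict[str, int],
    counts2: dict[str, int],
    samples_a: list[str],
    samples_b: list[str],
    min_total: int,
    pairing: str,
    continuity: bool,
) -> AltSiteRecord:
    strata = _strata_from_counts(counts1, counts2, samples_a, samples_b, pairing)
    rec = AltSiteRecord(
        gene_id=gene.gene_id,
        kind=kind,
        chrom=gene.chrom,
        strand=gene.strand,
        site1=s1,
        site2=s2,
        window1=w1,
        window2=w2,
        strata=strata,
        cmh=CMHResult(None, None, None, 0, len(strata)),
        usage_a=_usage_fraction(counts1, counts2, samples_a),
        usage_b=_usage_fraction(counts1, counts2, samples_b),
    )
    total = sum(s.n for s in strata)
    if total < min_total:
        rec.reason = f"low_signal(total={total}<{min_total})"
        return rec
    rec.cmh = cmh_test(strata, continuity=continuity)
    if not rec.cmh.defined:
        rec.reason = "degenerate_strata"
    return rec


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def apply_fdr(records: list[AltSiteRecord]) -> list[AltSiteRecord]:
    """BH FDR across all *tested* records (one family per call)."""
    tested = [r for r in records if r.cmh.defined]
    if tested:
        fdrs = bh_fdr(np.array([r.cmh.pvalue for r in tested]))
        for r, q in zip(tested, fdrs):
            r.fdr = float(q)
    return records


def altsite_table(records: list[AltSiteRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "kind": r.kind,
                "chrom": r.chrom,
                "strand": r.strand,
                "site1": r.site1,
                "site2": r.site2,
                "window1": f"{r.window1[0]}-{r.window1[1]}",
                "window2": f"{r.window2[0]}-{r.window2[1]}",
                "n_strata": r.cmh.n_strata,
                "odds_ratio": r.cmh.odds_ratio if r.cmh.defined else np.nan,
                "statistic": r.cmh.statistic if r.cmh.defined else np.nan,
                "pvalue": r.cmh.pvalue if r.cmh.defined else np.nan,
                "fdr": r.fdr if r.fdr is not None else np.nan,
                "usage_site1_condA": r.usage_a if r.usage_a is not None else np.nan,
                "usage_site1_condB": r.usage_b if r.usage_b is not None else np.nan,
                "reason": r.reason or "",
            }
        )
    return pd.DataFrame(rows)
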