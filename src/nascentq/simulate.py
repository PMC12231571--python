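"""Deterministic synthetic nascent-transcription data for testing.

Generates toy genomes (GTF) and per-sample alignments (sorted BAM or a
plus/minus bedGraph pair) with the read-distribution features of real
PRO-seq/GRO-seq libraries:

* a promoter-proximal peak of paused-polymerase reads 20–60 nt
  downstream of each TSS,
* roughly uniform gene-body coverage at a configurable reads/kb,
* read accumulation just upstream of the TTS (the cleavage and
  polyadenylation zone),
* an exponential-tailed readthrough extension past the TTS whose mass is
  a fraction of the terminating signal,
* condition-dependent usage shifts between isoform groups (alternative
  TSS/TTS events), per-gene condition multipliers (differential
  transcription), per-gene batch multipliers, and multiplicative
  library-size differences between samples.

Every read is emitted as a fixed-length 30-bp perfect alignment whose
3' end is the sampled polymerase position; there is no sequence-level
noise.  All randomness is derived from the SimSpec seed, so a given
spec reproduces its outputs byte for byte.  Machine-readable truth
tables record which genes carry which planted effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

READ_LENGTH = 30
DEFAULT_CONDITIONS = ("A", "B")


@dataclass
class IsoformLayout:
    """One TSS/TTS pair (a transcript group) of a simulated gene."""

    tss: int  # biological start, 0-based base position
    tts: int  # biological end, 0-based base position


@dataclass
class GeneLayout:
    """Layout and per-condition emission rates for one simulated gene.

    Rates are expected read counts at library scale 1.0; the per-sample
    Poisson means multiply in library size, the gene's batch multiplier
    and its condition multiplier.  ``usage`` gives each condition's
    read-share across isoform groups (must sum to 1); a usage shift
    between conditions plants an alternative-TSS/TTS event.
    ``readthrough_frac`` is the share of terminating polymerases that
    continue past the TTS, with exponential decay of mean
    ``readthrough_decay`` bp.
    """

    gene_id: str
    chrom: str
    strand: str
    isoforms: list[IsoformLayout]
    pause_mass: float = 200.0  # expected promoter-peak reads
    body_density: float = 10.0  # reads per kb of gene body
    tts_mass: float = 100.0  # expected termination-zone reads
    pause_offset: int = 40  # centre of the pause peak, nt downstream of TSS
    pause_sd: float = 8.0
    tts_zone: int = 400  # termination reads fall within this many bp of the TTS
    last_exon_len: int = 1500
    usage: dict[str, tuple[float, ...]] = field(default_factory=dict)
    condition_mult: dict[str, float] = field(default_factory=dict)
    batch_mult: dict[str, float] = field(default_factory=dict)
    readthrough_frac: dict[str, float] = field(default_factory=dict)
    readthrough_decay: float = 8000.0

    def usage_of(self, condition: str) -> tuple[float, ...]:
        u = self.usage.get(condition)
        if u is None:
            u = tuple([1.0 / len(self.isoforms)] * len(self.isoforms))
        return u

    def span(self, iso: IsoformLayout) -> tuple[int, int]:
        lo, hi = sorted((iso.tss, iso.tts))
        return lo, hi + 1


@dataclass
class SampleLayout:
    sample_id: str
    condition: str
    batch: str = "b1"
    lib_scale: float = 1.0


@dataclass
class SimSpec:
    """Complete description of a simulated study; the seed fixes all
    randomness."""

    seed: int
    chrom_sizes: dict[str, int]
    genes: list[GeneLayout]
    samples: list[SampleLayout]

    def validate(self) -> None:
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ConfigError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if not g.isoforms:
                raise ConfigError(f"{g.gene_id}: no isoforms")
            for iso in g.isoforms:
                lo, hi = g.span(iso)
                if lo < 0 or hi > size:
                    raise ConfigError(
                        f"{g.gene_id}: isoform ({iso.tss},{iso.tts}) exceeds "
                        f"{g.chrom} bounds [0,{size})"
                    )
                if g.strand == "+" and not iso.tss < iso.tts:
                    raise ConfigError(f"{g.gene_id}: + strand needs tss < tts")
                if g.strand == "-" and not iso.tss > iso.tts:
                    raise ConfigError(f"{g.gene_id}: - strand needs tss > tts")
            for cond, u in g.usage.items():
                if len(u) != len(g.isoforms):
                    raise ConfigError(f"{g.gene_id}: usage length mismatch ({cond})")
                if abs(sum(u) - 1.0) > 1e-9 or any(x < 0 for x in u):
                    raise ConfigError(f"{g.gene_id}: usage must be a distribution")
            for frac in g.readthrough_frac.values():
                if frac < 0:
                    raise ConfigError(f"{g.gene_id}: negative readthrough fraction")
        if not self.samples:
            raise ConfigError("spec has no samples")
        if len({s.sample_id for s in self.samples}) != len(self.samples):
            raise ConfigError("duplicate sample_id in spec")


# ---------------------------------------------------------------------------
# site-level sampling


def _sample_rng(spec: SimSpec, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, sample_index]))


def _emit_gene(
    rng: np.random.Generator,
    gene: GeneLayout,
    iso: IsoformLayout,
    rate_scale: float,
    chrom_size: int,
) -> np.ndarray:
    """Sample 3'-end site positions (genomic) for one isoform group."""
    sign = 1 if gene.strand == "+" else -1
    sites: list[np.ndarray] = []
    # promoter-proximal pause peak
    n = rng.poisson(gene.pause_mass * rate_scale)
    if n:
        offs = np.rint(rng.normal(gene.pause_offset, gene.pause_sd, size=n)).astype(int)
        sites.append(iso.tss + sign * offs)
    # uniform gene body (from +1 kb to the TTS)
    body_len = abs(iso.tts - iso.tss) + 1 - 1000
    if body_len > 0:
        n = rng.poisson(gene.body_density * (body_len / 1000.0) * rate_scale)
        if n:
            offs = rng.integers(1000, 1000 + body_len, size=n)
            sites.append(iso.tss + sign * offs)
    # termination-zone accumulation just upstream of the TTS
    n = rng.poisson(gene.tts_mass * rate_scale)
    if n:
        offs = rng.integers(0, gene.tts_zone, size=n)
        sites.append(iso.tts - sign * offs)
    if sites:
        pos = np.concatenate(sites)
    else:
        pos = np.empty(0, dtype=int)
    return np.clip(pos, 0, chrom_size - 1)


def _emit_readthrough(
    rng: np.random.Generator,
    gene: GeneLayout,
    iso: IsoformLayout,
    frac: float,
    rate_scale: float,
    chrom_size: int,
) -> np.ndarray:
    sign = 1 if gene.strand == "+" else -1
    n = rng.poisson(gene.tts_mass * frac * rate_scale)
    if not n:
        return np.empty(0, dtype=int)
    tail = rng.exponential(gene.readthrough_decay, size=n).astype(int) + 1
    pos = iso.tts + sign * tail
    return np.clip(pos, 0, chrom_size - 1)


def sample_sites(
    spec: SimSpec, sample: SampleLayout, sample_index: int
) -> dict[tuple[str, str], np.ndarray]:
    """All 3'-end site positions for one sample, keyed by (chrom, strand)."""
    rng = _sample_rng(spec, sample_index)
    out: dict[tuple[str, str], list[np.ndarray]] = {}
    for gene in spec.genes:
        size = spec.chrom_sizes[gene.chrom]
        usage = gene.usage_of(sample.condition)
        cond_mult = gene.condition_mult.get(sample.condition, 1.0)
        batch_mult = gene.batch_mult.get(sample.batch, 1.0)
        base = sample.lib_scale * cond_mult * batch_mult
        frac = gene.readthrough_frac.get(sample.condition, 0.0)
        for iso, share in zip(gene.isoforms, usage):
            scale = base * share
            if scale <= 0:
                continue
            pos = _emit_gene(rng, gene, iso, scale, size)
            rt = _emit_readthrough(rng, gene, iso, frac, scale, size)
            if len(rt):
                pos = np.concatenate([pos, rt])
            if len(pos):
                out.setdefault((gene.chrom, gene.strand), []).append(pos)
    return {
        key: np.sort(np.concatenate(chunks)) for key, chunks in out.items()
    }


def expected_readthrough_ratio(gene: GeneLayout, condition: str, window: int = 50_000) -> float:
    """Analytic expectation of the downstream/last-exon count ratio.

    Numerator: terminating mass x readthrough fraction x the probability
    that the exponential tail lands inside the window.  Denominator:
    termination-zone reads plus the body coverage overlapping the last
    exon (the termination zone and last exon both about the TTS).
    """
    frac = gene.readthrough_frac.get(condition, 0.0)
    p_in = 1.0 - math.exp(-window / gene.readthrough_decay)
    num = gene.tts_mass * frac * p_in
    le_body_kb = min(gene.last_exon_len, max(abs(gene.isoforms[0].tts - gene.isoforms[0].tss) + 1 - 1000, 0)) / 1000.0
    den = gene.tts_mass + gene.body_density * le_body_kb
    return num / den


# ---------------------------------------------------------------------------
# file emission


def make_toy_gtf(spec: SimSpec, path: str | Path) -> None:
    """Write the spec's gene layouts as a GTF (1-based inclusive).

    Each isoform group becomes one transcript.  Genes long enough get a
    short first exon and a ``last_exon_len`` terminal exon (so the last
    exon is a proper sub-interval); short genes are single-exon.
    Re-parsing reproduces every (TSS, TTS) pair exactly.
    """
    with open(path, "w") as fh:
        for gene in spec.genes:
            for i, iso in enumerate(gene.isoforms, start=1):
                lo, hi = gene.span(iso)
                tid = f"{gene.gene_id}.t{i}"
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tid}"; '
                    f'gene_name "{gene.gene_id}";'
                )
                span_len = hi - lo
                first_len = 600
                if span_len >= first_len + gene.last_exon_len + 100:
                    if gene.strand == "+":
                        exons = [(lo, lo + first_len), (hi - gene.last_exon_len, hi)]
                    else:
                        exons = [(lo, lo + gene.last_exon_len), (hi - first_len, hi)]
                else:
                    exons = [(lo, hi)]
                fh.write(
                    f"{gene.chrom}\tnascentq_sim\ttranscript\t{lo + 1}\t{hi}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{gene.chrom}\tnascentq_sim\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


def write_bedgraph_pair(
    sites: dict[tuple[str, str], np.ndarray], plus_path: str | Path, minus_path: str | Path
) -> None:
    """Write single-base bedGraph tracks of 3'-end counts (minus negated)."""
    for path, strand, sign in ((plus_path, "+", 1), (minus_path, "-", -1)):
        with open(path, "w") as fh:
            for (chrom, s), pos in sorted(sites.items()):
                if s != strand:
                    continue
                uniq, cnt = np.unique(pos, return_counts=True)
                for p, c in zip(uniq, cnt):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{sign * c}\n")


def write_bam(
    sites: dict[tuple[str, str], np.ndarray],
    chrom_sizes: dict[str, int],
    path: str | Path,
    read_length: int = READ_LENGTH,
) -> None:
    """Write coordinate-sorted BAM of perfect 30-bp alignments whose 3'
    ends sit at the sampled sites."""
    import pysam

    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
    }
    tid_of = {c: i for i, c in enumerate(chroms)}
    records = []
    for (chrom, strand), pos in sites.items():
        size = chrom_sizes[chrom]
        for p in pos.tolist():
            if strand == "+":
                start = max(0, p - (read_length - 1))
                end = p + 1
            else:
                start = p
                end = min(size, p + read_length)
            records.append((tid_of[chrom], start, end, strand))
    records.sort()
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (tid, start, end, strand) in enumerate(records):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.reference_id = tid
            a.reference_start = start
            a.mapping_quality = 60
            a.flag = 16 if strand == "-" else 0
            length = end - start
            a.query_sequence = "A" * length
            a.cigarstring = f"{length}M"
            bam.write(a)


def truth_table(spec: SimSpec) -> pd.DataFrame:
    """Per-gene planted-effect summary driving recovery tests."""
    conds = sorted(
        {s.condition for s in spec.samples}
    ) or list(DEFAULT_CONDITIONS)
    rows = []
    for g in spec.genes:
        row: dict = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "n_isoforms": len(g.isoforms),
        }
        usages = {c: g.usage_of(c) for c in conds}
        row["usage"] = ";".join(
            f"{c}:" + ",".join(f"{u:.3f}" for u in usages[c]) for c in conds
        )
        shift = max(
            (
                abs(usages[conds[0]][i] - usages[conds[-1]][i])
                for i in range(len(g.isoforms))
            ),
            default=0.0,
        )
        tss_vals = sorted({iso.tss for iso in g.isoforms})
        tts_vals = sorted({iso.tts for iso in g.isoforms})
        row["usage_shift"] = shift
        row["is_atss"] = shift > 0 and len(tss_vals) > 1
        row["is_atts"] = shift > 0 and len(tts_vals) > 1
        mult = [g.condition_mult.get(c, 1.0) for c in conds]
        row["true_log2fc"] = (
            float(np.log2(mult[-1] / mult[0])) if mult[0] > 0 else np.nan
        )
        row["is_differential"] = not math.isclose(mult[0], mult[-1])
        fr = [g.readthrough_frac.get(c, 0.0) for c in conds]
        row["readthrough_frac"] = ";".join(f"{c}:{f:.3f}" for c, f in zip(conds, fr))
        row["is_readthrough_change"] = not math.isclose(fr[0], fr[-1])
        row["batch_mult"] = ";".join(
            f"{b}:{m:.3f}" for b, m in sorted(g.batch_mult.items())
        )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_reads(
    spec: SimSpec,
    out_dir: str | Path,
    fmt: str = "bam",
) -> dict[str, object]:
    """Emit per-sample alignments plus truth tables into ``out_dir``.

    ``fmt`` is ``"bam"`` or ``"bedgraph"``.  Returns a manifest mapping
    sample_id to the written path(s); also writes ``truth_genes.tsv``,
    ``design.tsv`` and ``genes.gtf``.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {}
    design_rows = []
    for i, sample in enumerate(spec.samples):
        sites = sample_sites(spec, sample, i)
        # design.tsv records paths relative to the bundle directory so a
        # bundle is relocatable and byte-identical across runs
        if fmt == "bam":
            path = out / f"{sample.sample_id}.bam"
            write_bam(sites, spec.chrom_sizes, path)
            manifest[sample.sample_id] = str(path)
            align = path.name
        elif fmt == "bedgraph":
            plus = out / f"{sample.sample_id}.plus.bedGraph"
            minus = out / f"{sample.sample_id}.minus.bedGraph"
            write_bedgraph_pair(sites, plus, minus)
            manifest[sample.sample_id] = (str(plus), str(minus))
            align = f"{plus.name},{minus.name}"
        else:
            raise ConfigError(f"unknown format {fmt!r}")
        design_rows.append(
            {
                "sample_id": sample.sample_id,
                "alignment": align,
                "condition": sample.condition,
                "batch": sample.batch,
            }
        )
    make_toy_gtf(spec, out / "genes.gtf")
    truth_table(spec).to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame(design_rows).to_csv(out / "design.tsv", sep="\t", index=False)
    with open(out / "chrom.sizes", "w") as fh:
        for c in sorted(spec.chrom_sizes):
            fh.write(f"{c}\t{spec.chrom_sizes[c]}\n")
    manifest["gtf"] = str(out / "genes.gtf")
    manifest["truth"] = str(out / "truth_genes.tsv")
    manifest["design"] = str(out / "design.tsv")
    return manifest


def caches_from_spec(spec: SimSpec, read_rule: str = "three_prime"):
    """In-memory count caches for every sample, no files written.

    Equivalent to simulating alignments and re-counting them (each read's
    representative base is the sampled site), so pipelines can be tested
    without touching disk.
    """
    from .counts import cache_from_site_counts

    spec.validate()
    caches = []
    for i, sample in enumerate(spec.samples):
        sites = sample_sites(spec, sample, i)
        maps = {}
        for key, pos in sites.items():
            uniq, cnt = np.unique(pos, return_counts=True)
            maps[key] = dict(zip(uniq.tolist(), cnt.tolist()))
        caches.append(cache_from_site_counts(maps, sample.sample_id, read_rule))
    return caches


# ---------------------------------------------------------------------------
# count-level surrogates (fast paths for statistical calibration work)


def simulate_pair_counts(
    n_genes: int,
    usage_a: float,
    usage_b: float,
    reads_per_sample: float,
    n_a: int = 2,
    n_b: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Count-level two-site usage draws for many genes at once.

    For each gene and sample the total read count is Poisson with mean
    ``reads_per_sample``; site-1 counts are binomial with the sample
    condition's usage fraction.  Returns (site1, site2) arrays of shape
    (n_genes, n_a + n_b) plus the sample-id lists of each condition.
    """
    rng = np.random.default_rng(seed)
    samples_a = [f"A{i + 1}" for i in range(n_a)]
    samples_b = [f"B{i + 1}" for i in range(n_b)]
    fracs = np.array([usage_a] * n_a + [usage_b] * n_b)
    totals = rng.poisson(reads_per_sample, size=(n_genes, n_a + n_b))
    site1 = rng.binomial(totals, fracs[None, :])
    site2 = totals - site1
    return site1, site2, samples_a, samples_b


# ---------------------------------------------------------------------------
# a standard demonstration study


def demo_spec(seed: int = 1) -> SimSpec:
    """A compact two-condition, two-batch study exercising every planted
    effect: alternative TSS and TTS usage, readthrough gain, up/down
    differential genes, a batch-affected gene and quiet null genes."""
    chrom_sizes = {"chrS1": 1_200_000, "chrS2": 1_200_000}
    genes: list[GeneLayout] = []

    def g(gid, chrom, strand, isoforms, **kw):
        genes.append(GeneLayout(gid, chrom, strand, isoforms, **kw))

    # alternative TSS usage switch (90:10 -> 10:90), shared TTS
    g(
        "gATSS", "chrS1", "+",
        [IsoformLayout(50_000, 70_000), IsoformLayout(53_000, 70_000)],
        pause_mass=500.0,
        usage={"A": (0.9, 0.1), "B": (0.1, 0.9)},
    )
    # alternative TTS usage switch (80:20 -> 20:80), shared TSS
    g(
        "gATTS", "chrS1", "+",
        [IsoformLayout(150_000, 165_000), IsoformLayout(150_000, 172_000)],
        tts_mass=400.0,
        usage={"A": (0.8, 0.2), "B": (0.2, 0.8)},
    )
    # readthrough gain in condition B
    g(
        "gRT", "chrS1", "+", [IsoformLayout(300_000, 320_000)],
        tts_mass=300.0,
        readthrough_frac={"A": 0.1, "B": 0.6},
    )
    # stable readthrough control
    g(
        "gRTnull", "chrS1", "-", [IsoformLayout(520_000, 500_000)],
        tts_mass=300.0,
        readthrough_frac={"A": 0.2, "B": 0.2},
    )
    baseline_rt = {"A": 0.05, "B": 0.05}  # modest readthrough exists everywhere
    # differential transcription, up and down in B
    g(
        "gUP", "chrS2", "+", [IsoformLayout(50_000, 65_000)],
        condition_mult={"A": 1.0, "B": 2.0}, readthrough_frac=dict(baseline_rt),
    )
    g(
        "gDOWN", "chrS2", "-", [IsoformLayout(215_000, 200_000)],
        condition_mult={"A": 1.0, "B": 0.5}, readthrough_frac=dict(baseline_rt),
    )
    # batch-affected null gene (confounder, not a condition effect)
    g(
        "gBATCH", "chrS2", "+", [IsoformLayout(350_000, 365_000)],
        batch_mult={"b1": 1.0, "b2": 2.5}, readthrough_frac=dict(baseline_rt),
    )
    # quiet nulls, mixed strands, spaced so 50-kb downstream windows are clear
    for i, start in enumerate(range(520_000, 1_000_000, 80_000), start=1):
        strand = "+" if i % 2 else "-"
        iso = (
            IsoformLayout(start, start + 12_000)
            if strand == "+"
            else IsoformLayout(start + 12_000, start)
        )
        g(f"gNULL{i}", "chrS2", strand, [iso], readthrough_frac=dict(baseline_rt))
    samples = [
        SampleLayout("A1", "A", "b1", 1.0),
        SampleLayout("A2", "A", "b2", 1.2),
        SampleLayout("B1", "B", "b1", 0.9),
        SampleLayout("B2", "B", "b2", 1.1),
    ]
    return SimSpec(seed=seed, chrom_sizes=chrom_sizes, genes=genes, samples=samples)
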