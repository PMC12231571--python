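"""Shared fixtures: the seeded demonstration study and cache builders."""

from __future__ import annotations

import numpy as np
import pytest

import nascentq as nq


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Demo study simulated once per session: bedGraph pairs + GTF + truth."""
    out = tmp_path_factory.mktemp("demo")
    spec = nq.demo_spec(seed=7)
    manifest = nq.simulate_reads(spec, out, fmt="bedgraph")
    return {"spec": spec, "manifest": manifest, "dir": out}


@pytest.fixture(scope="session")
def demo_caches(demo_bundle):
    spec = demo_bundle["spec"]
    manifest = demo_bundle["manifest"]
    caches = [
        nq.build_cache(tuple(manifest[s.sample_id]), sample_id=s.sample_id)
        for s in spec.samples
    ]
    return caches


@pytest.fixture(scope="session")
def demo_genes(demo_bundle):
    return nq.parse_gtf(demo_bundle["manifest"]["gtf"])


def make_cache(sites, sample_id="s", read_rule="three_prime"):
    """CountCache from {(chrom, strand): {pos: count}} maps."""
    return nq.cache_from_site_counts(sites, sample_id, read_rule)


def random_track(rng, chrom="chr1", strand="+", n_sites=200, lo=0, hi=100_000):
    """A random sparse site-count map on one strand."""
    pos = rng.integers(lo, hi, size=n_sites)
    cnt = rng.integers(1, 6, size=n_sites)
    sitemap: dict[int, int] = {}
    for p, c in zip(pos.tolist(), cnt.tolist()):
        sitemap[p] = sitemap.get(p, 0) + c
    return {(chrom, strand): sitemap}


def site_sum(sitemap: dict[int, int], start: int, end: int) -> int:
    """Naive oracle: sum of site counts in [start, end)."""
    return sum(c for p, c in sitemap.items() if start <= p < end)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
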