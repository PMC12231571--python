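"""Define active enhancers from de-novo transcript calls.

Enhancer RNAs are short divergent transcripts at intergenic loci.  Given
stranded de-novo transcript calls (normally from an external caller run
on pooled reads), this example drops calls within -2 kb/+20 kb of any
annotated gene, pairs the remaining divergent plus/minus transcripts by
5' proximity and quantifies each enhancer by reads on both strands.
"""

import tempfile

import nascentq as nq
from nascentq import enhancers

spec = nq.demo_spec(seed=1)
caches = nq.caches_from_spec(spec)
with tempfile.TemporaryDirectory() as d:
    gtf = f"{d}/genes.gtf"
    nq.make_toy_gtf(spec, gtf)
    genes = nq.parse_gtf(gtf)

# synthetic de-novo calls: one genic (will be filtered), one divergent
# intergenic pair (an enhancer), one lone plus transcript (unpaired)
calls = [
    enhancers.StrandedInterval("chrS1", 52_000, 52_600, "+", "genic"),
    enhancers.StrandedInterval("chrS1", 449_000, 449_500, "-", "eRNA_minus"),
    enhancers.StrandedInterval("chrS1", 449_700, 450_200, "+", "eRNA_plus"),
    enhancers.StrandedInterval("chrS2", 470_000, 470_400, "+", "lonely"),
]
survivors = enhancers.filter_genic(calls, genes)
pairs = enhancers.pair_bidirectional(survivors)
table = enhancers.quantify_enhancers(pairs, caches)

print(f"{len(calls)} calls -> {len(survivors)} intergenic -> {len(pairs)} enhancer(s)")
print(table.to_string(index=False))
print(
    "\nEach enhancer is a divergent transcript pair outside every gene's "
    "-2 kb/+20 kb\nexclusion zone; count:* sums reads of both strands over "
    "the union span."
)
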