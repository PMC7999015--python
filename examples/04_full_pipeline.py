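"""Run the whole discovery pipeline on the packaged fixture.

Chains homology screen -> SNP detection -> allele counting ->
imprinting calls -> qPCR profiling, writing one TSV per stage plus a
JSON summary under ./pipeline_out.
"""

import json

from fvimprint import run_fixture

result = run_fixture("pipeline_out")
print(json.dumps(result.summary, indent=2))
# The funnel: 15 queries -> 17 candidate homologs (one query has none,
# two have paralogous hits) -> 10 candidates lack parental SNPs -> 7
# informative genes -> 5 endosperm MEGs, none imprinted in embryo.
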