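#!/usr/bin/env python
"""Generate and write one synthetic two-population dataset.

Default study conditions: N_e 60,000 vs 10,000 (the largest chimpanzee
contrast), gamma_L = 5 at nonsynonymous sites, ten diploids per population,
8 x 5 Mb chromosomes with 80 gene cassettes.  Writes VCF/BED/TSV inputs plus
a truth JSON under scratch/simdata/ (the VCF runs to tens of megabytes, so
it lives outside results/) for consumption by external tools or the CLI.
"""

import json

from hetexcess import SimConfig, generate_dataset

config = SimConfig(seed=1)
dataset = generate_dataset(config)
paths = dataset.write("scratch/simdata")
print(json.dumps(paths, indent=1))
print(f"variants: {len(dataset.variants)}")
print(f"theoretical delta: {dataset.truth['theoretical_delta']:.4f}")
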