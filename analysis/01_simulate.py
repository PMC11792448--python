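#!/usr/bin/env python
"""Generate the synthetic mock-community study and write it to disk.

Produces the full file set the later stages consume: reference FASTA, ASV
count/sequence/metadata TSVs, the morphology table, and the ground-truth
tables (planted bias, read provenance, designed compositions).
"""

import argparse
from pathlib import Path

from mockdebias import GeneratorConfig, generate_experiment, write_fixture

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/simulated"))
args = parser.parse_args()

config = GeneratorConfig(seed=args.seed)
table, truth = generate_experiment(config)
paths = write_fixture(table, truth, args.out)

n_mock = sum(1 for m in table.metadata if m.input_cells)
print(f"wrote {len(paths)} files to {args.out}")
print(f"  {table.counts.shape[0]} samples ({n_mock} cell-mock), {table.counts.shape[1]} ASVs")
print(f"  protocols: {', '.join(config.protocols)}")
print(f"  dilutions: {', '.join(f'{d:.0e}' for d in config.dilutions)} input cells, depth {config.depth}")
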