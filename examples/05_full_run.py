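"""Full pipeline run from a config file.

Generates a self-contained fixture (taxonomy, genomes, BIOM profile,
config), then runs design -> abundances -> reads -> gold standards ->
anonymization. The same seed always reproduces the same bytes.
"""

import tempfile

from mgsim.config import load_config
from mgsim.fixtures import generate_full_fixture
from mgsim.pipeline import run_pipeline

fx = generate_full_fixture(
    tempfile.mkdtemp(), seed=13, n_samples=2, sample_mode="replicates",
    total_bases=300_000, genome_length=8000,
)
out = run_pipeline(load_config(fx.config))

print(f"output tree under {out}:")
for p in sorted(out.rglob("*")):
    if p.is_file():
        print(f"  {p.relative_to(out)}  ({p.stat().st_size} B)")
print("\nPer sample: FASTQ pair, truth SAM, gold assembly, binning and")
print("profiling gold standards, anonymization maps; plus the pooled")
print("co-assembly and the designed community table at the root.")
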