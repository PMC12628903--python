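"""Build a labeled PPI dataset from STRING-format inputs.

Generates a small toy STRING links file + FASTA (spanning every filtering
boundary), then runs the construction pipeline: score labeling (< 0.4
negative, > 0.8 positive), 50-800 residue length filter, 40%-identity
greedy clustering, and 1:10 negative subsampling.  Prints the number of
records surviving each stage — the same audit the generator's manifest
predicts.
"""

import tempfile

from plmppi.dataset import build_dataset
from plmppi.fixtures import make_toy_string

with tempfile.TemporaryDirectory() as tmp:
    links, fasta, manifest_path, manifest = make_toy_string(
        n_proteins=12, seed=7, out_dir=tmp)
    pairs, split, proteins, counts = build_dataset(
        links, fasta, ratio=manifest["params"]["ratio"], seed=7, k=2)

print("stage counts (pipeline == generator manifest):")
for stage, n in counts.items():
    print(f"  {stage:24s} {n:4d}   (expected {manifest['counts'][stage]})")
print(f"train/validation sizes: {len(split.train)}/{len(split.validation)}")
# Each stage's count matches the generator's independent enumeration; the
# final pool holds all positives plus ratio x as many sampled negatives.
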