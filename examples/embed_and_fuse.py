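"""Per-protein embedding fusion: pool two PLM-shaped matrices into 2816 dims.

The synthetic embedder stands in for the two protein language models: it
emits a 1536 x L matrix (Ankh width) and a 1280 x L matrix (ESM-2 width)
deterministically from (sequence, seed).  Each matrix row is averaged over
residues and the two pooled vectors are concatenated, Ankh first.
"""

from plmppi.dataset import ProteinRecord
from plmppi.embedding import SyntheticEmbedder, concat_pair_vector, mean_pool

protein = ProteinRecord("demo", "MKVLAWGKEQISAHDTPLR")
embedder = SyntheticEmbedder(seed=42)

mat_a = embedder.embed(protein, "synthetic-a")
mat_e = embedder.embed(protein, "synthetic-e")
print(f"Ankh-width matrix:  {mat_a.values.shape}  (features x residues)")
print(f"ESM-2-width matrix: {mat_e.values.shape}")

vec = concat_pair_vector(mean_pool(mat_a), mean_pool(mat_e))
print(f"fused per-protein vector: {vec.shape[0]} dims "
      f"(= {mat_a.values.shape[0]} + {mat_e.values.shape[0]})")
print(f"entry mean {vec.mean():+.4f}, entry sd {vec.std():.4f}")
# The fused vector is the model input; entries hover near zero because each
# embedding column is a unit-variance pseudo-random code averaged over L.
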