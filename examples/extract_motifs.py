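"""Turn trained convolutional filters into PWMs and name them by TF.

Each filter's activating subsequences (above half its maximum score)
are stacked into a position weight matrix; high-information filters are
matched against the benchmark motif set.
"""

import numpy as np

from attnteract.model import ModelConfig
from attnteract.motifs import extract_filter_motifs, map_filters_to_tfs, match_pwms
from attnteract.seqdata import split_dataset
from attnteract.synth import benchmark_motifs, generate_benchmark1
from attnteract.training import train

ds, _ = generate_benchmark1(2000, 4000, rng=np.random.default_rng(1))
split_dataset(ds, (0.8, 0.1, 0.1), seed=1)
config = ModelConfig(seq_len=300, n_filters=32, filter_len=13, pool_window=6,
                     n_heads=4, d_k=32, attn_out=32)
model = train(config, ds, epochs=5, seed=1).model

test = ds.split_subset("test")
filters = extract_filter_motifs(model, test.sequences)
mapping = map_filters_to_tfs(
    match_pwms(filters, list(benchmark_motifs().values()), min_ic=3.0),
    n_filters=config.n_filters)

print("filter  IC(bits)  hits  consensus          TF")
for f in sorted(filters, key=lambda f: -f.ic)[:8]:
    consensus = f.pwm.consensus if f.pwm else "-"
    print(f"{f.index:6d}  {f.ic:8.2f}  {f.activation_count:4d}  "
          f"{consensus:<18s} {mapping[f.index]}")
# Filters with information content > 3 bits and a close PWM match are
# named after the embedded factor they rediscovered; the rest stay
# uncharacterized.
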