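# attnteract

Inference of cooperating transcription-factor (TF) motif pairs from a
convolution + multi-head self-attention sequence model — plus an
Integrated-Gradients feature-interaction scorer (FIS) as an independent
comparison route.

## Who this is for

Regulatory genomicists who train sequence-to-label deep models (TF
binding, chromatin accessibility, single- or multi-label) and want more
than per-position importance: *which pairs of motifs act together*.
Cooperativity between TFs is the hallmark of enhancer and promoter
logic, but attribution methods score features one at a time. This
package reads pairwise structure directly out of a self-attention
layer, tests it statistically, and names the participants.

## The method in brief

A sequence `X ∈ {0,1}^{4×L}` passes through a convolutional filter bank
(`F` filters, length `A`, ReLU, max-pool window `M_p`), optionally a
bidirectional LSTM, and `k` self-attention heads:

```
Q = X W_Q,  K = X W_K,  V = X W_V
A(Q, K) = softmax(Q Kᵀ / √d_k)        # row-stochastic, d × d
Z = A V,          d = ⌊(L − A + 1)/M_p⌋
```

Head outputs are combined, collapsed and standardized into a feature
vector read out by a fully connected layer (binary cross entropy, or
mean per-task binary cross entropy with logits for multi-label data).

For interpretation, the `k` attention matrices of each high-confidence
test example are collapsed by an elementwise max; the attention value
at each position pair is assigned to the convolutional filters active
there (above half their maximum score — the same rule that turns
filters into PWM motifs). Each filter pair's *attention profile* —
foreground versus background — is tested with a one-sided Mann–Whitney
U test, Benjamini–Hochberg corrected, and significant pairs (adjusted
p < 0.05, maximum attention ≥ 0.10) are mapped to TF pairs via motif
matching. The FIS route reaches the same call table from a different
principle: mutate one motif, watch the Integrated-Gradients attribution
of another change.

A synthetic benchmark generator (interacting motif pair planted in
positives, one member in negatives, decoys everywhere; exact
ground-truth coordinates returned) makes the whole pipeline testable
end to end without any external data. See `docs/methods.md` for the
full model, parameter defaults and design rationale.

## Worked example

`examples/call_interactions.py` runs the full loop — simulate 6 000
sequences, train 5 epochs, extract motifs, test attention profiles —
in a few minutes on one CPU:

```
$ python examples/call_interactions.py
test AUC: 0.954
172 confident positives, 373 background negatives
ELF1 - SIX5: adjusted p = 0.00e+00, 513 supporting examples, median distance 90 bp
```

The model separates the classes (AUC 0.954); the only statistically
significant TF pair is exactly the planted ELF1–SIX5 interaction,
supported by 513 example/position observations at a median distance of
90 bp — the spacing the generator happened to produce. The other
examples each demonstrate one capability (generation and ground truth,
training, motif extraction and naming, FIS on models with known
interaction structure), e.g.:

```
$ python examples/extract_motifs.py
filter  IC(bits)  hits  consensus          TF
    12     17.12   403  GATCCTGAGAGGC      SIX5
     3     15.36   418  CCCGGAAGTCCAC      ELF1
    ...
```

High-information filters rediscover the embedded motifs and are named
by PWM matching; the rest stay uncharacterized.

There is also a thin CLI mirroring the library stages:

```bash
attnteract simulate --out-dir run --seed 1
attnteract train --out-dir run --seed 1 --epochs 5
attnteract evaluate --out-dir run
attnteract motifs --out-dir run
attnteract interactions --out-dir run --attn-cutoff 0.10
attnteract fis --out-dir run
attnteract compare --out-dir run
```

Each stage writes TSV/MEME/JSON artifacts and a manifest into the run
directory; identical configs and seeds reproduce byte-identical
outputs.

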