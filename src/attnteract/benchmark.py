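"""End-to-end embedded-motif benchmark: generate, train, call interactions.

This is the self-contained recovery experiment the package ships with:
random sequences with an interacting motif pair (ELF1/SIX5) planted in
positives, exactly one of the two in negatives, and decoys (TAL1/AP3)
scattered over both classes.  A model trained on it should separate the
classes nearly perfectly, and the attention route should call the
planted pair — and only pairs involving it — significant.

The default problem size (2 000 positives, 4 000 negatives, 32 filters,
4 heads, 5 epochs) is a scaled-down rendition of the full 120 000
sequence benchmark that keeps a complete run in the minutes range on one
CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .interactions import InteractionCall, call_interactions, profiles_from_batch
from .model import ModelConfig
from .motifs import FilterMotif, extract_filter_motifs, map_filters_to_tfs, match_pwms
from .seqdata import encode_batch, split_dataset
from .synth import benchmark_motifs, generate_benchmark1
from .training import ConfidenceThresholds, evaluate_auc, select_confident_examples, train

__all__ = ["BenchmarkRun", "run_scaled_benchmark", "PLANTED_PAIR", "DECOYS"]

PLANTED_PAIR = ("ELF1", "SIX5")
DECOYS = ("TAL1", "AP3")


@dataclasses.dataclass
class BenchmarkRun:
    """Everything one benchmark run produces."""

    seed: int
    n_pos: int
    n_neg: int
    test_auc: float
    filter_motifs: list[FilterMotif]
    filter_to_tf: dict[int, str]
    calls: list[InteractionCall]
    n_foreground: int
    n_background: int

    @property
    def significant_tf_pairs(self) -> set[tuple[str, str]]:
        return {c.tf_pair for c in self.calls}

    @property
    def planted_pair_called(self) -> bool:
        return tuple(sorted(PLANTED_PAIR)) in self.significant_tf_pairs

    @property
    def decoy_decoy_called(self) -> bool:
        return any(set(p) <= set(DECOYS) for p in self.significant_tf_pairs)

    @property
    def only_planted_involved(self) -> bool:
        """True iff every significant pair involves a planted motif."""
        planted = set(PLANTED_PAIR)
        return all(set(p) & planted for p in self.significant_tf_pairs)


def run_scaled_benchmark(seed: int, n_pos: int = 2000, n_neg: int = 4000,
                         length: int = 300, n_filters: int = 32,
                         filter_len: int = 13, pool_window: int = 6,
                         n_heads: int = 4, d_k: int = 32, epochs: int = 5,
                         attn_cutoff: float = 0.10, alpha: float = 0.05,
                         use_rnn: bool = False) -> BenchmarkRun:
    """One full generate/train/interpret cycle at reduced scale."""
    ds, _records = generate_benchmark1(n_pos, n_neg, length=length,
                                       rng=np.random.default_rng(seed))
    split_dataset(ds, (0.8, 0.1, 0.1), seed=seed)
    config = ModelConfig(seq_len=length, n_filters=n_filters,
                         filter_len=filter_len, pool_window=pool_window,
                         n_heads=n_heads, d_k=d_k, attn_out=d_k,
                         task="binary", use_rnn=use_rnn)
    result = train(config, ds, epochs=epochs, seed=seed)
    model = result.model
    auc = evaluate_auc(model, ds, "test")["median"]

    thresholds = ConfidenceThresholds(attention=attn_cutoff)
    fg_idx, bg_idx = select_confident_examples(model, ds, thresholds, "test")
    fg = ds.subset(fg_idx)
    bg = ds.subset(bg_idx)

    # motif extraction on the confident positives defines the per-filter
    # activation maxima reused by the interaction step
    filters = extract_filter_motifs(model, fg.sequences)
    max_act = np.array([f.max_activation for f in filters])
    matches = match_pwms(filters, list(benchmark_motifs().values()),
                         min_ic=thresholds.min_ic)
    mapping = map_filters_to_tfs(matches, n_filters=config.n_filters)

    def batch_profiles(subset):
        x = encode_batch(subset.sequences, config.seq_len)
        all_profiles = {}
        for start in range(0, len(subset), 256):
            res = model.forward(x[start:start + 256])
            chunk = profiles_from_batch(
                res.attention, res.pooled, max_act,
                subset.ids[start:start + 256], config.pool_window, attn_cutoff)
            for pair, prof in chunk.items():
                if pair in all_profiles:
                    base = all_profiles[pair]
                    base.values += prof.values
                    base.example_ids += prof.example_ids
                    base.position_pairs += prof.position_pairs
                    base.distances_bp += prof.distances_bp
                else:
                    all_profiles[pair] = prof
            # re-apply the cutoff after merging chunks
        return {p: pr for p, pr in all_profiles.items()
                if pr.max_value >= attn_cutoff}

    profiles_fg = batch_profiles(fg)
    profiles_bg = batch_profiles(bg) if len(bg) else {}
    calls = call_interactions(profiles_fg, profiles_bg, mapping, alpha)
    return BenchmarkRun(seed=seed, n_pos=n_pos, n_neg=n_neg,
                        test_auc=float(auc), filter_motifs=filters,
                        filter_to_tf=mapping, calls=calls,
                        n_foreground=len(fg), n_background=len(bg))
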