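"""Feature Interaction Scores via Integrated Gradients.

The comparison method for attention-based interaction calls: for each
analyzed sequence, each activated first-layer filter in turn becomes the
*source* motif.  All other activated filters are *targets*.  Integrated
Gradients attributions are computed for every target span, the source
span is mutated to random bases matching the sequence's GC content, the
attributions are recomputed, and the Feature Interaction Score of the
(source, target) pair is the change in the target's attribution.  A
non-zero FIS means the model's use of the target depends on the source —
the signature of an interaction.  Significance testing reuses the same
Mann-Whitney U / Benjamini-Hochberg pipeline as the attention route.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor
from .interactions import InteractionCall, PairAttentionProfile, call_interactions
from .model import Model

__all__ = [
    "FISRecord", "integrated_gradients", "motif_attribution", "mutate_source",
    "activated_filter_spans", "fis_for_example", "fis_profiles",
    "fis_call_interactions", "compare_methods",
]


@dataclasses.dataclass(frozen=True)
class FISRecord:
    """One (source, target) attribution change for one example."""

    example_id: object
    source_filter: int
    source_span: tuple[int, int]
    target_filter: int
    target_span: tuple[int, int]
    before: float
    after: float

    def __post_init__(self):
        a, b = self.source_span, self.target_span
        if max(a[0], b[0]) < min(a[1], b[1]):
            raise ValueError("source and target spans must not overlap")

    @property
    def fis(self) -> float:
        return self.before - self.after


def integrated_gradients(model: Model, x: np.ndarray,
                         baseline: np.ndarray | None = None, m: int = 64,
                         task_indices=None) -> np.ndarray:
    """Integrated Gradients attribution matrix for one input.

    Right-point Riemann approximation of the path integral from
    ``baseline`` to ``x``::

        IG = (x - baseline) * (1/m) * sum_{k=1..m} dF(baseline + k/m (x - b)) / dx

    ``F`` is the positive-class logit for a binary model; for
    multi-label models it is the sum of the logits at ``task_indices``
    (the caller restricts these to true-positive predictions).

    The default baseline is the uniform matrix with 0.25 per channel
    (the expectation of a random one-hot sequence).  An all-zero
    baseline is degenerate for this architecture: zero input gives
    constant features, and the standardization layers then make the
    network almost scale-invariant along the interpolation ray, so the
    whole output change collapses into an epsilon-neighborhood of the
    baseline and no finite step count satisfies completeness.
    """
    if m < 1:
        raise ValueError("step count m must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    baseline = np.full_like(x, 0.25) if baseline is None \
        else np.asarray(baseline, float)
    if baseline.shape != x.shape:
        raise ValueError("baseline shape must match the input")
    if task_indices is None:
        task_indices = [1] if model.config.task == "binary" else [0]
    alphas = (np.arange(1, m + 1) / m)[:, None, None]
    steps = baseline[None] + alphas * (x - baseline)[None]    # (m, 4, L)
    xt = Tensor(steps, requires_grad=True)
    result = model.forward(xt)
    objective = result.logits[:, list(task_indices)].sum()
    objective.backward()
    grads = xt.grad
    if grads is None or not np.all(np.isfinite(grads)):
        raise RuntimeError("non-finite or missing gradients in integrated gradients")
    return (x - baseline) * grads.mean(axis=0)


def motif_attribution(attr: np.ndarray, span: tuple[int, int]) -> float:
    """Total attribution over the columns of ``span`` (half-open)."""
    start, end = span
    return float(np.asarray(attr)[:, start:end].sum())


def mutate_source(x: np.ndarray, span: tuple[int, int], gc: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Replace the span's columns by random one-hot bases at the given GC.

    P(G) + P(C) = ``gc`` split evenly, likewise A/T; everything outside
    the span is untouched.
    """
    start, end = span
    x = np.asarray(x, dtype=np.float64)
    if start < 0 or end > x.shape[1] or start > end:
        raise ValueError(f"span {span} out of bounds for length {x.shape[1]}")
    out = x.copy()
    if end > start:
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]   # A, C, G, T
        draws = rng.choice(4, size=end - start, p=probs)
        out[:, start:end] = 0.0
        out[draws, np.arange(start, end)] = 1.0
    return out


def activated_filter_spans(model: Model, conv_map: np.ndarray,
                           max_activation: np.ndarray) -> dict[int, tuple[int, int]]:
    """Best-activation window per activated filter for one example.

    A filter is activated when its maximum post-ReLU score in this
    example exceeds half its global maximum (the motif-extraction rule);
    its span is the filter-length window at the argmax position.
    Overlapping spans are pruned greedily, keeping stronger activations,
    so source and target spans never overlap.
    """
    a = model.config.filter_len
    best_pos = conv_map.argmax(axis=1)
    best_val = conv_map.max(axis=1)
    active = np.flatnonzero((best_val > 0.5 * max_activation) & (max_activation > 0))
    spans: dict[int, tuple[int, int]] = {}
    for j in sorted(active, key=lambda j: -best_val[j]):
        span = (int(best_pos[j]), int(best_pos[j]) + a)
        if all(span[1] <= s or span[0] >= e for s, e in spans.values()):
            spans[int(j)] = span
    return spans


def fis_for_example(model: Model, x: np.ndarray,
                    spans: dict[int, tuple[int, int]], example_id,
                    rng: np.random.Generator, m: int = 64,
                    task_indices=None, gc: float | None = None
                    ) -> list[FISRecord]:
    """All (source, target) FIS records for one example.

    Needs at least two activated filter spans, otherwise returns [].
    ``gc`` defaults to the GC fraction of the sequence itself.
    """
    if len(spans) < 2:
        return []
    x = np.asarray(x, dtype=np.float64)
    if gc is None:
        content = x.sum(axis=1)
        total = content.sum()
        gc = float((content[1] + content[2]) / total) if total else 0.5
    before_attr = integrated_gradients(model, x, m=m, task_indices=task_indices)
    records = []
    for source, s_span in spans.items():
        mutated = mutate_source(x, s_span, gc, rng)
        after_attr = integrated_gradients(model, mutated, m=m,
                                          task_indices=task_indices)
        for target, t_span in spans.items():
            if target == source:
                continue
            records.append(FISRecord(
                example_id, source, s_span, target, t_span,
                before=motif_attribution(before_attr, t_span),
                after=motif_attribution(after_attr, t_span)))
    return records


def fis_profiles(records: list[FISRecord],
                 use_abs: bool = True) -> dict[tuple[int, int], PairAttentionProfile]:
    """Group FIS magnitudes into per-pair profiles (source/target collapsed).

    The unordered filter pair (j1 < j2) accumulates one value per record;
    ``use_abs`` scores |before - after| (the default — interactions are
    read from the size of the attribution change), otherwise the signed
    difference.  Distances are span-start separations in bp.
    """
    profiles: dict[tuple[int, int], PairAttentionProfile] = {}
    for r in records:
        pair = tuple(sorted((r.source_filter, r.target_filter)))
        prof = profiles.get(pair)
        if prof is None:
            prof = profiles[pair] = PairAttentionProfile(pair)
        value = abs(r.fis) if use_abs else r.fis
        prof.add(value, r.example_id,
                 (r.source_span[0], r.target_span[0]), pool_window=1)
    return profiles


def fis_call_interactions(records_fg: list[FISRecord],
                          records_bg: list[FISRecord],
                          filter_to_tf: dict[int, str], alpha: float = 0.05,
                          use_abs: bool = True) -> list[InteractionCall]:
    """Significant TF pairs from FIS records; same pipeline as attention.

    The output schema is identical to the attention route's, so overlap
    reports can compare the two methods directly.  Raises on an empty
    background, mirroring the attention route.
    """
    fg = fis_profiles(records_fg, use_abs)
    bg = fis_profiles(records_bg, use_abs)
    return call_interactions(fg, bg, filter_to_tf, alpha)


def compare_methods(attention_calls: list[InteractionCall],
                    fis_calls: list[InteractionCall], top_n: int = 15) -> dict:
    """Overlap between the two methods' top interactions.

    Both call lists are ranked by supporting-example frequency
    (descending, ties by adjusted p); the report gives the two top-n TF
    pair lists and their intersection.
    """
    def top(calls):
        ranked = sorted(calls, key=lambda c: (-c.frequency, c.adj_p_value))
        return [c.tf_pair for c in ranked[:top_n]]

    top_a, top_f = top(attention_calls), top(fis_calls)
    common = [p for p in top_f if p in top_a]
    return {
        "top_attention": top_a,
        "top_fis": top_f,
        "common": common,
        "n_common": len(common),
        "top_n": top_n,
    }
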