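"""Attention-based inference of interacting filter (and TF) pairs.

For every analyzed example the per-head attention matrices are collapsed
into a single d x d matrix by an elementwise maximum over heads.  At
each pair of attended positions the convolutional filters active there
(same half-of-global-max rule as motif extraction) receive that
attention value, building an *attention profile* per filter pair across
all examples.  Profiles whose maximum never reaches the attention cutoff
(0.10 by default) are discarded.  Each surviving pair's foreground
profile is compared against its background profile with a one-sided
Mann-Whitney U test, p-values are Benjamini-Hochberg adjusted across all
tested pairs, and significant filter pairs are translated into unique,
non-self TF pairs.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import UNCHARACTERIZED

logger = logging.getLogger(__name__)

__all__ = [
    "PairAttentionProfile", "InteractionCall",
    "collapse_heads", "active_filters_at", "extract_pair_attention",
    "aggregate_profiles", "profiles_from_batch",
    "mann_whitney_test", "benjamini_hochberg",
    "call_interactions", "family_summary", "overlap_enrichment",
    "calls_to_frame",
]


@dataclasses.dataclass
class PairAttentionProfile:
    """Attention values collected for one filter pair, j1 < j2.

    One value per contributing (example, position pair); ``distances_bp``
    converts pooled-index separation to base pairs via the pooling
    window.
    """

    pair: tuple[int, int]
    values: list[float] = dataclasses.field(default_factory=list)
    example_ids: list = dataclasses.field(default_factory=list)
    position_pairs: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    distances_bp: list[int] = dataclasses.field(default_factory=list)

    def add(self, value: float, example_id, positions: tuple[int, int],
            pool_window: int) -> None:
        self.values.append(float(value))
        self.example_ids.append(example_id)
        self.position_pairs.append(positions)
        self.distances_bp.append(abs(positions[0] - positions[1]) * pool_window)

    @property
    def max_value(self) -> float:
        return max(self.values) if self.values else 0.0

    @property
    def frequency(self) -> int:
        """Number of distinct supporting examples."""
        return len(set(self.example_ids))


@dataclasses.dataclass
class InteractionCall:
    """One significant interaction, reported at the TF-pair level."""

    filter_pair: tuple[int, int]
    tf_pair: tuple[str, str]
    p_value: float
    adj_p_value: float
    max_attention: float
    frequency: int
    median_distance_bp: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= self.adj_p_value <= 1.0 + 1e-12):
            raise ValueError("require 0 <= p <= adjusted p <= 1")


# ------------------------------------------------------------- matrix steps
def collapse_heads(attn: np.ndarray) -> np.ndarray:
    """Elementwise maximum over heads: (k, d, d) -> (d, d)."""
    attn = np.asarray(attn)
    if attn.ndim != 3:
        raise ValueError("expected a (k, d, d) stack of attention matrices")
    return attn.max(axis=0)


def active_filters_at(pooled: np.ndarray, position: int,
                      max_activation: np.ndarray) -> np.ndarray:
    """Filters active at one pooled position.

    Filter j is active iff ``pooled[j, position]`` strictly exceeds half
    of its global maximum activation (an activation exactly at the
    threshold does not qualify).  Filters with non-positive global
    maximum are never active.
    """
    thr = 0.5 * np.asarray(max_activation)
    col = pooled[:, position]
    return np.flatnonzero((col > thr) & (thr > 0))


def extract_pair_attention(collapsed: np.ndarray, pooled: np.ndarray,
                           max_activation: np.ndarray, example_id
                           ) -> list[tuple[tuple[int, int], float, tuple[int, int]]]:
    """Assign attention values to filter pairs for one example.

    For each unordered position pair (i1, i2), i1 != i2, the symmetrized
    attention ``max(collapsed[i1, i2], collapsed[i2, i1])`` is assigned
    to every cross pair of (filters active at i1) x (filters active at
    i2).  Pairs are canonicalized j1 < j2; a filter paired with itself at
    two positions is kept (distinct filters only is enforced later at the
    TF level, where self-interactions are dropped).
    """
    d = collapsed.shape[0]
    active = [active_filters_at(pooled, i, max_activation) for i in range(d)]
    occupied = [i for i in range(d) if len(active[i])]
    out = []
    for i1, i2 in itertools.combinations(occupied, 2):
        value = max(collapsed[i1, i2], collapsed[i2, i1])
        for j1 in active[i1]:
            for j2 in active[i2]:
                if j1 == j2:
                    continue
                pair = (int(j1), int(j2)) if j1 < j2 else (int(j2), int(j1))
                out.append((pair, float(value), (i1, i2)))
    return out


def aggregate_profiles(records, pool_window: int,
                       attn_cutoff: float = 0.10
                       ) -> dict[tuple[int, int], PairAttentionProfile]:
    """Accumulate per-example records into profiles and apply the cutoff.

    ``records`` is an iterable of ``(example_id, pair, value, positions)``.
    Pairs whose maximum attention value stays below ``attn_cutoff`` are
    discarded entirely.
    """
    profiles: dict[tuple[int, int], PairAttentionProfile] = {}
    for example_id, pair, value, positions in records:
        prof = profiles.get(pair)
        if prof is None:
            prof = profiles[pair] = PairAttentionProfile(pair)
        prof.add(value, example_id, positions, pool_window)
    return {p: prof for p, prof in profiles.items()
            if prof.max_value >= attn_cutoff}


def profiles_from_batch(attention: np.ndarray, pooled: np.ndarray,
                        max_activation: np.ndarray, example_ids,
                        pool_window: int, attn_cutoff: float = 0.10
                        ) -> dict[tuple[int, int], PairAttentionProfile]:
    """Profiles for a batch: collapse heads, extract pairs, aggregate.

    ``attention`` is (N, k, d, d) and ``pooled`` (N, F, d) as returned by
    the model's forward pass; ``max_activation`` must come from the same
    sequence set used for motif extraction so the two activation rules
    agree.
    """
    def records():
        for n, ex_id in enumerate(example_ids):
            collapsed = collapse_heads(attention[n])
            for pair, value, positions in extract_pair_attention(
                    collapsed, pooled[n], max_activation, ex_id):
                yield ex_id, pair, value, positions

    return aggregate_profiles(records(), pool_window, attn_cutoff)


# ------------------------------------------------------------- statistics
def mann_whitney_test(fg, bg) -> float:
    """One-sided (foreground greater) Mann-Whitney U p-value.

    Exact null distribution for small tie-free samples (n1 + n2 <= 20),
    normal approximation with tie correction otherwise.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([fg, bg])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(fg, bg, alternative="greater",
                                    method=method).pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment; input order preserved."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


# ----------------------------------------------------------------- calling
def call_interactions(profiles_fg: dict, profiles_bg: dict,
                      filter_to_tf: dict[int, str], alpha: float = 0.05,
                      fallback_background: bool = True) -> list[InteractionCall]:
    """Significant, deduplicated TF-pair interaction calls.

    Per foreground pair: Mann-Whitney U against the same pair's
    background profile (when ``fallback_background`` is on, a pair absent
    from the background is tested against the pooled attention values of
    all background pairs — the generic null for attention magnitude);
    Benjamini-Hochberg across all tested pairs; pairs with adjusted
    p < ``alpha`` are mapped to TF pairs.  Pairs whose two filters map to
    the same TF, or to no characterized TF, are dropped; multiple filter
    pairs mapping to one TF pair collapse into a single call keeping the
    smallest adjusted p and summing frequencies.
    """
    if not profiles_bg:
        raise ValueError(
            "background profiles are empty: build a background set (negative "
            "test examples or dinucleotide-shuffled sequences) first")
    bg_pool = np.concatenate([p.values for p in profiles_bg.values()])
    tested, pvals = [], []
    for pair, prof in sorted(profiles_fg.items()):
        bg_prof = profiles_bg.get(pair)
        if bg_prof is not None and bg_prof.values:
            bg_values = bg_prof.values
        elif fallback_background:
            bg_values = bg_pool
        else:
            logger.warning("pair %s has no background profile; skipped", pair)
            continue
        tested.append((pair, prof))
        pvals.append(mann_whitney_test(prof.values, bg_values))
    if not tested:
        return []
    adj = benjamini_hochberg(pvals)

    best: dict[tuple[str, str], InteractionCall] = {}
    for (pair, prof), p_raw, p_adj in zip(tested, pvals, adj):
        if p_adj >= alpha:
            continue
        tf1 = filter_to_tf.get(pair[0], UNCHARACTERIZED)
        tf2 = filter_to_tf.get(pair[1], UNCHARACTERIZED)
        if tf1 == tf2 or UNCHARACTERIZED in (tf1, tf2):
            continue  # self-interactions / unnamed filters are not reported
        tf_pair = tuple(sorted((tf1, tf2)))
        call = InteractionCall(
            filter_pair=pair, tf_pair=tf_pair, p_value=float(p_raw),
            adj_p_value=float(p_adj), max_attention=prof.max_value,
            frequency=prof.frequency,
            median_distance_bp=float(np.median(prof.distances_bp)))
        cur = best.get(tf_pair)
        if cur is None:
            best[tf_pair] = call
        else:
            merged = dataclasses.replace(
                cur if cur.adj_p_value <= call.adj_p_value else call,
                frequency=cur.frequency + call.frequency)
            best[tf_pair] = merged
    return sorted(best.values(), key=lambda c: (c.adj_p_value, c.tf_pair))


_CALL_COLUMNS = ["filter1", "filter2", "tf1", "tf2", "p_value", "adj_p_value",
                 "max_attention", "frequency", "median_distance_bp"]


def calls_to_frame(calls: list[InteractionCall]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=_CALL_COLUMNS)
    return pd.DataFrame([{
        "filter1": c.filter_pair[0], "filter2": c.filter_pair[1],
        "tf1": c.tf_pair[0], "tf2": c.tf_pair[1],
        "p_value": c.p_value, "adj_p_value": c.adj_p_value,
        "max_attention": c.max_attention, "frequency": c.frequency,
        "median_distance_bp": c.median_distance_bp,
    } for c in calls])


def family_summary(calls: list[InteractionCall],
                   tf_to_family: dict[str, str]) -> pd.DataFrame:
    """Frequency table of unordered TF-family pairs, sorted descending."""
    counts: dict[tuple[str, str], int] = {}
    for c in calls:
        fam = tuple(sorted(tf_to_family.get(tf, "unknown") for tf in c.tf_pair))
        counts[fam] = counts.get(fam, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["family1", "family2", "count", "percent"])
    total = sum(counts.values())
    rows = [{"family1": k[0], "family2": k[1], "count": v,
             "percent": 100.0 * v / total}
            for k, v in counts.items()]
    return pd.DataFrame(rows).sort_values(
        ["count", "family1", "family2"], ascending=[False, True, True]
    ).reset_index(drop=True)


def overlap_enrichment(predicted: set, known: set, universe: int) -> float:
    """Upper-tail hypergeometric p-value of the predicted/known overlap.

    ``universe`` is the number of candidate pairs the two sets were drawn
    from (e.g. all unordered pairs of the matched TFs).  Pairs are
    canonicalized to unordered tuples before intersecting.
    """
    canon = lambda s: {tuple(sorted(p)) for p in s}
    predicted, known = canon(predicted), canon(known)
    if not known or not predicted:
        return 1.0
    if universe < max(len(predicted), len(known)):
        raise ValueError("universe smaller than the sets drawn from it")
    overlap = len(predicted & known)
    return float(stats.hypergeom.sf(overlap - 1, universe, len(known),
                                    len(predicted)))
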