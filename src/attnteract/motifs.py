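"""Filter-to-motif conversion and filter-to-TF naming.

First-layer convolutional filters are interpreted as motifs by
collecting, across a set of high-confidence sequences, every substring
whose activation exceeds half of that filter's maximum activation over
all sequences, stacking the substrings into a counts-with-pseudocount
position weight matrix, and scoring its information content against the
background.

Filters are then named after transcription factors either by parsing a
TomTom result table (for real motif databases) or, for self-contained
runs, with the bundled PWM matcher, which aligns a filter PWM against
each database motif at every offset and scores the best mean per-column
Euclidean distance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Model
from .seqdata import ALPHABET, Sequence, encode_batch
from .synth import MotifModel

__all__ = [
    "FilterMotif", "MotifMatch", "collect_activating_substrings",
    "build_pwm", "information_content", "extract_filter_motifs",
    "write_meme", "read_meme", "parse_tomtom", "match_pwms",
    "map_filters_to_tfs",
]

UNCHARACTERIZED = "uncharacterized"


@dataclasses.dataclass
class FilterMotif:
    """One filter's learned motif and its activation statistics."""

    index: int
    pwm: MotifModel | None          # None when the filter never activates
    ic: float                       # information content, bits
    activation_count: int           # substrings above the half-max threshold
    max_activation: float


@dataclasses.dataclass(frozen=True)
class MotifMatch:
    """One filter-vs-database comparison row (TomTom dialect)."""

    filter_index: int
    tf_name: str
    p_value: float
    q_value: float
    tf_family: str = ""

    def __post_init__(self):
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q-value {self.q_value} outside [0, 1]")


def collect_activating_substrings(model: Model, seqs: list[Sequence],
                                  batch_size: int = 256):
    """Per-filter activating substrings, positions, and the half-max rule.

    A window activates filter j when its post-ReLU convolution score
    exceeds 0.5 x (the global maximum score of filter j over all given
    sequences).  Returns ``(per_filter, max_activation)`` where
    ``per_filter[j]`` is a list of ``(example_index, position, substring)``
    and ``max_activation`` the per-filter global maxima.
    """
    cfg = model.config
    if not seqs:
        return ([[] for _ in range(cfg.n_filters)],
                np.zeros(cfg.n_filters))
    x = encode_batch(seqs, cfg.seq_len)
    conv_maps = []
    for start in range(0, len(seqs), batch_size):
        conv_maps.append(model.forward(x[start:start + batch_size]).conv_map)
    conv = np.concatenate(conv_maps)                     # (N, F, L')
    max_act = conv.max(axis=(0, 2))                      # (F,)
    per_filter: list[list[tuple[int, int, str]]] = [[] for _ in range(cfg.n_filters)]
    padded = [s.bases if len(s.bases) == cfg.seq_len
              else _pad_to(s.bases, cfg.seq_len) for s in seqs]
    for j in range(cfg.n_filters):
        if max_act[j] <= 0:
            continue
        hits = np.argwhere(conv[:, j, :] > 0.5 * max_act[j])
        for n, i in hits:
            per_filter[j].append((int(n), int(i),
                                  padded[n][i:i + cfg.filter_len]))
    return per_filter, max_act


def _pad_to(bases: str, length: int) -> str:
    from .seqdata import equalize_length
    return equalize_length(Sequence("_", bases), length).bases


def build_pwm(substrings: list[str], pseudocount: float = 0.5,
              background: np.ndarray | None = None,
              name: str = "motif") -> MotifModel | None:
    """Counts-with-pseudocount PWM from equal-length substrings.

    ``N`` characters contribute no counts.  Returns ``None`` for an empty
    substring list (a filter that never activated).
    """
    if not substrings:
        return None
    widths = {len(s) for s in substrings}
    if len(widths) != 1:
        raise ValueError(f"substrings differ in length: {sorted(widths)}")
    w = widths.pop()
    counts = np.full((4, w), float(pseudocount))
    for s in substrings:
        for c, base in enumerate(s):
            k = ALPHABET.find(base)
            if k >= 0:
                counts[k, c] += 1.0
    return MotifModel(name, counts / counts.sum(axis=0, keepdims=True))


def information_content(pwm: MotifModel,
                        background: np.ndarray | None = None) -> float:
    """Kullback-Leibler divergence from background, in bits, summed over columns."""
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    p = pwm.pwm
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q[:, None]), 0.0)
    return float(terms.sum())


def extract_filter_motifs(model: Model, seqs: list[Sequence],
                          pseudocount: float = 0.5,
                          background: np.ndarray | None = None
                          ) -> list[FilterMotif]:
    """Full filter -> motif pipeline: collect, stack, score."""
    per_filter, max_act = collect_activating_substrings(model, seqs)
    out = []
    for j, hits in enumerate(per_filter):
        pwm = build_pwm([s for _, _, s in hits], pseudocount, background,
                        name=f"filter_{j}")
        ic = information_content(pwm, background) if pwm is not None else 0.0
        out.append(FilterMotif(j, pwm, ic, len(hits), float(max_act[j])))
    return out


# --------------------------------------------------------------- MEME format
def write_meme(motifs: list[FilterMotif | MotifModel], path,
               background: np.ndarray | None = None) -> None:
    """MEME minimal motif format (the input TomTom expects)."""
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*q))
        for m in motifs:
            model = m.pwm if isinstance(m, FilterMotif) else m
            if model is None:
                continue
            name = model.name if isinstance(m, MotifModel) else f"filter_{m.index}"
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {model.width} "
                     f"nsites= 20 E= 0\n")
            for col in model.pwm.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    def finish(name, rows):
        pwm = np.array(rows).T
        # written probabilities are rounded; renormalize the columns
        return MotifModel(name, pwm / pwm.sum(axis=0, keepdims=True))

    motifs: list[MotifModel] = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    motifs.append(finish(name, rows))
                parts = line.split()
                name, rows = parts[1], []
            elif name is not None and line and line[0] in "0123456789.":
                rows.append([float(v) for v in line.split()[:4]])
    if name is not None and rows:
        motifs.append(finish(name, rows))
    return motifs


# ----------------------------------------------------------- filter naming
def parse_tomtom(path) -> list[MotifMatch]:
    """Parse a TomTom TSV result table into :class:`MotifMatch` rows.

    Expects the standard columns ``Query_ID``, ``Target_ID``, ``p-value``
    and ``q-value``; query ids must follow the ``filter_<j>`` convention
    used by :func:`write_meme`.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"Query_ID", "Target_ID", "p-value", "q-value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TomTom columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        query = str(row["Query_ID"])
        try:
            idx = int(query.rsplit("_", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}: query id {query!r} is not of the form filter_<j>"
            ) from exc
        out.append(MotifMatch(idx, str(row["Target_ID"]),
                              float(row["p-value"]), float(row["q-value"])))
    return out


def match_pwms(filters: list[FilterMotif], database: list[MotifModel],
               max_mean_dist: float = 0.5, min_overlap: int = 5,
               min_ic: float = 0.0) -> list[MotifMatch]:
    """Bundled filter-vs-database matcher for self-contained runs.

    Slides each database PWM along the filter PWM (uniform 0.25 columns
    fill the non-overlapping part implicitly by requiring ``min_overlap``
    aligned columns) and scores the mean per-column Euclidean distance of
    the best alignment.  A match is reported when that distance is below
    ``max_mean_dist``; the distance doubles as both p- and q-value proxy
    so :func:`map_filters_to_tfs` ranks matches identically to a TomTom
    table sorted by significance.
    """
    out = []
    for f in filters:
        if f.pwm is None or f.ic < min_ic:
            continue
        for target in database:
            dist = _best_alignment_distance(f.pwm.pwm, target.pwm, min_overlap)
            if dist is not None and dist < max_mean_dist:
                score = min(1.0, dist)
                out.append(MotifMatch(f.index, target.name, score, score))
    return out


def _best_alignment_distance(query: np.ndarray, target: np.ndarray,
                             min_overlap: int) -> float | None:
    wq, wt = query.shape[1], target.shape[1]
    min_overlap = min(min_overlap, wq, wt)
    best = None
    for offset in range(-wt + min_overlap, wq - min_overlap + 1):
        q_lo, q_hi = max(0, offset), min(wq, offset + wt)
        t_lo = q_lo - offset
        overlap = q_hi - q_lo
        if overlap < min_overlap:
            continue
        diff = query[:, q_lo:q_hi] - target[:, t_lo:t_lo + overlap]
        dist = float(np.mean(np.linalg.norm(diff, axis=0)))
        if best is None or dist < best:
            best = dist
    return best


def map_filters_to_tfs(matches: list[MotifMatch],
                       n_filters: int | None = None) -> dict[int, str]:
    """Most significant database hit per filter.

    Smallest q-value wins; ties break by smallest p-value and then by
    lexicographic TF name, so the result is invariant to row order.
    Filters without any row map to ``"uncharacterized"`` when
    ``n_filters`` is given.
    """
    best: dict[int, MotifMatch] = {}
    for m in matches:
        cur = best.get(m.filter_index)
        if cur is None or (m.q_value, m.p_value, m.tf_name) < \
                (cur.q_value, cur.p_value, cur.tf_name):
            best[m.filter_index] = m
    mapping = {j: m.tf_name for j, m in best.items()}
    if n_filters is not None:
        for j in range(n_filters):
            mapping.setdefault(j, UNCHARACTERIZED)
    return mapping
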