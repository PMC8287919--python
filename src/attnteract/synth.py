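"""Synthetic benchmark datasets and shuffled background sets.

The generator emulates the embedded-motif interaction benchmark: random
DNA sequences in which positives carry an instance of *both* members of
an interacting motif pair, negatives carry exactly one of the two, and
decoy motifs are scattered over both classes.  Ground-truth embedding
coordinates are returned so recovery can be verified exactly.

The module also builds null backgrounds for significance testing:
test sequences are shuffled with the Altschul-Erickson Euler-path
algorithm, which preserves the overlapping dinucleotide count table
exactly, and motifs derived from CNN filters are re-embedded in
proportion to how often each filter was active in the real data.

The bundled ELF1/SIX5/TAL1/AP3 position weight matrices are synthetic
stand-ins constructed from each factor's core consensus; they model the
right motif families, not any specific database entry.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .seqdata import ALPHABET, LabeledDataset, Sequence

__all__ = [
    "MotifModel", "EmbeddingRecord", "motif_from_consensus", "benchmark_motifs",
    "sample_background_sequence", "embed_motif", "generate_benchmark1",
    "dinucleotide_shuffle", "build_background_set", "dinucleotide_counts",
]


@dataclasses.dataclass(frozen=True)
class MotifModel:
    """A named motif as a 4 x w column-stochastic probability matrix."""

    name: str
    pwm: np.ndarray

    def __post_init__(self):
        pwm = np.asarray(self.pwm, dtype=np.float64)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[0] != 4:
            raise ValueError("pwm must be a 4 x w matrix")
        if pwm.size and (np.any(pwm < 0)
                         or np.max(np.abs(pwm.sum(axis=0) - 1.0)) > 1e-9):
            raise ValueError(f"pwm columns of {self.name!r} must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.pwm.argmax(axis=0))

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one instance, sampling each column independently."""
        return "".join(
            ALPHABET[rng.choice(4, p=self.pwm[:, c])] for c in range(self.width))


@dataclasses.dataclass(frozen=True)
class EmbeddingRecord:
    """Ground truth for one embedded motif instance (0-based start)."""

    sequence_id: str
    motif_name: str
    start: int
    instance: str

    @property
    def end(self) -> int:
        return self.start + len(self.instance)


def motif_from_consensus(name: str, consensus: str, p: float = 0.85) -> MotifModel:
    """PWM putting probability ``p`` on the consensus base per column.

    ``p`` = 0.85 gives realistically degenerate instances; ``p`` = 1
    yields a point-mass motif whose samples always equal the consensus.
    """
    w = len(consensus)
    off = (1.0 - p) / 3.0
    pwm = np.full((4, w), off)
    for c, base in enumerate(consensus.upper()):
        pwm[ALPHABET.index(base), c] = p
    return MotifModel(name, pwm)


def benchmark_motifs(p: float = 0.97) -> dict[str, MotifModel]:
    """Synthetic stand-in motifs for the benchmark's four factors.

    ELF1 carries an ETS GGAA core, SIX5 a homeodomain-like site, TAL1 an
    E-box and AP3 a MADS CArG box; the exact matrices are constructed,
    not taken from a motif database.  The consensus probability ``p`` is
    set so that the two classes are almost perfectly separable by a
    likelihood scan with the true PWMs (the benchmark is designed to be
    solvable; sharp core positions are also what strong TF motifs look
    like).
    """
    return {
        "ELF1": motif_from_consensus("ELF1", "ACCCGGAAGT", p),
        "SIX5": motif_from_consensus("SIX5", "GATCCTGAGA", p),
        "TAL1": motif_from_consensus("TAL1", "AACAGATGGT", p),
        "AP3": motif_from_consensus("AP3", "CCATTTTTGG", p),
    }


def sample_background_sequence(length: int, gc: float = 0.5,
                               rng: np.random.Generator | None = None,
                               seq_id: str = "bg") -> Sequence:
    """I.i.d. random sequence with P(G) + P(C) = ``gc`` (split evenly)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    idx = rng.choice(4, size=length, p=probs)
    bases = "".join(np.array(list(ALPHABET))[idx]) if length else ""
    return Sequence(seq_id, bases)


def embed_motif(seq: Sequence, motif: MotifModel, pos: int,
                rng: np.random.Generator) -> tuple[Sequence, EmbeddingRecord]:
    """Replace ``seq[pos:pos+w]`` with a fresh draw from the motif."""
    w = motif.width
    if pos < 0 or pos + w > len(seq):
        raise ValueError(
            f"embedding of {motif.name!r} (w={w}) at {pos} exceeds "
            f"sequence bounds (L={len(seq)})")
    instance = motif.sample(rng)
    bases = seq.bases[:pos] + instance + seq.bases[pos + w:]
    return Sequence(seq.id, bases), EmbeddingRecord(seq.id, motif.name, pos, instance)


def _place_non_overlapping(length: int, widths: list[int],
                           rng: np.random.Generator,
                           max_tries: int = 200) -> list[int]:
    """Uniform-ish non-overlapping starts for the given widths."""
    for _ in range(max_tries):
        starts, spans = [], []
        ok = True
        for w in widths:
            for _ in range(max_tries):
                s = int(rng.integers(0, length - w + 1))
                if all(s + w <= a or s >= b for a, b in spans):
                    starts.append(s)
                    spans.append((s, s + w))
                    break
            else:
                ok = False
                break
        if ok:
            return starts
    raise ValueError(
        f"cannot place motifs of widths {widths} without overlap in {length} bp")


def generate_benchmark1(n_pos: int, n_neg: int,
                        pair: tuple[MotifModel, MotifModel] | None = None,
                        decoys: list[MotifModel] | None = None,
                        length: int = 300, gc: float = 0.5,
                        decoy_prob: float = 0.3,
                        rng: np.random.Generator | int | None = None,
                        ) -> tuple[LabeledDataset, list[EmbeddingRecord]]:
    """Embedded-motif interaction benchmark.

    Every positive sequence contains one instance of each member of
    ``pair`` (the simulated interaction); every negative contains exactly
    one of the two, chosen at random.  Each decoy motif is additionally
    embedded with probability ``decoy_prob`` per sequence, in both
    classes.  All embeddings are mutually non-overlapping, with positions
    uniform among the placements that keep them so.

    Defaults: ELF1/SIX5 as the interacting pair, TAL1/AP3 as decoys,
    300 bp sequences at GC 0.5.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    motifs = benchmark_motifs()
    if pair is None:
        pair = (motifs["ELF1"], motifs["SIX5"])
    if decoys is None:
        decoys = [motifs["TAL1"], motifs["AP3"]]
    min_len = sum(m.width for m in (*pair, *decoys))
    if length < min_len:
        raise ValueError(f"length {length} cannot hold all motifs ({min_len} bp)")

    sequences: list[Sequence] = []
    labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)]).astype(np.int64)
    records: list[EmbeddingRecord] = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        seq_id = f"pos_{i}" if positive else f"neg_{i - n_pos}"
        seq = sample_background_sequence(length, gc, rng, seq_id)
        if positive:
            planted = list(pair)
        else:
            planted = [pair[int(rng.integers(2))]]
        planted += [d for d in decoys if rng.random() < decoy_prob]
        starts = _place_non_overlapping(length, [m.width for m in planted], rng)
        for motif, start in zip(planted, starts):
            seq, rec = embed_motif(seq, motif, start, rng)
            records.append(rec)
        sequences.append(seq)
    return LabeledDataset(sequences, labels), records


def dinucleotide_counts(bases: str) -> dict[str, int]:
    """Count table of the overlapping 2-mers of ``bases``."""
    counts: dict[str, int] = {}
    for i in range(len(bases) - 1):
        di = bases[i:i + 2]
        counts[di] = counts.get(di, 0) + 1
    return counts


def dinucleotide_shuffle(seq: Sequence, rng: np.random.Generator) -> Sequence:
    """Shuffle preserving the exact overlapping-dinucleotide count table.

    Altschul-Erickson construction: the sequence is an Euler path in the
    multigraph whose edges are its dinucleotides; a uniform random Euler
    path with the same start vertex is drawn by choosing, for every
    vertex other than the final one, a random "last exit" edge that must
    lead to the final vertex, then shuffling the remaining exits.  First
    and last bases are preserved by construction.
    """
    s = seq.bases
    if len(s) < 2:
        return Sequence(seq.id, s)
    # adjacency: out-edges (successor characters) per vertex, in order
    edges: dict[str, list[str]] = {}
    for i in range(len(s) - 1):
        edges.setdefault(s[i], []).append(s[i + 1])
    last_vertex = s[-1]
    vertices = list(edges.keys())

    def last_edges_connect() -> dict[str, str] | None:
        chosen = {v: edges[v][int(rng.integers(len(edges[v])))]
                  for v in vertices if v != last_vertex}
        # every vertex must reach last_vertex via chosen last-exits
        for v in chosen:
            hops, cur = 0, v
            while cur != last_vertex:
                if cur not in chosen or hops > len(vertices):
                    return None
                cur = chosen[cur]
                hops += 1
        return chosen

    while True:
        chosen = last_edges_connect()
        if chosen is not None:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last_vertex:
            rest.remove(chosen[v])
        rng.shuffle(rest)
        if v != last_vertex:
            rest.append(chosen[v])
        shuffled[v] = rest
    # walk the Euler path
    out = [s[0]]
    counters = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return Sequence(seq.id, "".join(out))


def build_background_set(test_seqs: list[Sequence],
                         filter_motifs: list[MotifModel],
                         activation_counts: list[int] | np.ndarray,
                         rng: np.random.Generator) -> list[Sequence]:
    """Null sequences for significance testing of multi-label models.

    Each test sequence is dinucleotide-shuffled; then, for each filter
    motif, as many instances as the filter was active in the real test
    data are embedded at uniformly random sequence/position pairs.
    Placements avoid previously embedded spans (rejection sampling) so
    every requested instance survives intact; an instance is dropped
    only if no non-overlapping placement can be found.
    """
    activation_counts = np.asarray(activation_counts, dtype=np.int64)
    if len(activation_counts) != len(filter_motifs):
        raise ValueError("one activation count per filter motif required")
    shuffled = [dinucleotide_shuffle(s, rng) for s in test_seqs]
    if not shuffled:
        return []
    occupied: list[list[tuple[int, int]]] = [[] for _ in shuffled]
    for motif, count in zip(filter_motifs, activation_counts):
        w = motif.width
        for _ in range(int(count)):
            if w == 0:
                continue
            for _attempt in range(200):
                tgt = int(rng.integers(len(shuffled)))
                seq = shuffled[tgt]
                if w > len(seq):
                    continue
                pos = int(rng.integers(0, len(seq) - w + 1))
                if all(pos + w <= a or pos >= b for a, b in occupied[tgt]):
                    shuffled[tgt], _ = embed_motif(seq, motif, pos, rng)
                    occupied[tgt].append((pos, pos + w))
                    break
    return shuffled
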