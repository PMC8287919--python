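"""Config-driven end-to-end runs with on-disk artifacts and manifests.

Each stage reads its inputs from a run directory, writes its outputs
there under conventional names, and drops a JSON manifest recording the
parameters and a hash of the configuration, so any two runs with the
same config and seeds produce identical files.  Stages depend on each
other only through those files; a missing upstream artifact raises an
error naming the command that produces it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fis as fis_mod
from .interactions import (call_interactions, calls_to_frame, family_summary,
                           profiles_from_batch)
from .model import Model, ModelConfig
from .motifs import (extract_filter_motifs, map_filters_to_tfs, match_pwms,
                     parse_tomtom, read_meme, write_meme)
from .seqdata import (LabeledDataset, encode_batch, read_fasta,
                      read_label_table, split_dataset, write_fasta,
                      write_label_table)
from .synth import benchmark_motifs, generate_benchmark1
from .training import (ConfidenceThresholds, evaluate_auc,
                       select_confident_examples, train)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "load_config", "cmd_simulate", "cmd_train", "cmd_evaluate",
    "cmd_motifs", "cmd_interactions", "cmd_fis", "cmd_compare",
]

_FILES = {
    "fasta": "sequences.fa",
    "labels": "labels.tsv",
    "embeddings": "embeddings.tsv",
    "checkpoint": "model.npz",
    "split": "split.tsv",
    "train_log": "training_log.tsv",
    "auc": "auc.json",
    "meme": "filters.meme",
    "filter_stats": "filter_stats.tsv",
    "interactions": "interactions.tsv",
    "families": "family_summary.tsv",
    "fis": "fis_interactions.tsv",
    "compare": "method_overlap.tsv",
}


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs; loadable from YAML with CLI overrides."""

    out_dir: str = "run"
    seed: int = 0
    # simulation
    n_pos: int = 2000
    n_neg: int = 4000
    seq_len: int = 300
    gc: float = 0.5
    decoy_prob: float = 0.3
    # model / training
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    epochs: int = 5
    batch_size: int = 16
    lr: float = 3e-3
    # interpretation
    thresholds: ConfidenceThresholds = dataclasses.field(
        default_factory=ConfidenceThresholds)
    alpha: float = 0.05
    fis_steps: int = 64
    fis_max_examples: int = 50
    motif_db: str | None = None      # MEME file; None -> bundled benchmark motifs
    tomtom_tsv: str | None = None    # pre-computed TomTom results, overrides matcher
    sim_motifs: str | None = None    # MEME file for the generator: first two
                                     # motifs form the pair, the rest are decoys
    tf_families: str | None = None   # TSV (tf, family) enabling the family summary
    top_n: int = 15

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def path(self, key: str) -> Path:
        return Path(self.out_dir) / _FILES[key]


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    model_kwargs = raw.pop("model", {})
    thr_kwargs = raw.pop("thresholds", {})
    cfg = RunConfig(**raw)
    if model_kwargs:
        cfg.model = ModelConfig(**{**dataclasses.asdict(cfg.model), **model_kwargs})
    if thr_kwargs:
        cfg.thresholds = ConfidenceThresholds(
            **{**dataclasses.asdict(cfg.thresholds), **thr_kwargs})
    cfg.model.seq_len = cfg.seq_len
    return cfg


def _write_manifest(cfg: RunConfig, stage: str, extra: dict | None = None) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stage": stage, "config_hash": cfg.config_hash(),
                "seed": cfg.seed, "config": dataclasses.asdict(cfg)}
    if extra:
        manifest.update(extra)
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _require(cfg: RunConfig, key: str, producer: str) -> Path:
    path = cfg.path(key)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the '{producer}' command first")
    return path


def _load_dataset(cfg: RunConfig) -> LabeledDataset:
    seqs = read_fasta(_require(cfg, "fasta", "simulate"))
    table = read_label_table(_require(cfg, "labels", "simulate"))
    labels = table.loc[[s.id for s in seqs]].to_numpy()
    if labels.shape[1] == 1:
        labels = labels[:, 0]
    ds = LabeledDataset(seqs, labels)
    split_path = cfg.path("split")
    if split_path.exists():
        tags = pd.read_csv(split_path, sep="\t").set_index("id")
        ds.split = tags.loc[ds.ids, "split"].to_numpy(dtype=object)
    return ds


# ------------------------------------------------------------------- stages
def cmd_simulate(cfg: RunConfig) -> None:
    """Generate the embedded-motif benchmark dataset and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    pair = decoys = None
    if cfg.sim_motifs:
        motifs = read_meme(cfg.sim_motifs)
        if len(motifs) < 2:
            raise ValueError(f"{cfg.sim_motifs}: need at least two motifs "
                             "(the interacting pair)")
        pair, decoys = (motifs[0], motifs[1]), motifs[2:]
    ds, records = generate_benchmark1(cfg.n_pos, cfg.n_neg, pair=pair,
                                      decoys=decoys, length=cfg.seq_len,
                                      gc=cfg.gc, decoy_prob=cfg.decoy_prob,
                                      rng=rng)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.sequences, cfg.path("fasta"))
    write_label_table(ds.ids, ds.labels, cfg.path("labels"))
    pd.DataFrame([{"sequence_id": r.sequence_id, "motif": r.motif_name,
                   "start": r.start, "instance": r.instance}
                  for r in records]).to_csv(cfg.path("embeddings"), sep="\t",
                                            index=False)
    _write_manifest(cfg, "simulate", {
        "n_total": len(ds), "n_pos": cfg.n_pos, "n_neg": cfg.n_neg,
        "seq_len": cfg.seq_len, "gc": cfg.gc, "decoy_prob": cfg.decoy_prob})
    logger.info("wrote %d sequences to %s", len(ds), cfg.path("fasta"))


def cmd_train(cfg: RunConfig) -> None:
    ds = _load_dataset(cfg)
    split_dataset(ds, (0.8, 0.1, 0.1), seed=cfg.seed)
    pd.DataFrame({"id": ds.ids, "split": ds.split}).to_csv(
        cfg.path("split"), sep="\t", index=False)
    result = train(cfg.model, ds, epochs=cfg.epochs, batch_size=cfg.batch_size,
                   lr=cfg.lr, seed=cfg.seed)
    result.model.save(cfg.path("checkpoint"))
    result.write_log(cfg.path("train_log"))
    _write_manifest(cfg, "train", {"epochs_run": len(result.history)})


def cmd_evaluate(cfg: RunConfig) -> dict:
    _require(cfg, "checkpoint", "train")
    model = Model.load(cfg.path("checkpoint"))
    ds = _load_dataset(cfg)
    report = {split: evaluate_auc(model, ds, split)
              for split in ("val", "test")}
    with open(cfg.path("auc"), "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(cfg, "evaluate")
    return report


def _confident_and_filters(cfg: RunConfig):
    model = Model.load(_require(cfg, "checkpoint", "train"))
    ds = _load_dataset(cfg)
    if not (ds.split == "test").any():
        raise FileNotFoundError(
            f"{cfg.path('split')} lacks test tags: run the 'train' command first")
    fg_idx, bg_idx = select_confident_examples(model, ds, cfg.thresholds, "test")
    fg, bg = ds.subset(fg_idx), ds.subset(bg_idx)
    filters = extract_filter_motifs(model, fg.sequences)
    return model, ds, fg, bg, filters


def cmd_motifs(cfg: RunConfig) -> None:
    """Extract filter motifs, write the MEME file and activation stats."""
    _model, _ds, _fg, _bg, filters = _confident_and_filters(cfg)
    write_meme(filters, cfg.path("meme"))
    pd.DataFrame([{"filter": f.index, "ic_bits": f.ic,
                   "activation_count": f.activation_count,
                   "max_activation": f.max_activation}
                  for f in filters]).to_csv(cfg.path("filter_stats"), sep="\t",
                                            index=False)
    _write_manifest(cfg, "motifs")


def _filter_mapping(cfg: RunConfig, filters) -> dict[int, str]:
    if cfg.tomtom_tsv:
        return map_filters_to_tfs(parse_tomtom(cfg.tomtom_tsv),
                                  n_filters=cfg.model.n_filters)
    db = read_meme(cfg.motif_db) if cfg.motif_db \
        else list(benchmark_motifs().values())
    matches = match_pwms(filters, db, min_ic=cfg.thresholds.min_ic)
    return map_filters_to_tfs(matches, n_filters=cfg.model.n_filters)


def cmd_interactions(cfg: RunConfig) -> pd.DataFrame:
    """Attention-route interaction calls on the confident test examples."""
    model, _ds, fg, bg, filters = _confident_and_filters(cfg)
    max_act = np.array([f.max_activation for f in filters])
    mapping = _filter_mapping(cfg, filters)

    def batch_profiles(subset):
        merged: dict = {}
        x = encode_batch(subset.sequences, cfg.model.seq_len)
        for start in range(0, len(subset), 256):
            res = model.forward(x[start:start + 256])
            chunk = profiles_from_batch(res.attention, res.pooled, max_act,
                                        subset.ids[start:start + 256],
                                        cfg.model.pool_window,
                                        cfg.thresholds.attention)
            for pair, prof in chunk.items():
                if pair in merged:
                    base = merged[pair]
                    base.values += prof.values
                    base.example_ids += prof.example_ids
                    base.position_pairs += prof.position_pairs
                    base.distances_bp += prof.distances_bp
                else:
                    merged[pair] = prof
        return {p: pr for p, pr in merged.items()
                if pr.max_value >= cfg.thresholds.attention}

    profiles_fg, profiles_bg = batch_profiles(fg), batch_profiles(bg)
    if profiles_fg and profiles_bg:
        calls = call_interactions(profiles_fg, profiles_bg, mapping, cfg.alpha)
    else:
        logger.warning("no attention profile cleared the cutoff on the "
                       "%s side; writing an empty interaction table",
                       "foreground" if not profiles_fg else "background")
        calls = []
    frame = calls_to_frame(calls)
    frame.to_csv(cfg.path("interactions"), sep="\t", index=False)
    if cfg.tf_families:
        families = pd.read_csv(cfg.tf_families, sep="\t")
        fam_map = dict(zip(families.iloc[:, 0], families.iloc[:, 1]))
        family_summary(calls, fam_map).to_csv(cfg.path("families"), sep="\t",
                                              index=False)
    _write_manifest(cfg, "interactions", {"n_calls": len(calls)})
    return frame


def cmd_fis(cfg: RunConfig) -> pd.DataFrame:
    """FIS-route interaction calls (Integrated Gradients based)."""
    model, _ds, fg, bg, filters = _confident_and_filters(cfg)
    max_act = np.array([f.max_activation for f in filters])
    mapping = _filter_mapping(cfg, filters)
    rng = np.random.default_rng(cfg.seed + 1)

    def records_for(subset, cap):
        records = []
        n = min(len(subset), cap)
        x = encode_batch(subset.sequences[:n], cfg.model.seq_len)
        for i in range(n):
            conv = model.forward(x[i:i + 1]).conv_map[0]
            spans = fis_mod.activated_filter_spans(model, conv, max_act)
            records += fis_mod.fis_for_example(model, x[i], spans,
                                               subset.ids[i], rng,
                                               m=cfg.fis_steps)
        return records

    records_fg = records_for(fg, cfg.fis_max_examples)
    records_bg = records_for(bg, cfg.fis_max_examples)
    if records_fg and records_bg:
        calls = fis_mod.fis_call_interactions(records_fg, records_bg,
                                              mapping, cfg.alpha)
    else:
        logger.warning("no FIS records on the %s side; writing an empty table",
                       "foreground" if not records_fg else "background")
        calls = []
    frame = calls_to_frame(calls)
    frame.to_csv(cfg.path("fis"), sep="\t", index=False)
    _write_manifest(cfg, "fis", {"n_calls": len(calls)})
    return frame


def cmd_compare(cfg: RunConfig) -> pd.DataFrame:
    """Overlap report between attention-route and FIS-route calls."""
    for key, producer in (("interactions", "interactions"), ("fis", "fis")):
        _require(cfg, key, producer)

    def load_calls(key):
        df = pd.read_csv(cfg.path(key), sep="\t")
        return [fis_mod.InteractionCall(
            (int(r.filter1), int(r.filter2)), (r.tf1, r.tf2), r.p_value,
            r.adj_p_value, r.max_attention, int(r.frequency),
            r.median_distance_bp) for r in df.itertuples()]

    report = fis_mod.compare_methods(load_calls("interactions"),
                                     load_calls("fis"), cfg.top_n)
    rows = [{"tf1": p[0], "tf2": p[1],
             "in_attention_top": p in report["top_attention"],
             "in_fis_top": p in report["top_fis"]}
            for p in dict.fromkeys(report["top_fis"] + report["top_attention"])]
    frame = pd.DataFrame(rows, columns=["tf1", "tf2", "in_attention_top",
                                        "in_fis_top"])
    frame.to_csv(cfg.path("compare"), sep="\t", index=False)
    _write_manifest(cfg, "compare", {"n_common": report["n_common"],
                                     "top_n": cfg.top_n})
    return frame
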