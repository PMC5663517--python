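"""End-to-end pipeline: featurize -> train -> hills -> cluster -> motifs -> score.

`run_pipeline` drives the whole analysis on an in-memory labeled dataset and
returns a result bundle; `run_all` additionally reads inputs from disk and
writes the full output directory. The same hill/motif stages can also be run
on top of the naive multi-class (MCC) baseline weights for benchmarking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataio import LabeledDataset, write_outputs
from .features import FeatureMatrix, KmerSpace, count_and_standardize
from .hills import DEFAULT_THRESHOLD, Hill, find_hills
from .model import TrainConfig, WeightSet
from .motifs import PWM, MotifScoreTable, cluster_hills, discover_pwm, score_table
from .trainer import admm_fit, fit_mcc_baseline

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    dataset: LabeledDataset
    features: FeatureMatrix
    model: WeightSet
    hills: list[Hill] = field(default_factory=list)
    motifs: list[PWM] = field(default_factory=list)
    table: MotifScoreTable | None = None


def _label_weights(model: WeightSet) -> dict[str, np.ndarray]:
    return {p: model.W_lab[j] for j, p in enumerate(model.structure.labels)}


def discover_and_score(
    dataset: LabeledDataset,
    space: KmerSpace,
    source_weights: dict[str, tuple[np.ndarray, list[int]]],
    score_weights: dict[str, np.ndarray],
    hill_thresh: float = DEFAULT_THRESHOLD,
    seed: int = 1,
    max_hills: int = 1000,
    min_cluster_for_em: int = 10,
) -> tuple[list[Hill], list[PWM], MotifScoreTable]:
    """Hill-finding, clustering and motif discovery per source model.

    ``source_weights`` maps a model name (a subclass or a label) to its
    weight vector and the indices of the sequences it may scan — hills for
    a model are called only on sequences belonging to it. Discovered PWMs
    from all sources are pooled and scored against every ``score_weights``
    model.
    """
    all_hills: list[Hill] = []
    motifs: list[PWM] = []
    for si, (name, (w, idx)) in enumerate(sorted(source_weights.items())):
        hills = find_hills([dataset.sequences[i] for i in idx], list(idx), w,
                           space, source_model=name, threshold=hill_thresh)
        all_hills.extend(hills)
        if len(hills) < min_cluster_for_em:
            log.info("model %s: %d hills, skipping motif discovery", name, len(hills))
            continue
        clusters = cluster_hills(hills, space, seed=seed + 17 * si,
                                 max_hills=max_hills)
        for ci, cluster in enumerate(clusters):
            if len(cluster) < min_cluster_for_em:
                continue
            pwm = discover_pwm([h.dna for h in cluster],
                               seed=seed + 17 * si + ci + 1,
                               name=f"{name}_c{ci}",
                               source_cluster=f"{name}/{ci}")
            motifs.append(pwm)
    motifs.sort(key=lambda m: -m.llr)  # strongest first; stabilizes dedupe
    table = score_table(motifs, score_weights, space)
    return all_hills, motifs, table


def run_pipeline(dataset: LabeledDataset, config: TrainConfig | None = None,
                 hill_thresh: float = DEFAULT_THRESHOLD,
                 space: KmerSpace | None = None,
                 include_subclass_scores: bool = True,
                 discovery: str = "subclass") -> PipelineResult:
    """Full deconvolution on an in-memory dataset.

    ``discovery`` selects which trained models are scanned for hills:
    ``"subclass"`` (default) scans each subclass model over its member
    sequences — subclass models carry the full, un-attenuated signal of
    their label combination, and a discovered motif is then attributed to
    the spanning labels whose (sparser) models score it positively;
    ``"label"`` scans each label model over that label's sequences.
    """
    config = config or TrainConfig()
    space = space or KmerSpace()
    fm = count_and_standardize(dataset.sequences, space)
    model = admm_fit(fm.X, dataset.Y, dataset.b, dataset.structure, config)
    struct = dataset.structure
    if discovery == "subclass":
        members = dataset.Y.argmax(axis=1)
        sources = {name: (model.W_sub[i, :-1], np.flatnonzero(members == i))
                   for i, name in enumerate(struct.subclass_names)}
    elif discovery == "label":
        sources = {p: (model.W_lab[j],
                       [i for i, s in enumerate(dataset.label_sets) if p in s])
                   for j, p in enumerate(struct.labels)}
    else:
        raise ValueError(f"unknown discovery mode {discovery!r}")
    score_weights = _label_weights(model)
    if include_subclass_scores:
        score_weights.update({name: model.W_sub[i, :-1]
                              for i, name in enumerate(struct.subclass_names)})
    hills, motifs, table = discover_and_score(
        dataset, space, sources, score_weights,
        hill_thresh=hill_thresh, seed=config.seed)
    return PipelineResult(dataset=dataset, features=fm, model=model,
                          hills=hills, motifs=motifs, table=table)


def run_mcc_pipeline(dataset: LabeledDataset, fm: FeatureMatrix,
                     lam: float = 0.1, seed: int = 1,
                     hill_thresh: float = DEFAULT_THRESHOLD
                     ) -> tuple[dict[str, np.ndarray], MotifScoreTable]:
    """The naive multi-class baseline run through the same motif stages."""
    W, _, labels = fit_mcc_baseline(fm.X, dataset.label_sets, lam=lam, seed=seed)
    label_weights = {p: W[j] for j, p in enumerate(labels)}
    sources = {p: (W[j], [i for i, s in enumerate(dataset.label_sets) if p in s])
               for j, p in enumerate(labels)}
    _, _, table = discover_and_score(dataset, fm.space, sources, label_weights,
                                     hill_thresh=hill_thresh, seed=seed)
    return label_weights, table


def run_all(dataset: LabeledDataset, outdir, config: TrainConfig | None = None,
            hill_thresh: float = DEFAULT_THRESHOLD, window: int = 150):
    """Run the pipeline and write the complete output bundle."""
    config = config or TrainConfig()
    res = run_pipeline(dataset, config, hill_thresh=hill_thresh)
    write_outputs(res.model, res.features.space, res.table, outdir,
                  hills=res.hills, sites=dataset.sites, window=window,
                  config={**config.__dict__, "hill_thresh": hill_thresh})
    return res
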