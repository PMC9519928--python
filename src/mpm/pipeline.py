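"""End-to-end orchestration: enrich -> select -> embed -> featurize -> classify.

``run_experiment`` is the in-memory engine over a parsed :class:`Dataset`;
``run_pipeline`` wraps it with file IO, a YAML config, per-stage logging and
a reproducibility manifest.  Every stochastic stage receives a seed derived
deterministically from the experiment seed and a stage tag, so a run is a
pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import entities_io as eio
from .bio_features import FamilyEncoder, SemanticSimilarityMatrix
from .classifier import (PairFeaturizer, predict_scores,
                         sample_training_negatives, train_model)
from .evaluation import (MetricReport, SplitSpec, compute_report, make_splits,
                         sample_test_negatives)
from .feature_selection import (assign_disease_categories,
                                collapse_rare_categories, relieff_importance,
                                select_top_pcgs)
from .hetnet import SdneConfig, build_heterogeneous_adjacency, train_sdne
from .message_passing import enrich_matrix
from .synthetic import Dataset

logger = logging.getLogger("mpm")

__version__ = "0.1.0"


def derive_seed(seed: int, tag: str) -> int:
    """Stable per-stage sub-seed in [0, 2^31)."""
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineSettings:
    """Tunables of one experiment (paths excluded)."""

    iterations: int = 1              # message-passing steps
    K: int = 100                     # PCGs kept by ReliefF
    relieff_k_neighbors: int = 10
    min_category_size: int = 10
    sdne: SdneConfig = field(default_factory=SdneConfig)
    n_estimators: int = 350
    train_negative_ratio: int = 1
    test_negative_ratio: int = 1
    threshold: float = 0.5
    split_mode: str = "transductive"
    test_fraction: float = 0.2
    seed: int = 0
    # ablation switches (full model keeps both True)
    use_message_passing: bool = True
    use_feature_selection: bool = True
    include_pcg_edges: bool = True


@dataclass
class ExperimentResult:
    split: SplitSpec
    selected_pcgs: list[str]
    scores: pd.DataFrame
    labels: np.ndarray
    report: MetricReport
    model: object
    featurizer: PairFeaturizer
    embeddings: object
    enriched_mirna: np.ndarray
    enriched_disease: np.ndarray


def run_experiment(dataset: Dataset, settings: PipelineSettings | None = None,
                   split: SplitSpec | None = None) -> ExperimentResult:
    """Run the full method on one split and score the held-out pairs."""
    st = settings or PipelineSettings()
    mreg, dreg = dataset.mirna_registry, dataset.disease_registry
    preg = dataset.pcg_net.pcg_registry

    # 1. association profiles over the PCG registry
    w_mp = dataset.mirna_pcg.to_matrix(mreg, preg)
    w_dp = dataset.disease_pcg.to_matrix(dreg, preg)

    # 2. message-passing enrichment
    if st.use_message_passing and st.iterations > 0:
        w_mp = enrich_matrix(dataset.pcg_net, w_mp, iterations=st.iterations)
        w_dp = enrich_matrix(dataset.pcg_net, w_dp, iterations=st.iterations)
    logger.info("enriched profiles: miRNA %s, disease %s", w_mp.shape, w_dp.shape)

    # 3. ontology-supervised feature selection on the disease profiles
    if st.use_feature_selection:
        labeling = collapse_rare_categories(
            assign_disease_categories(dataset.ontology, dreg.ids),
            min_size=st.min_category_size)
        y = labeling.label_array(dreg.ids)
        importance = relieff_importance(w_dp, y, k_neighbors=st.relieff_k_neighbors,
                                        seed=derive_seed(st.seed, "relieff"))
        pk_idx = select_top_pcgs(importance, K=min(st.K, w_dp.shape[1]))
        pk_ids = [preg.id(int(i)) for i in pk_idx]
    else:
        pk_ids = preg.ids
    logger.info("selected %d PCGs", len(pk_ids))

    # 4. evaluation split
    positives = sorted(dataset.mirna_disease.pairs())
    if split is None:
        split = make_splits(positives, st.split_mode,
                            seed=derive_seed(st.seed, "split"),
                            test_fraction=st.test_fraction)
        if isinstance(split, list):
            split = split[0]
    if not split.test_neg:
        split.test_neg = sample_test_negatives(
            split, nr=st.test_negative_ratio,
            seed=derive_seed(st.seed, "test-neg"), all_positives=positives)

    # 5. heterogeneous network from training associations only
    mp_block = w_mp if st.include_pcg_edges else np.zeros_like(w_mp)
    dp_block = w_dp if st.include_pcg_edges else np.zeros_like(w_dp)
    net = dataset.pcg_net if st.include_pcg_edges else _edgeless(dataset.pcg_net)
    adj = build_heterogeneous_adjacency(
        set(split.train_pairs), mreg, dreg, mp_block, dp_block, net, pk_ids,
        forbidden_pairs=set(split.test_pos))
    logger.info("heterogeneous adjacency: %s nodes", adj.matrix.shape[0])

    # 6. SDNE structural embeddings
    sdne_cfg = SdneConfig(**{**asdict(st.sdne), "seed": derive_seed(st.seed, "sdne")})
    embeddings = train_sdne(adj, sdne_cfg)

    # 7. biological features fitted on the training universe
    train_mirnas = sorted({m for m, _ in split.train_pairs}) or mreg.ids
    train_diseases = sorted({d for _, d in split.train_pairs}) or dreg.ids
    encoder = FamilyEncoder.fit(dataset.families, train_mirnas)
    simmat = SemanticSimilarityMatrix.fit(dataset.ontology, train_diseases)
    featurizer = PairFeaturizer(embeddings, dataset.families, encoder, simmat,
                                mreg, dreg)

    # 8. classifier training on train positives + sampled negatives
    train_neg = sample_training_negatives(
        set(positives), train_mirnas, train_diseases,
        ratio=st.train_negative_ratio, seed=derive_seed(st.seed, "train-neg"))
    # negatives sampled outside *all* known positives so held-out true pairs
    # are never mislabeled during training
    need = st.train_negative_ratio * len(split.train_pairs)
    train_neg = train_neg[:need]
    train_pairs = list(split.train_pairs) + train_neg
    y_train = np.array([1] * len(split.train_pairs) + [0] * len(train_neg))
    X_train = featurizer.matrix(train_pairs)
    model = train_model(X_train, y_train, n_estimators=st.n_estimators,
                        seed=derive_seed(st.seed, "forest"),
                        manifest={"split": split.manifest_hash, "mode": split.mode})
    logger.info("trained forest on %d pairs (%d features)", len(train_pairs),
                X_train.shape[1])

    # 9. score the held-out pairs
    test_pairs = list(split.test_pos) + list(split.test_neg)
    labels = np.array([1] * len(split.test_pos) + [0] * len(split.test_neg))
    scores_df = predict_scores(model, test_pairs, featurizer=featurizer)
    scores_df["label"] = labels
    report = compute_report(scores_df["score"].to_numpy(), labels,
                            nr=st.test_negative_ratio, threshold=st.threshold,
                            ids=[f"{m}|{d}" for m, d in test_pairs])
    return ExperimentResult(split=split, selected_pcgs=list(pk_ids),
                            scores=scores_df, labels=labels, report=report,
                            model=model, featurizer=featurizer,
                            embeddings=embeddings,
                            enriched_mirna=w_mp, enriched_disease=w_dp)


def _edgeless(net):
    from .entities_io import DirectedInteractionNetwork
    return DirectedInteractionNetwork(net.pcg_registry, set())


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------

INPUT_KEYS = ("pcg_network", "mirna_pcg", "disease_pcg", "mirna_disease",
              "ontology", "families")


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    outdir: str
    settings: PipelineSettings = field(default_factory=PipelineSettings)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        missing = [k for k in INPUT_KEYS if k not in raw.get("inputs", {})]
        if missing:
            raise ValueError(f"config missing input paths: {missing}")
        st_raw = dict(raw.get("settings", {}))
        sdne_raw = dict(st_raw.pop("sdne", {}))
        if "encoder_sizes" in sdne_raw:
            sdne_raw["encoder_sizes"] = tuple(sdne_raw["encoder_sizes"])
        settings = PipelineSettings(sdne=SdneConfig(**sdne_raw), **st_raw)
        return cls(inputs=dict(raw["inputs"]), outdir=raw.get("outdir", "mpm_out"),
                   settings=settings)


def load_dataset(inputs: dict[str, str]) -> Dataset:
    """Parse the six TSV inputs into a Dataset."""
    net = eio.read_edge_list(inputs["pcg_network"])
    mp = eio.read_association_table(inputs["mirna_pcg"], "miRNA", "PCG", "binary")
    dp = eio.read_association_table(inputs["disease_pcg"], "disease", "PCG", "score")
    md = eio.read_association_table(inputs["mirna_disease"], "miRNA", "disease", "binary")
    tree = eio.read_ontology(inputs["ontology"])
    fam = eio.read_family_map(inputs["families"])
    return Dataset(pcg_net=net, mirna_pcg=mp, disease_pcg=dp, mirna_disease=md,
                   ontology=tree, families=fam)


def run_pipeline(cfg: PipelineConfig) -> ExperimentResult:
    """File-based end-to-end run: parse inputs, execute, persist artefacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps({"inputs": cfg.inputs, "settings": _settings_dict(cfg.settings)},
                       sort_keys=True).encode()).hexdigest(),
        "input_hashes": {},
        "seed": cfg.settings.seed,
        "stage_seeds": {tag: derive_seed(cfg.settings.seed, tag)
                        for tag in ("relieff", "split", "test-neg", "sdne",
                                    "train-neg", "forest")},
        "status": "running",
        "timings": {},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))

    t0 = time.perf_counter()
    stage = "load_inputs"
    try:
        manifest["input_hashes"] = {k: _file_hash(v) for k, v in cfg.inputs.items()}
        dataset = load_dataset(cfg.inputs)
        manifest["timings"][stage] = round(time.perf_counter() - t0, 3)
        stage = "run_experiment"
        t1 = time.perf_counter()
        result = run_experiment(dataset, cfg.settings)
        manifest["timings"][stage] = round(time.perf_counter() - t1, 3)
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # persist intermediates and outputs
    pd.DataFrame({"pcg_id": result.selected_pcgs}).to_csv(
        outdir / "selected_pcgs.tsv", sep="\t", index=False)
    emb = result.embeddings
    emb_df = pd.DataFrame(emb.matrix, columns=[f"e{i}" for i in range(emb.dim)])
    emb_df.insert(0, "node_id", emb.node_ids)
    emb_df.to_csv(outdir / "embeddings.tsv", sep="\t", index=False)
    eio.write_score_table(result.scores[["miRNA_id", "disease_id", "score"]],
                          outdir / "scores.tsv")
    (outdir / "metrics.json").write_text(
        json.dumps(result.report.to_dict(), indent=1))
    (outdir / "split_manifest.json").write_text(json.dumps({
        "mode": result.split.mode,
        "hash": result.split.manifest_hash,
        "n_train": len(result.split.train_pairs),
        "n_test_pos": len(result.split.test_pos),
        "n_test_neg": len(result.split.test_neg),
        "held_out_diseases": result.split.held_out_diseases,
    }, indent=1))

    manifest["status"] = "completed"
    manifest["timings"]["total"] = round(time.perf_counter() - t0, 3)
    manifest_path.write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline completed in %.1fs -> %s", manifest["timings"]["total"], outdir)
    return result


def _settings_dict(st: PipelineSettings) -> dict:
    d = asdict(st)
    d["sdne"]["encoder_sizes"] = list(d["sdne"]["encoder_sizes"])
    return d


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
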