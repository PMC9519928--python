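"""Seeded synthetic benchmark with a planted miRNA-disease association mechanism.

The generator emulates the six pipeline inputs.  Its premise mirrors the
biological rationale of the method: miRNA-disease relevance is mediated by
shared protein-coding-gene (PCG) neighbourhoods.  Each disease category owns
a disjoint set of "signal" PCGs; diseases and miRNAs of a category link to
those signal PCGs (strongly / binarily) on top of a sparse random background,
and a miRNA-disease pair is truly associated exactly when their latent
categories match, subject to label noise.

Everything is a deterministic function of ``SyntheticConfig.seed``: each
artifact draws from its own child stream of a single ``SeedSequence`` so one
artifact's sampling never perturbs another's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .entities_io import (
    AssociationTable,
    DirectedInteractionNetwork,
    EntityRegistry,
    FamilyMap,
    OntologyTree,
    RELATION_SEMANTICS,
)

RELATIONS = sorted(RELATION_SEMANTICS)  # deterministic label order


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults are the benchmark's study conditions."""

    n_pcg: int = 200
    n_mirna: int = 50
    n_disease: int = 30
    n_categories: int = 3
    edges_per_pcg: float = 3.0
    signal_pcgs_per_category: int = 10
    profile_density: float = 0.05
    assoc_noise: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pcg", "n_mirna", "n_disease", "n_categories",
                     "signal_pcgs_per_category"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("profile_density", "assoc_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.edges_per_pcg < 0:
            raise ValueError("edges_per_pcg must be >= 0")
        if self.n_categories * self.signal_pcgs_per_category > self.n_pcg:
            raise ValueError(
                "signal PCG sets cannot be disjoint: "
                f"{self.n_categories} x {self.signal_pcgs_per_category} > {self.n_pcg}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of the planted mechanism (for evaluation only)."""

    category_of_disease: dict[str, str]
    category_of_mirna: dict[str, str]
    signal_pcg_sets: dict[str, list[str]]
    true_pairs: set[tuple[str, str]]

    def to_json(self) -> str:
        payload = {
            "category_of_disease": self.category_of_disease,
            "category_of_mirna": self.category_of_mirna,
            "signal_pcg_sets": {k: sorted(v) for k, v in self.signal_pcg_sets.items()},
            "true_pairs": sorted(map(list, self.true_pairs)),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class Dataset:
    """Parsed in-memory form of the six inputs."""

    pcg_net: DirectedInteractionNetwork
    mirna_pcg: AssociationTable
    disease_pcg: AssociationTable
    mirna_disease: AssociationTable
    ontology: OntologyTree
    families: FamilyMap
    mirna_registry: EntityRegistry = field(default=None)
    disease_registry: EntityRegistry = field(default=None)

    def __post_init__(self):
        if self.mirna_registry is None:
            mirnas = set(self.mirna_pcg.left_ids()) | {m for m, _ in self.mirna_disease.records}
            mirnas |= set(self.families.mapping)
            self.mirna_registry = EntityRegistry.from_ids("miRNA", sorted(mirnas))
        if self.disease_registry is None:
            diseases = set(self.disease_pcg.left_ids()) | {d for _, d in self.mirna_disease.records}
            self.disease_registry = EntityRegistry.from_ids("disease", sorted(diseases))
        # associations may mention PCGs absent from the interaction network
        for table in (self.mirna_pcg, self.disease_pcg):
            for _, pcg in table.records:
                self.pcg_net.pcg_registry.add(pcg)


@dataclass
class SyntheticWorld:
    """Raw generated tables (writable as TSV) plus their parsed Dataset."""

    tables: dict[str, pd.DataFrame]
    dataset: Dataset
    truth: SyntheticTruth
    config: SyntheticConfig

    FILENAMES = {
        "pcg_network": "pcg_network.tsv",
        "mirna_pcg": "mirna_pcg.tsv",
        "disease_pcg": "disease_pcg.tsv",
        "mirna_disease": "mirna_disease.tsv",
        "ontology": "ontology.tsv",
        "families": "families.tsv",
    }

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for key, fname in self.FILENAMES.items():
            path = outdir / fname
            self.tables[key].to_csv(path, sep="\t", index=False)
            paths[key] = path
        (outdir / "truth.json").write_text(self.truth.to_json())
        (outdir / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        return paths


def simulate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Generate all six inputs plus ground truth, fully determined by cfg.seed."""
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_net, rng_dis, rng_mir, rng_pairs, _reserved = map(np.random.default_rng, streams)

    pcg_ids = [f"G{i:04d}" for i in range(cfg.n_pcg)]
    mirna_ids = [f"hsa-mir-{i:04d}" for i in range(cfg.n_mirna)]
    disease_ids = [f"D{i:03d}" for i in range(cfg.n_disease)]
    cat_codes = [f"C{c + 1:02d}" for c in range(cfg.n_categories)]

    # (a) directed PCG functional interaction network
    rows = []
    for i, src in enumerate(pcg_ids):
        k = min(int(rng_net.poisson(cfg.edges_per_pcg)), cfg.n_pcg - 1)
        if k == 0:
            continue
        others = np.delete(np.arange(cfg.n_pcg), i)
        targets = rng_net.choice(others, size=k, replace=False)
        for t in targets:
            rows.append((src, pcg_ids[t], RELATIONS[rng_net.integers(len(RELATIONS))]))
    net_df = pd.DataFrame(rows, columns=["source", "target", "relation"])

    # (b) disjoint signal PCG sets, one per category
    perm = rng_net.permutation(cfg.n_pcg)
    signal_sets = {
        cat_codes[c]: [pcg_ids[j] for j in sorted(
            perm[c * cfg.signal_pcgs_per_category:(c + 1) * cfg.signal_pcgs_per_category])]
        for c in range(cfg.n_categories)
    }
    signal_of = {cat: set(members) for cat, members in signal_sets.items()}

    # balanced round-robin category assignment keeps all categories above the
    # rare-category collapse threshold at the default sizes
    cat_of_disease = {d: cat_codes[i % cfg.n_categories] for i, d in enumerate(disease_ids)}
    cat_of_mirna = {m: cat_codes[i % cfg.n_categories] for i, m in enumerate(mirna_ids)}

    # (c) disease-PCG scored profiles: strong signal + weak sparse background
    drows = []
    for d in disease_ids:
        own = signal_of[cat_of_disease[d]]
        for g in pcg_ids:
            if g in own:
                drows.append((d, g, round(float(rng_dis.uniform(0.6, 1.0)), 6)))
            elif rng_dis.random() < cfg.profile_density:
                drows.append((d, g, round(float(rng_dis.uniform(0.0, 0.4)), 6)))
    disease_pcg_df = pd.DataFrame(drows, columns=["disease_id", "pcg_id", "score"])

    # (d) miRNA-PCG binary profiles
    mrows = []
    for m in mirna_ids:
        own = signal_of[cat_of_mirna[m]]
        for g in pcg_ids:
            if g in own or rng_mir.random() < cfg.profile_density:
                mrows.append((m, g))
    mirna_pcg_df = pd.DataFrame(mrows, columns=["mirna_id", "pcg_id"])

    # (e) true pairs: category match, then independent noise flips
    true_pairs = set()
    for m in mirna_ids:
        for d in disease_ids:
            match = cat_of_mirna[m] == cat_of_disease[d]
            if rng_pairs.random() < cfg.assoc_noise:
                match = not match
            if match:
                true_pairs.add((m, d))
    md_df = pd.DataFrame(sorted(true_pairs), columns=["mirna_id", "disease_id"])

    # (f) ontology: category roots implicit, diseases as leaves
    onto_df = pd.DataFrame(
        [(d, f"{cat_of_disease[d]}.{i + 1:03d}") for i, d in enumerate(disease_ids)],
        columns=["disease_id", "tree_code"],
    )

    # (g) families follow the latent miRNA category
    fam_df = pd.DataFrame(
        [(m, f"FAM-{cat_of_mirna[m]}") for m in mirna_ids],
        columns=["mirna_id", "family"],
    )

    tables = {
        "pcg_network": net_df,
        "mirna_pcg": mirna_pcg_df,
        "disease_pcg": disease_pcg_df,
        "mirna_disease": md_df,
        "ontology": onto_df,
        "families": fam_df,
    }
    dataset = _parse_tables(tables, pcg_ids)
    truth = SyntheticTruth(cat_of_disease, cat_of_mirna,
                           {k: list(v) for k, v in signal_sets.items()}, true_pairs)
    return SyntheticWorld(tables=tables, dataset=dataset, truth=truth, config=cfg)


def _parse_tables(tables: dict[str, pd.DataFrame], pcg_ids: list[str]) -> Dataset:
    """Build the in-memory Dataset directly from the generated frames."""
    registry = EntityRegistry.from_ids("PCG", pcg_ids)
    net = DirectedInteractionNetwork(registry)
    for s, t, rel in tables["pcg_network"].itertuples(index=False):
        net.add_edge(s, t)
        if RELATION_SEMANTICS[rel]:
            net.add_edge(t, s)

    mp = AssociationTable("miRNA", "PCG")
    for m, g in tables["mirna_pcg"].itertuples(index=False):
        mp.add(m, g, 1.0)
    dp = AssociationTable("disease", "PCG")
    for d, g, s in tables["disease_pcg"].itertuples(index=False):
        dp.add(d, g, float(s))
    md = AssociationTable("miRNA", "disease")
    for m, d in tables["mirna_disease"].itertuples(index=False):
        md.add(m, d, 1.0)

    tree = OntologyTree()
    for d, code in tables["ontology"].itertuples(index=False):
        tree.add(d, code)
    tree.close()

    fam = FamilyMap(dict(tables["families"].itertuples(index=False)))
    return Dataset(pcg_net=net, mirna_pcg=mp, disease_pcg=dp,
                   mirna_disease=md, ontology=tree, families=fam)
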