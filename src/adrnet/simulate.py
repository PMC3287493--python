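"""Synthetic DrugBank/SIDER/HAPPI/GO-shaped data with a planted toxicity
mechanism.

The generator emulates the five flat inputs the pipeline consumes. Proteins
are partitioned into modules; protein interactions are dense and
high-confidence within modules, sparse and low-confidence between them. A
few modules are "toxic": a drug is toxic (pre-noise) iff one of its targets
lies in a toxic module or touches one through a single high-confidence
(>= 4 star) interaction — toxicity propagates exactly one physical-
interaction hop, so one-level network expansion can recover signal the raw
target matrix lacks. Deep GO terms are module-specific (shallow terms are
shared), so term-level rollup recovers the same module structure from
annotations alone. Labels are flipped with a small noise rate and surfaced
as ADR names mapped in-range ("Cardiotoxicity_Sim" -> I99) or out of range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (ADRIcdMap, DrugADRMap, DrugTargetMap, GODag, PPINetwork,
                 canonical_adr_name, read_drug_adr_table,
                 read_drug_target_table, read_icd10_table, read_obo,
                 read_ppi_table, write_drug_adr_table, write_drug_target_table,
                 write_icd10_table, write_ppi_table)

logger = logging.getLogger(__name__)

#: star grade at which the planted toxicity relation crosses an interaction
TOXIC_HOP_MIN_STARS = 4

TOXIC_ADR = "Cardiotoxicity_Sim"
BENIGN_ADRS = ("Nausea_Sim", "Headache_Sim", "Rash_Sim")
ADR_CODES = {TOXIC_ADR: "I99", "Nausea_Sim": "R11",
             "Headache_Sim": "R51", "Rash_Sim": "R21"}


@dataclass
class SynthConfig:
    """Knobs of the planted-mechanism generator (defaults = study conditions)."""

    n_drugs: int = 200
    n_proteins: int = 300
    n_modules: int = 12
    toxic_modules: int = 2
    targets_per_drug: tuple[int, int] = (1, 5)
    p_edge_within: float = 0.3
    p_edge_between: float = 0.01
    stars_within: tuple[float, ...] = (0.03, 0.07, 0.15, 0.30, 0.45)
    stars_between: tuple[float, ...] = (0.55, 0.25, 0.12, 0.05, 0.03)
    go_depth: int = 7
    label_noise: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.toxic_modules <= self.n_modules:
            raise ValueError("toxic_modules must be within 0..n_modules")
        lo, hi = self.targets_per_drug
        if not 1 <= lo <= hi <= self.n_proteins:
            raise ValueError("targets_per_drug must lie within [1, n_proteins]")
        for p in (self.p_edge_within, self.p_edge_between, self.label_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for dist in (self.stars_within, self.stars_between):
            if len(dist) != 5 or abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
                raise ValueError("star distributions need 5 probabilities summing to 1")
        if self.go_depth < 2:
            raise ValueError("go_depth must be >= 2")
        if self.p_edge_within == 0.0 and self.toxic_modules > 0:
            logger.warning("p_edge_within = 0: the one-hop toxicity mechanism "
                           "has no within-module interactions to propagate over")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "targets_per_drug" in raw:
            raw["targets_per_drug"] = tuple(raw["targets_per_drug"])
        for key in ("stars_within", "stars_between"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SynthDataset:
    """In-memory view of one generated dataset plus its ground truth."""

    config: SynthConfig
    targets: DrugTargetMap
    adrs: DrugADRMap
    icd: ADRIcdMap
    ppi: PPINetwork
    dag: GODag
    truth: pd.DataFrame          # drug_id, label_prenoise, label, mechanism
    modules: dict[str, int]      # protein_id -> module index
    toxic_module_ids: tuple[int, ...]


def _go_id(k: int) -> str:
    return f"GO:{k:07d}"


def _build_ontology(cfg: SynthConfig) -> tuple[dict[str, str], dict[str, set[str]],
                                               str, dict[int, list[str]]]:
    """Shared shallow terms plus one module-specific chain down to go_depth.

    Returns (terms, parents, root, module_chain) where module_chain[m] lists
    module m's private terms from the shallowest private level to the leaf.
    """
    terms: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    counter = 1
    root = _go_id(counter)
    terms[root] = "biological process"
    parents[root] = set()
    counter += 1

    shared_depth = min(3, cfg.go_depth - 1) if cfg.go_depth > 2 else 1
    shared_by_level: dict[int, list[str]] = {1: [root]}
    for level in range(2, shared_depth + 1):
        n_terms = 3
        shared_by_level[level] = []
        for i in range(n_terms):
            gid = _go_id(counter)
            counter += 1
            terms[gid] = f"shared process L{level}.{i}"
            parent = shared_by_level[level - 1][i % len(shared_by_level[level - 1])]
            parents[gid] = {parent}
            shared_by_level[level].append(gid)

    module_chain: dict[int, list[str]] = {}
    attach = shared_by_level[shared_depth]
    for m in range(cfg.n_modules):
        chain: list[str] = []
        parent = attach[m % len(attach)]
        for level in range(shared_depth + 1, cfg.go_depth + 1):
            gid = _go_id(counter)
            counter += 1
            terms[gid] = f"module {m} process L{level}"
            parents[gid] = {parent}
            chain.append(gid)
            parent = gid
        module_chain[m] = chain
    return terms, parents, root, module_chain


def generate(cfg: SynthConfig) -> SynthDataset:
    """Draw one full dataset from the generator's seeded distribution."""
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    drugs = [f"D{i:04d}" for i in range(cfg.n_drugs)]

    # modules: shuffled even partition; the first toxic_modules indices are toxic
    order = rng.permutation(cfg.n_proteins)
    modules: dict[str, int] = {}
    for m, chunk in enumerate(np.array_split(order, cfg.n_modules)):
        for i in chunk:
            modules[proteins[i]] = m
    toxic_ids = tuple(range(cfg.toxic_modules))
    toxic_prot = {p for p, m in modules.items() if m in toxic_ids}

    # interactions: dense/high-star within modules, sparse/low-star between
    stars_levels = np.arange(1, 6)
    edges: list[tuple[str, str, int]] = []
    for i in range(cfg.n_proteins):
        for j in range(i + 1, cfg.n_proteins):
            within = modules[proteins[i]] == modules[proteins[j]]
            p = cfg.p_edge_within if within else cfg.p_edge_between
            if rng.random() < p:
                dist = cfg.stars_within if within else cfg.stars_between
                stars = int(rng.choice(stars_levels, p=dist))
                edges.append((proteins[i], proteins[j], stars))
    ppi = PPINetwork.from_edges(edges)

    # ontology + annotations: every protein carries its module's leaf term;
    # some also carry a shared term or a foreign leaf (annotation noise)
    terms, parents, root, module_chain = _build_ontology(cfg)
    shared_terms = [t for t in terms
                    if t != root and not terms[t].startswith("module")]
    annotations: dict[str, set[str]] = {}
    for p in proteins:
        ann = {module_chain[modules[p]][-1]}
        if shared_terms and rng.random() < 0.3:
            ann.add(shared_terms[int(rng.integers(len(shared_terms)))])
        if rng.random() < 0.1:
            foreign = int(rng.integers(cfg.n_modules))
            ann.add(module_chain[foreign][-1])
        annotations[p] = ann
    dag = GODag(terms=terms, parents=parents, root=root,
                annotations=annotations)

    # drug targets: uniform without replacement
    lo, hi = cfg.targets_per_drug
    dt_pairs: set[tuple[str, str]] = set()
    drug_targets: dict[str, list[str]] = {}
    for d in drugs:
        k = int(rng.integers(lo, hi + 1))
        chosen = [proteins[i] for i in rng.choice(cfg.n_proteins, size=k,
                                                  replace=False)]
        drug_targets[d] = chosen
        dt_pairs.update((d, p) for p in chosen)

    # planted mechanism: direct hit, or one high-confidence hop away
    hop_adjacent: set[str] = set()
    for u, v, s in ppi.edges():
        if s >= TOXIC_HOP_MIN_STARS:
            if u in toxic_prot and v not in toxic_prot:
                hop_adjacent.add(v)
            if v in toxic_prot and u not in toxic_prot:
                hop_adjacent.add(u)
    rows = []
    for d in drugs:
        ts = drug_targets[d]
        if any(t in toxic_prot for t in ts):
            mechanism = "direct"
        elif any(t in hop_adjacent for t in ts):
            mechanism = "one_hop"
        else:
            mechanism = "none"
        prenoise = int(mechanism != "none")
        label = prenoise ^ int(rng.random() < cfg.label_noise)
        rows.append((d, prenoise, label, mechanism))
    truth = pd.DataFrame(rows, columns=["drug_id", "label_prenoise",
                                        "label", "mechanism"])

    # ADR assignment surfaces the (noisy) label through the name->ICD-10 join
    adr_pairs: set[tuple[str, str]] = set()
    for d, _, label, _ in rows:
        if label:
            adr_pairs.add((d, canonical_adr_name(TOXIC_ADR)))
        benign = BENIGN_ADRS[int(rng.integers(len(BENIGN_ADRS)))]
        adr_pairs.add((d, canonical_adr_name(benign)))
    icd = ADRIcdMap({canonical_adr_name(n): c for n, c in ADR_CODES.items()})

    return SynthDataset(config=cfg,
                        targets=DrugTargetMap(frozenset(dt_pairs)),
                        adrs=DrugADRMap(frozenset(adr_pairs)),
                        icd=icd, ppi=ppi, dag=dag, truth=truth,
                        modules=modules, toxic_module_ids=toxic_ids)


def _write_obo(dag: GODag, path: Path) -> None:
    lines = ["format-version: 1.2", ""]
    for gid in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {gid}")
        lines.append(f"name: {dag.terms[gid]}")
        lines.append("namespace: biological_process")
        for parent in sorted(dag.parents.get(gid, ())):
            lines.append(f"is_a: {parent} ! {dag.terms[parent]}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def write_dataset(ds: SynthDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the six input files plus truth.tsv; deterministic byte layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("drug_targets", "drug_targets.tsv"), ("drug_adr", "drug_adr.tsv"),
        ("adr_icd10", "adr_icd10.tsv"), ("ppi", "ppi.tsv"),
        ("annotations", "annotations.tsv"), ("ontology", "ontology.obo"),
        ("truth", "truth.tsv")]}
    write_drug_target_table(ds.targets, paths["drug_targets"])
    write_drug_adr_table(ds.adrs, paths["drug_adr"])
    write_icd10_table(ds.icd, paths["adr_icd10"])
    write_ppi_table(ds.ppi, paths["ppi"])
    ann_rows = sorted((p, g) for p, gs in ds.dag.annotations.items() for g in gs)
    pd.DataFrame(ann_rows, columns=["protein_id", "go_id"]).to_csv(
        paths["annotations"], sep="\t", index=False)
    _write_obo(ds.dag, paths["ontology"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a dataset and write it under ``out_dir`` (see write_dataset)."""
    return write_dataset(generate(cfg), out_dir)


def load_dataset(in_dir: str | Path) -> SynthDataset:
    """Re-read a written dataset through the ordinary table readers."""
    d = Path(in_dir)
    return SynthDataset(
        config=SynthConfig(),
        targets=read_drug_target_table(d / "drug_targets.tsv"),
        adrs=read_drug_adr_table(d / "drug_adr.tsv"),
        icd=read_icd10_table(d / "adr_icd10.tsv"),
        ppi=read_ppi_table(d / "ppi.tsv"),
        dag=read_obo(d / "ontology.obo", d / "annotations.tsv"),
        truth=pd.read_csv(d / "truth.tsv", sep="\t"),
        modules={}, toxic_module_ids=())
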