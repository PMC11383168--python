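"""End-to-end orchestration: simulate/load -> networks -> PageRank ->
consensus -> differential -> regulatee/enrichment -> permutation tests.

A single YAML config drives every stage. One master seed is declared in the
config; each stage derives its own seed by stable hashing of
(master, stage name), so stages are reproducible independently. Stages are
cached by a content hash of their parameters and upstream hashes: rerunning
with an unchanged config skips completed stages. The run manifest records
the config hash, package version, seeds and a digest of every output file —
and no wall-clock state, so identical runs produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .differential import (
    assign_peaks_to_genes,
    build_peak_matrix,
    call_dars,
    call_degs,
    differential_pagerank,
    hypergeometric_enrichment,
    read_gmt,
    regulatee_profiles,
    write_gmt,
)
from .io import (
    JointnetError,
    read_bedpe,
    read_expression_matrix,
    read_fasta,
    read_gene_annotation,
    read_marker_panel,
    read_metadata,
    read_narrowpeak,
    read_pwm_library,
)
from .network import (
    NetworkParams,
    RegulatoryNetwork,
    assign_regulatory_regions,
    build_network,
    network_from_tables,
    network_to_tables,
)
from .pagerank import PageRankTable, consensus_edges, pagerank_table
from .permutation import (
    MarkerPanel,
    PermutationConfig,
    activation_ratio_test,
    cumulative_induction_test,
)
from .simulate import CohortBundle, CohortConfig, PlantedProgram, simulate_cohort, write_bundle

log = logging.getLogger("jointnet")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed from the master seed: stable, independent, < 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class Contrast:
    a: str
    b: str
    axis: str = "group"          # group | condition
    condition: str | None = None  # fixed condition for group contrasts
    group: str | None = None      # fixed group for condition contrasts

    @property
    def name(self) -> str:
        fixed = self.condition if self.axis == "group" else self.group
        return f"{self.a}_vs_{self.b}_{fixed or 'all'}"


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    seed: int = 0
    simulate: dict | None = None          # CohortConfig fields; None -> load inputs
    inputs: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    pagerank: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)   # min_fraction
    diff: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)
    contrasts: list[dict] = field(default_factory=list)
    gene_sets: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise JointnetError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stable_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # a location, not part of the analysis
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _cohort_config(block: dict, seed: int) -> CohortConfig:
    block = dict(block or {})
    progs = block.pop("planted_programs", None)
    if progs is not None:
        progs = tuple(PlantedProgram(**p) for p in progs)
    tnf = block.pop("tnf_induction_log2fc", None)
    return CohortConfig(
        planted_programs=progs, tnf_induction_log2fc=tnf,
        seed=block.pop("seed", seed), **block,
    )


@dataclass
class ResultBundle:
    networks: dict[str, RegulatoryNetwork]
    pagerank: PageRankTable
    consensus: dict[tuple[str, str], Any]
    differential: dict[str, dict[str, pd.DataFrame]]
    profiles: dict[str, Any]
    enrichment: dict[str, pd.DataFrame]
    permutation: dict[str, Any]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageCache:
    """Skip a stage when its parameter/upstream hash is unchanged on disk."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir

    def stage_dir(self, name: str) -> Path:
        d = self.out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def is_fresh(self, name: str, key: str) -> bool:
        f = self.out_dir / name / ".stage_hash"
        return f.exists() and f.read_text().strip() == key

    def mark(self, name: str, key: str) -> None:
        (self.out_dir / name / ".stage_hash").write_text(key + "\n")


def _stage_key(*parts: object) -> str:
    return hashlib.sha256(repr(parts).encode()).hexdigest()[:16]


def load_inputs(inputs: Mapping[str, str]) -> CohortBundle:
    """Load a cohort from on-disk files (the format the simulator writes)."""
    required = ["expression", "metadata", "annotation", "genome", "motifs", "peaks_dir"]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise JointnetError(f"missing input paths: {missing}")
    for key, p in inputs.items():
        if not Path(p).exists():
            raise JointnetError(f"input path does not exist: {key} = {p}")
    annotation = read_gene_annotation(inputs["annotation"])
    metadata = read_metadata(inputs["metadata"])
    expression = read_expression_matrix(inputs["expression"])
    metadata.require_covers(expression.sample_ids, "expression")
    peaksets = []
    for sid in expression.sample_ids:
        p = Path(inputs["peaks_dir"]) / f"{sid}.narrowPeak"
        if not p.exists():
            raise JointnetError(f"missing peak file for sample {sid}: {p}")
        peaksets.append(read_narrowpeak(p, sid))
    interactions = read_bedpe(inputs["interactions"]) if "interactions" in inputs else None
    panels = read_marker_panel(inputs["markers"]) if "markers" in inputs else {}
    return CohortBundle(
        config=None, genome=read_fasta(inputs["genome"]), annotation=annotation,
        motifs=read_pwm_library(inputs["motifs"], annotation), peaksets=peaksets,
        expression=expression, metadata=metadata, interactions=interactions,
        marker_panels=panels, truth={},
    )


def _parse_contrasts(config: PipelineConfig, metadata) -> list[Contrast]:
    groups = set(metadata.table["group"])
    conditions = set(metadata.table["condition"])
    out = []
    for c in config.contrasts:
        ct = Contrast(**c)
        labels = groups if ct.axis == "group" else conditions
        for lab in (ct.a, ct.b):
            if lab not in labels:
                raise JointnetError(f"contrast references unknown {ct.axis} label '{lab}'")
        out.append(ct)
    return out


def _virtual_metadata(metadata, contrast: Contrast):
    """For condition contrasts, view condition labels as the 'group' column."""
    from .io import SampleMetadata

    t = metadata.table.copy()
    if contrast.axis == "condition":
        if contrast.group is not None:
            t = t[t["group"] == contrast.group]
        t = t.assign(group=t["condition"])
    return SampleMetadata(t)


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute every stage in dependency order under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out)
    manifest: dict[str, Any] = {
        "package": "jointnet",
        "version": __version__,
        "config_hash": config.stable_hash(),
        "master_seed": config.seed,
        "stage_seeds": {},
        "files": {},
    }

    # ---- stage: cohort ----
    if config.simulate is not None:
        sim_seed = derive_seed(config.seed, "simulate")
        cc = _cohort_config(config.simulate, sim_seed)
        manifest["stage_seeds"]["simulate"] = cc.seed
        key = _stage_key("simulate", dataclasses.asdict(cc))
        sim_dir = cache.stage_dir("cohort")
        bundle = simulate_cohort(cc)
        if not cache.is_fresh("cohort", key):
            log.info("simulating cohort (%d samples)", len(bundle.metadata.sample_ids))
            write_bundle(bundle, sim_dir)
            cache.mark("cohort", key)
    else:
        bundle = load_inputs(config.inputs)
        key = _stage_key("inputs", sorted(config.inputs.items()))
    contrasts = _parse_contrasts(config, bundle.metadata)

    # ---- stage: networks ----
    params = NetworkParams(**config.network)
    region_map = assign_regulatory_regions(
        bundle.annotation, bundle.interactions,
        promoter_window=(params.promoter_upstream, params.promoter_downstream),
        peaks=bundle.peaksets[0] if (bundle.interactions is None or not len(bundle.interactions)) else None,
        enhancer_max_dist=params.enhancer_max_dist,
    )
    net_dir = cache.stage_dir("networks")
    net_key = _stage_key("networks", key, dataclasses.asdict(params))
    networks: dict[str, RegulatoryNetwork] = {}
    if cache.is_fresh("networks", net_key):
        log.info("networks: cached")
        for ps in bundle.peaksets:
            edges = pd.read_csv(net_dir / f"{ps.sample_id}.edges.tsv", sep="\t", comment="#")
            nodes = pd.read_csv(net_dir / f"{ps.sample_id}.nodes.tsv", sep="\t", comment="#")
            networks[ps.sample_id] = network_from_tables(ps.sample_id, edges, nodes)
    else:
        hit_cache: dict = {}
        for ps in bundle.peaksets:
            net = build_network(
                ps.sample_id, bundle.expression, ps, region_map,
                bundle.motifs, bundle.genome, params, hit_cache,
            )
            networks[ps.sample_id] = net
            edges, nodes = network_to_tables(net)
            edges.to_csv(net_dir / f"{ps.sample_id}.edges.tsv", sep="\t", index=False)
            nodes.to_csv(net_dir / f"{ps.sample_id}.nodes.tsv", sep="\t", index=False)
        cache.mark("networks", net_key)
        log.info("built %d networks", len(networks))

    # ---- stage: pagerank ----
    pr_dir = cache.stage_dir("pagerank")
    tf_ids = sorted(bundle.motifs.pwms)
    table = pagerank_table(list(networks.values()), tf_ids=tf_ids, **config.pagerank)
    table.scores.to_csv(pr_dir / "pagerank.tsv", sep="\t", index_label="tf")

    # ---- stage: consensus ----
    cons_dir = cache.stage_dir("consensus")
    min_fraction = config.consensus.get("min_fraction", 0.7)
    consensus: dict[tuple[str, str], Any] = {}
    meta = bundle.metadata
    for group in sorted(set(meta.table["group"])):
        for cond in sorted(set(meta.table["condition"])):
            sids = meta.samples_in(group=group, condition=cond)
            nets = [networks[s] for s in sids if s in networks]
            if not nets:
                continue
            cs = consensus_edges(nets, min_fraction, group_key=(group, cond))
            consensus[(group, cond)] = cs
            cs.edges.to_csv(cons_dir / f"{group}_{cond}.tsv", sep="\t", index=False)

    # ---- stage: differential ----
    diff_dir = cache.stage_dir("differential")
    dp = config.diff
    peak_matrix, consensus_peaks = build_peak_matrix(bundle.peaksets)
    region_gene = assign_peaks_to_genes(consensus_peaks, region_map)
    differential: dict[str, dict[str, pd.DataFrame]] = {}
    profiles: dict[str, Any] = {}
    enrichment: dict[str, pd.DataFrame] = {}

    if config.gene_sets:
        gene_sets = read_gmt(config.gene_sets)
    elif bundle.marker_panels or len(bundle.truth.get("edges", [])):
        gene_sets = {f"panel_{k}": v for k, v in bundle.marker_panels.items()}
        if "edges" in bundle.truth and len(bundle.truth["edges"]):
            for tf, sub in bundle.truth["edges"].groupby("tf_id"):
                gene_sets[f"program_{tf}"] = sorted(sub["gene_id"])
        write_gmt(gene_sets, diff_dir / "gene_sets.gmt")
    else:
        gene_sets = {}

    for ct in contrasts:
        vmeta = _virtual_metadata(meta, ct)
        fixed_cond = ct.condition if ct.axis == "group" else None
        res: dict[str, pd.DataFrame] = {}
        res["pagerank"] = differential_pagerank(
            table, vmeta, ct.a, ct.b, condition=fixed_cond,
            p_thresh=dp.get("pr_p", 0.05),
        )
        res["deg"] = call_degs(
            bundle.expression, vmeta, ct.a, ct.b, condition=fixed_cond,
            p_thresh=dp.get("deg_p", 0.05), lfc_thresh=dp.get("deg_lfc", 0.58),
        )
        res["dar"] = call_dars(
            peak_matrix, vmeta, ct.a, ct.b, condition=fixed_cond,
            fdr_thresh=dp.get("dar_fdr", 0.05), lfc_thresh=dp.get("dar_lfc", 0.58),
        )
        differential[ct.name] = res
        for kind, tab in res.items():
            tab.to_csv(diff_dir / f"{ct.name}.{kind}.tsv", sep="\t", index=False)

        diff_tfs = sorted(res["pagerank"].loc[res["pagerank"]["called"], "feature_id"])
        if ct.axis == "group":
            cs_sets = [consensus[k] for k in
                       [(ct.a, fixed_cond), (ct.b, fixed_cond)] if k in consensus]
        else:
            cs_sets = [consensus[k] for k in
                       [(ct.group, ct.a), (ct.group, ct.b)] if k in consensus]
        prof = regulatee_profiles(diff_tfs, cs_sets or list(consensus.values()),
                                  res["deg"], res["dar"], region_gene)
        profiles[ct.name] = prof
        if gene_sets and prof.union:
            enr = hypergeometric_enrichment(
                sorted(prof.union), gene_sets, bundle.annotation.gene_ids
            )
            enrichment[ct.name] = enr
            enr.to_csv(diff_dir / f"{ct.name}.enrichment.tsv", sep="\t", index=False)

    # ---- stage: permutation tests ----
    perm_dir = cache.stage_dir("permutation")
    permutation: dict[str, Any] = {}
    pcfg_raw = dict(config.permutation)
    M = pcfg_raw.get("M", 1000)
    direction = pcfg_raw.get("direction", "greater")
    panels = bundle.marker_panels
    if panels.get("activated") and panels.get("resting"):
        panel = MarkerPanel.from_dict(panels)
        groups = sorted(set(meta.table["group"]))
        conditions = sorted(set(meta.table["condition"]))
        base_cond = conditions[-1] if len(conditions) > 1 else conditions[0]
        unstim = next((c for c in conditions if c.lower().startswith("un")), conditions[0])
        tnf = next((c for c in conditions if c.lower() == "tnf"), base_cond)
        rows = []
        for gi in groups:
            for gj in groups:
                if gi >= gj:
                    continue
                pc = PermutationConfig(
                    M=M, seed=derive_seed(config.seed, f"perm:{gi}:{gj}"),
                    direction=direction,
                )
                act = activation_ratio_test(
                    bundle.expression, meta, panel, gi, gj, pc, condition=unstim
                )
                permutation[f"activation:{gi}:{gj}"] = act
                rows.append(("activation", gi, gj, act.observed, act.p_value))
                if panel.cytokine_mmp:
                    ind = cumulative_induction_test(
                        bundle.expression, meta, panel.cytokine_mmp, gi, gj, pc,
                        condition=tnf,
                    )
                    permutation[f"induction:{gi}:{gj}"] = ind
                    rows.append(("induction", gi, gj, ind.observed, ind.p_value))
        pd.DataFrame(
            rows, columns=["test", "group_i", "group_j", "observed", "p_value"]
        ).to_csv(perm_dir / "permutation.tsv", sep="\t", index=False)

    # ---- manifest ----
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name not in ("manifest.json",):
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ResultBundle(networks, table, consensus, differential, profiles,
                        enrichment, permutation, manifest)
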