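"""Synthetic multi-omic cohort generator with planted ground truth.

Emulates the study design the analysis assumes: three sample groups (joint
locations) by two conditions (unstimulated / TNF-stimulated), ten subjects
per group, each sample contributing a normalized expression profile and an
open-chromatin peak set over a shared synthetic genome. Group-specific
regulatory programs are planted as (i) elevated TF expression, (ii) the
TF's consensus motif in target-gene promoter (and optionally enhancer)
peaks, and (iii) elevated intensity of those peaks in the target group.
Counts are negative binomial (var = mu + mu^2 * dispersion) and peak
intensities log-normal; expression is normalized by median-of-ratios size
factors so planted fold changes are not distorted by composition bias.

Every planted effect is recorded in truth tables so downstream recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    EPInteractions,
    ExpressionMatrix,
    GenomeAnnotation,
    JointnetError,
    MotifLibrary,
    PeakSet,
    SampleMetadata,
    write_bedpe,
    write_expression_matrix,
    write_fasta,
    write_gene_annotation,
    write_marker_panel,
    write_metadata,
    write_narrowpeak,
    write_pwm_library,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedProgram:
    """A group-specific TF regulatory program to plant in the cohort.

    The TF gains ``expr_log2fc`` expression in ``target_group`` (both
    conditions), its ``n_targets`` target genes carry the TF's consensus
    motif in their promoter peak, gain ``target_expr_log2fc`` expression and
    have peak intensity multiplied by ``peak_intensity_multiplier`` in the
    target group.
    """

    tf_id: str
    target_group: str
    expr_log2fc: float = 1.0
    peak_intensity_multiplier: float = 2.0
    n_targets: int = 15
    target_expr_log2fc: float = 1.0
    with_enhancers: bool = False


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort; the seed fully determines output."""

    n_per_group: int = 10
    groups: tuple[str, ...] = ("hand", "hip", "knee")
    conditions: tuple[str, ...] = ("unstim", "TNF")
    n_genes: int = 300
    n_tfs: int = 30
    genome_len: int = 500_000
    nb_dispersion: float = 0.05
    motif_length: int = 8
    gene_length: int = 600
    peak_halfwidth: int = 250
    intensity_sigma: float = 0.25
    library_size_sigma: float = 0.15
    planted_programs: tuple[PlantedProgram, ...] | None = None  # None -> one per group
    # TNF condition: additive log2 induction of the cytokine/MMP panel,
    # group-specific magnitude (largest in the first group by default).
    tnf_induction_log2fc: Mapping[str, float] | None = None
    n_activated_markers: int = 25
    n_resting_markers: int = 20
    n_cytokine_mmp: int = 15
    activated_marker_group: str | None = "hand"
    resting_marker_group: str | None = "knee"
    marker_log2fc: float = 1.0
    seed: int = 0

    def resolved_programs(self) -> tuple[PlantedProgram, ...]:
        if self.planted_programs is not None:
            return tuple(self.planted_programs)
        progs = []
        for k, group in enumerate(self.groups):
            progs.append(
                PlantedProgram(tf_id=_tf_name(k), target_group=group, with_enhancers=(k == 0))
            )
        return tuple(progs)

    def resolved_tnf_induction(self) -> dict[str, float]:
        if self.tnf_induction_log2fc is not None:
            return dict(self.tnf_induction_log2fc)
        # descending induction over groups, mirroring an amplified response
        # in the first group
        top = 2.0
        return {g: top - 0.5 * i for i, g in enumerate(self.groups)}


def null_config(**overrides) -> CohortConfig:
    """A cohort with no planted effects: groups fully exchangeable."""
    base = dict(
        planted_programs=(),
        tnf_induction_log2fc={},
        activated_marker_group=None,
        resting_marker_group=None,
    )
    base.update(overrides)
    return CohortConfig(**base)


@dataclass
class CohortBundle:
    """Everything a pipeline run consumes, plus ground truth."""

    config: CohortConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    motifs: MotifLibrary
    peaksets: list[PeakSet]
    expression: ExpressionMatrix
    metadata: SampleMetadata
    interactions: EPInteractions
    marker_panels: dict[str, list[str]]
    truth: dict[str, pd.DataFrame]


def _tf_name(k: int) -> str:
    return f"TF{k + 1:03d}"


def _gene_name(k: int) -> str:
    return f"G{k + 1:04d}"


def simulate_nb_counts(mean, dispersion: float, n: int | None = None, seed=None) -> np.ndarray:
    """Negative-binomial counts with var = mean + mean^2 * dispersion.

    ``mean`` may be a scalar (then ``n`` draws are made) or an array (one
    draw per element). ``seed`` is an int or a Generator. A dispersion at or
    near zero falls back to Poisson.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean = np.asarray(mean, dtype=float)
    if n is not None and mean.ndim == 0:
        mean = np.full(n, float(mean))
    if (mean < 0).any():
        raise JointnetError("negative mean for count simulation")
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def plant_motif(sequence: str, motif: str, position: int) -> str:
    """Overwrite ``sequence[position:position+len(motif)]`` with ``motif``."""
    if position < 0 or position + len(motif) > len(sequence):
        raise JointnetError(
            f"motif of length {len(motif)} at {position} exceeds sequence of length {len(sequence)}"
        )
    return sequence[:position] + motif + sequence[position + len(motif):]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _random_pwm(rng: np.random.Generator, length: int, major: float = 0.85) -> np.ndarray:
    consensus = rng.integers(0, 4, length)
    pwm = np.full((length, 4), (1.0 - major) / 3.0)
    pwm[np.arange(length), consensus] = major
    return pwm


def _median_of_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor normalization robust to a minority of shifted genes."""
    logc = np.log(counts.to_numpy() + 0.5)
    ref = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - ref, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return counts / sf


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full synthetic cohort for ``config`` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    programs = config.resolved_programs()
    tnf_induction = config.resolved_tnf_induction()

    n_genes, n_tfs = config.n_genes, config.n_tfs
    if n_tfs > n_genes:
        raise JointnetError("n_tfs cannot exceed n_genes")
    gene_ids = [_tf_name(k) for k in range(n_tfs)]
    gene_ids += [_gene_name(k) for k in range(n_tfs, n_genes)]

    # --- gene layout: non-overlapping, evenly spaced, alternating strand ---
    margin = 6000
    spacing = (config.genome_len - 2 * margin) // n_genes
    if spacing < config.gene_length + 2 * config.peak_halfwidth:
        raise JointnetError(
            f"genome of {config.genome_len} bp too small for {n_genes} genes"
        )
    chrom = "chrS"
    starts = margin + spacing * np.arange(n_genes)
    strands = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + config.gene_length,
            "strand": strands,
            "is_tf": [g.startswith("TF") for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    annotation = GenomeAnnotation(ann)
    tss = annotation.table["tss"]

    # --- genome and motif library ---
    genome_seq = _random_sequence(rng, config.genome_len)
    pwms = {t: _random_pwm(rng, config.motif_length) for t in gene_ids[:n_tfs]}
    motifs = MotifLibrary(pwms)

    # --- choose planted targets (non-TF genes, disjoint across programs) ---
    available = [g for g in gene_ids if not g.startswith("TF")]
    rng.shuffle(available)
    cursor = 0
    program_targets: dict[str, list[str]] = {}
    for prog in programs:
        if prog.n_targets > len(available) - cursor:
            raise JointnetError("not enough genes to assign planted targets")
        program_targets[prog.tf_id] = sorted(available[cursor:cursor + prog.n_targets])
        cursor += prog.n_targets
    remaining = available[cursor:]

    # --- marker panels (disjoint from planted targets and each other) ---
    need = config.n_activated_markers + config.n_resting_markers + config.n_cytokine_mmp
    if need > len(remaining):
        raise JointnetError("not enough genes for the requested marker panels")
    activated = sorted(remaining[: config.n_activated_markers])
    resting = sorted(
        remaining[config.n_activated_markers: config.n_activated_markers + config.n_resting_markers]
    )
    cyt = sorted(remaining[config.n_activated_markers + config.n_resting_markers: need])
    marker_panels = {"activated": activated, "resting": resting, "cytokine_mmp": cyt}

    # --- plant motifs in promoter peaks (shared genome) + enhancer links ---
    truth_motifs = []
    ep_rows = []
    peak_coords: dict[str, tuple[int, int, str]] = {}  # peak name -> (start, end, gene)
    hw = config.peak_halfwidth
    for g in gene_ids:
        t = int(tss[g])
        peak_coords[f"{g}_prom"] = (t - hw, t + hw, g)
    planted_peak_mult: dict[str, dict[str, float]] = {}  # peak name -> {group: mult}
    for prog in programs:
        consensus = motifs.consensus(prog.tf_id)
        for g in program_targets[prog.tf_id]:
            t = int(tss[g])
            pos = t - hw + 60
            genome_seq = plant_motif(genome_seq, consensus, pos)
            truth_motifs.append((prog.tf_id, g, chrom, pos, f"{g}_prom"))
            planted_peak_mult.setdefault(f"{g}_prom", {})[prog.target_group] = (
                prog.peak_intensity_multiplier
            )
            if prog.with_enhancers:
                e_start = max(0, t - 20_000)
                name = f"{g}_enh"
                peak_coords[name] = (e_start, e_start + 300, g)
                epos = e_start + 100
                genome_seq = plant_motif(genome_seq, consensus, epos)
                truth_motifs.append((prog.tf_id, g, chrom, epos, name))
                planted_peak_mult.setdefault(name, {})[prog.target_group] = (
                    prog.peak_intensity_multiplier
                )
                ep_rows.append((chrom, e_start, e_start + 300, g, 1.0))
    genome = {chrom: genome_seq}
    interactions = EPInteractions(
        pd.DataFrame(ep_rows, columns=["chrom", "start", "end", "gene_id", "confidence"])
    )

    # --- sample metadata ---
    meta_rows = []
    for group in config.groups:
        for i in range(config.n_per_group):
            subject = f"{group}{i + 1:02d}"
            for cond in config.conditions:
                meta_rows.append((f"{subject}_{cond}", group, cond, subject))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "group", "condition", "subject_id"]
    ).set_index("sample_id")
    metadata = SampleMetadata(meta)
    sample_ids = list(meta.index)

    # --- expression effects: per-(gene, group, condition) log2 offsets ---
    effect_rows = []  # (gene, group, condition-or-'*', log2fc, source)
    for prog in programs:
        effect_rows.append((prog.tf_id, prog.target_group, "*", prog.expr_log2fc, "program_tf"))
        for g in program_targets[prog.tf_id]:
            effect_rows.append((g, prog.target_group, "*", prog.target_expr_log2fc, "program_target"))
    if config.activated_marker_group is not None:
        for g in activated:
            effect_rows.append((g, config.activated_marker_group, "*", config.marker_log2fc, "activated_marker"))
    if config.resting_marker_group is not None:
        for g in resting:
            effect_rows.append((g, config.resting_marker_group, "*", config.marker_log2fc, "resting_marker"))
    tnf_conditions = [c for c in config.conditions if c.lower() == "tnf"]
    for group, lfc in tnf_induction.items():
        for cond in tnf_conditions:
            for g in cyt:
                effect_rows.append((g, group, cond, lfc, "tnf_induction"))

    gene_index = {g: k for k, g in enumerate(gene_ids)}
    offsets = np.zeros((n_genes, len(sample_ids)))
    group_of = meta["group"].to_numpy()
    cond_of = meta["condition"].to_numpy()
    for gene, group, cond, lfc, _src in effect_rows:
        col_mask = group_of == group
        if cond != "*":
            col_mask &= cond_of == cond
        offsets[gene_index[gene], col_mask] += lfc

    base_mean = np.exp(rng.uniform(np.log(30.0), np.log(300.0), n_genes))
    lib = np.exp(rng.normal(0.0, config.library_size_sigma, len(sample_ids)))
    mu = base_mean[:, None] * (2.0 ** offsets) * lib[None, :]
    counts = simulate_nb_counts(mu, config.nb_dispersion, seed=rng)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    expression = ExpressionMatrix(
        _median_of_ratios(counts_df).astype(float), unit="median-ratio normalized counts"
    )

    # --- peaks: shared coordinates, per-sample log-normal intensity ---
    peak_names = sorted(peak_coords)
    base_intensity = pd.Series(
        np.exp(rng.normal(np.log(10.0), 0.5, len(peak_names))), index=peak_names
    )
    peaksets = []
    for sid in sample_ids:
        group = meta.loc[sid, "group"]
        noise = np.exp(rng.normal(0.0, config.intensity_sigma, len(peak_names)))
        mult = np.array(
            [planted_peak_mult.get(p, {}).get(group, 1.0) for p in peak_names]
        )
        rows = []
        for p, nz, m in zip(peak_names, noise, mult):
            s, e, _g = peak_coords[p]
            rows.append((chrom, s, e, p, base_intensity[p] * nz * m, (e - s) // 2))
        peaksets.append(
            PeakSet(sid, pd.DataFrame(
                rows, columns=["chrom", "start", "end", "name", "intensity", "summit_offset"]
            ))
        )

    # --- truth tables ---
    truth = {
        "tfs": pd.DataFrame(
            [
                (p.tf_id, p.target_group, p.expr_log2fc, p.peak_intensity_multiplier,
                 len(program_targets[p.tf_id]))
                for p in programs
            ],
            columns=["tf_id", "target_group", "expr_log2fc", "peak_intensity_multiplier", "n_targets"],
        ),
        "edges": pd.DataFrame(
            [
                (p.tf_id, g, p.target_group)
                for p in programs
                for g in program_targets[p.tf_id]
            ],
            columns=["tf_id", "gene_id", "target_group"],
        ),
        "expression_effects": pd.DataFrame(
            effect_rows, columns=["gene_id", "group", "condition", "log2fc", "source"]
        ),
        "motifs": pd.DataFrame(
            truth_motifs, columns=["tf_id", "gene_id", "chrom", "position", "peak_name"]
        ),
        "peaks": pd.DataFrame(
            [
                (p, grp, m, peak_coords[p][2])
                for p, d in sorted(planted_peak_mult.items())
                for grp, m in sorted(d.items())
            ],
            columns=["peak_name", "group", "multiplier", "gene_id"],
        ),
    }

    return CohortBundle(
        config=config,
        genome=genome,
        annotation=annotation,
        motifs=motifs,
        peaksets=peaksets,
        expression=expression,
        metadata=metadata,
        interactions=interactions,
        marker_panels=marker_panels,
        truth=truth,
    )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write the bundle in the standard on-disk formats plus truth/*.tsv."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    write_fasta(bundle.genome, out / "genome.fa")
    write_gene_annotation(bundle.annotation, out / "annotation.tsv")
    write_pwm_library(bundle.motifs, out / "motifs.meme")
    write_expression_matrix(bundle.expression, out / "expression.tsv")
    write_metadata(bundle.metadata, out / "metadata.tsv")
    if len(bundle.interactions):
        write_bedpe(bundle.interactions, out / "interactions.bedpe")
    write_marker_panel(bundle.marker_panels, out / "markers.tsv")
    for ps in bundle.peaksets:
        write_narrowpeak(ps, out / "peaks" / f"{ps.sample_id}.narrowPeak")
    for name, df in bundle.truth.items():
        df.to_csv(out / "truth" / f"{name}.tsv", sep="\t", index=False)


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """A reduced cohort for fast tests: same structure, smaller scale."""
    base = dict(
        n_genes=60,
        n_tfs=6,
        genome_len=120_000,
        n_activated_markers=10,
        n_resting_markers=8,
        n_cytokine_mmp=6,
        planted_programs=tuple(
            PlantedProgram(tf_id=_tf_name(k), target_group=g, n_targets=5,
                           with_enhancers=(k == 0))
            for k, g in enumerate(("hand", "hip", "knee"))
        ),
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)
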