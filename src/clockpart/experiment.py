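"""Replication management: simulate -> partition -> fit -> date -> score.

`run_experiment` executes the full factorial experiment (rate priors x
calibration strategies x clock models x schemes x replicates) on one
clock-violation level, persisting intermediate artifacts per replicate
(gene trees, alignments, surfaces, traces) and returning a tidy report
table of the four performance measures per cell.

The library functions are the interface; the short scripts under
``examples/`` show each stage in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_sim
from .clock_sim import RateDriftConfig, replicate_rng, simulate_gene_trees, gene_realizations_table
from .codon_sim import (
    NucleotideAlignment,
    concatenate_alignments,
    conserved_gene_model,
    less_conserved_gene_model,
    simulate_alignment,
    _ClassKernels,
)
from .evaluate import aggregate_report, compute_node_metrics, metrics_frame
from .mcmc import (
    Calibration,
    McmcSettings,
    RatePriorConfig,
    TimePriorConfig,
    run_mcmc,
)
from .ml import SubstModelConfig, fit_branch_lengths, write_surfaces
from .partitioning import (
    bic_greedy_merge,
    fixed_scheme,
    gap_statistic_cluster,
    make_blocks,
    sbsd_distance_matrix,
    write_scheme_json,
)
from .trees import build_reference_timetree, write_gene_trees_newick

__all__ = ["ExperimentConfig", "run_experiment", "simulate_replicate"]

RATE_PRIORS = {
    "G(2,4)": (2.0, 4.0),
    "G(2,40)": (2.0, 40.0),
    "G(2,0.4)": (2.0, 0.4),
}

CALIBRATIONS = {
    "root": (Calibration(node=1, lower=0.8, upper=1.2),),
    "root+node3": (
        Calibration(node=1, lower=0.8, upper=1.2),
        Calibration(node=3, lower=0.525, upper=0.575),
    ),
    "root+wrong3": (
        Calibration(node=1, lower=0.8, upper=1.2),
        Calibration(node=3, lower=0.575, upper=0.625),
    ),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One clock-violation level of the factorial dating experiment.

    ``rate_priors``, ``calibrations``, ``clock_models`` and ``schemes``
    are crossed; ``n_replicates`` independent datasets are simulated and
    shared across all cells.  Chain lengths default to a scaled-down
    profile; the full reference protocol (100 replicates, burn-in 1e6,
    10^4 samples every 500) is obtained by passing those values.
    """

    sigma2: float = 0.25
    rate_priors: tuple[str, ...] = ("G(2,4)",)
    calibrations: tuple[str, ...] = ("root",)
    clock_models: tuple[str, ...] = ("IR",)
    schemes: tuple[str, ...] = ("C",)
    n_replicates: int = 10
    n_genes: int = 50
    n_codons: int = 500
    master_seed: int = 1
    burn_in: int = 3000
    sample_interval: int = 3
    n_samples: int = 2000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for rp in self.rate_priors:
            if rp not in RATE_PRIORS:
                raise ValueError(f"unknown rate prior {rp!r}")
        for cal in self.calibrations:
            if cal not in CALIBRATIONS:
                raise ValueError(f"unknown calibration strategy {cal!r}")
        for cm in self.clock_models:
            if cm not in ("IR", "AR"):
                raise ValueError(f"unknown clock model {cm!r}")
        for sc in self.schemes:
            if sc not in ("C", "CP", "G", "GCP", "PF", "CS"):
                raise ValueError(f"unknown scheme {sc!r}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def simulate_replicate(
    config: ExperimentConfig, replicate: int, tree=None
) -> tuple[NucleotideAlignment, list]:
    """Simulate one replicate's 50-gene dataset (half conserved genes,
    half less-conserved) and return the nucleotide super-alignment and
    gene realizations."""
    if tree is None:
        tree = build_reference_timetree()
    rng = replicate_rng(config.master_seed, replicate)
    drift = RateDriftConfig(
        sigma2=config.sigma2, n_genes=config.n_genes
    )
    genes = simulate_gene_trees(tree, drift, rng)
    half = config.n_genes // 2
    models = {
        "conserved": conserved_gene_model(n_codons=config.n_codons),
        "less": less_conserved_gene_model(n_codons=config.n_codons),
    }
    kernels = {k: _ClassKernels(m) for k, m in models.items()}
    alns = []
    for g, gr in enumerate(genes):
        key = "conserved" if g < half else "less"
        alns.append(
            simulate_alignment(gr, models[key], tree, rng, kernels=kernels[key])
        )
    return concatenate_alignments(alns), genes


def _scheme_for(
    kind: str,
    aln: NucleotideAlignment,
    tree,
    config: ExperimentConfig,
    rng: np.random.Generator,
    subst: SubstModelConfig,
):
    blocks = make_blocks(aln)
    if kind in ("C", "CP", "G", "GCP"):
        return fixed_scheme(kind, config.n_genes), blocks
    if kind == "PF":
        return (
            bic_greedy_merge(blocks, aln, tree, config=subst),
            blocks,
        )
    # CS: per-block branch lengths -> distance matrix -> gap clustering
    bl = np.stack(
        [
            fit_branch_lengths(aln.columns(b.columns), tree, subst).bhat
            for b in blocks
        ]
    )
    dist = sbsd_distance_matrix(bl)
    return gap_statistic_cluster(dist, max_k=min(10, len(blocks)), rng=rng), blocks


def _cell_seed(master_seed: int, rep: int, *labels: str) -> int:
    """Stable per-cell chain seed (process-independent)."""
    tag = "|".join(str(x) for x in labels)
    h = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "little")
    return int(
        np.random.SeedSequence((master_seed, rep, h)).generate_state(1)[0]
        % (2**31)
    )


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the factorial experiment; returns one report row per
    (rate prior, calibration, clock model, scheme) cell with the four
    measures averaged over nodes and replicates."""
    tree = build_reference_timetree()
    subst = SubstModelConfig()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "master_seed": config.master_seed}

    all_metrics: dict[tuple, list] = {}
    for rep in range(config.n_replicates):
        rep_dir = out_dir / f"rep{rep:03d}" if out_dir else None
        if rep_dir:
            rep_dir.mkdir(exist_ok=True)
        t0 = time.time()
        aln, genes = simulate_replicate(config, rep, tree=tree)
        if rep_dir:
            write_gene_trees_newick(
                rep_dir / "gene_trees.nwk",
                [tree.to_newick(g.nuc_lengths) for g in genes],
            )
            gene_realizations_table(genes, replicate=rep).to_csv(
                rep_dir / "gene_rates.tsv", sep="\t", index=False
            )
            codon_sim.write_phylip(rep_dir / "alignment.phy", aln.taxa, aln.sequences())
            codon_sim.write_partition_file(rep_dir / "blocks.partitions", aln)

        scheme_rng = replicate_rng(config.master_seed, 10_000 + rep)
        surface_cache: dict[bytes, object] = {}

        for kind in config.schemes:
            scheme, blocks = _scheme_for(kind, aln, tree, config, scheme_rng, subst)
            if rep_dir:
                write_scheme_json(rep_dir / f"scheme_{kind}.json", scheme, blocks)
            surfaces = []
            for pid, cols in enumerate(scheme.partition_columns(blocks), start=1):
                key = cols.tobytes()
                if key not in surface_cache:
                    surface_cache[key] = fit_branch_lengths(
                        aln.columns(cols), tree, subst, partition=pid
                    )
                surfaces.append(surface_cache[key])
            if rep_dir:
                write_surfaces(
                    rep_dir / f"surfaces_{kind}.json", surfaces,
                    meta={**meta, "replicate": rep, "scheme": kind},
                )

            for prior_name in config.rate_priors:
                shape, rate = RATE_PRIORS[prior_name]
                rate_prior = RatePriorConfig(rate_shape=shape, rate_rate=rate)
                for cal_name in config.calibrations:
                    time_prior = TimePriorConfig(
                        calibrations=CALIBRATIONS[cal_name]
                    )
                    for clock in config.clock_models:
                        settings = McmcSettings(
                            burn_in=config.burn_in,
                            sample_interval=config.sample_interval,
                            n_samples=config.n_samples,
                            seed=_cell_seed(
                                config.master_seed, rep, kind, prior_name,
                                cal_name, clock,
                            ),
                            clock_model=clock,
                        )
                        summary = run_mcmc(
                            tree, surfaces, time_prior, rate_prior, settings,
                            scheme_label=kind,
                        )
                        if rep_dir:
                            trace = pd.DataFrame(
                                summary.age_samples,
                                columns=[f"t{l}" for l in summary.node_labels],
                            )
                            trace.to_csv(
                                rep_dir
                                / f"trace_{kind}_{prior_name}_{cal_name}_{clock}.tsv",
                                sep="\t", index=False,
                            )
                        cell = (prior_name, cal_name, clock, kind)
                        all_metrics.setdefault(cell, []).extend(
                            compute_node_metrics(summary, tree, replicate=rep)
                        )
        if out_dir:
            (out_dir / f"rep{rep:03d}.done").write_text(
                json.dumps({**meta, "replicate": rep, "seconds": time.time() - t0})
            )

    rows = []
    for (prior_name, cal_name, clock, kind), metrics in all_metrics.items():
        report = aggregate_report(metrics, label=kind)
        rows.append(
            {
                "rate_prior": prior_name,
                "calibration": cal_name,
                "clock_model": clock,
                "scheme": kind,
                "n_replicates": report.n_replicates,
                **{k: v for k, v in report.overall.items()},
            }
        )
        if out_dir:
            metrics_frame(metrics).to_csv(
                out_dir / f"metrics_{kind}_{prior_name}_{cal_name}_{clock}.csv",
                index=False,
            )
    df = pd.DataFrame(rows)
    if out_dir:
        df.to_csv(out_dir / "report.csv", index=False)
    return df
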