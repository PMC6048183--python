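"""End-to-end orchestration: collapse -> delimit -> test -> associate.

A :class:`RunConfig` (usually loaded from YAML) names the per-gene inputs —
an ultrametric chronogram for GMYC, a substitution-scaled tree for PTP, an
alignment, a tip map — plus the specimen table, or alternatively a
`simulate` block whose parameters are handed to the synthetic-data
generator. :func:`run_pipeline` writes per-gene haplotype tables and
alignment statistics, the delimited partitions and their cluster counts,
the per-OTU association table, a machine-readable summary and a run log
recording every setting and seed in force. All outputs are plain TSV/JSON
and byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .association import LifeStageAssociation, rows_to_frame, summarize
from .core import read_gene_tree, read_specimen_table, read_tip_map
from .gmyc import GMYC
from .haplotypes import Alignment, collapse_haplotypes, stats_frame
from .ptp import PTP
from .simulate import SimConfig, simulate_dataset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class GeneConfig:
    name: str
    time_tree: str | None = None
    subst_tree: str | None = None
    alignment: str | None = None
    tip_map: str | None = None
    outgroup: str | None = None


@dataclass
class RunConfig:
    outdir: str
    genes: list[GeneConfig] = field(default_factory=list)
    specimens: str | None = None
    simulate: SimConfig | None = None
    methods: tuple[str, ...] = ("PTP", "GMYC")
    support_threshold: float = 0.95
    gmyc_df: int = 3
    ptp_mode: str = "heuristic"
    collapse_mode: str = "strict"
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and not self.genes:
            raise PipelineError("config", "need either a simulate block or gene inputs")
        if self.simulate is None and self.specimens is None:
            raise PipelineError("config", "association needs a specimen table")
        if not self.methods:
            raise PipelineError("config", "no delimitation method enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genes = [GeneConfig(**g) for g in raw.pop("genes", [])]
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimConfig(**sim)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(genes=genes, simulate=sim, **raw)


def _stage_seed(base: int, k: int) -> int:
    return (base * 1009 + k) % (2**31 - 1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage, returning the summary dict (also written to disk)."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    written: list[str] = []

    def emit(name: str, writer) -> str:
        path = os.path.join(cfg.outdir, name)
        writer(path)
        written.append(name)
        return path

    def fail(stage: str, exc: Exception):
        with open(os.path.join(cfg.outdir, "MANIFEST"), "w") as fh:
            fh.write("status\tincomplete\n")
            fh.write(f"failed_stage\t{stage}\n")
            for name in written:
                fh.write(f"artifact\t{name}\n")
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: inputs ---------------------------------------------------
    try:
        if cfg.simulate is not None:
            dataset = simulate_dataset(cfg.simulate)
            specimens = dataset.specimens
            time_trees = {g: gd.time_tree for g, gd in dataset.genes.items()}
            subst_trees = {g: gd.subst_tree for g, gd in dataset.genes.items()}
            alignments = {g: gd.alignment for g, gd in dataset.genes.items()}
            dataset.write(os.path.join(cfg.outdir, "inputs"))
            written.append("inputs/")
        else:
            specimens = read_specimen_table(cfg.specimens)
            time_trees, subst_trees, alignments = {}, {}, {}
            for gc in cfg.genes:
                tmap = read_tip_map(gc.tip_map) if gc.tip_map else None
                if gc.time_tree:
                    time_trees[gc.name] = read_gene_tree(
                        gc.time_tree, gc.name, tip_map=tmap, outgroup=gc.outgroup)
                if gc.subst_tree:
                    subst_trees[gc.name] = read_gene_tree(
                        gc.subst_tree, gc.name, tip_map=tmap, outgroup=gc.outgroup)
                if gc.alignment:
                    alignments[gc.name] = Alignment.from_fasta(gc.alignment, gc.name)
    except PipelineError:
        raise
    except Exception as exc:
        fail("inputs", exc)

    # ---- stage: haplotypes & alignment stats -----------------------------
    try:
        if alignments:
            emit("alignment_stats.tsv",
                 lambda p: stats_frame(sorted(alignments.values(), key=lambda a: a.gene))
                 .to_csv(p, sep="\t", index=False, float_format="%.4f"))
            for gene in sorted(alignments):
                hs = collapse_haplotypes(alignments[gene], cfg.collapse_mode)
                emit(f"{gene}_haplotypes.fasta", hs.to_alignment().to_fasta)
                emit(f"{gene}_haplotype_membership.tsv",
                     lambda p, hs=hs: hs.membership_frame().to_csv(p, sep="\t", index=False))
    except Exception as exc:
        fail("haplotypes", exc)

    # ---- stage: delimitation ---------------------------------------------
    partitions = []
    fit_reports = {}
    try:
        order = sorted(set(time_trees) | set(subst_trees))
        for k, gene in enumerate(order):
            if "GMYC" in cfg.methods and gene in time_trees:
                res = GMYC(time_trees[gene]).fit(df=cfg.gmyc_df,
                                                 seed=_stage_seed(cfg.seed, 2 * k))
                partitions.append(res.partition)
                fit_reports[f"{gene}_GMYC"] = res.to_dict()
            if "PTP" in cfg.methods and gene in subst_trees:
                res = PTP(subst_trees[gene]).fit(method=cfg.ptp_mode,
                                                 seed=_stage_seed(cfg.seed, 2 * k + 1))
                partitions.append(res.partition)
                fit_reports[f"{gene}_PTP"] = res.to_dict()
        if not partitions:
            raise ValueError("no partitions produced (check methods and tree inputs)")
        emit("partitions.tsv",
             lambda p: pd.concat([q.to_frame() for q in partitions])
             .to_csv(p, sep="\t", index=False))
        emit("cluster_counts.tsv",
             lambda p: pd.DataFrame(
                 [{"gene": q.gene, "method": q.method, "n_clusters": q.n_clusters}
                  for q in partitions]).to_csv(p, sep="\t", index=False))
    except Exception as exc:
        fail("delimitation", exc)

    # ---- stage: association ----------------------------------------------
    try:
        mono_trees = {g: subst_trees.get(g) or time_trees[g]
                      for g in sorted(set(time_trees) | set(subst_trees))}
        model = LifeStageAssociation(
            specimens, partitions, trees=mono_trees,
            support_threshold=cfg.support_threshold,
        )
        results = model.fit()
        emit("association_table.tsv",
             lambda p: rows_to_frame(results.rows).to_csv(p, sep="\t", index=False))
        emit("larvae_assignments.tsv",
             lambda p: results.larvae_assignments().to_csv(p, sep="\t", index=False))
        summary = {
            "counts": summarize(results.rows),
            "cluster_counts": {f"{q.gene}_{q.method}": q.n_clusters for q in partitions},
            "fits": fit_reports,
        }
        emit("summary.json",
             lambda p: open(p, "w").write(json.dumps(summary, indent=2, sort_keys=True)))
    except Exception as exc:
        fail("association", exc)

    # ---- run log ----------------------------------------------------------
    import dendropy
    import numpy
    import scipy

    log = {
        "stagematch": __version__,
        "versions": {"numpy": numpy.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__, "dendropy": dendropy.__version__},
        "seed": cfg.seed,
        "settings": {
            "methods": list(cfg.methods),
            "support_threshold": cfg.support_threshold,
            "gmyc_df": cfg.gmyc_df,
            "ptp_mode": cfg.ptp_mode,
            "collapse_mode": cfg.collapse_mode,
            "simulated": cfg.simulate is not None,
        },
        "artifacts": written,
    }
    emit("runlog.json", lambda p: open(p, "w").write(json.dumps(log, indent=2, sort_keys=True)))
    with open(os.path.join(cfg.outdir, "MANIFEST"), "w") as fh:
        fh.write("status\tcomplete\n")
        for name in written:
            fh.write(f"artifact\t{name}\n")
    return summary
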