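"""End-to-end orchestration: simulate -> AMT DB -> assign -> align -> test
-> enrich -> network, with a run manifest for provenance.

Each stage derives its own seed deterministically from the global seed
and the stage name, so a stage can be re-run in isolation and a full
re-run with the same config reproduces identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, amtdb, depstats, io, matching, network, synthetic
from .enrichment import AnnotationSet, enrich_terms, read_gmt

__all__ = ["PipelineConfig", "run_pipeline", "report_summary", "stage_seed", "percentage"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class ReportError(ValueError):
    """Manifest incomplete for reporting."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    outdir: str = "out"
    seed: int = 0
    # simulate stage
    n_proteins: int = 100
    peptides_per_protein: tuple[int, int] = (3, 8)
    de_fraction: float = 0.2
    fold_change_range: tuple[float, float] = (1.5, 4.0)
    n_per_group: int = 9
    n_replicates: int = 3
    noise: synthetic.NoiseModel | None = None
    # matching stage
    tolerances: matching.MatchTolerances = field(default_factory=matching.MatchTolerances)
    drop_ambiguous: bool = False
    # testing stage
    filter_cfg: depstats.FilterConfig = field(default_factory=depstats.FilterConfig)
    test_cfg: depstats.TestConfig = field(default_factory=depstats.TestConfig)
    # enrichment stage
    enrich_mode: str = "fisher"
    gmt_path: str | None = None
    edges_path: str | None = None
    # optional pre-existing inputs (skip simulation)
    runs_glob: str | None = None
    samples_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "noise" in kwargs and kwargs["noise"] is not None:
            kwargs["noise"] = synthetic.NoiseModel(**kwargs["noise"])
        if "tolerances" in kwargs and kwargs["tolerances"] is not None:
            kwargs["tolerances"] = matching.MatchTolerances(**kwargs["tolerances"])
        if "filter_cfg" in kwargs and kwargs["filter_cfg"] is not None:
            kwargs["filter_cfg"] = depstats.FilterConfig(**kwargs["filter_cfg"])
        if "test_cfg" in kwargs and kwargs["test_cfg"] is not None:
            kwargs["test_cfg"] = depstats.TestConfig(**kwargs["test_cfg"])
        for key in ("peptides_per_protein", "fold_change_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.runs_glob is not None and self.samples_path is None:
            raise ConfigError("runs_glob requires samples_path")
        for p in (self.samples_path, self.gmt_path, self.edges_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; write artifacts; return the manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": []}

    def record(stage: str, path: Path | None = None, **counts) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(cfg.seed, stage),
            **counts,
        }
        if path is not None:
            manifest["outputs"].append(str(path))

    # --- simulate (or load) -------------------------------------------------
    truth = None
    if cfg.runs_glob is None:
        sim_seed = stage_seed(cfg.seed, "simulate")
        truth = synthetic.generate_ground_truth(
            n_proteins=cfg.n_proteins,
            peptides_per_protein=cfg.peptides_per_protein,
            de_fraction=cfg.de_fraction,
            fold_change_range=cfg.fold_change_range,
            seed=sim_seed,
        )
        design = synthetic.CohortDesign(cfg.n_per_group, cfg.n_replicates)
        noise = cfg.noise or synthetic.NoiseModel()
        noise = synthetic.NoiseModel(**{**asdict(noise), "seed": sim_seed})
        runs, sheet, truth_manifest = synthetic.simulate_cohort(truth, design, noise)
        io.write_tsv(sheet, out / "samples.tsv")
        io.write_tsv(truth_manifest, out / "truth_manifest.tsv")
        record(
            "simulate",
            out / "samples.tsv",
            n_runs=len(runs),
            n_features=int(sum(len(df) for df in runs.values())),
            n_planted_de=len(truth.de_proteins),
        )
        protein_map = truth.protein_map()
    else:
        import glob as _glob

        paths = sorted(_glob.glob(cfg.runs_glob))
        if not paths:
            raise ConfigError(f"no run tables match {cfg.runs_glob}")
        runs = {Path(p).stem: io.read_run_table(p) for p in paths}
        runs = {str(df["run_id"].iloc[0]): df for df in runs.values()}
        sheet = io.read_tsv(cfg.samples_path)
        record("load", None, n_runs=len(runs))
        protein_map = None

    # --- AMT DB -------------------------------------------------------------
    db, calibrated, reports = amtdb.compile_amt_database(runs, protein_map)
    io.write_tsv(db.to_frame(), out / "amt_db.tsv")
    record(
        "build_db",
        out / "amt_db.tsv",
        n_entries=len(db),
        n_runs_calibrated=sum(r.calibrated for r in reports),
    )

    # --- assignment ---------------------------------------------------------
    assign_parts = []
    totals = dict(n_total=0, n_identified=0, n_amt_assigned=0)
    for rid in sorted(calibrated):
        a, s = matching.assign_peptides(
            calibrated[rid], db, cfg.tolerances, cfg.drop_ambiguous
        )
        assign_parts.append(a)
        totals["n_total"] += s.n_total
        totals["n_identified"] += s.n_identified
        totals["n_amt_assigned"] += s.n_amt_assigned
    assignments = pd.concat(assign_parts, ignore_index=True)
    io.write_tsv(assignments, out / "assignments.tsv")
    summary = matching.AssignmentSummary(**totals)
    record(
        "assign",
        out / "assignments.tsv",
        **totals,
        n_with_id=summary.n_with_id,
        id_fraction=summary.id_fraction,
    )

    # --- alignment ----------------------------------------------------------
    features = pd.concat(calibrated.values(), ignore_index=True)
    raw = align.build_alignment(assignments, features)
    log2_table = np.log2(raw)
    normed = align.quantile_normalize(log2_table)
    subject_table, meta = align.collapse_replicates(normed, sheet)
    io.write_matrix(subject_table, out / "aligned_subjects.tsv")
    record(
        "align",
        out / "aligned_subjects.tsv",
        n_peptides=int(subject_table.shape[0]),
        n_subjects=int(subject_table.shape[1]),
    )

    # --- differential test --------------------------------------------------
    if protein_map is None:
        # infer peptide -> protein from the AMT DB annotations
        pm = {
            p: sorted(e.protein_ids)[0]
            for p, e in db.entries.items()
            if e.protein_ids
        }
        protein_map = pd.Series(pm, name="protein_id")
    test_cfg = depstats.TestConfig(
        **{**asdict(cfg.test_cfg), "seed": stage_seed(cfg.seed, "test")}
    )
    pep_res, prot_res = depstats.run_differential_test(
        subject_table, meta, protein_map, cfg.filter_cfg, test_cfg
    )
    io.write_tsv(pep_res, out / "peptide_results.tsv")
    io.write_tsv(prot_res, out / "protein_results.tsv")
    n_dep = int(prot_res["is_dep"].sum()) if len(prot_res) else 0
    deps = prot_res.loc[prot_res["is_dep"]] if len(prot_res) else prot_res
    record(
        "test",
        out / "protein_results.tsv",
        n_peptides_tested=len(pep_res),
        n_proteins=len(prot_res),
        n_significant_peptides=int(pep_res["significant"].sum()) if len(pep_res) else 0,
        n_deps=n_dep,
        n_up=int((deps["direction"] == "up").sum()) if n_dep else 0,
        n_down=int((deps["direction"] == "down").sum()) if n_dep else 0,
        n_mixed=int((deps["direction"] == "mixed").sum()) if n_dep else 0,
    )

    # --- enrichment + network ----------------------------------------------
    if cfg.gmt_path is not None and len(prot_res):
        annotations = read_gmt(cfg.gmt_path)
        universe = set(prot_res["protein_id"])
        dep_set = set(deps["protein_id"])
        if dep_set:
            enr = enrich_terms(dep_set, annotations, universe, mode=cfg.enrich_mode)
        else:
            enr = pd.DataFrame()
        io.write_tsv(enr, out / "enrichment.tsv")
        record(
            "enrich",
            out / "enrichment.tsv",
            n_terms=len(enr),
            n_significant_terms=int(enr["significant"].sum()) if len(enr) else 0,
        )
        if cfg.edges_path is not None:
            edges = network.read_edge_list(cfg.edges_path)
            g = network.build_network(prot_res, enr, edges, annotations)
            nodes_df, edges_df = network.network_to_frames(g)
            io.write_tsv(nodes_df, out / "network_nodes.tsv")
            io.write_tsv(edges_df, out / "network_edges.sif.tsv")
            record(
                "network",
                out / "network_nodes.tsv",
                n_nodes=g.number_of_nodes(),
                n_edges=g.number_of_edges(),
                n_malformed_edges=edges.attrs.get("n_skipped", 0),
            )

    manifest["outputs"] = sorted(set(manifest["outputs"]))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def percentage(part: int, total: int) -> float:
    """Percentage to one decimal; 0.0 for an empty denominator."""
    return round(100.0 * part / total, 1) if total else 0.0


def report_summary(manifest: dict) -> dict:
    """Counts and one-decimal percentages from a completed run manifest."""
    stages = manifest.get("stages", {})
    if "test" not in stages or "align" not in stages:
        raise ReportError("manifest lacks completed align/test stages")
    t = stages["test"]
    n_deps = t["n_deps"]
    if n_deps != t["n_up"] + t["n_down"] + t["n_mixed"]:
        raise ReportError("DEP direction counts do not add up")
    return {
        "n_peptides": stages["align"]["n_peptides"],
        "n_proteins": t["n_proteins"],
        "n_deps": n_deps,
        "n_up": t["n_up"],
        "n_down": t["n_down"],
        "n_mixed": t["n_mixed"],
        "pct_up": percentage(t["n_up"], n_deps),
        "pct_down": percentage(t["n_down"], n_deps),
    }
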