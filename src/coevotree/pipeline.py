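"""End-to-end orchestration: inputs -> distances -> mirrortree -> report.

A run is described by a :class:`RunConfig` naming one target gene pair and
a panel of control genes.  In genetic-distance mode every gene is an
aligned protein FASTA and distances come from the JTT ML estimator; in
patristic mode every gene is one or more Newick trees (e.g. produced by
different tree-building methods) and distances are patristic.  Either way
the statistical core is identical: mirrortree correlation for the target
pair and for target-anchor/control pairs, then Fisher r-to-z comparisons
of the target correlation against each control correlation.

Per-control failures (parse errors, missing branch lengths, insufficient
taxon overlap) are recorded in the run log and the run continues; only a
failure of the target pair aborts the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import ProteinAlignment
from .coevolution import (ControlPanelReport, CorrelationResult, DEFAULT_CUTOFF,
                          control_panel_analysis, mirrortree_correlation)
from .distances import bootstrap_distances, distance_matrix, write_phylip
from .errors import CoevotreeError, InvalidParameterError
from .simulate import (CoevolutionParams, evolve_alignment,
                       simulate_coevolving_gene_trees, simulate_species_tree)
from .trees import patristic_matrix, read_newick

MODES = ("genetic-distance", "patristic", "simulate-validate")


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one coevolution analysis run."""

    mode: str
    genes: Mapping[str, Any]  # label -> path, or label -> {method: path}
    target_pair: tuple[str, str]
    control_genes: tuple[str, ...] = ()
    cutoff: float = DEFAULT_CUTOFF
    bootstrap: int = 0
    seed: int = 0
    output_dir: str | None = None
    sign_convention: str = "equation"

    def __post_init__(self):
        if self.mode not in MODES:
            raise InvalidParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if len(self.target_pair) != 2:
            raise InvalidParameterError("target_pair must name exactly two genes")
        missing = [g for g in (*self.target_pair, *self.control_genes)
                   if g not in self.genes]
        if missing:
            raise InvalidParameterError(f"genes not in inputs: {missing}")
        if not 0.0 < self.cutoff < 1.0:
            raise InvalidParameterError(f"cutoff must be in (0, 1), got {self.cutoff}")
        object.__setattr__(self, "target_pair", tuple(self.target_pair))
        object.__setattr__(self, "control_genes", tuple(self.control_genes))
        object.__setattr__(self, "genes", dict(self.genes))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class RunResult:
    """Results table plus structured run log."""

    table: pd.DataFrame
    run_log: dict
    reports: dict[str, ControlPanelReport] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "results.tsv", sep="\t", index=False)
        with open(out / "runlog.json", "w") as fh:
            json.dump(self.run_log, fh, indent=2, sort_keys=True)


def _panel_rows(method: str, target: CorrelationResult,
                report: ControlPanelReport) -> list[dict]:
    rows = [{"gene_pair": "-".join(target.gene_pair), "method": method,
             "role": "target", "r": target.r, "r_fisher": target.r_fisher,
             "n_taxa": target.n_taxa, "z_vs_target": 0.0, "p": np.nan,
             "above_cutoff": report.target_above_cutoff, "error": ""}]
    for _, row in report.table.iterrows():
        rows.append({"gene_pair": row["control"], "method": method,
                     "role": "control", "r": row["r"],
                     "r_fisher": row["r_fisher"], "n_taxa": row["n_taxa"],
                     "z_vs_target": row["z_vs_target"], "p": row["p"],
                     "above_cutoff": row["r"] > report.cutoff,
                     "error": row["error"]})
    return rows


def run_genetic_distance_mode(cfg: RunConfig) -> RunResult:
    """JTT genetic-distance mirrortree run per the configured design."""
    if cfg.mode != "genetic-distance":
        raise InvalidParameterError(f"config mode is {cfg.mode!r}")
    log: dict = {"version": __version__, "mode": cfg.mode, "seed": cfg.seed,
                 "genes": {}, "failures": {}, "target_pair": list(cfg.target_pair)}
    matrices = {}
    anchor, partner = cfg.target_pair
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    for gene in dict.fromkeys((*cfg.target_pair, *cfg.control_genes)):
        path = cfg.genes[gene]
        try:
            aln = ProteinAlignment.read_fasta(path)
            res = distance_matrix(aln)
            matrices[gene] = res.matrix
            entry = {"input": str(path), "n_taxa": aln.n_taxa,
                     "n_sites": aln.length,
                     "n_saturated_pairs": len(res.saturated_pairs)}
            if cfg.bootstrap > 0:
                bs = bootstrap_distances(aln, n_replicates=cfg.bootstrap,
                                         seed=cfg.seed)
                entry["bootstrap_mean_se"] = float(
                    bs.standard_errors[np.triu_indices(aln.n_taxa, 1)].mean())
            if out_dir is not None:
                write_phylip(res.matrix, out_dir / f"{gene}.jtt.phylip")
            log["genes"][gene] = entry
        except (CoevotreeError, OSError, ValueError) as exc:
            log["failures"][gene] = f"{type(exc).__name__}: {exc}"
            if gene in cfg.target_pair:
                raise CoevotreeError(
                    f"target gene {gene!r} failed: {exc}") from exc

    target = mirrortree_correlation(matrices[anchor], matrices[partner],
                                    gene_pair=cfg.target_pair)
    controls = []
    for gene in cfg.control_genes:
        if gene not in matrices:
            continue
        try:
            controls.append(mirrortree_correlation(
                matrices[anchor], matrices[gene], gene_pair=(anchor, gene)))
        except CoevotreeError as exc:
            log["failures"][f"{anchor}-{gene}"] = f"{type(exc).__name__}: {exc}"
    report = control_panel_analysis(target, controls, cutoff=cfg.cutoff,
                                    sign_convention=cfg.sign_convention) \
        if controls else ControlPanelReport(
            target=target, cutoff=cfg.cutoff,
            table=pd.DataFrame(columns=["control", "r", "r_fisher", "n_taxa",
                                        "z_vs_target", "p", "error"]))
    table = pd.DataFrame(_panel_rows("jtt-ml", target, report))
    log["target_r"] = target.r
    log["target_above_cutoff"] = report.target_above_cutoff
    result = RunResult(table=table, run_log=log, reports={"jtt-ml": report})
    if out_dir is not None:
        result.write(out_dir)
    return result


def _gene_methods(entry) -> dict[str, str]:
    """Normalize a gene input to {method: path}."""
    if isinstance(entry, Mapping):
        return {str(k): str(v) for k, v in entry.items()}
    return {"input": str(entry)}


def run_patristic_mode(cfg: RunConfig) -> RunResult:
    """Patristic-distance mirrortree run, one sub-table per tree method."""
    if cfg.mode != "patristic":
        raise InvalidParameterError(f"config mode is {cfg.mode!r}")
    log: dict = {"version": __version__, "mode": cfg.mode, "seed": cfg.seed,
                 "genes": {}, "failures": {}, "target_pair": list(cfg.target_pair)}
    anchor, partner = cfg.target_pair
    matrices: dict[tuple[str, str], Any] = {}
    methods: set[str] = set()
    for gene in dict.fromkeys((*cfg.target_pair, *cfg.control_genes)):
        for method, path in _gene_methods(cfg.genes[gene]).items():
            try:
                dm = patristic_matrix(read_newick(path))
                matrices[gene, method] = dm
                methods.add(method)
                log["genes"][f"{gene}/{method}"] = {
                    "input": str(path), "n_taxa": len(dm.ids)}
            except (CoevotreeError, OSError) as exc:
                log["failures"][f"{gene}/{method}"] = f"{type(exc).__name__}: {exc}"
                if gene in cfg.target_pair:
                    raise CoevotreeError(
                        f"target gene {gene!r} ({method}) failed: {exc}") from exc

    rows, reports = [], {}
    for method in sorted(methods):
        if (anchor, method) not in matrices or (partner, method) not in matrices:
            log["failures"][f"target/{method}"] = "target pair incomplete for method"
            continue
        target = mirrortree_correlation(matrices[anchor, method],
                                        matrices[partner, method],
                                        gene_pair=cfg.target_pair)
        controls = []
        for gene in cfg.control_genes:
            if (gene, method) not in matrices:
                continue
            try:
                controls.append(mirrortree_correlation(
                    matrices[anchor, method], matrices[gene, method],
                    gene_pair=(anchor, gene)))
            except CoevotreeError as exc:
                log["failures"][f"{anchor}-{gene}/{method}"] = \
                    f"{type(exc).__name__}: {exc}"
        report = control_panel_analysis(
            target, controls, cutoff=cfg.cutoff,
            sign_convention=cfg.sign_convention) if controls else \
            ControlPanelReport(target=target, cutoff=cfg.cutoff,
                               table=pd.DataFrame(
                                   columns=["control", "r", "r_fisher", "n_taxa",
                                            "z_vs_target", "p", "error"]))
        reports[method] = report
        rows.extend(_panel_rows(method, target, report))
    if not rows:
        raise CoevotreeError("target pair failed for every tree method")
    result = RunResult(table=pd.DataFrame(rows), run_log=log, reports=reports)
    if cfg.output_dir:
        result.write(cfg.output_dir)
    return result


# ------------------------------------------------- synthetic experiments ---

def simulate_panel_experiment(seed: int, n_taxa: int = 50,
                              rho_target: float = 0.9,
                              rho_control: float = 0.0,
                              n_controls: int = 8,
                              rate_sd: float = 0.5,
                              cutoff: float = DEFAULT_CUTOFF,
                              sign_convention: str = "equation",
                              ) -> ControlPanelReport:
    """One synthetic control-panel run on patristic distances.

    Simulates a species tree, a target gene pair with rate correlation
    ``rho_target`` and ``n_controls`` independent gene pairs at
    ``rho_control``, then runs the control-panel comparison.  This mirrors
    the one-target/eight-housekeeping-controls design used for real data.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 + n_controls)
    species = simulate_species_tree(n_taxa, seed=int(seeds[0]) & 0x7FFFFFFF)
    pair = simulate_coevolving_gene_trees(
        species, CoevolutionParams(rho=rho_target, rate_sd=rate_sd,
                                   seed=int(seeds[1]) & 0x7FFFFFFF))
    target = mirrortree_correlation(patristic_matrix(pair.tree_a),
                                    patristic_matrix(pair.tree_b),
                                    gene_pair=("target_a", "target_b"))
    controls = []
    for i in range(n_controls):
        cpair = simulate_coevolving_gene_trees(
            species, CoevolutionParams(rho=rho_control, rate_sd=rate_sd,
                                       seed=int(seeds[2 + i]) & 0x7FFFFFFF))
        controls.append(mirrortree_correlation(
            patristic_matrix(cpair.tree_a), patristic_matrix(cpair.tree_b),
            gene_pair=("target_a", f"control_{i+1}")))
    return control_panel_analysis(target, controls, cutoff=cutoff,
                                  sign_convention=sign_convention)


def _rho_sweep(seed: int, rhos, n_taxa: int, rate_sd: float,
               n_replicates: int) -> dict:
    means = []
    for k, rho in enumerate(rhos):
        rs = []
        child = np.random.SeedSequence([seed, k])
        states = child.generate_state(2 * n_replicates)
        for i in range(n_replicates):
            sp = simulate_species_tree(
                n_taxa, seed=int(states[2 * i]) & 0x7FFFFFFF)
            pair = simulate_coevolving_gene_trees(
                sp, CoevolutionParams(rho=rho, rate_sd=rate_sd,
                                      seed=int(states[2 * i + 1]) & 0x7FFFFFFF))
            rs.append(mirrortree_correlation(
                patristic_matrix(pair.tree_a),
                patristic_matrix(pair.tree_b)).r)
        means.append(float(np.mean(rs)))
    return {"rhos": list(rhos), "mean_r": means,
            "monotone_pass": bool(np.all(np.diff(means) > 0))}


def run_validation_suite(seed: int = 0, n_taxa: int = 50,
                         rate_sd: float = 0.5, n_replicates: int = 50,
                         n_panel_runs: int = 100,
                         consistency_sites: int = 50_000,
                         consistency_reps: int = 10,
                         out_path=None) -> dict:
    """Synthetic self-validation of the whole pipeline.

    Runs the rho-sweep parameter-recovery experiment, the baseline-inflation
    / control-panel specificity measurement, and the ML-distance consistency
    check, and returns (optionally writes) a machine-readable summary with a
    pass flag per property.  Failures are reported, not raised.
    """
    from .distances import jtt_pairwise_distance, p_distance
    from .jtt import jtt_model
    from .trees import parse_newick

    rhos = (0.0, 0.25, 0.5, 0.75, 1.0)
    sweep = _rho_sweep(seed, rhos, n_taxa, rate_sd, n_replicates)

    # perfect-coevolution limit: rho=1, no rate noise -> identical trees
    sp = simulate_species_tree(n_taxa, seed=seed)
    pair = simulate_coevolving_gene_trees(
        sp, CoevolutionParams(rho=1.0, rate_sd=0.0, seed=seed))
    r_perfect = mirrortree_correlation(patristic_matrix(pair.tree_a),
                                       patristic_matrix(pair.tree_b)).r
    perfect = {"r": r_perfect, "pass": bool(r_perfect > 1 - 1e-9)}

    panel_states = np.random.SeedSequence([seed, 101]).generate_state(n_panel_runs)
    target_flags, control_flag_rates, favoring = [], [], []
    for s in panel_states:
        report = simulate_panel_experiment(int(s) & 0x7FFFFFFF,
                                           n_taxa=n_taxa, rate_sd=rate_sd)
        target_flags.append(report.target_above_cutoff)
        control_flag_rates.append(
            float((report.table["r"] > report.cutoff).mean()))
        favoring.append(bool((report.table["z_vs_target"] > 0).median() >= 0.5))
    baseline_mean_r = sweep["mean_r"][0]
    baseline = {
        "mean_r_rho0": baseline_mean_r,
        "target_flag_rate": float(np.mean(target_flags)),
        "control_flag_rate": float(np.mean(control_flag_rates)),
        "target_favoring_rate": float(np.mean(favoring)),
        "pass": bool(baseline_mean_r > 0
                     and np.mean(target_flags) > np.mean(control_flag_rates)),
    }

    model = jtt_model()
    states = np.random.SeedSequence([seed, 202]).generate_state(
        3 * consistency_reps)
    consistency = {"true_d": [0.1, 0.5, 1.0], "mean_estimate": [],
                   "within_10pct": [], "jtt_ge_p_distance": True}
    k = 0
    for d in consistency["true_d"]:
        ests = []
        for _ in range(consistency_reps):
            tree = parse_newick(f"(A:{d / 2},B:{d / 2});")
            aln = evolve_alignment(tree, model, n_sites=consistency_sites,
                                   seed=int(states[k]) & 0x7FFFFFFF)
            k += 1
            est = jtt_pairwise_distance(aln.sequence("A"), aln.sequence("B"),
                                        model).distance
            if est < p_distance(aln.sequence("A"), aln.sequence("B")):
                consistency["jtt_ge_p_distance"] = False
            ests.append(est)
        ests = np.asarray(ests)
        consistency["mean_estimate"].append(float(ests.mean()))
        consistency["within_10pct"].append(
            float(np.mean(np.abs(ests - d) <= 0.1 * d)))
    consistency["pass"] = bool(
        consistency["jtt_ge_p_distance"]
        and all(f >= 0.9 for f in consistency["within_10pct"]))

    summary = {
        "seed": seed,
        "version": __version__,
        "parameters": {"n_taxa": n_taxa, "rate_sd": rate_sd,
                       "n_replicates": n_replicates,
                       "n_panel_runs": n_panel_runs,
                       "consistency_sites": consistency_sites,
                       "consistency_reps": consistency_reps},
        "rho_sweep": sweep,
        "perfect_coevolution": perfect,
        "baseline_inflation": baseline,
        "estimator_consistency": consistency,
        "all_pass": bool(sweep["monotone_pass"] and perfect["pass"]
                         and baseline["pass"] and consistency["pass"]),
    }
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
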