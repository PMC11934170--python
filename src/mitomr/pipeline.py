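"""End-to-end orchestration of the drug-target screen.

``screen_panel`` runs the in-memory pipeline (instrument selection ->
harmonization -> MR -> FDR/tiering -> candidate/core/direction
classification) over a panel of protein exposures and nine outcome
datasets. ``run_screen`` drives the same stages from a YAML config with
file inputs or a simulation block and writes the report bundle:
``mr_results.tsv`` (display precision) and ``mr_results_full.tsv``,
``classification.tsv``, ``venn_counts.json``, ``beta_heatmap.tsv``, and,
when expression validation is enabled, ``scores.tsv`` and
``de_results.tsv``, plus a ``run_log.txt`` recording seeds and versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .expression import (
    ExpressionMatrix, GeneSet, combat_adjust, median_split, moderated_t_de,
    risk_enrichment,
)
from .gwas_io import SummaryStatsTable, harmonize, kept_pairs, read_summary_stats
from .instruments import (
    LDTable, SelectionConfig, read_blocklist, read_ld_table, select_instruments,
)
from .mr import METHOD_IVW, METHOD_WALD, MRConfig, MRReport, run_mr
from .screening import (
    ScreeningConfig, adjust_by_dataset, assign_tier, classify_printed,
    classify_targets, load_printed_estimates, risk_resistance_sets, venn_counts,
)

__all__ = ["PipelineConfig", "ScreenResult", "screen_panel", "run_screen",
           "replay_fixture", "write_bundle"]

log = logging.getLogger("mitomr")


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see the YAML schema in the docs).

    ``exposures`` maps exposure ids to summary-stats paths; ``outcomes``
    maps dataset ids to ``{path, category}``; ``ld`` and ``blocklist`` are
    optional paths. Alternatively a ``simulate`` mapping (panel simulation
    arguments) replaces the file inputs. ``expression`` optionally carries
    ``values``/``annotation`` paths or ``simulate: true``.
    """

    output_dir: str = "mitomr_out"
    seed: int = 0
    exposures: Dict[str, str] = field(default_factory=dict)
    outcomes: Dict[str, Dict[str, str]] = field(default_factory=dict)
    ld: Optional[str] = None
    blocklist: Optional[str] = None
    simulate: Optional[Dict] = None
    expression: Optional[Dict] = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    mr: MRConfig = field(default_factory=MRConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"output_dir", "seed", "exposures", "outcomes", "ld",
                 "blocklist", "simulate", "expression", "selection", "mr",
                 "screening"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if not (raw.get("exposures") and raw.get("outcomes")) and not raw.get("simulate"):
            raise ConfigurationError(
                "config needs exposures/outcomes or a simulate block"
            )
        kwargs = {}
        for key in ("output_dir", "seed", "exposures", "outcomes", "ld",
                    "blocklist", "simulate", "expression"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, typ in (("selection", SelectionConfig), ("mr", MRConfig),
                         ("screening", ScreeningConfig)):
            if key in raw:
                section = dict(raw[key])
                if key == "selection" and "confounder_rsids" in section:
                    section["confounder_rsids"] = frozenset(section["confounder_rsids"])
                kwargs[key] = typ(**section)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc


@dataclass
class ScreenResult:
    """In-memory report bundle."""

    mr_results: pd.DataFrame
    calls: pd.DataFrame
    classification: pd.DataFrame
    venn: Dict
    heatmap: pd.DataFrame
    instruments: Dict[str, object] = field(default_factory=dict)
    scores: Optional[pd.DataFrame] = None
    de_results: Optional[pd.DataFrame] = None


def _headline(report: MRReport):
    """The tiering estimate for a pair: Wald ratio if k = 1 else IVW."""
    for method in (METHOD_WALD, METHOD_IVW):
        for est in report.estimates:
            if est.method == method:
                return est
    return None


def screen_panel(
    exposures: Mapping[str, SummaryStatsTable],
    outcomes: Mapping[str, Mapping[str, SummaryStatsTable]],
    lds: Mapping[str, LDTable],
    selection: SelectionConfig = SelectionConfig(),
    mr_cfg: MRConfig = MRConfig(),
    screening: ScreeningConfig = ScreeningConfig(),
) -> ScreenResult:
    """Run the MR screen over a panel.

    ``outcomes[exposure_id][dataset_id]`` holds the outcome table relevant
    to that exposure's SNPs (outcome summary statistics restricted to the
    neighbourhood of each protein's instruments).
    """
    mr_rows: List[dict] = []
    call_rows: List[dict] = []
    instrument_sets: Dict[str, object] = {}
    for exp_id, exposure in exposures.items():
        iset = select_instruments(exposure, lds[exp_id], selection)
        instrument_sets[exp_id] = iset
        if iset.k == 0:
            log.info("exposure %s: empty instrument set, skipped", exp_id)
            continue
        exp_sel = exposure.subset(iset.rsids)
        for ds_id, outcome in outcomes[exp_id].items():
            pairs = kept_pairs(harmonize(exp_sel, outcome))
            if pairs.empty:
                log.info("pair %s/%s: no harmonized instruments", exp_id, ds_id)
                continue
            report = run_mr(pairs, exp_id, ds_id, mr_cfg)
            for est in report.estimates:
                or_, lo, hi = est.or_, *est.or_ci
                mr_rows.append(
                    {
                        "exposure": exp_id, "outcome": ds_id,
                        "outcome_category": outcome.outcome_category,
                        "nsnp": est.nsnp, "method": est.method,
                        "beta": est.beta, "se": est.se, "p_value": est.p,
                        "or": or_, "or_ci_low": lo, "or_ci_high": hi,
                    }
                )
            head = _headline(report)
            if head is not None:
                call_rows.append(
                    {
                        "exposure": exp_id, "dataset_id": ds_id,
                        "outcome_category": outcome.outcome_category,
                        "beta": head.beta, "se": head.se, "p": head.p,
                    }
                )
    mr_results = pd.DataFrame(mr_rows)
    calls = pd.DataFrame(call_rows)
    if calls.empty:
        empty_cls = pd.DataFrame(
            columns=["exposure", "is_candidate", "is_core", "direction",
                     "supporting_categories", "n_significant_datasets"]
        )
        return ScreenResult(mr_results, calls, empty_cls, {}, pd.DataFrame(),
                            instrument_sets)
    calls = adjust_by_dataset(calls, screening)
    calls["tier"] = [assign_tier(p, q) for p, q in zip(calls["p"], calls["q"])]
    if not mr_results.empty:
        qmap = calls.set_index(["exposure", "dataset_id"])["q"]
        mr_results["q_value"] = [
            qmap.get((e, o), np.nan)
            for e, o in zip(mr_results["exposure"], mr_results["outcome"])
        ]
    classification = classify_targets(calls, screening)
    venn = venn_counts(calls, screening)
    heatmap = calls.pivot(index="exposure", columns="dataset_id", values="beta")
    return ScreenResult(mr_results, calls, classification, venn, heatmap,
                        instrument_sets)


def validate_expression(
    matrix: ExpressionMatrix,
    risk: GeneSet,
    resistance: GeneSet,
    adjust: bool = True,
    dn_only_scoring: bool = False,
) -> tuple:
    """Batch-adjust, score, median-split DN samples, and test genes.

    Returns ``(scores frame, de frame)``. Scoring uses the full cohort by
    default; ``dn_only_scoring`` restricts the scoring cohort to DN samples.
    """
    if adjust and matrix.batch.nunique() > 1:
        matrix = combat_adjust(matrix)
    cohort = matrix
    if dn_only_scoring:
        dn = [s for s in matrix.samples if matrix.group[s] == "DN"]
        cohort = matrix.restrict_samples(dn)
    scores = risk_enrichment(cohort, risk, resistance)
    dn_samples = [s for s in cohort.samples if matrix.group[s] == "DN"]
    split = median_split(scores.loc[dn_samples, "risk_enrichment"])
    scores["split"] = split.reindex(scores.index)
    de = moderated_t_de(matrix.restrict_samples(dn_samples), split)
    return scores, de


def write_bundle(result: ScreenResult, output_dir: str, seed: int) -> List[str]:
    """Write the TSV/JSON report bundle; returns the paths written."""
    os.makedirs(output_dir, exist_ok=True)
    paths = []

    def emit(name, writer):
        path = os.path.join(output_dir, name)
        writer(path)
        paths.append(path)

    display = result.mr_results.copy()
    if not display.empty:
        for col in ("beta", "se"):
            display[col] = display[col].map(lambda v: f"{v:.4f}")
        for col in ("or", "or_ci_low", "or_ci_high"):
            display[col] = display[col].map(lambda v: f"{v:.3f}")
    emit("mr_results.tsv", lambda p: display.to_csv(p, sep="\t", index=False))
    emit("mr_results_full.tsv",
         lambda p: result.mr_results.to_csv(p, sep="\t", index=False))
    emit("classification.tsv",
         lambda p: result.classification.to_csv(p, sep="\t", index=False))
    emit("venn_counts.json", lambda p: open(p, "w").write(
        json.dumps(result.venn, indent=2, sort_keys=True)))
    emit("beta_heatmap.tsv", lambda p: result.heatmap.to_csv(p, sep="\t"))
    if result.scores is not None:
        emit("scores.tsv", lambda p: result.scores.to_csv(p, sep="\t"))
    if result.de_results is not None:
        emit("de_results.tsv",
             lambda p: result.de_results.to_csv(p, sep="\t", index=False))
    emit("run_log.txt", lambda p: open(p, "w").write(
        f"mitomr {__version__}\nseed {seed}\n"))
    return paths


def _load_file_panel(cfg: PipelineConfig):
    exposures, outcomes, lds = {}, {}, {}
    blocklist = read_blocklist(cfg.blocklist) if cfg.blocklist else frozenset()
    selection = dataclasses.replace(
        cfg.selection, confounder_rsids=cfg.selection.confounder_rsids | blocklist
    )
    outcome_tables = {
        ds_id: read_summary_stats(spec["path"], "outcome", spec["category"],
                                  trait_id=ds_id)
        for ds_id, spec in cfg.outcomes.items()
    }
    for exp_id, path in cfg.exposures.items():
        exposures[exp_id] = read_summary_stats(path, "exposure", trait_id=exp_id)
        outcomes[exp_id] = outcome_tables
        lds[exp_id] = read_ld_table(cfg.ld) if cfg.ld else LDTable()
        if cfg.ld:
            lds[exp_id].positions.update(
                {
                    r["rsid"]: (r["chrom"], int(r["pos"]))
                    for _, r in exposures[exp_id].records.iterrows()
                    if pd.notna(r["pos"])
                }
            )
    return exposures, outcomes, lds, selection


def run_screen(cfg: PipelineConfig) -> ScreenResult:
    """Execute the configured pipeline and write the report bundle."""
    from .simulate import (
        ExprSimConfig, MRSimConfig, PanelSimConfig, simulate_expression,
        simulate_screen_panel,
    )

    if cfg.simulate is not None:
        sim_args = dict(cfg.simulate)
        mr_args = sim_args.pop("mr", {})
        panel_cfg = PanelSimConfig(
            seed=sim_args.pop("seed", cfg.seed),
            mr=MRSimConfig(**mr_args), **sim_args,
        )
        panel = simulate_screen_panel(panel_cfg)
        exposures = {n: p.exposure for n, p in panel.proteins.items()}
        outcomes = {n: p.outcomes for n, p in panel.proteins.items()}
        lds = {n: p.ld for n, p in panel.proteins.items()}
        selection = cfg.selection
    else:
        if not cfg.exposures or not cfg.outcomes:
            raise ConfigurationError("config needs exposures/outcomes or a simulate block")
        exposures, outcomes, lds, selection = _load_file_panel(cfg)

    result = screen_panel(exposures, outcomes, lds, selection, cfg.mr,
                          cfg.screening)

    if cfg.expression:
        expr = dict(cfg.expression)
        risk_names, res_names = risk_resistance_sets(result.classification)
        if expr.get("simulate"):
            sim_cfg = ExprSimConfig(
                seed=expr.get("seed", cfg.seed),
                **{k: v for k, v in expr.items() if k not in ("simulate", "seed")},
            )
            sim = simulate_expression(sim_cfg)
            matrix = sim.matrix
            # name the signal genes after the classified proteins so the
            # screening-derived sets map onto the matrix
            rename = {}
            for old, new in zip(sim.risk_genes, risk_names):
                rename[old] = new
            for old, new in zip(sim.resistance_genes, res_names):
                rename[old] = new
            matrix.values.rename(index=rename, inplace=True)
            risk_members = [rename.get(g, g) for g in sim.risk_genes]
            res_members = [rename.get(g, g) for g in sim.resistance_genes]
        else:
            from .expression import read_expression_tsv

            matrix = read_expression_tsv(expr["values"], expr["annotation"])
            risk_members = [g for g in risk_names if g in matrix.genes]
            res_members = [g for g in res_names if g in matrix.genes]
        if risk_members and res_members:
            scores, de = validate_expression(
                matrix, GeneSet("risk", frozenset(risk_members)),
                GeneSet("resistance", frozenset(res_members)),
            )
            result.scores, result.de_results = scores, de
        else:
            log.warning("expression validation skipped: empty gene set")

    write_bundle(result, cfg.output_dir, cfg.seed)
    return result


def replay_fixture(which: str = "core",
                   cfg: ScreeningConfig = ScreeningConfig()) -> pd.DataFrame:
    """Screening-stage classification of the packaged printed estimates."""
    return classify_printed(load_printed_estimates(which), cfg)
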