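"""End-to-end pipeline: simulate → preprocess → telomere → clocks →
associations → enrichment → report.

Each stage reads/writes plain-text artifacts under the run's output
directory and appends a record to the run manifest, so a completed run is
fully reproducible from its config (fixed seeds throughout; no
timestamps in any output).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from kidbioage import __version__
from kidbioage.associations import (
    AssociationSpec,
    fdr_adjust,
    partial_correlation,
    prepare_markers,
    results_table,
    run_association,
    sensitivity_suite,
    transform_outcomes,
)
from kidbioage.clock import ClockModel, predict_ages, progression_test, tune_and_fit, validate
from kidbioage.enrichment import GeneSet, ora_collection, ora_table, read_gmt
from kidbioage.preprocess import Scaler, harmonize_block, scale_features
from kidbioage.synth import (
    BLOCK_KINDS,
    CBCL_OUTCOMES,
    CELL_FRACTION_COLUMNS,
    SimConfig,
    SyntheticStudy,
    _stream,
    generate_study,
    read_fixtures,
    write_fixtures,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "telomere", "clock", "associate", "enrich", "report")

#: outcome column → model family used in the association stage
OUTCOME_FAMILIES = {
    "zbmi": "linear",
    "height_z": "linear",
    "fat_pct": "linear",
    "raven_score": "linear",
    "dprime": "linear",
    "hrt_se": "linear",
    "cbcl_internalizing": "linear",
    "cbcl_externalizing": "linear",
    "fev1_pct": "linear",
    "puberty_started": "logistic",
}
#: risk-factor columns tested with the marker as the dependent variable
RISK_FACTORS = (
    "birthweight_kg",
    "maternal_smoking",
    "passive_smoke",
    "kidmed_score",
    "physical_activity",
    "fas_ordinal",
    "social_capital_ordinal",
    "maternal_education_ordinal",
)
#: extended-adjustment set for the risk-adjusted sensitivity variant
RISK_ADJUST_COLUMNS = ("fas_ordinal", "social_capital_ordinal", "birthweight_kg", "maternal_smoking", "passive_smoke")

CLOCK_BLOCKS = {
    "immunometabolic": ("proteins", "serum_metab", "urine_metab"),
    "transcriptome": ("transcripts",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    output_dir: str = "results/run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    folds: int = 10
    test_fraction: float = 0.25
    clocks: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(CLOCK_BLOCKS))
    fdr_include_sensitivity: bool = False
    run_sensitivity: bool = True
    gmt_path: str | None = None  # defaults to a simulated collection

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        if not 0.0 < self.test_fraction < 1.0:
            raise PipelineError("test_fraction must be in (0, 1)")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        for key in ("block_sizes", "n_age_features", "delta_age_outcome_effects"):
            if isinstance(getattr(sim, key), dict):
                pass  # yaml already gives plain dicts
        for tup_key in ("age_range", "censor_quantiles"):
            val = getattr(sim, tup_key)
            if isinstance(val, list):
                setattr(sim, tup_key, tuple(val))
        cfg = cls(sim=sim, **{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        cfg.clocks = {k: tuple(v) for k, v in cfg.clocks.items()}
        return cfg


def run_pipeline(config: RunConfig, study: SyntheticStudy | None = None) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "seed": config.seed, "stages": {}}
    state: dict = {"study": study}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        runner = globals()[f"_stage_{stage}"]
        try:
            record = runner(config, state, out)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            raise PipelineError(
                f"stage '{stage}' failed: {exc}. Reproduce with: kidbioage {stage} --seed {config.seed}"
            ) from exc
        record["status"] = "ok"
        manifest["stages"][stage] = record
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _get_study(config: RunConfig, state: dict) -> SyntheticStudy:
    if state.get("study") is None:
        fixture_dir = Path(config.output_dir) / "fixtures"
        if (fixture_dir / "cohort.csv").exists():
            state["study"] = read_fixtures(fixture_dir)
        else:
            state["study"] = generate_study(config.sim)
    return state["study"]


def _stage_simulate(config: RunConfig, state: dict, out: Path) -> dict:
    study = generate_study(config.sim)
    state["study"] = study
    manifest = write_fixtures(study, out / "fixtures")
    return {"n_children": len(study.cohort), "files": sorted(manifest["files"])}


def _stage_preprocess(config: RunConfig, state: dict, out: Path) -> dict:
    study = _get_study(config, state)
    harmonized, reports = {}, {}
    for label, block in study.blocks.items():
        kind = BLOCK_KINDS.get(label, "protein")
        harmonized[label], reports[label] = harmonize_block(block, kind, seed=config.seed)
    state["harmonized"] = harmonized
    qc_path = out / "qc_report.json"
    qc_payload = {
        label: {k: v for k, v in rep.to_dict().items() if k != "parameters"} for label, rep in reports.items()
    }
    qc_path.write_text(json.dumps(qc_payload, indent=1))
    return {
        label: {"n_samples": b.n_samples, "n_features": b.n_features, "dropped": len(reports[label].dropped_features)}
        for label, b in harmonized.items()
    }


def _stage_telomere(config: RunConfig, state: dict, out: Path) -> dict:
    from kidbioage.telomere import relative_ts, results_frame

    study = _get_study(config, state)
    results = relative_ts(study.qpcr_wells)
    frame = results_frame(results)
    frame.to_csv(out / "telomere.csv", float_format="%.10g")
    state["telomere"] = frame
    return {
        "n": len(frame),
        "cohort_mean_relative_ts": float(frame["relative_ts"].mean()),
        "median_cv_ts_pct": float(frame["cv_ts"].median()),
    }


def _train_one_clock(
    config: RunConfig,
    name: str,
    labels: tuple[str, ...],
    harmonized: dict,
    panel_harmonized: dict,
    cohort: pd.DataFrame,
    panel_ids: list[str],
) -> dict:
    # samples present in every block of this clock
    ids = None
    for label in labels:
        blk_ids = set(harmonized[label].values.index)
        ids = blk_ids if ids is None else ids & blk_ids
    ids = sorted(ids)
    rng = _stream(config.seed, f"clock_split_{name}")
    n_test = int(round(config.test_fraction * len(ids)))
    test_ids = sorted(rng.choice(ids, size=n_test, replace=False).tolist())
    train_ids = [i for i in ids if i not in set(test_ids)]

    train_frames, all_frames, panel_frames, scalers = [], [], [], {}
    for label in labels:
        block = harmonized[label]
        train_block = block.subset_samples(train_ids)
        scaled_train, scaler = scale_features(train_block)
        scalers[label] = scaler
        train_frames.append(scaled_train)
        all_frames.append(scaler.transform(block.values.loc[ids]))
        if panel_ids and label in panel_harmonized:
            pvals = panel_harmonized[label].values
            keep = [i for i in panel_ids if i in pvals.index]
            panel_frames.append(scaler.transform(pvals.loc[keep]))

    ages = cohort.loc[train_ids, "age_years"]
    model = tune_and_fit(train_frames, ages, folds=config.folds, seed=config.seed)

    all_scaled = pd.concat(all_frames, axis=1)
    preds_all = predict_ages(model, all_scaled, cohort.loc[ids, "age_years"])
    test_scaled = all_scaled.loc[test_ids]
    val = validate(model, [test_scaled], cohort.loc[test_ids, "age_years"], groups=cohort.loc[test_ids, "centre"])

    progression = None
    if panel_frames:
        panel_scaled = pd.concat(panel_frames, axis=1)
        pids = [i for i in panel_scaled.index if i in preds_all.index]
        panel_preds = predict_ages(
            model, panel_scaled.loc[pids], cohort.loc[pids, "age_years"] + config.sim.panel_gap_years
        )
        progression = progression_test(preds_all.loc[pids], panel_preds)

    return {
        "model": model,
        "predictions": preds_all,
        "validation": val,
        "progression": progression,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }


def _stage_clock(config: RunConfig, state: dict, out: Path) -> dict:
    study = _get_study(config, state)
    if "harmonized" not in state:
        _stage_preprocess(config, state, out)
    panel_harmonized = {}
    for label, block in study.panel_blocks.items():
        kind = BLOCK_KINDS.get(label, "protein")
        panel_harmonized[label], _ = harmonize_block(block, kind, seed=config.seed + 1, apply_filter=False)

    record: dict = {}
    state["clocks"] = {}
    for name, labels in config.clocks.items():
        res = _train_one_clock(
            config, name, labels, state["harmonized"], panel_harmonized, study.cohort, study.panel_ids
        )
        state["clocks"][name] = res
        model: ClockModel = res["model"]
        model.to_json(out / f"clock_{name}.json")
        res["predictions"].to_csv(out / f"predictions_{name}.csv", float_format="%.10g")
        val = res["validation"]
        rec = {
            "alpha": model.alpha,
            "lambda": model.lam,
            "nonzero_predictors": len(model.nonzero_features),
            "block_composition": model.block_composition,
            "test_r": val.pearson_r,
            "test_mae_years": val.mae,
            "test_n": val.n,
        }
        if res["progression"] is not None:
            prog = res["progression"]
            rec["progression"] = {
                "mean_increase_years": prog.mean_increase,
                "t": prog.t,
                "one_sided_p": prog.one_sided_p,
                "n_pairs": prog.n_pairs,
            }
        record[name] = rec
    return record


def analysis_table(study: SyntheticStudy, markers: pd.DataFrame) -> pd.DataFrame:
    """Cohort table joined with markers, ordinal-coded categoricals and
    analysis-scale outcomes."""
    data = study.cohort.join(markers)
    for col, order in (
        ("fas_category", ["low", "medium", "high"]),
        ("social_capital", ["low", "medium", "high"]),
        ("maternal_education", ["primary", "secondary", "university"]),
    ):
        data[col.split("_category")[0] + "_ordinal" if col == "fas_category" else f"{col}_ordinal"] = (
            data[col].map({lv: i for i, lv in enumerate(order)}).astype(float)
        )
    continuous = [o for o, fam in OUTCOME_FAMILIES.items() if fam == "linear"]
    return transform_outcomes(data, continuous=continuous, log_plus_one=CBCL_OUTCOMES)


def base_association_specs(marker_names: list[str]) -> list[AssociationSpec]:
    specs = []
    for marker in marker_names:
        for outcome, family in OUTCOME_FAMILIES.items():
            specs.append(
                AssociationSpec(exposure=marker, outcome=outcome, direction="outcome_as_dependent", family=family)
            )
        for risk in RISK_FACTORS:
            specs.append(
                AssociationSpec(exposure=risk, outcome=marker, direction="marker_as_dependent", family="linear")
            )
    return specs


def _stage_associate(config: RunConfig, state: dict, out: Path) -> dict:
    study = _get_study(config, state)
    if "clocks" not in state:
        _stage_clock(config, state, out)
    if "telomere" not in state:
        _stage_telomere(config, state, out)

    deltas = {name: res["predictions"] for name, res in state["clocks"].items()}
    markers = prepare_markers(
        state["telomere"], deltas, epigenetic=study.cohort["epigenetic_age"], chronological=study.cohort["age_years"]
    )
    data = analysis_table(study, markers)
    state["analysis_data"] = data
    marker_names = list(markers.columns)

    specs = base_association_specs(marker_names)
    results = [run_association(s, data) for s in specs]
    sens = []
    if config.run_sensitivity:
        # sensitivity variants target the marker -> developmental-outcome models
        outcome_specs = [s for s in specs if s.direction == "outcome_as_dependent"]
        sens = sensitivity_suite(
            outcome_specs, data, cell_columns=tuple(CELL_FRACTION_COLUMNS), risk_columns=RISK_ADJUST_COLUMNS
        )
    family = results + sens if config.fdr_include_sensitivity else results
    fdr_adjust(family)
    table = results_table(results + sens)
    table.to_csv(out / "associations.csv", index=False, float_format="%.6g")
    state["associations"] = results
    state["association_table"] = table

    # partial correlations between markers, adjusted for age and centre
    rows = []
    for i, a in enumerate(marker_names):
        for b in marker_names[i + 1 :]:
            sub = data[[a, b, "age_years", "centre"]].dropna()
            r, p = partial_correlation(sub[a], sub[b], sub[["age_years", "centre"]])
            rows.append({"marker_a": a, "marker_b": b, "partial_r": r, "p": p, "n": len(sub)})
    pc = pd.DataFrame(rows)
    pc.to_csv(out / "marker_partial_correlations.csv", index=False, float_format="%.6g")

    n_sig = int(sum(1 for r in results if r.q is not None and r.q < 0.05))
    return {
        "n_primary": len(results),
        "n_sensitivity": len(sens),
        "fdr_family_size": len(family),
        "n_fdr_significant": n_sig,
        "markers": marker_names,
    }


def simulate_gene_sets(
    study: SyntheticStudy, seed: int, n_sets: int = 20, set_size: int = 30
) -> tuple[list[GeneSet], dict[str, str], list[str]]:
    """A synthetic gene-set collection over the transcript block.

    Transcript features are mapped 1:1 to synthetic gene symbols. One set
    is deliberately loaded with true age-associated genes; the rest are
    random draws from the universe, so ORA should flag the loaded set.
    """
    rng = _stream(seed, "gene_sets")
    features = list(study.blocks["transcripts"].values.columns)
    gene_of = {f: f"GENE{j:04d}" for j, f in enumerate(features)}
    universe = sorted(gene_of.values())
    true_genes = [gene_of[f] for f in study.ground_truth.true_age_coefficients.get("transcripts", {}) if f in gene_of]
    sets = []
    n_loaded = min(int(0.8 * set_size), len(true_genes))
    loaded = list(rng.choice(true_genes, size=n_loaded, replace=False)) + list(
        rng.choice(universe, size=set_size - n_loaded, replace=False)
    )
    sets.append(GeneSet(name="AGE_REGULATED_SYNTHETIC", genes=frozenset(loaded), source="synthetic"))
    for i in range(n_sets - 1):
        members = rng.choice(universe, size=set_size, replace=False)
        sets.append(GeneSet(name=f"RANDOM_SET_{i:02d}", genes=frozenset(members), source="synthetic"))
    return sets, gene_of, universe


def _stage_enrich(config: RunConfig, state: dict, out: Path) -> dict:
    study = _get_study(config, state)
    if "clocks" not in state:
        _stage_clock(config, state, out)
    if "transcriptome" not in state["clocks"]:
        return {"note": "no transcriptome clock configured; enrichment skipped"}
    model: ClockModel = state["clocks"]["transcriptome"]["model"]
    if config.gmt_path is not None:
        collection = read_gmt(config.gmt_path)
        gene_of = {f: f for f in model.feature_names}
        universe = [gene_of[f] for f in model.feature_names]
    else:
        collection, gene_of, universe = simulate_gene_sets(study, config.seed)
        universe = [gene_of[f] for f in model.feature_names if f in gene_of]
    query = [gene_of[f] for f in model.nonzero_features if f in gene_of]
    results = ora_collection(query, collection, universe)
    table = ora_table(results)
    table.to_csv(out / "enrichment.csv", index=False, float_format="%.6g")
    state["enrichment"] = results
    top = results[0]
    return {
        "n_sets": len(results),
        "n_significant": int(sum(1 for r in results if r.significant)),
        "top_set": {"name": top.set_name, "k": top.k, "p": top.p, "q": top.q},
    }


def _stage_report(config: RunConfig, state: dict, out: Path) -> dict:
    """Marker × outcome summary grid (estimate, CI, p, q)."""
    if "association_table" not in state:
        return {"note": "associations not run; nothing to report"}
    table = state["association_table"]
    primary = table[(table["variant"] == "primary") & (table["direction"] == "outcome_as_dependent")].copy()
    primary["cell"] = primary.apply(
        lambda r: f"{r['estimate']:.3f} ({r['ci_low']:.3f}, {r['ci_high']:.3f}) p={r['p']:.2g} q={r['q']:.2g}", axis=1
    )
    grid = primary.pivot(index="outcome", columns="exposure", values="cell")
    grid.to_csv(out / "summary_grid.csv")
    return {"outcomes": len(grid), "markers": grid.shape[1]}
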