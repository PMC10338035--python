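"""Synthetic pediatric multi-omic cohort with recorded ground truth.

The generator emulates the structure of a multi-centre child exposome
cohort: ~1000 children aged 5–12 across six study centres, four omic
blocks (plasma proteins, serum metabolites, urinary metabolites and blood
transcripts) carrying a sparse linear age signal, plate batch effects,
below/above-LOQ censoring and urinary dilution; a qPCR well table for
telomere length; developmental outcomes with configurable dependence on a
per-child latent Δ age; and a "panel" subset re-measured ~0.5 years later.

Every random draw comes from a named stream split from the master seed, so
adding a component never perturbs the draws of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from kidbioage.preprocess import (
    ABOVE_LOQ2,
    BELOW_LOQ1,
    IN_RANGE,
    OmicsBlock,
    read_block_tsv,
    write_block_tsv,
)


class ConfigError(ValueError):
    """Raised when a :class:`SimConfig` field is invalid."""


DEFAULT_BLOCK_SIZES = {"proteins": 36, "serum_metab": 177, "urine_metab": 44, "transcripts": 500}
DEFAULT_N_AGE_FEATURES = {"proteins": 12, "serum_metab": 40, "urine_metab": 10, "transcripts": 100}
BLOCK_KINDS = {
    "proteins": "protein",
    "serum_metab": "serum_metabolite",
    "urine_metab": "urine_metabolite",
    "transcripts": "transcript",
}
#: outcome → SD of outcome per year of Δ age (log-odds per year for puberty)
DEFAULT_DELTA_EFFECTS = {
    "zbmi": 0.3,
    "height_z": 0.15,
    "fat_pct": 0.25,
    "raven_score": 0.0,
    "dprime": 0.1,
    "hrt_se": -0.1,
    "cbcl_internalizing": 0.0,
    "cbcl_externalizing": 0.1,
    "fev1_pct": 0.0,
    "puberty_started": 0.4,
}
CENTRES = ["centre_1", "centre_2", "centre_3", "centre_4", "centre_5", "centre_6"]
ETHNICITIES = ["white_european", "asian_pakistani", "other"]
CBCL_OUTCOMES = ("cbcl_internalizing", "cbcl_externalizing")
CELL_FRACTION_COLUMNS = ["cf_cd4t", "cf_cd8t", "cf_mono", "cf_bcell", "cf_nk", "cf_neut", "cf_eos"]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults reproduce the reference study conditions: n≈1000 children,
    ages uniform on 5–12 years across 6 centres, block sizes matching the
    post-QC assay panels (36 proteins, 177 serum metabolites, 44 urinary
    metabolites; transcripts scaled to 500 features), ~15% of children
    re-measured 0.5 years later.
    """

    n_children: int = 1000
    age_range: tuple[float, float] = (5.0, 12.0)
    n_centres: int = 6
    block_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BLOCK_SIZES))
    n_age_features: dict[str, int] | None = None  # default: ~30% of each block
    age_effect_scale: float = 0.3  # per-feature slope magnitude, log2-units / year
    noise_sd: float = 1.0
    delta_age_sd: float = 0.8  # SD of the latent per-child Δ age, years
    plate_count: int = 12
    plate_effect_sd: float = 0.25
    censor_quantiles: tuple[float, float] = (0.05, 0.98)
    urine_dilution_log_sd: float = 0.4
    panel_fraction: float = 0.15
    panel_gap_years: float = 0.5
    delta_age_outcome_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DELTA_EFFECTS))
    covariate_missing_rate: float = 0.02
    qpcr_replicates: int = 3
    qpcr_cq_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_age_features is None:
            if self.block_sizes == DEFAULT_BLOCK_SIZES:
                self.n_age_features = dict(DEFAULT_N_AGE_FEATURES)
            else:
                self.n_age_features = {b: max(1, int(round(0.3 * s))) for b, s in self.block_sizes.items()}

    def validate(self) -> None:
        if self.n_children <= 0:
            raise ConfigError("n_children must be > 0")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range lower bound must be below the upper bound")
        if self.n_centres <= 0 or self.n_centres > len(CENTRES):
            raise ConfigError(f"n_centres must be in 1..{len(CENTRES)}")
        if self.plate_count <= 0:
            raise ConfigError("plate_count must be > 0")
        for name, p in (
            ("panel_fraction", self.panel_fraction),
            ("covariate_missing_rate", self.covariate_missing_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        lo, hi = self.censor_quantiles
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0 and lo < hi):
            raise ConfigError("censor_quantiles must be probabilities with lower < upper")
        for label, size in self.block_sizes.items():
            if size <= 0:
                raise ConfigError(f"block_sizes[{label!r}] must be > 0")
            n_sig = self.n_age_features.get(label, 0)
            if n_sig < 0 or n_sig > size:
                raise ConfigError(f"n_age_features[{label!r}] must be in 0..block_sizes[{label!r}]")


@dataclass
class GroundTruth:
    """What the simulator planted, for recovery checks downstream."""

    true_age_coefficients: dict[str, dict[str, float]]  # block → feature → slope
    true_delta_age: pd.Series  # per child, years
    true_outcome_effects: dict[str, float]
    plate_assignments: dict[str, dict[str, str]]  # block → sample → plate
    dilution_factors: pd.Series  # urinary samples
    true_ts: pd.Series  # per-child telomere/single-copy ratio

    def to_dict(self) -> dict:
        return {
            "true_age_coefficients": self.true_age_coefficients,
            "true_delta_age": {str(k): float(v) for k, v in self.true_delta_age.items()},
            "true_outcome_effects": self.true_outcome_effects,
            "plate_assignments": self.plate_assignments,
            "dilution_factors": {str(k): float(v) for k, v in self.dilution_factors.items()},
            "true_ts": {str(k): float(v) for k, v in self.true_ts.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_age_coefficients=d["true_age_coefficients"],
            true_delta_age=pd.Series(d["true_delta_age"], name="true_delta_age"),
            true_outcome_effects=d["true_outcome_effects"],
            plate_assignments=d["plate_assignments"],
            dilution_factors=pd.Series(d["dilution_factors"], name="dilution_factor"),
            true_ts=pd.Series(d["true_ts"], name="true_ts"),
        )


@dataclass
class SyntheticStudy:
    cohort: pd.DataFrame  # indexed by child id; covariates + outcomes
    blocks: dict[str, OmicsBlock]
    qpcr_wells: pd.DataFrame
    panel_blocks: dict[str, OmicsBlock]  # follow-up visit, panel subset only
    panel_ids: list[str]
    ground_truth: GroundTruth


def _stream(seed: int, name: str) -> np.random.Generator:
    """A named RNG stream: independent of other streams and of call order."""
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(name.encode()))))


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Simulate a full study per ``config``; deterministic given ``config.seed``."""
    config.validate()
    ids = [f"child_{i:04d}" for i in range(config.n_children)]

    rng_age = _stream(config.seed, "ages")
    ages = pd.Series(
        rng_age.uniform(config.age_range[0], config.age_range[1], config.n_children), index=ids, name="age_years"
    )
    true_delta = pd.Series(
        _stream(config.seed, "delta_age").normal(0.0, config.delta_age_sd, config.n_children),
        index=ids,
        name="true_delta_age",
    )
    bio_age = ages + true_delta

    cohort = _simulate_covariates(config, ids, ages)
    _simulate_outcomes(config, cohort, true_delta)

    # latent epigenetic age: accepted downstream as a precomputed column
    rng_dnam = _stream(config.seed, "dnam_age")
    cohort["epigenetic_age"] = (
        ages + 0.85 * true_delta + rng_dnam.normal(0.0, 0.8, config.n_children)
    ).round(6)

    blocks: dict[str, OmicsBlock] = {}
    coefs: dict[str, dict[str, float]] = {}
    plate_assignments: dict[str, dict[str, str]] = {}
    dilution = pd.Series(1.0, index=ids, name="dilution_factor")
    for label in sorted(config.block_sizes):
        block, block_coefs, plates, dil = _simulate_block(config, label, ids, bio_age)
        blocks[label] = block
        coefs[label] = block_coefs
        if plates is not None:
            plate_assignments[label] = {s: str(p) for s, p in plates.items()}
        if dil is not None:
            dilution = dil

    rng_panel = _stream(config.seed, "panel")
    n_panel = int(round(config.panel_fraction * config.n_children))
    panel_ids = sorted(rng_panel.choice(ids, size=n_panel, replace=False).tolist())
    panel_blocks: dict[str, OmicsBlock] = {}
    if panel_ids:
        panel_bio_age = bio_age.loc[panel_ids] + config.panel_gap_years
        for label in sorted(config.block_sizes):
            block, _, _, _ = _simulate_block(
                config, label, panel_ids, panel_bio_age, stream_suffix="_panel", coefs=coefs[label]
            )
            panel_blocks[label] = block

    true_ts, qpcr = _simulate_qpcr(config, ids, ages)

    truth = GroundTruth(
        true_age_coefficients=coefs,
        true_delta_age=true_delta,
        true_outcome_effects=dict(config.delta_age_outcome_effects),
        plate_assignments=plate_assignments,
        dilution_factors=dilution,
        true_ts=true_ts,
    )
    return SyntheticStudy(
        cohort=cohort, blocks=blocks, qpcr_wells=qpcr, panel_blocks=panel_blocks, panel_ids=panel_ids, ground_truth=truth
    )


def _simulate_covariates(config: SimConfig, ids: list[str], ages: pd.Series) -> pd.DataFrame:
    n = len(ids)
    rng = _stream(config.seed, "covariates")
    cohort = pd.DataFrame(index=pd.Index(ids, name="child_id"))
    cohort["age_years"] = ages.round(6)
    cohort["sex"] = np.where(rng.random(n) < 0.55, "male", "female")
    cohort["ethnicity"] = rng.choice(ETHNICITIES, size=n, p=[0.89, 0.06, 0.05])
    cohort["centre"] = rng.choice(CENTRES[: config.n_centres], size=n)
    cohort["maternal_education"] = rng.choice(["primary", "secondary", "university"], size=n, p=[0.14, 0.35, 0.51])
    cohort["birthweight_kg"] = rng.normal(3.4, 0.5, n).round(6)
    cohort["maternal_smoking"] = (rng.random(n) < 0.15).astype(int)
    cohort["passive_smoke"] = (rng.random(n) < 0.30).astype(int)
    cohort["physical_activity"] = np.clip(rng.normal(50, 20, n), 0, None).round(2)
    cohort["kidmed_score"] = rng.integers(-4, 12, n)
    cohort["fas_category"] = rng.choice(["low", "medium", "high"], size=n, p=[0.2, 0.45, 0.35])
    cohort["social_capital"] = rng.choice(["low", "medium", "high"], size=n)
    fractions = rng.dirichlet([8, 4, 2, 2, 2, 20, 1], size=n)
    for j, col in enumerate(CELL_FRACTION_COLUMNS):
        cohort[col] = fractions[:, j].round(6)
    # MCAR missingness, only on questionnaire-style covariates
    mcar_cols = ["kidmed_score", "fas_category", "social_capital", "physical_activity", "birthweight_kg"]
    for col in mcar_cols:
        mask = rng.random(n) < config.covariate_missing_rate
        cohort.loc[mask, col] = np.nan
    return cohort


def _simulate_outcomes(config: SimConfig, cohort: pd.DataFrame, true_delta: pd.Series) -> None:
    """Outcomes = linear predictor in covariates + Δ-age effect + unit noise."""
    rng = _stream(config.seed, "outcomes")
    n = len(cohort)
    female = (cohort["sex"] == "female").astype(float).to_numpy()
    age_c = (cohort["age_years"] - cohort["age_years"].mean()).to_numpy()
    eff = config.delta_age_outcome_effects
    delta = true_delta.to_numpy()

    def lin(outcome: str, covariate_part: np.ndarray) -> np.ndarray:
        return covariate_part + eff.get(outcome, 0.0) * delta + rng.normal(0.0, 1.0, n)

    cohort["zbmi"] = lin("zbmi", 0.1 * female).round(6)
    cohort["height_z"] = lin("height_z", 0.05 * female).round(6)
    cohort["fat_pct"] = (22 + 4 * lin("fat_pct", 0.4 * female)).round(4)
    cohort["raven_score"] = np.clip(np.round(18 + 4 * lin("raven_score", 0.8 * age_c / 2)), 0, 36).astype(int)
    cohort["dprime"] = lin("dprime", 0.3 * age_c / 2).round(6)
    cohort["hrt_se"] = (300 + 90 * lin("hrt_se", -0.3 * age_c / 2)).round(4)
    for cbcl in CBCL_OUTCOMES:
        latent = 1.5 + 0.6 * lin(cbcl, 0.0)
        cohort[cbcl] = np.clip(np.round(np.exp(latent) - 1), 0, 70).astype(int)
    cohort["fev1_pct"] = (98 + 10 * lin("fev1_pct", 0.0)).round(4)
    logits = -1.5 + 0.9 * age_c + 1.0 * female + eff.get("puberty_started", 0.0) * delta
    cohort["puberty_started"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)


def _simulate_block(
    config: SimConfig,
    label: str,
    ids: list[str],
    bio_age: pd.Series,
    stream_suffix: str = "",
    coefs: dict[str, float] | None = None,
):
    """One omic block: baseline + slope·bio_age + plate effect + noise, then
    block-kind-specific dilution, censoring and metadata."""
    kind = BLOCK_KINDS.get(label, "protein")
    p = config.block_sizes[label]
    n_sig = config.n_age_features.get(label, 0)
    n = len(ids)
    features = [f"{label}_f{j:04d}" for j in range(p)]
    rng_struct = _stream(config.seed, f"block_structure_{label}")  # shared between visits
    rng = _stream(config.seed, f"block_{label}{stream_suffix}")

    baselines = rng_struct.normal(8.0, 1.5, p)
    if coefs is None:
        signal_idx = rng_struct.choice(p, size=n_sig, replace=False)
        slopes = np.zeros(p)
        signs = rng_struct.choice([-1.0, 1.0], size=n_sig)
        slopes[signal_idx] = signs * config.age_effect_scale * rng_struct.uniform(0.5, 1.5, n_sig)
        coefs = {features[j]: float(slopes[j]) for j in range(p) if slopes[j] != 0.0}
    slopes = np.array([coefs.get(f, 0.0) for f in features])

    x = baselines[None, :] + np.outer(bio_age.to_numpy(), slopes) + rng.normal(0.0, config.noise_sd, (n, p))

    plates: pd.Series | None = None
    if kind in ("protein", "serum_metabolite", "transcript"):
        plates = pd.Series(
            [f"plate_{k:02d}" for k in rng.integers(0, config.plate_count, n)], index=ids, name="plate"
        )
        plate_offsets = rng.normal(0.0, config.plate_effect_sd, (config.plate_count, p))
        plate_idx = plates.str.slice(-2).astype(int).to_numpy()
        x = x + plate_offsets[plate_idx]

    values = pd.DataFrame(x, index=pd.Index(ids, name="sample_id"), columns=features)
    meta = pd.DataFrame(index=pd.Index(features, name="feature_id"))
    meta["block"] = label
    meta["cv_percent"] = rng.uniform(3.0, 25.0, p).round(3)
    meta["call_rate"] = 1.0
    meta["lod"] = np.nan
    meta["loq1"] = np.nan
    meta["loq2"] = np.nan

    censored = None
    dilution = None
    if kind == "protein":
        lo_q, hi_q = config.censor_quantiles
        loq1 = values.quantile(lo_q, axis=0)
        loq2 = values.quantile(hi_q, axis=0)
        meta["loq1"] = loq1.round(6)
        meta["loq2"] = loq2.round(6)
        meta["lod"] = (loq1 - 0.5).round(6)
        censored = pd.DataFrame(IN_RANGE, index=values.index, columns=features, dtype=int)
        censored[values.lt(loq1, axis=1)] = BELOW_LOQ1
        censored[values.gt(loq2, axis=1)] = ABOVE_LOQ2
        values = values.mask(censored != IN_RANGE)
    elif kind == "serum_metabolite":
        # a small fraction of poor assays: CV > 30% and LOD cutting into the data
        poor = rng.random(p) < 0.05
        meta.loc[poor, "cv_percent"] = rng.uniform(31.0, 60.0, int(poor.sum())).round(3)
        lod_q = np.where(poor, rng.uniform(0.32, 0.5, p), rng.uniform(0.0, 0.05, p))
        meta["lod"] = np.array([values.iloc[:, j].quantile(lod_q[j]) for j in range(p)]).round(6)
        values = np.exp2(values * 0.25)  # stored as raw positive concentrations
        meta["lod"] = np.exp2(meta["lod"] * 0.25).round(6)
    elif kind == "urine_metabolite":
        rng_dil = _stream(config.seed, f"dilution_{label}{stream_suffix}")
        dilution = pd.Series(
            np.exp(rng_dil.normal(0.0, config.urine_dilution_log_sd, n)), index=ids, name="dilution_factor"
        )
        concentrations = np.exp2(values * 0.5)  # raw positive scale
        values = concentrations.mul(dilution, axis=0)
    elif kind == "transcript":
        call = np.where(rng.random(p) < 0.03, rng.uniform(0.0, 0.009, p), rng.uniform(0.6, 1.0, p))
        meta["call_rate"] = call.round(4)
        sample_call = np.where(rng.random(n) < 0.01, rng.uniform(0.1, 0.39, n), rng.uniform(0.8, 1.0, n))
        sample_meta = pd.DataFrame({"call_rate": sample_call.round(4)}, index=values.index)
        block = OmicsBlock(values=values, feature_meta=meta, sample_plates=plates, sample_meta=sample_meta)
        return block, coefs, plates, dilution

    block = OmicsBlock(values=values, feature_meta=meta, censored=censored, sample_plates=plates)
    return block, coefs, plates, dilution


def _simulate_qpcr(config: SimConfig, ids: list[str], ages: pd.Series):
    """Triplicate telomere (T) and single-copy (S) wells with per-run
    calibrators, 6-point dilution standards and a run-level Cq shift."""
    rng = _stream(config.seed, "qpcr")
    n = len(ids)
    eff = {"T": 0.95, "S": 0.92}
    # weak negative age trend, matching the weak telomere–age correlation
    log_ts = -0.01 * (ages.to_numpy() - 8.0) + rng.normal(0.0, 0.15, n)
    true_ts = pd.Series(np.exp(log_ts), index=ids, name="true_ts")
    dna_input = np.exp(rng.normal(0.0, 0.2, n))  # single-copy quantity per child

    run_size = 84
    rows = []
    order = rng.permutation(n)
    n_runs = int(np.ceil(n / run_size))
    run_shift = rng.normal(0.0, 0.5, n_runs)
    base_cq = {"T": 20.0, "S": 24.0}
    reps = config.qpcr_replicates
    for r in range(n_runs):
        run_id = f"run_{r:02d}"
        members = order[r * run_size : (r + 1) * run_size]
        for target in ("T", "S"):
            slope = -1.0 / np.log10(1.0 + eff[target])
            # calibrator quantity defined as 1 on both targets
            for c in range(8):
                for k in range(reps):
                    cq = base_cq[target] + run_shift[r] + rng.normal(0.0, config.qpcr_cq_noise_sd)
                    rows.append((f"cal_{c}", target, run_id, k, cq, "inter_run_calibrator", np.nan))
            for d in range(6):
                q = 10.0 ** (-0.5 * d)
                for k in range(reps):
                    cq = base_cq[target] + run_shift[r] - slope * (-np.log10(q)) + rng.normal(
                        0.0, config.qpcr_cq_noise_sd
                    )
                    rows.append((f"std_{d}", target, run_id, k, cq, "dilution_standard", q))
            for i in members:
                quantity = true_ts.iloc[i] * dna_input[i] if target == "T" else dna_input[i]
                cq_mean = base_cq[target] + run_shift[r] - np.log(quantity) / np.log(1.0 + eff[target])
                for k in range(reps):
                    rows.append(
                        (ids[i], target, run_id, k, cq_mean + rng.normal(0.0, config.qpcr_cq_noise_sd), "sample", np.nan)
                    )
    wells = pd.DataFrame(
        rows, columns=["sample_id", "target", "run_id", "replicate_index", "cq", "role", "input_quantity"]
    )
    wells["cq"] = wells["cq"].round(6)
    return true_ts, wells


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixtures(study: SyntheticStudy, directory: str | Path) -> dict:
    """Write the study as plain-text fixtures; returns a file manifest.

    Layout: ``cohort.csv``, ``block_<label>.tsv`` + ``features_<label>.tsv``
    per block, ``block_<label>_panel.tsv`` for the follow-up visit,
    ``qpcr.csv`` and ``truth.json``. Round-trips losslessly through
    :func:`read_fixtures`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "panel_ids": study.panel_ids}

    cohort_path = directory / "cohort.csv"
    study.cohort.to_csv(cohort_path, float_format="%.17g")
    manifest["files"]["cohort.csv"] = {"rows": len(study.cohort), "columns": study.cohort.shape[1]}

    for label, block in study.blocks.items():
        vpath, mpath = directory / f"block_{label}.tsv", directory / f"features_{label}.tsv"
        write_block_tsv(block, vpath, mpath)
        manifest["files"][vpath.name] = {"rows": block.n_samples, "columns": block.n_features}
        manifest["files"][mpath.name] = {"rows": block.n_features, "columns": len(block.feature_meta.columns)}
    if study.panel_blocks:
        for label, block in study.panel_blocks.items():
            vpath = directory / f"block_{label}_panel.tsv"
            mpath = directory / f"features_{label}_panel.tsv"
            write_block_tsv(block, vpath, mpath)
            manifest["files"][vpath.name] = {"rows": block.n_samples, "columns": block.n_features}
            manifest["files"][mpath.name] = {"rows": block.n_features, "columns": len(block.feature_meta.columns)}
    else:
        manifest["panel"] = "absent (panel_fraction=0)"

    qpcr_path = directory / "qpcr.csv"
    study.qpcr_wells.to_csv(qpcr_path, index=False, float_format="%.17g")
    manifest["files"]["qpcr.csv"] = {"rows": len(study.qpcr_wells), "columns": study.qpcr_wells.shape[1]}

    truth_path = directory / "truth.json"
    try:
        truth_path.write_text(json.dumps(study.ground_truth.to_dict(), indent=1))
    except OSError as exc:
        raise OSError(f"failed writing ground truth to {truth_path}: {exc}") from exc
    manifest["files"]["truth.json"] = {"rows": 1, "columns": 1}

    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_fixtures(directory: str | Path) -> SyntheticStudy:
    """Read a study previously written by :func:`write_fixtures`."""
    directory = Path(directory)
    cohort = pd.read_csv(directory / "cohort.csv", index_col="child_id")
    truth = GroundTruth.from_dict(json.loads((directory / "truth.json").read_text()))
    manifest = json.loads((directory / "manifest.json").read_text())

    def plates_for(label: str, index: pd.Index) -> pd.Series | None:
        assign = truth.plate_assignments.get(label)
        if assign is None:
            return None
        return pd.Series({s: assign[s] for s in index if s in assign}, name="plate").reindex(index)

    blocks: dict[str, OmicsBlock] = {}
    panel_blocks: dict[str, OmicsBlock] = {}
    for vpath in sorted(directory.glob("block_*.tsv")):
        label = vpath.stem.removeprefix("block_")
        is_panel = label.endswith("_panel")
        mpath = directory / f"features_{label}.tsv"
        block = read_block_tsv(vpath, mpath)
        base_label = label.removesuffix("_panel")
        block.sample_plates = None if is_panel else plates_for(base_label, block.values.index)
        if not is_panel and BLOCK_KINDS.get(base_label) == "transcript":
            # sample call rates are re-derivable only from the original study;
            # fixture reads re-attach a complete-call default
            block.sample_meta = pd.DataFrame({"call_rate": 1.0}, index=block.values.index)
        (panel_blocks if is_panel else blocks)[base_label] = block

    qpcr = pd.read_csv(directory / "qpcr.csv")
    return SyntheticStudy(
        cohort=cohort,
        blocks=blocks,
        qpcr_wells=qpcr,
        panel_blocks=panel_blocks,
        panel_ids=list(manifest.get("panel_ids", [])),
        ground_truth=truth,
    )
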