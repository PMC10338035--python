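"""Omics QC filtering, batch correction, censored-value imputation and scaling.

The preprocessing rules are assay-specific:

``protein``
    Keep features with >30% of measurements inside the linear range of
    quantification ``[LOQ1, LOQ2]``; log2; plate-mean correction; values
    outside the linear range imputed from a truncated normal.
``serum_metabolite``
    Drop features with CV% > 30 **and** >30% of values below the LOD
    (both conditions required).
``urine_metabolite``
    Median fold-change (probabilistic-quotient) normalization against a
    reference profile to remove urinary dilution, then a ½-minimum offset
    and log2.
``transcript``
    Drop samples with a detection call rate < 40% and features with a
    call rate < 1%.

Every block is finally mean-centred and scaled to unit sample SD, with the
training scaler stored for re-use on held-out or follow-up data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: censoring codes used in ``OmicsBlock.censored``
BELOW_LOQ1 = -1
IN_RANGE = 0
ABOVE_LOQ2 = 1

FEATURE_META_COLUMNS = ["feature_id", "block", "lod", "loq1", "loq2", "plate", "cv_percent", "call_rate"]


class PreprocessError(ValueError):
    """Raised when a block violates a preprocessing precondition."""


@dataclass
class OmicsBlock:
    """A samples × features matrix with per-feature assay metadata.

    Parameters
    ----------
    values
        Samples × features matrix; index = sample ids, columns = feature ids.
        Censored cells are NaN and carry a nonzero code in ``censored``.
    feature_meta
        Indexed by feature id; columns ``block``, ``lod``, ``loq1``, ``loq2``,
        ``cv_percent``, ``call_rate`` (any may be NaN where not applicable).
    censored
        Optional same-shape integer matrix of censoring codes
        (−1 below LOQ1, 0 in range, +1 above LOQ2).
    sample_plates
        Optional per-sample plate labels (assay batch), aligned to ``values.index``.
    sample_meta
        Optional per-sample table (e.g. ``call_rate`` for transcript arrays).
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    censored: pd.DataFrame | None = None
    sample_plates: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise PreprocessError(f"duplicate sample ids: {dupes[:5]}")
        missing = [f for f in self.values.columns if f not in self.feature_meta.index]
        if missing:
            raise PreprocessError(f"features absent from feature_meta: {missing[:5]}")
        if "loq1" in self.feature_meta and "loq2" in self.feature_meta:
            both = self.feature_meta[["loq1", "loq2"]].dropna()
            bad = both[both["loq1"] > both["loq2"]]
            if len(bad):
                raise PreprocessError(f"LOQ1 > LOQ2 for features: {bad.index.tolist()[:5]}")
        if self.censored is not None and self.censored.shape != self.values.shape:
            raise PreprocessError("censored mask shape does not match values")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "OmicsBlock":
        return OmicsBlock(
            values=self.values.copy(),
            feature_meta=self.feature_meta.copy(),
            censored=None if self.censored is None else self.censored.copy(),
            sample_plates=None if self.sample_plates is None else self.sample_plates.copy(),
            sample_meta=None if self.sample_meta is None else self.sample_meta.copy(),
        )

    def subset_features(self, keep: list) -> "OmicsBlock":
        out = self.copy()
        out.values = out.values[keep]
        out.feature_meta = out.feature_meta.loc[keep]
        if out.censored is not None:
            out.censored = out.censored[keep]
        return out

    def subset_samples(self, keep: list) -> "OmicsBlock":
        out = self.copy()
        out.values = out.values.loc[keep]
        if out.censored is not None:
            out.censored = out.censored.loc[keep]
        if out.sample_plates is not None:
            out.sample_plates = out.sample_plates.loc[keep]
        if out.sample_meta is not None:
            out.sample_meta = out.sample_meta.loc[keep]
        return out


@dataclass
class QCReport:
    """Record of what a preprocessing stage dropped, imputed or estimated."""

    dropped_features: list = field(default_factory=list)  # (feature_id, reason)
    dropped_samples: list = field(default_factory=list)  # (sample_id, reason)
    imputed_cell_count: int = 0
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dropped_features": [list(t) for t in self.dropped_features],
            "dropped_samples": [list(t) for t in self.dropped_samples],
            "imputed_cell_count": int(self.imputed_cell_count),
            "parameters": self.parameters,
        }

    def merged(self, other: "QCReport") -> "QCReport":
        return QCReport(
            dropped_features=self.dropped_features + other.dropped_features,
            dropped_samples=self.dropped_samples + other.dropped_samples,
            imputed_cell_count=self.imputed_cell_count + other.imputed_cell_count,
            parameters={**self.parameters, **other.parameters},
        )


@dataclass
class Scaler:
    """Stored feature means and sample SDs from a training matrix."""

    means: pd.Series
    sds: pd.Series

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.means.index if f not in values.columns]
        if missing:
            raise PreprocessError(f"scaler features absent from input: {missing[:5]}")
        x = values[self.means.index]
        return (x - self.means) / self.sds


def _require_meta(block: OmicsBlock, columns: list[str], rule: str) -> None:
    for col in columns:
        if col not in block.feature_meta.columns or block.feature_meta[col].isna().all():
            raise PreprocessError(f"feature metadata column '{col}' required for the {rule} rule is missing")


def filter_quantifiable(block: OmicsBlock, kind: str) -> tuple[OmicsBlock, QCReport]:
    """Apply the assay-specific quantifiability filter.

    ``protein``: keep features with >30% of measurements inside
    ``[LOQ1, LOQ2]`` (cells censored outside the linear range count against).
    ``serum_metabolite``: drop features with CV% > 30 *and* more than 30% of
    values below the LOD — both conditions are required.
    ``transcript``: drop samples with call rate < 0.40 first, then features
    with call rate < 0.01.
    """
    report = QCReport(parameters={"filter_rule": kind})
    if kind == "protein":
        _require_meta(block, ["loq1", "loq2"], "protein")
        frac_in_range = _fraction_in_linear_range(block)
        keep = frac_in_range > 0.30
        for f in block.values.columns[~keep]:
            report.dropped_features.append((f, "linear_range_le_30pct"))
        out = block.subset_features(list(block.values.columns[keep]))
    elif kind == "serum_metabolite":
        _require_meta(block, ["cv_percent", "lod"], "serum_metabolite")
        below_lod = block.values.lt(block.feature_meta["lod"], axis=1).mean(axis=0)
        cv = block.feature_meta.loc[block.values.columns, "cv_percent"]
        drop = (cv > 30.0) & (below_lod > 0.30)
        for f in block.values.columns[drop.values]:
            report.dropped_features.append((f, "cv_gt_30_and_below_lod_gt_30pct"))
        out = block.subset_features(list(block.values.columns[~drop.values]))
    elif kind == "transcript":
        _require_meta(block, ["call_rate"], "transcript")
        # sample filter applied before the feature filter
        out = block
        if block.sample_meta is not None and "call_rate" in block.sample_meta.columns:
            sample_cr = block.sample_meta["call_rate"]
            bad = sample_cr < 0.40
            for s in sample_cr.index[bad]:
                report.dropped_samples.append((s, "sample_call_rate_lt_40pct"))
            out = block.subset_samples(list(sample_cr.index[~bad]))
        feat_cr = out.feature_meta.loc[out.values.columns, "call_rate"]
        drop = feat_cr < 0.01
        for f in out.values.columns[drop.values]:
            report.dropped_features.append((f, "feature_call_rate_lt_1pct"))
        out = out.subset_features(list(out.values.columns[~drop.values]))
    elif kind == "urine_metabolite":
        out = block  # no exclusion rule for the NMR urinary panel
    else:
        raise PreprocessError(f"unknown filter kind: {kind!r}")
    return out, report


def _fraction_in_linear_range(block: OmicsBlock) -> pd.Series:
    loq1 = block.feature_meta.loc[block.values.columns, "loq1"]
    loq2 = block.feature_meta.loc[block.values.columns, "loq2"]
    in_range = block.values.ge(loq1, axis=1) & block.values.le(loq2, axis=1)
    if block.censored is not None:
        in_range &= block.censored.eq(IN_RANGE)
    return in_range.mean(axis=0)


def log2_block(block: OmicsBlock) -> OmicsBlock:
    """log2-transform values and any LOD/LOQ bounds (assumed on the raw scale)."""
    out = block.copy()
    if (out.values <= 0).any().any():
        bad = out.values.columns[(out.values <= 0).any(axis=0)].tolist()
        raise PreprocessError(f"non-positive values cannot be log2-transformed (features {bad[:5]})")
    out.values = np.log2(out.values)
    for col in ("lod", "loq1", "loq2"):
        if col in out.feature_meta.columns:
            with np.errstate(divide="ignore", invalid="ignore"):
                out.feature_meta[col] = np.log2(out.feature_meta[col])
    return out


def plate_center(block: OmicsBlock) -> OmicsBlock:
    """Remove plate batch effects by mean-shifting each plate to the grand mean.

    For each feature *f* and plate *p*: ``x' = x − (mean_{p,f} − grand_mean_f)``.
    Censored (NaN) cells are ignored when computing the means. A feature
    entirely missing on a plate leaves that plate untouched for that feature.
    The operation is idempotent and preserves each feature's grand mean.
    """
    if block.sample_plates is None:
        raise PreprocessError("plate labels are required for plate correction")
    out = block.copy()
    plates = out.sample_plates.reindex(out.values.index)
    grand = out.values.mean(axis=0)
    for plate, idx in out.values.groupby(plates, observed=True).groups.items():
        plate_mean = out.values.loc[idx].mean(axis=0)
        shift = (plate_mean - grand).fillna(0.0)  # feature absent on plate: untouched
        if plate_mean.isna().any():
            logger.warning("plate %s has features with no observed values; left uncorrected", plate)
        out.values.loc[idx] = out.values.loc[idx] - shift
    return out


def impute_truncated(block: OmicsBlock, seed: int) -> tuple[OmicsBlock, QCReport]:
    """Impute out-of-range cells from a truncated normal distribution.

    Per feature, μ and σ are estimated (sample SD) from the in-range values;
    below-LOQ1 cells are drawn from N(μ, σ) truncated to (−∞, LOQ1] and
    above-LOQ2 cells from the [LOQ2, ∞) truncation. Deterministic given
    ``seed``. Features with fewer than 3 in-range values are dropped.
    """
    if block.censored is None:
        raise PreprocessError("censoring flags are required for truncated-normal imputation")
    rng = np.random.default_rng(seed)
    out = block.copy()
    report = QCReport(parameters={"imputation": "truncated_normal", "seed": seed})
    drop: list = []
    for f in out.values.columns:
        codes = out.censored[f].to_numpy()
        vals = out.values[f].to_numpy(copy=True)
        in_range = codes == IN_RANGE
        if in_range.sum() < 3:
            drop.append(f)
            report.dropped_features.append((f, "lt_3_in_range_values"))
            continue
        mu = float(np.mean(vals[in_range]))
        sigma = float(np.std(vals[in_range], ddof=1))
        sigma = max(sigma, 1e-12)
        loq1 = float(out.feature_meta.at[f, "loq1"])
        loq2 = float(out.feature_meta.at[f, "loq2"])
        lo = codes == BELOW_LOQ1
        hi = codes == ABOVE_LOQ2
        if lo.any():
            b = (loq1 - mu) / sigma
            vals[lo] = stats.truncnorm.rvs(-np.inf, b, loc=mu, scale=sigma, size=int(lo.sum()), random_state=rng)
            report.imputed_cell_count += int(lo.sum())
        if hi.any():
            a = (loq2 - mu) / sigma
            vals[hi] = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=int(hi.sum()), random_state=rng)
            report.imputed_cell_count += int(hi.sum())
        out.values[f] = vals
    if drop:
        out = out.subset_features([f for f in out.values.columns if f not in set(drop)])
    return out, report


def median_fold_change_normalize(
    block: OmicsBlock, reference: pd.Series | None = None
) -> tuple[OmicsBlock, pd.Series]:
    """Median fold-change (probabilistic-quotient) normalization of a urinary block.

    The dilution factor of sample *s* is the median over features of
    ``x_{s,f} / ref_f`` where ``ref`` defaults to the feature-wise median
    profile. Each sample is divided by its factor; an offset of ½ the
    minimal (positive) value of the normalized block is added and values
    are expressed as log2. Returns the normalized block and the per-sample
    dilution factors.
    """
    x = block.values
    if reference is None:
        reference = x.median(axis=0)
    reference = reference.reindex(x.columns)
    if (reference <= 0).any() or reference.isna().any():
        bad = reference.index[(reference <= 0) | reference.isna()].tolist()
        raise PreprocessError(f"non-positive reference entries for features: {bad[:5]}")
    all_zero = (x <= 0).all(axis=1)
    if all_zero.any():
        raise PreprocessError(f"all-zero sample(s): {x.index[all_zero].tolist()[:5]}")
    factors = x.div(reference, axis=1).median(axis=1)
    factors.name = "dilution_factor"
    out = block.copy()
    normalized = x.div(factors, axis=0)
    positive_min = normalized[normalized > 0].min().min()
    offset = 0.5 * float(positive_min)
    out.values = np.log2(normalized + offset)
    return out, factors


def scale_features(block: OmicsBlock) -> tuple[OmicsBlock, Scaler]:
    """Mean-centre and scale every feature to unit sample SD (ddof=1).

    Zero-variance features are dropped. The returned :class:`Scaler` must be
    applied — never re-estimated — on test or follow-up data.
    """
    if block.values.isna().any().any():
        raise PreprocessError("censored/missing cells must be imputed before scaling")
    means = block.values.mean(axis=0)
    sds = block.values.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = [(f, "zero_variance") for f in block.values.columns[~keep]]
    if dropped:
        logger.info("dropping %d zero-variance features", len(dropped))
    out = block.subset_features(list(block.values.columns[keep]))
    scaler = Scaler(means=means[keep], sds=sds[keep])
    out.values = scaler.transform(out.values)
    return out, scaler


def harmonize_block(
    block: OmicsBlock, kind: str, seed: int = 0, apply_filter: bool = True
) -> tuple[OmicsBlock, QCReport]:
    """Assay-specific pipeline up to (but not including) scaling.

    Order: quantifiability filter; then per kind — protein (stored log2):
    plate correction, truncated-normal imputation; urine: median fold-change
    normalization (raw scale) with ½-min offset and log2; serum: log2.
    ``apply_filter=False`` skips the filter (e.g. follow-up data restricted
    afterwards to training features).
    """
    if apply_filter:
        block, report = filter_quantifiable(block, kind)
    else:
        report = QCReport(parameters={"filter_rule": "skipped"})
    if kind == "protein":
        if block.sample_plates is not None:
            block = plate_center(block)
        if block.censored is not None and (block.censored != IN_RANGE).any().any():
            block, rep2 = impute_truncated(block, seed=seed)
            report = report.merged(rep2)
    elif kind == "urine_metabolite":
        block, factors = median_fold_change_normalize(block)
        report.parameters["dilution_factors"] = {str(k): float(v) for k, v in factors.items()}
    elif kind == "serum_metabolite":
        block = log2_block(block)
    elif kind == "transcript":
        pass  # expression values already log2
    return block, report


def preprocess_block(block: OmicsBlock, kind: str, seed: int = 0) -> tuple[OmicsBlock, Scaler, QCReport]:
    """Full assay-specific pipeline: filter → transform → mean/SD scale."""
    block, report = harmonize_block(block, kind, seed=seed)
    scaled, scaler = scale_features(block)
    return scaled, scaler, report


# ---------------------------------------------------------------------------
# I/O: TSV matrices (first column = sample id) and feature-metadata TSV


def write_block_tsv(block: OmicsBlock, values_path: str | Path, meta_path: str | Path) -> None:
    vals = block.values.copy().astype(object)
    if block.censored is not None:
        loq1 = block.feature_meta["loq1"]
        loq2 = block.feature_meta["loq2"]
        for f in vals.columns:
            lo = block.censored[f] == BELOW_LOQ1
            hi = block.censored[f] == ABOVE_LOQ2
            vals.loc[lo, f] = f"<LOQ1:{loq1[f]!r}"
            vals.loc[hi, f] = f">LOQ2:{loq2[f]!r}"
    vals.index.name = "sample_id"
    vals.to_csv(values_path, sep="\t", float_format="%.17g")
    meta = block.feature_meta.copy()
    meta.index.name = "feature_id"
    for col in FEATURE_META_COLUMNS[1:]:
        if col not in meta.columns:
            meta[col] = np.nan
    meta[FEATURE_META_COLUMNS[1:]].to_csv(meta_path, sep="\t", float_format="%.17g")


def read_block_tsv(
    values_path: str | Path,
    meta_path: str | Path,
    sample_plates: pd.Series | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> OmicsBlock:
    raw = pd.read_csv(values_path, sep="\t", index_col="sample_id", dtype=object)
    meta = pd.read_csv(meta_path, sep="\t", index_col="feature_id")
    censored = pd.DataFrame(IN_RANGE, index=raw.index, columns=raw.columns, dtype=int)
    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    any_censored = False
    for f in raw.columns:
        col = raw[f]
        lo = col.str.startswith("<LOQ1", na=False)
        hi = col.str.startswith(">LOQ2", na=False)
        ok = ~(lo | hi)
        values.loc[ok, f] = col[ok].astype(float)
        censored.loc[lo, f] = BELOW_LOQ1
        censored.loc[hi, f] = ABOVE_LOQ2
        any_censored = any_censored or bool(lo.any() or hi.any())
    return OmicsBlock(
        values=values,
        feature_meta=meta,
        censored=censored if any_censored else None,
        sample_plates=sample_plates,
        sample_meta=sample_meta,
    )
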