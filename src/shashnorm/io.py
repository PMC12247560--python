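"""Cohort file I/O, preprocessing, and model persistence.

Cohorts are delimited text tables, one row per subject, with age (years),
sex (0/1, where 1 codes male; "F"/"M" and "female"/"male" are accepted),
a categorical site label, and one or more real response phenotypes.
Sites are densely re-coded with a persisted mapping.  Responses may be
feature-wise standardised (mean/sd estimated on a declared fit split
only) with an optional preceding log transform; the record of every
transform is stored so it can be inverted and reapplied at prediction
time.

Fitted models are persisted as a directory bundle: a JSON manifest with
the model spec (knots included), the site mapping and standardisation
record, plus the MAP point and/or posterior draws as arrays.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .inference import PosteriorSamples, map_estimate, sample_posterior
from .models import HBRModel, ModelSpec, build_design_matrix

_BUNDLE_VERSION = 1

_SEX_CODES = {
    "0": 0, "1": 1, "f": 0, "m": 1, "female": 0, "male": 1,
    "0.0": 0, "1.0": 1,
}


@dataclasses.dataclass
class CohortTable:
    """Validated cohort with provenance of any standardisation applied."""

    df: pd.DataFrame
    site_mapping: dict
    response_cols: list
    standardisation: Optional[dict] = None

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_sites(self) -> int:
        return len(self.site_mapping)

    @property
    def site_codes(self) -> np.ndarray:
        return self.df["site_code"].to_numpy()

    def decode_site(self, code: int) -> str:
        inv = {v: k for k, v in self.site_mapping.items()}
        return inv[code]


@dataclasses.dataclass
class FoldSpec:
    """Cross-validation assignment after the minimum-count filter.

    ``assignment`` holds the test-fold index per subject, or -1 for rows
    removed because their site-by-sex cell fell below ``min_count``.
    """

    k: int
    assignment: np.ndarray
    min_count: int

    def train_idx(self, fold: int) -> np.ndarray:
        return np.where((self.assignment != fold) & (self.assignment >= 0))[0]

    def test_idx(self, fold: int) -> np.ndarray:
        return np.where(self.assignment == fold)[0]


def read_cohort(path, age_col="age", sex_col="sex", site_col="site",
                response_cols: Optional[Sequence[str]] = None,
                subject_col: Optional[str] = "subject",
                delimiter: str = ",",
                site_mapping: Optional[dict] = None) -> CohortTable:
    """Read and validate a delimited cohort file.

    Missing columns, non-numeric age or responses, and unknown sex codes
    raise descriptive errors.  Site labels are densely coded in sorted
    order (or through a supplied mapping, for held-out data; labels absent
    from it get fresh codes beyond the training range).
    """
    raw = pd.read_csv(path, delimiter=delimiter)
    for col in (age_col, sex_col, site_col):
        if col not in raw.columns:
            raise ValueError(f"cohort file {path} is missing column {col!r}")
    if response_cols is None:
        reserved = {age_col, sex_col, site_col, subject_col}
        response_cols = [c for c in raw.columns if c not in reserved]
    if not response_cols:
        raise ValueError("no response columns found")

    df = pd.DataFrame()
    df["subject"] = (
        raw[subject_col].astype(str)
        if subject_col and subject_col in raw.columns
        else [f"sub-{i:05d}" for i in range(len(raw))]
    )
    age = pd.to_numeric(raw[age_col], errors="coerce")
    if age.isna().any():
        raise ValueError(f"column {age_col!r} contains non-numeric ages")
    df["age"] = age.astype(float)

    sex = raw[sex_col].astype(str).str.strip().str.lower()
    bad = ~sex.isin(_SEX_CODES)
    if bad.any():
        raise ValueError(
            f"unknown sex codes {sorted(set(sex[bad]))}; expected 0/1, F/M"
        )
    df["sex"] = sex.map(_SEX_CODES).astype(int)

    site = raw[site_col].astype(str)
    if site_mapping is None:
        site_mapping = {lab: i for i, lab in enumerate(sorted(site.unique()))}
    else:
        site_mapping = dict(site_mapping)
        nxt = max(site_mapping.values(), default=-1) + 1
        for lab in sorted(site.unique()):
            if lab not in site_mapping:
                site_mapping[lab] = nxt
                nxt += 1
    df["site"] = site
    df["site_code"] = site.map(site_mapping).astype(int)

    for col in response_cols:
        if col not in raw.columns:
            raise ValueError(f"cohort file {path} is missing response {col!r}")
        v = pd.to_numeric(raw[col], errors="coerce")
        if v.isna().any():
            raise ValueError(f"response column {col!r} contains non-numeric values")
        df[col] = v.astype(float)

    return CohortTable(df=df, site_mapping=site_mapping,
                       response_cols=list(response_cols))


def cohort_from_frame(df: pd.DataFrame, response_cols=("response",)) -> CohortTable:
    """Adopt an in-memory frame (e.g. a simulated cohort) as a CohortTable."""
    mapping = {lab: i for i, lab in enumerate(sorted(df["site"].astype(str).unique()))}
    out = df.copy()
    out["site_code"] = out["site"].astype(str).map(mapping).astype(int)
    return CohortTable(df=out, site_mapping=mapping,
                       response_cols=list(response_cols))


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

def standardise(cohort: CohortTable, fit_idx: np.ndarray,
                log_transform: Sequence[str] = ()) -> CohortTable:
    """Feature-wise standardise responses: subtract mean, divide by sd.

    Transform parameters are estimated on ``fit_idx`` rows only and
    applied to every row.  Columns listed in ``log_transform`` (strictly
    positive ones) are log-transformed first; the flag is recorded, never
    auto-detected.  Invertible via :func:`destandardise`.
    """
    fit_idx = np.asarray(fit_idx)
    if fit_idx.size == 0:
        raise ValueError("fit split must be non-empty")
    df = cohort.df.copy()
    record = {}
    for col in cohort.response_cols:
        v = df[col].to_numpy(dtype=float)
        use_log = col in log_transform
        if use_log:
            if np.any(v <= 0):
                raise ValueError(f"log transform requires {col!r} > 0 everywhere")
            v = np.log(v)
        mean = float(np.mean(v[fit_idx]))
        sd = float(np.std(v[fit_idx], ddof=0))
        if sd == 0.0:
            raise ValueError(f"column {col!r} has zero sd on the fit split")
        df[col] = (v - mean) / sd
        record[col] = {"mean": mean, "sd": sd, "log": use_log}
    return CohortTable(df=df, site_mapping=cohort.site_mapping,
                       response_cols=cohort.response_cols,
                       standardisation=record)


def destandardise(values, record_col: dict) -> np.ndarray:
    """Invert the stored standardisation for one column."""
    v = np.asarray(values, dtype=float) * record_col["sd"] + record_col["mean"]
    return np.exp(v) if record_col["log"] else v


def apply_standardisation(values, record_col: dict) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if record_col["log"]:
        v = np.log(v)
    return (v - record_col["mean"]) / record_col["sd"]


# ---------------------------------------------------------------------------
# Stratified folds
# ---------------------------------------------------------------------------

def stratified_folds(cohort: CohortTable, k: int = 10, min_count: int = 10,
                     seed: Optional[int] = None) -> FoldSpec:
    """Stratified k-fold assignment on site-by-sex cells.

    Site-by-sex cells with fewer than ``min_count`` subjects are dropped
    before splitting (assignment -1), so every retained cell — and hence
    every retained site — appears in each fold's training split.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = cohort.df
    cell = df["site_code"].astype(str) + ":" + df["sex"].astype(str)
    counts = cell.value_counts()
    keep = cell.map(counts) >= min_count
    n_keep = int(keep.sum())
    if n_keep < k:
        raise ValueError(f"only {n_keep} subjects retained, fewer than k={k}")
    assignment = np.full(len(df), -1, dtype=int)
    idx = np.where(keep.to_numpy())[0]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test) in enumerate(skf.split(idx, cell.to_numpy()[idx])):
        assignment[idx[test]] = fold
    return FoldSpec(k=k, assignment=assignment, min_count=min_count)


# ---------------------------------------------------------------------------
# Fitting surface and persistence
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FittedModel:
    """Everything needed to score held-out data: spec, transforms, fit."""

    spec: ModelSpec
    site_mapping: dict
    n_sites: int
    response_col: str
    standardisation: Optional[dict] = None
    map_theta: Optional[np.ndarray] = None
    samples: Optional[PosteriorSamples] = None

    def _bind(self, cohort: CohortTable, y=None):
        if self.spec.knots is None:
            raise ValueError("fitted model has no stored knots")
        df = cohort.df
        X, _ = build_design_matrix(df["age"].to_numpy(), df["sex"].to_numpy(),
                                   knots=self.spec.knots)
        batch = df["site_code"].to_numpy()
        y = np.zeros(len(df)) if y is None else y
        return HBRModel(self.spec, X, batch, y, n_sites=self.n_sites)

    def point(self, estimator: str = "map") -> np.ndarray:
        if estimator == "map":
            if self.map_theta is None:
                raise ValueError("no MAP point stored")
            return self.map_theta
        if estimator == "posterior_mean":
            if self.samples is None:
                raise ValueError("no posterior draws stored")
            return self.samples.posterior_mean()
        raise ValueError(f"unknown estimator {estimator!r}")


def fit_model(cohort: CohortTable, response_col: str, variant: str = "Sb1",
              method: str = "mcmc", seed: Optional[int] = None,
              chains: int = 2, iterations: int = 1500, burn_in: int = 500,
              spec: Optional[ModelSpec] = None) -> FittedModel:
    """Fit one model variant to one response column of a cohort.

    ``method`` is ``"mcmc"`` (NUTS posterior draws), ``"map"``
    (optimisation only), or ``"both"``.  Knots are derived from the
    training ages and stored on the spec.
    """
    spec = spec if spec is not None else ModelSpec.by_name(variant)
    df = cohort.df
    X, knots = build_design_matrix(df["age"].to_numpy(), df["sex"].to_numpy(),
                                   knots=spec.knots)
    spec.knots = knots
    y = df[response_col].to_numpy(dtype=float)
    model = HBRModel(spec, X, df["site_code"].to_numpy(), y,
                     n_sites=len(cohort.site_mapping))
    fitted = FittedModel(
        spec=spec, site_mapping=cohort.site_mapping,
        n_sites=len(cohort.site_mapping), response_col=response_col,
        standardisation=cohort.standardisation,
    )
    if method in ("mcmc", "both"):
        fitted.samples = sample_posterior(
            model, chains=chains, iterations=iterations, burn_in=burn_in,
            seed=seed,
        )
    if method in ("map", "both"):
        fitted.map_theta = map_estimate(model, seed=seed).theta
    return fitted


def predict_params(fitted: FittedModel, cohort: CohortTable,
                   estimator: str = "map"):
    """Per-subject (mu, sigma, epsilon, delta) on a (possibly new) cohort.

    Sites unseen at fit time receive the group-mean offset.
    """
    model = fitted._bind(cohort)
    return model.predict_likelihood_params(fitted.point(estimator))


def save_model(fitted: FittedModel, path) -> None:
    """Persist a fitted model as a directory bundle with a JSON manifest."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": _BUNDLE_VERSION,
        "spec": fitted.spec.to_dict(),
        "site_mapping": fitted.site_mapping,
        "n_sites": fitted.n_sites,
        "response_col": fitted.response_col,
        "standardisation": fitted.standardisation,
        "has_map": fitted.map_theta is not None,
        "has_samples": fitted.samples is not None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if fitted.map_theta is not None:
        np.save(path / "map_theta.npy", fitted.map_theta)
    if fitted.samples is not None:
        fitted.samples.save(path / "samples.npz")


def load_model(path) -> FittedModel:
    """Load a model bundle; refuses version mismatches and missing knots."""
    path = pathlib.Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["version"] != _BUNDLE_VERSION:
        raise ValueError(
            f"model bundle version {manifest['version']} != {_BUNDLE_VERSION}"
        )
    spec = ModelSpec.from_dict(manifest["spec"])
    if spec.knots is None:
        raise ValueError("model bundle is missing the spline knot record")
    fitted = FittedModel(
        spec=spec,
        site_mapping=manifest["site_mapping"],
        n_sites=manifest["n_sites"],
        response_col=manifest["response_col"],
        standardisation=manifest["standardisation"],
    )
    if manifest["has_map"]:
        fitted.map_theta = np.load(path / "map_theta.npy")
    if manifest["has_samples"]:
        fitted.samples = PosteriorSamples.load(path / "samples.npz")
    return fitted
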