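"""Cohort selection and the linear-model analysis of the extracted volumes.

Selection is a regular-expression query over free-text radiology reports;
the analysis cohort is then restricted to ages >= 45 at scan and cleaned by
a Tukey-style IQR rule on the ICV-corrected brain volume (brain/ICV ratio).
The models are ordinary least squares:

    ICV   = b0 + b1*gender + b2*age + sum_i b3i*group_i + b4*seq
                + sum_j b5j*type_j + b6*fs + e
    brain = same terms + b7*ICV + e

with dummy-coded factors (open-question group and Philips NT Intera scanner
as reference levels), adjusted group means evaluated at age 60.5 years and
ICV 1150 ml, and Bonferroni-corrected pairwise group contrasts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ReportTable",
    "RegressionSpec",
    "RegressionFit",
    "query_reports",
    "filter_age",
    "iqr_filter",
    "fit_model",
    "adjusted_means",
    "success_rate_report",
    "simulate_cohort",
]

MIN_AGE_YEARS = 45
EVAL_AGE_YEARS = 60.5
EVAL_ICV_ML = 1150.0
GROUPS = ("dementia+", "dementia-", "MS+", "MS-", "open")
SCANNER_MODELS = ("NT Intera", "Discovery", "Signa", "Sonata")


@dataclass
class ReportTable:
    """Rows of (study_id, report_text [, protocol_code, diagnosis_label])."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "study_id" not in self.table or "report_text" not in self.table:
            raise ValueError("report table needs study_id and report_text columns")
        if self.table["study_id"].duplicated().any():
            raise ValueError("study_id values must be unique")


def query_reports(
    table: ReportTable | pd.DataFrame,
    pattern: str,
    case_sensitive: bool = False,
) -> list[str]:
    """Study IDs whose report text matches ``pattern``, in table order."""
    df = table.table if isinstance(table, ReportTable) else table
    flags = 0 if case_sensitive else re.IGNORECASE
    compiled = re.compile(pattern, flags)  # invalid pattern raises re.error
    hits = df["report_text"].astype(str).apply(lambda t: bool(compiled.search(t)))
    return df.loc[hits, "study_id"].tolist()


def filter_age(records: pd.DataFrame, min_age: int = MIN_AGE_YEARS) -> pd.DataFrame:
    """Keep records with age at scan >= ``min_age`` (inclusive).

    Records with missing age are dropped with a warning: age is a model
    covariate and cannot be imputed from a scrubbed header.
    """
    if records.empty:
        return records
    missing = records["age"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} record(s) with missing age")
    kept = records[~missing]
    return kept[kept["age"] >= min_age]


def _iqr_bounds(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def iqr_filter(
    records: pd.DataFrame,
    value: str | pd.Series | None = None,
    per_group: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tukey outlier rule on the ICV-corrected brain volume.

    A record is excluded iff its value lies strictly outside
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR]; quartiles use linear interpolation
    between order statistics.  Applied within each disease group by
    default.  Fewer than 4 records (per group) excludes nothing, with a
    warning.  Returns ``(kept, excluded)``, a disjoint partition of the
    input.
    """
    if value is None:
        values = records["brain_ml"] / records["icv_ml"]
    elif isinstance(value, str):
        values = records[value]
    else:
        values = value
    values = pd.Series(np.asarray(values, dtype=float), index=records.index)

    out_mask = pd.Series(False, index=records.index)
    groups = (
        records.groupby("group").groups.items()
        if per_group and "group" in records
        else [("all", records.index)]
    )
    for name, idx in groups:
        vals = values.loc[idx]
        if len(vals) < 4:
            warnings.warn(f"group {name!r}: fewer than 4 records, no exclusion")
            continue
        lo, hi = _iqr_bounds(vals.to_numpy())
        out_mask.loc[idx] = (vals < lo) | (vals > hi)
    return records[~out_mask], records[out_mask]


# ---------------------------------------------------------------------------
# Regression models


@dataclass(frozen=True)
class RegressionSpec:
    """Design of the ICV / brain-volume models.

    ``response`` is ``"icv_ml"`` or ``"brain_ml"``; the ICV covariate is
    included exactly when the response is brain volume.  Gender is coded
    0/1 (reference level 0); factors are dummy-coded at the stated
    reference levels.  ``eval_age``/``eval_icv`` set the covariate values
    at which adjusted means are reported.
    """

    response: str = "icv_ml"
    include_icv: bool | None = None
    gender_reference: str = "F"
    group_reference: str = "open"
    scanner_reference: str = "NT Intera"
    sequence_reference: str = "GR"
    eval_age: float = EVAL_AGE_YEARS
    eval_icv: float = EVAL_ICV_ML
    # absolute covariate levels of the evaluation point: fixed scan
    # conditions, independent of how the dummies are coded
    eval_scanner: str = "NT Intera"
    eval_sequence: str = "GR"

    @property
    def with_icv(self) -> bool:
        if self.include_icv is not None:
            return self.include_icv
        return self.response == "brain_ml"


@dataclass
class RegressionFit:
    """OLS fit: coefficient table, fit statistics, adjusted means, contrasts."""

    spec: RegressionSpec
    params: pd.DataFrame  # coef, se, t, p, ci_low, ci_high per term
    r_squared: float
    r_squared_adj: float
    f_statistic: float
    df_model: int
    df_resid: int
    adjusted_means: pd.DataFrame
    contrasts: pd.DataFrame
    results: object = field(repr=False, default=None)  # statsmodels results

    def predict_row(self, row: pd.Series | dict) -> float:
        exog = _design_row(pd.Series(row), self.results.model.exog_names)
        return float(exog @ self.results.params.to_numpy())


def _build_design(records: pd.DataFrame, spec: RegressionSpec):
    """Dummy-coded design matrix; factors with one observed level drop out."""
    df = records.reset_index(drop=True)
    design = pd.DataFrame(index=df.index)
    design["const"] = 1.0
    design["gender"] = (df["gender"] != spec.gender_reference).astype(float)
    design["age"] = df["age"].astype(float)
    dropped = []
    for col, ref, prefix in (
        ("group", spec.group_reference, "group"),
        ("sequence", spec.sequence_reference, "seq"),
        ("scanner_model", spec.scanner_reference, "type"),
    ):
        if df[col].nunique() < 2:
            dropped.append(col)
            continue
        levels = [lv for lv in df[col].unique() if lv != ref]
        for lv in sorted(levels):
            design[f"{prefix}[{lv}]"] = (df[col] == lv).astype(float)
    if df["field_strength"].nunique() >= 2:
        design["fs"] = df["field_strength"].astype(float)
    else:
        dropped.append("field_strength")
    if spec.with_icv:
        design["icv"] = df["icv_ml"].astype(float)
    if dropped:
        warnings.warn(f"factor(s) with a single level dropped: {dropped}")
    return design, df[spec.response].astype(float)


def _design_row(row: pd.Series, exog_names: list[str]) -> np.ndarray:
    """Design vector for one (possibly counterfactual) observation."""
    out = np.zeros(len(exog_names))
    for pos, name in enumerate(exog_names):
        if name == "const":
            out[pos] = 1.0
        elif name == "gender":
            if "gender_num" in row:
                out[pos] = float(row["gender_num"])
            else:
                out[pos] = 0.0 if str(row["gender"]) in ("F", "0") else 1.0
        elif name == "age":
            out[pos] = float(row["age"])
        elif name == "fs":
            out[pos] = float(row["field_strength"])
        elif name == "icv":
            out[pos] = float(row["icv_ml"])
        else:
            prefix, level = name.split("[", 1)
            level = level[:-1]
            key = {"group": "group", "seq": "sequence", "type": "scanner_model"}[
                prefix
            ]
            out[pos] = 1.0 if str(row[key]) == level else 0.0
    return out


def fit_model(records: pd.DataFrame, spec: RegressionSpec) -> RegressionFit:
    """Fit the ICV or brain-volume OLS model and summarise it.

    Adjusted means per (group, gender) are the model predictions at age
    ``spec.eval_age`` (and ICV ``spec.eval_icv`` for the brain model) with
    sequence, scanner and field strength at their reference/typical values;
    pairwise group contrasts carry Bonferroni-adjusted p-values.  A
    rank-deficient design is an error naming the aliased columns.
    """
    design, response = _build_design(records, spec)
    if len(records) <= design.shape[1]:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        u, s, vt = np.linalg.svd(design.to_numpy(), full_matrices=False)
        aliased = [
            design.columns[i]
            for i in np.abs(vt[rank:]).max(axis=0).argsort()[::-1][: design.shape[1] - rank]
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    results = sm.OLS(response, design).fit()
    ci = results.conf_int()
    params = pd.DataFrame(
        {
            "coef": results.params,
            "se": results.bse,
            "t": results.tvalues,
            "p": results.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )

    fit = RegressionFit(
        spec=spec,
        params=params,
        r_squared=float(results.rsquared),
        r_squared_adj=float(results.rsquared_adj),
        f_statistic=float(results.fvalue),
        df_model=int(results.df_model),
        df_resid=int(results.df_resid),
        adjusted_means=pd.DataFrame(),
        contrasts=pd.DataFrame(),
        results=results,
    )
    fit.adjusted_means = adjusted_means(fit, records)
    fit.contrasts = _group_contrasts(fit, records)
    return fit


def _eval_row(fit: RegressionFit, group: str, gender_num: float,
              records: pd.DataFrame) -> np.ndarray:
    spec = fit.spec
    typical = {
        "gender_num": gender_num,
        "age": spec.eval_age,
        "group": group,
        "sequence": spec.eval_sequence,
        "scanner_model": spec.eval_scanner,
        "field_strength": float(records["field_strength"].mode().iloc[0]),
        "icv_ml": spec.eval_icv,
    }
    return _design_row(pd.Series(typical), list(fit.results.model.exog_names))


def adjusted_means(fit: RegressionFit, records: pd.DataFrame) -> pd.DataFrame:
    """Model-adjusted response per group and gender at the evaluation point."""
    rows = []
    groups = sorted(records["group"].unique())
    for group in groups:
        for gender_num, gender in ((0.0, "F"), (1.0, "M")):
            exog = _eval_row(fit, group, gender_num, records)
            pred = fit.results.get_prediction(exog)
            lo, hi = pred.conf_int()[0]
            rows.append(
                {
                    "group": group,
                    "gender": gender,
                    "mean": float(pred.predicted_mean[0]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)


def _group_contrasts(fit: RegressionFit, records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise group differences with Bonferroni-adjusted p-values."""
    groups = sorted(records["group"].unique())
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    if not pairs:
        return pd.DataFrame(
            columns=["group_a", "group_b", "estimate", "t", "p", "p_bonferroni"]
        )
    rows = []
    for a, b in pairs:
        row_a = _eval_row(fit, a, 0.0, records)
        row_b = _eval_row(fit, b, 0.0, records)
        test = fit.results.t_test(row_a - row_b)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "estimate": float(np.atleast_1d(test.effect)[0]),
                "t": float(np.atleast_1d(test.tvalue).ravel()[0]),
                "p": float(np.atleast_1d(test.pvalue).ravel()[0]),
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out


# ---------------------------------------------------------------------------
# Accounting


def success_rate_report(counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Step-wise success percentages relative to the selected count.

    ``counts`` maps protocol group -> ordered step -> count; counts must be
    non-negative and non-increasing across steps (a pipeline can only lose
    examinations).  A group with zero selected yields an empty row with a
    warning.
    """
    rows = []
    for group, steps in counts.items():
        values = list(steps.values())
        if any(v < 0 for v in values):
            raise ValueError(f"group {group!r}: negative count")
        if any(b > a for a, b in zip(values, values[1:])):
            raise ValueError(
                f"group {group!r}: counts increase across steps "
                "(pipeline accounting bug)"
            )
        selected = values[0]
        if selected == 0:
            warnings.warn(f"group {group!r}: zero examinations selected")
            rows.append({"group": group, **{k: np.nan for k in steps}})
            continue
        rows.append(
            {"group": group, **{k: 100.0 * v / selected for k, v in steps.items()}}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic cohorts (for validating the models themselves)


def simulate_cohort(
    n: int,
    betas: dict[str, float],
    noise_sd: float,
    seed: int = 0,
    response: str = "brain_ml",
) -> pd.DataFrame:
    """Draw a synthetic cohort from the linear model itself.

    Covariates mimic the structure of a mixed clinical archive: gender
    Bernoulli(0.5), age uniform on [45, 85], five disease groups, two
    sequences, four scanner models, field strength in {1.5, 3.0}, and (for
    the brain model) ICV normal around 1150 ml.  The response is the exact
    linear predictor plus Gaussian noise, so OLS on the result is estimating
    known truth.  ``betas`` uses keys: const, gender, age, group[...],
    seq[SE], type[...], fs, icv.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "gender": rng.choice(["F", "M"], n),
            "age": rng.uniform(45, 85, n),
            "group": rng.choice(GROUPS, n),
            "sequence": rng.choice(["GR", "SE"], n),
            "scanner_model": rng.choice(SCANNER_MODELS, n),
            "field_strength": rng.choice([1.5, 3.0], n),
        }
    )
    df["icv_ml"] = rng.normal(EVAL_ICV_ML, 100.0, n)
    linear = np.full(n, betas.get("const", 0.0))
    linear += betas.get("gender", 0.0) * (df["gender"] == "M").to_numpy()
    linear += betas.get("age", 0.0) * df["age"].to_numpy()
    for group in GROUPS:
        key = f"group[{group}]"
        if key in betas:
            linear += betas[key] * (df["group"] == group).to_numpy()
    linear += betas.get("seq[SE]", 0.0) * (df["sequence"] == "SE").to_numpy()
    for model in SCANNER_MODELS:
        key = f"type[{model}]"
        if key in betas:
            linear += betas[key] * (df["scanner_model"] == model).to_numpy()
    linear += betas.get("fs", 0.0) * df["field_strength"].to_numpy()
    if response == "brain_ml":
        linear += betas.get("icv", 0.0) * df["icv_ml"].to_numpy()
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    df[response] = linear + noise
    if response != "icv_ml" and "icv_ml" not in df:
        df["icv_ml"] = EVAL_ICV_ML
    return df
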