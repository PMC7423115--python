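"""Stage 2: posterior-probability-weighted logistic regression.

Each subject classified by the latent class mixed model contributes one
record per trajectory class, weighted by the posterior probability of
membership, so classification uncertainty propagates into the
disease-association estimates.  A-priori-classified subjects (the
low-cumulative-exposure class) and never-exposed reference subjects
contribute a single record with weight 1.  Confounders (age, CSI, CIE)
enter through fractional-polynomial transformations; region strata enter
as dummy indicators.  Because weighting duplicates subjects, robust
(sandwich) variances clustered by subject are reported alongside the
naive information-based ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FPSpec",
    "AssociationResult",
    "SeparationError",
    "expand_weighted",
    "fp_transform",
    "weighted_logistic",
    "compare_adjustments",
]

_FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class SeparationError(RuntimeError):
    """Quasi-complete separation detected in the logistic fit."""


@dataclass
class FPSpec:
    """Fractional polynomial of one covariate.

    ``powers`` has one (FP1) or two (FP2) entries from
    {-2, -1, -0.5, 0, 0.5, 1, 2, 3}; power 0 denotes the natural log, and
    repeated powers (p, p) expand to x^p and x^p ln x.  ``shift`` and
    ``scale`` default to an automatic positivity/scaling rule (shift by
    the smallest observed increment when values are non-positive; scale by
    the power of 10 of the range), resolved from the data at transform
    time.
    """

    variable: str
    powers: tuple
    shift: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.powers = tuple(float(p) for p in self.powers)
        if len(self.powers) not in (1, 2):
            raise ValueError("fractional polynomial degree must be 1 or 2")
        for p in self.powers:
            if p not in _FP_POWERS:
                raise ValueError(f"power {p} not in the standard FP set {_FP_POWERS}")


def _auto_shift(x: np.ndarray) -> float:
    if x.min() > 0:
        return 0.0
    ux = np.unique(x)
    d = np.diff(ux)
    incr = d[d > 0].min() if np.any(d > 0) else 1.0
    return float(incr - x.min())


def _auto_scale(x: np.ndarray) -> float:
    rng = x.max() - x.min()
    if rng <= 0:
        return 1.0
    return float(10.0 ** math.floor(math.log10(rng)))


def fp_transform(x, spec: FPSpec) -> np.ndarray:
    """Fractional-polynomial design columns for ``x`` (n x degree).

    Columns are (x')^p with x' = (x + shift)/scale, p = 0 meaning ln x';
    a repeated power contributes (x')^p and (x')^p ln x'.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    shift = _auto_shift(x) if spec.shift is None else spec.shift
    scale = _auto_scale(x + shift) if spec.scale is None else spec.scale
    xp = (x + shift) / scale
    if np.any(xp <= 0):
        raise ValueError(
            f"non-positive values of {spec.variable!r} after shift {shift}; "
            "supply a feasible shift"
        )

    def one(p):
        return np.log(xp) if p == 0.0 else xp**p

    cols = [one(spec.powers[0])]
    if len(spec.powers) == 2:
        if spec.powers[1] == spec.powers[0]:
            cols.append(cols[0] * np.log(xp) if spec.powers[0] != 0.0 else np.log(xp) ** 2)
        else:
            cols.append(one(spec.powers[1]))
    return np.column_stack(cols)


def fp_frame(x, spec: FPSpec) -> pd.DataFrame:
    """fp_transform with named columns ``<variable>_fp1`` (,``_fp2``)."""
    cols = fp_transform(x, spec)
    names = [f"{spec.variable}_fp{j + 1}" for j in range(cols.shape[1])]
    return pd.DataFrame(cols, columns=names)


# ---------------------------------------------------------------------------
# Weighted record expansion
# ---------------------------------------------------------------------------


def membership_table(
    posterior: pd.DataFrame,
    a_priori_ids=(),
    reference_ids=(),
    class_prefix: str = "class",
    a_priori_label: str | None = None,
) -> pd.DataFrame:
    """Per-subject class-membership probabilities over all categories.

    Rows are subjects; columns are trajectory-class probabilities
    (``class_1..class_G`` from the posterior, plus an a-priori class
    column when ``a_priori_ids`` is non-empty).  Reference subjects get an
    all-zero row — they are the reference category of the dummy coding.
    Every subject appears in exactly one of the three groups.
    """
    post = posterior.copy()
    if "subject_id" in post.columns:
        post = post.set_index("subject_id")
    G = post.shape[1]
    cols = [f"{class_prefix}_{g + 1}" for g in range(G)]
    post.columns = cols
    a_priori_ids = list(a_priori_ids)
    reference_ids = list(reference_ids)
    overlap = (set(post.index) & set(a_priori_ids)) | (
        set(post.index) & set(reference_ids)
    ) | (set(a_priori_ids) & set(reference_ids))
    if overlap:
        raise ValueError(f"subjects in more than one membership group: {sorted(overlap)[:5]}")
    if a_priori_ids:
        label = a_priori_label or f"{class_prefix}_{G + 1}"
        post[label] = 0.0
        ap = pd.DataFrame(0.0, index=pd.Index(a_priori_ids), columns=post.columns)
        ap[label] = 1.0
        post = pd.concat([post, ap])
    if reference_ids:
        ref = pd.DataFrame(0.0, index=pd.Index(reference_ids), columns=post.columns)
        post = pd.concat([post, ref])
    post.index.name = "subject_id"
    return post


def expand_weighted(
    subjects: pd.DataFrame,
    posterior: pd.DataFrame,
    a_priori_ids=(),
    reference_ids=(),
    class_prefix: str = "class",
) -> pd.DataFrame:
    """Expanded stage-2 dataset: one weighted record per subject x class.

    LCMM-classified subjects contribute G records weighted by their
    posterior probabilities (zero-weight records are dropped); a-priori
    and reference subjects contribute one record with weight 1 (the
    reference with all dummies zero).  Subject covariate columns are
    carried along.  Total weight equals the number of subjects.
    """
    memb = membership_table(posterior, a_priori_ids, reference_ids, class_prefix)
    subj = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    missing = set(subj.index) - set(memb.index)
    if missing:
        raise ValueError(
            f"subjects in no membership group (posterior / a priori / reference): "
            f"{sorted(missing)[:5]}"
        )
    return _records_from_membership(subj, memb.loc[memb.index.intersection(subj.index)])


# ---------------------------------------------------------------------------
# Weighted logistic regression
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """Weighted logistic fit: per-term odds ratios with robust (cluster
    sandwich) and naive 95% CIs, weighted log-likelihood and AIC."""

    label: str
    table: pd.DataFrame
    loglik: float
    aic: float
    n_records: int
    n_subjects: int


def _cluster_sandwich_se(X, y, w, mu, groups) -> np.ndarray:
    """Cluster-robust sandwich SEs for the weighted Bernoulli likelihood.

    Bread: inverse expected information (X' diag(w mu (1-mu)) X)^{-1}.
    Meat: outer products of per-cluster score sums, clusters = subjects
    (the weighted records of one subject are duplicates, not independent).
    """
    v = w * mu * (1.0 - mu)
    bread = np.linalg.pinv(X.T * v @ X)
    score = (w * (y - mu))[:, None] * X
    n_groups = int(groups.max()) + 1
    S = np.zeros((n_groups, X.shape[1]))
    np.add.at(S, groups, score)
    cov = bread @ (S.T @ S) @ bread
    return np.sqrt(np.diag(cov))


def weighted_logistic(
    records: pd.DataFrame,
    class_cols,
    covar_cols=(),
    label: str = "",
    separation_threshold: float = 15.0,
) -> AssociationResult:
    """Fit the posterior-weighted Bernoulli likelihood
    sum_r w_r [y_r ln mu_r + (1-y_r) ln(1-mu_r)] by weighted GLM.

    Robust variances use the cluster sandwich grouped by subject (records
    of one subject are duplicates, not independent observations); naive
    information-based CIs are reported alongside.  Coefficients beyond
    ``separation_threshold`` in absolute value raise SeparationError.
    """
    class_cols = list(class_cols)
    covar_cols = list(covar_cols)
    y = records["outcome"].to_numpy(dtype=float)
    w = records["weight"].to_numpy(dtype=float)
    if np.any((w <= 0) | (w > 1)):
        raise ValueError("weights must lie in (0, 1]")
    if y.min() == y.max():
        raise ValueError("need at least one case and one control record")
    # constant covariate columns carry no information beyond the intercept
    # and leave the design singular; drop them
    covar_cols = [c for c in covar_cols if records[c].nunique() > 1]
    X = sm.add_constant(records[class_cols + covar_cols].astype(float), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    naive = model.fit()
    # check the unit-scale class dummies only: FP-transformed covariates can
    # legitimately carry large coefficients because of their column scale
    class_coefs = naive.params[class_cols]
    if np.any(np.abs(class_coefs.to_numpy()) > separation_threshold):
        bad = class_coefs[np.abs(class_coefs) > separation_threshold]
        raise SeparationError(f"separation suspected: extreme coefficients {dict(bad)}")
    groups = records["subject_id"].astype("category").cat.codes.to_numpy()
    se_robust = _cluster_sandwich_se(X.to_numpy(dtype=float), y, w,
                                     np.asarray(naive.fittedvalues, dtype=float), groups)
    z = 1.959963984540054
    coefs = naive.params
    tab = pd.DataFrame(
        {
            "coef": coefs,
            "se_robust": pd.Series(se_robust, index=coefs.index),
            "se_naive": naive.bse,
            "odds_ratio": np.exp(coefs),
            "or_ci_low": np.exp(coefs - z * se_robust),
            "or_ci_high": np.exp(coefs + z * se_robust),
            "or_ci_low_naive": np.exp(coefs - z * naive.bse),
            "or_ci_high_naive": np.exp(coefs + z * naive.bse),
        }
    )
    return AssociationResult(
        label=label,
        table=tab,
        loglik=float(naive.llf),
        aic=float(naive.aic),
        n_records=len(records),
        n_subjects=int(records["subject_id"].nunique()),
    )


# ---------------------------------------------------------------------------
# Mutual-adjustment strategies
# ---------------------------------------------------------------------------


def _stratum_dummies(records: pd.DataFrame) -> pd.DataFrame:
    if "stratum" not in records.columns:
        return pd.DataFrame(index=records.index)
    return pd.get_dummies(records["stratum"], prefix="stratum", drop_first=True).astype(
        float
    )


def _cross_expand(
    records: pd.DataFrame, other_memb: pd.DataFrame, mode: str = "product"
) -> pd.DataFrame:
    """Augment records with the other exposure's class dummies.

    ``product`` mode takes one record per cross-classification cell with
    weight w x p_other (classifications treated as independent given the
    data); ``modal`` mode appends the modal-class dummies at unchanged
    weight.
    """
    other_cols = list(other_memb.columns)
    if mode == "modal":
        dummies = pd.DataFrame(0.0, index=other_memb.index, columns=other_cols)
        nonref = other_memb.sum(axis=1) > 0
        modal = other_memb.loc[nonref].idxmax(axis=1)
        for sid, c in modal.items():
            dummies.loc[sid, c] = 1.0
        joined = records.join(dummies, on="subject_id")
        return joined
    if mode != "product":
        raise ValueError("mode must be 'product' or 'modal'")
    is_ref = other_memb.sum(axis=1) == 0.0
    stacked = other_memb.loc[~is_ref].stack()
    stacked = stacked[stacked > 0.0]
    cells = stacked.rename("_p_other").reset_index()
    cells.columns = ["subject_id", "_other_class", "_p_other"]
    dummies = pd.get_dummies(cells["_other_class"]).reindex(columns=other_cols, fill_value=0)
    cells = pd.concat([cells[["subject_id", "_p_other"]], dummies.astype(float)], axis=1)
    ref = pd.DataFrame({"subject_id": other_memb.index[is_ref], "_p_other": 1.0})
    for c in other_cols:
        ref[c] = 0.0
    cells = pd.concat([cells, ref], ignore_index=True)
    out = records.merge(cells, on="subject_id", how="inner")
    out["weight"] = out["weight"] * out["_p_other"]
    return out.drop(columns=["_p_other"]).reset_index(drop=True)


@dataclass
class AdjustmentComparison:
    """Results of the three mutual-adjustment strategies for one exposure."""

    exposure: str
    results: dict  # strategy label -> AssociationResult
    aic_table: pd.DataFrame


def compare_adjustments(
    subjects: pd.DataFrame,
    primary_membership: pd.DataFrame,
    other_membership: pd.DataFrame,
    other_dose: pd.Series,
    exposure: str = "exposure",
    age_fp: FPSpec | None = None,
    dose_fp: FPSpec | None = None,
    other_mode: str = "product",
) -> AdjustmentComparison:
    """Fit the three mutual-adjustment strategies and compare by AIC.

    (i) no mutual adjustment; (ii) adjustment for the other exposure's
    cumulative dose at the index date (fractional polynomial); (iii)
    adjustment for the other exposure's trajectory-class membership
    (product-weighted cross-classification by default, modal optionally).
    All models adjust for age (fractional polynomial, default powers
    (-2, -2)) and region stratum dummies.
    """
    age_fp = age_fp or FPSpec("age", (-2.0, -2.0), shift=0.0, scale=10.0)
    dose_fp = dose_fp or FPSpec("dose", (0.0,))
    subj = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects

    # stage-2 records for the primary exposure
    records = _records_from_membership(subj, primary_membership)
    class_cols = list(primary_membership.columns)

    age_cols = fp_frame(records["age_index"].to_numpy(), age_fp)
    age_cols.index = records.index
    records = pd.concat([records, age_cols], axis=1)
    strat = _stratum_dummies(records)
    records = pd.concat([records, strat], axis=1)
    base_covars = list(age_cols.columns) + list(strat.columns)

    results: dict[str, AssociationResult] = {}
    results["none"] = weighted_logistic(
        records, class_cols, base_covars, label=f"{exposure}: no mutual adjustment"
    )

    dose = other_dose.reindex(records["subject_id"]).to_numpy(dtype=float)
    dose_cols = fp_frame(dose, dose_fp)
    dose_cols.index = records.index
    rec2 = pd.concat([records, dose_cols], axis=1)
    results["dose"] = weighted_logistic(
        rec2,
        class_cols,
        base_covars + list(dose_cols.columns),
        label=f"{exposure}: adjusted for the other exposure's cumulative dose",
    )

    rec3 = _cross_expand(records, other_membership, mode=other_mode)
    results["class"] = weighted_logistic(
        rec3,
        class_cols,
        base_covars + list(other_membership.columns),
        label=f"{exposure}: adjusted for the other exposure's trajectory class",
    )

    aic_table = pd.DataFrame(
        {
            "strategy": list(results),
            "AIC": [r.aic for r in results.values()],
            "loglik": [r.loglik for r in results.values()],
        }
    )
    return AdjustmentComparison(exposure, results, aic_table)


def _records_from_membership(subj: pd.DataFrame, memb: pd.DataFrame) -> pd.DataFrame:
    class_cols = list(memb.columns)
    is_ref = memb.sum(axis=1) == 0.0
    stacked = memb.loc[~is_ref].stack()
    stacked = stacked[stacked > 0.0]
    core = stacked.rename("weight").reset_index()
    core.columns = ["subject_id", "_class", "weight"]
    dummies = pd.get_dummies(core["_class"]).reindex(columns=class_cols, fill_value=0)
    core = pd.concat([core[["subject_id", "weight"]], dummies.astype(float)], axis=1)
    ref = pd.DataFrame({"subject_id": memb.index[is_ref], "weight": 1.0})
    for c in class_cols:
        ref[c] = 0.0
    out = pd.concat([core, ref], ignore_index=True)
    return out.merge(subj.reset_index().rename(columns={"index": "subject_id"}),
                     on="subject_id", how="left").reset_index(drop=True)
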