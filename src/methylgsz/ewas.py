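"""Per-CpG differential-methylation regression on M-values.

Each probe's M-values are regressed by ordinary least squares on smoking
status (the exposure; 1 = active smoker, 0 = never smoker) plus a covariate
set, and the smoking coefficient, its standard error, t-statistic and
two-sided p-value are reported with Benjamini-Hochberg adjustment across
probes. Two standard covariate sets are predefined:

* ``model1`` — age, sex, BMI, cell-type proportions, chip, array position
  (plus control-probe PCs when supplied);
* ``model2`` — model 1 plus alcohol use and socioeconomic status, with
  listwise deletion of samples missing either.

The design matrix is shared across probes, so the fit is a single vectorized
least-squares solve over the whole matrix rather than a per-probe loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CELL_TYPES, DataError, MethylationDataset
from .preprocess import beta_to_m

logger = logging.getLogger(__name__)

#: Median of the chi-squared distribution with 1 df (the null median of a
#: squared z-score); denominator of the genomic inflation factor.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))

# Cell proportions sum to one, so one (granulocytes, the dominant fraction)
# is dropped to keep the design full rank.
_MODEL1_NUMERIC = ("age", "sex", "bmi") + CELL_TYPES[:-1]
_MODEL1_CATEGORICAL = ("chip", "array_pos")


@dataclass
class ModelSpec:
    """Covariate specification for one EWAS run.

    ``covariates`` never includes smoking (the exposure). Categorical fields
    are indicator-coded against the first observed level.
    """

    name: str = "model1"
    covariates: tuple = _MODEL1_NUMERIC
    categorical: tuple = _MODEL1_CATEGORICAL
    include_control_pcs: int = 2
    drop_cell_type: str = CELL_TYPES[-1]

    def __post_init__(self) -> None:
        if "smoking" in self.covariates or "smoking" in self.categorical:
            raise DataError("smoking is the exposure and may not appear as a covariate")

    @classmethod
    def model1(cls) -> "ModelSpec":
        return cls()

    @classmethod
    def model2(cls) -> "ModelSpec":
        """Model 1 plus alcohol (units/week) and socioeconomic status."""
        return cls(name="model2",
                   covariates=_MODEL1_NUMERIC + ("alcohol",),
                   categorical=_MODEL1_CATEGORICAL + ("ses",))

    @classmethod
    def intercept_only(cls) -> "ModelSpec":
        """Smoking-only model (no covariates); used in small fixtures."""
        return cls(name="custom", covariates=(), categorical=(), include_control_pcs=0)


def build_design(sheet: pd.DataFrame, spec: ModelSpec,
                 control_pcs: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.Index]:
    """Design matrix [intercept, smoking, covariates, control PCs].

    Samples with a missing value in any required field are dropped
    (listwise deletion); the retained sample index is returned alongside.
    """
    needed = ["smoking", *spec.covariates, *spec.categorical]
    missing_cols = [c for c in needed if c not in sheet.columns]
    if missing_cols:
        raise DataError(f"sample sheet lacks fields required by {spec.name}: {missing_cols}")
    sub = sheet[needed].copy()
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        logger.info("%s: dropping %d samples with missing covariates",
                    spec.name, int((~complete).sum()))
    sub = sub.loc[complete]

    cols = {"intercept": np.ones(len(sub)), "smoking": sub["smoking"].astype(float)}
    for c in spec.covariates:
        cols[c] = sub[c].astype(float)
    X = pd.DataFrame(cols, index=sub.index)
    for c in spec.categorical:
        dummies = pd.get_dummies(sub[c].astype(str), prefix=c, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    if spec.include_control_pcs and control_pcs is not None:
        pcs = control_pcs.iloc[:, : spec.include_control_pcs].loc[X.index]
        X = pd.concat([X, pcs], axis=1)

    rank = np.linalg.matrix_rank(X.to_numpy(float))
    if rank < X.shape[1]:
        # identify offending columns by greedy rank scan
        bad = []
        base = np.empty((len(X), 0))
        for col in X.columns:
            cand = np.column_stack([base, X[col].to_numpy(float)])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(col)
            else:
                base = cand
        raise DataError(f"design matrix rank-deficient; collinear columns: {bad}")
    return X, X.index


class EwasModel:
    """Per-CpG OLS differential-methylation model.

    Parameters
    ----------
    dataset : MethylationDataset
        Filtered beta matrix with annotation and sample sheet.
    spec : ModelSpec
        Covariate set; defaults to model 1.
    control_pcs : DataFrame, optional
        Per-sample control-probe PC scores (samples x components).
    """

    def __init__(self, dataset: MethylationDataset, spec: ModelSpec | None = None,
                 control_pcs: pd.DataFrame | None = None):
        self.dataset = dataset
        self.spec = spec or ModelSpec.model1()
        self.control_pcs = control_pcs
        self.design, self.sample_index = build_design(
            dataset.sample_sheet.table, self.spec, control_pcs
        )

    def fit(self, m_total: int | None = None) -> "EwasResults":
        """Fit OLS per probe; returns :class:`EwasResults`.

        ``m_total`` overrides the Benjamini-Hochberg test count (defaults to
        the number of probes fitted), for adjusting a subset against a larger
        experiment-wide count.
        """
        X = self.design.to_numpy(float)
        n, p = X.shape
        df_resid = n - p
        if df_resid <= 0:
            raise DataError(f"non-positive residual df ({n} samples, {p} coefficients)")
        M = beta_to_m(self.dataset.beta[self.sample_index].to_numpy(float))

        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T                       # p x n
        coefs = M @ H.T                          # probes x p
        resid = M - coefs @ X.T
        rss = np.einsum("ij,ij->i", resid, resid)
        sigma2 = rss / df_resid
        j = self.design.columns.get_loc("smoking")
        effect = coefs[:, j]
        var_j = sigma2 * XtX_inv[j, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(var_j)
            t = effect / se
        degenerate = ~np.isfinite(t)
        if degenerate.any():
            warnings.warn(f"{int(degenerate.sum())} probe(s) with zero residual "
                          "variance; p set to missing")
        pvals = np.full(len(t), np.nan)
        ok = ~degenerate
        pvals[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_resid)

        table = pd.DataFrame({
            "effect": effect, "se": se, "t": t,
            "df": df_resid, "p": pvals,
        }, index=self.dataset.probe_ids)
        table.index.name = "probe_id"
        m_bh = m_total if m_total is not None else int(ok.sum())
        q = np.full(len(t), np.nan)
        q[ok] = bh_adjust(pvals[ok], m_bh)
        table["q"] = q
        table["n_used"] = n
        return EwasResults(self, table, m_total=m_bh)


class EwasResults:
    """Results of a per-CpG EWAS fit.

    ``table`` has one row per probe: effect (smoker - never difference in
    M-units), se, t, df, p, q (BH), n_used.
    """

    def __init__(self, model: EwasModel | None, table: pd.DataFrame, m_total: int):
        self.model = model
        self.table = table
        self.m_total = m_total

    @property
    def spec_name(self) -> str:
        return self.model.spec.name if self.model is not None else "unknown"

    def n_significant(self, fdr: float = 0.05) -> int:
        return int((self.table["q"] < fdr).sum())

    def genomic_lambda(self) -> float:
        p = self.table["p"].dropna().to_numpy()
        return genomic_lambda(p)

    def summary(self, fdr: float = 0.05) -> str:
        lam = self.genomic_lambda()
        lines = [
            f"EWAS results ({self.spec_name})",
            f"  probes tested:        {len(self.table)}",
            f"  samples used:         {int(self.table['n_used'].iloc[0])}",
            f"  BH test count (m):    {self.m_total}",
            f"  hits at FDR<{fdr:g}:     {self.n_significant(fdr)}",
            f"  genomic inflation λ:  {lam:.3f}",
            "  top probes:",
        ]
        top = self.table.nsmallest(5, "p")
        for pid, row in top.iterrows():
            lines.append(f"    {pid}  effect={row.effect:+.3f}  se={row.se:.3f}  "
                         f"p={row.p:.3g}  q={row.q:.3g}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["model_name"] = self.spec_name
        out.to_csv(path, sep="\t")

    def manhattan_data(self) -> pd.DataFrame:
        """Probe, chromosome, position, -log10 p — for external plotting."""
        ann = self.model.dataset.probe_annotation()
        return pd.DataFrame({
            "chromosome": ann["chromosome"],
            "position": ann["position"],
            "neglog10_p": -np.log10(self.table["p"]),
        }, index=self.table.index)


def bh_adjust(p, m_total: int | None = None) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    ``m_total`` may exceed ``len(p)`` to adjust a printed subset against the
    full experiment-wide test count (subset ranks must then equal global
    ranks, i.e. the subset holds the smallest p-values). Ties share the
    smaller adjusted value through the cumulative-minimum construction.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataError("p must be a 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise DataError(f"m_total={m} smaller than number of p-values {len(p)}")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    raw = p[order] * m / ranks
    q_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def genomic_lambda(p) -> float:
    """Genomic inflation factor from two-sided p-values.

    lambda = median of the observed 1-df chi-squared statistics divided by
    the null chi-squared median (~0.4549); 1 indicates calibrated tests.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise DataError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)
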