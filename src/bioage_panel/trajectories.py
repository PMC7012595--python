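"""Longitudinal trajectory models and biological-age residuals.

Each BA is modelled on all its available visit rows as

    BA_ijk = b0 + ns(CA_ijk; 3 df) + b4 * sex_ij + u_i + u_ij + e_ijk

a Gaussian mixed model with a natural cubic age spline (interior knots at
the 33.3/66.7 age percentiles, boundary knots at the observed age range),
a woman-minus-man level shift, and random intercepts for twin pair (u_i)
and individual (u_ij).  REML is used for estimation and residuals; full ML
only for the sex-interaction likelihood-ratio test.

The *BA residual* of a measurement is the observation minus the fixed-effect
prediction minus the empirical-Bayes (shrunken) predictions of both random
intercepts — the longitudinal analogue of "age acceleration": what remains
of a BA after age, sex, and stable pair/individual differences are removed.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .nested_lmm import NestedLMM
from .splines import NaturalSplineBasis

__all__ = [
    "BATrajectoryModel",
    "sex_interaction_test",
    "fit_all_trajectories",
    "add_residual_columns",
]


class BATrajectoryModel(BaseEstimator):
    """Spline mixed model for one BA; produces residuals and mean curves.

    Parameters
    ----------
    ba_col : str
        Column holding the BA values.
    spline_df : int
        Degrees of freedom of the natural age spline (3 by default).
    reml : bool
        REML (default) for estimation/residuals; set False for ML fits.
    """

    def __init__(self, ba_col: str, spline_df: int = 3, reml: bool = True,
                 age_col: str = "ca", sex_col: str = "sex",
                 pair_col: str = "pair_id", id_col: str = "individual_id"):
        self.ba_col = ba_col
        self.spline_df = spline_df
        self.reml = reml
        self.age_col = age_col
        self.sex_col = sex_col
        self.pair_col = pair_col
        self.id_col = id_col

    # -- fitting -----------------------------------------------------------

    def _design(self, df: pd.DataFrame, basis: NaturalSplineBasis,
                interaction: bool = False) -> np.ndarray:
        age = df[self.age_col].to_numpy(dtype=float)
        sex = df[self.sex_col].to_numpy(dtype=float)
        B = basis.transform(age)
        cols = [np.ones(len(df)), *B.T, sex]
        if interaction:
            cols.extend((B * sex[:, None]).T)
        return np.column_stack(cols)

    def _rows(self, df: pd.DataFrame) -> pd.DataFrame:
        need = [self.ba_col, self.age_col, self.sex_col, self.pair_col, self.id_col]
        return df.dropna(subset=need)

    def fit(self, df: pd.DataFrame, interaction: bool = False):
        rows = self._rows(df)
        if rows[self.pair_col].nunique() < 2 or len(rows) < 2:
            raise ValueError("need at least 2 pairs and 2 observations")
        basis = NaturalSplineBasis.from_data(
            rows[self.age_col].to_numpy(dtype=float), df=self.spline_df)
        X = self._design(rows, basis, interaction=interaction)
        res = NestedLMM(reml=self.reml).fit(
            rows[self.ba_col].to_numpy(dtype=float), X,
            rows[self.pair_col].to_numpy(), rows[self.id_col].to_numpy())
        self.basis_ = basis
        self.result_ = res
        self.interaction_ = interaction
        self.fe_params_ = res.fe_params
        self.fe_se_ = res.fe_se
        self.sigma2_pair_ = res.sigma2_pair
        self.sigma2_individual_ = res.sigma2_individual
        self.sigma2_resid_ = res.sigma2_resid
        self.llf_ = res.llf
        self.n_obs_ = res.n_obs
        self.n_individuals_ = res.n_individuals
        self.n_pairs_ = res.n_pairs
        self.train_index_ = rows.index
        return self

    # -- products ----------------------------------------------------------

    @property
    def sex_effect_(self) -> tuple[float, float]:
        """Woman-minus-man level shift and its standard error."""
        j = 1 + self.basis_.df
        return float(self.fe_params_[j]), float(self.fe_se_[j])

    def transform(self, df: pd.DataFrame | None = None,
                  kind: str = "eb") -> pd.Series:
        """Measurement-level BA residuals for the fitted rows.

        kind="eb" (default): observation - fixed effects - empirical-Bayes
        pair and individual intercepts.  kind="marginal": fixed effects only.
        Returned as a Series aligned to the fitting rows' index.
        """
        if df is not None and not df.index.equals(self.train_index_):
            raise ValueError(
                "residuals are defined for the rows the model was fitted on; "
                "refit on the new table instead"
            )
        return pd.Series(self.result_.resid(kind=kind), index=self.train_index_,
                         name=f"resid_{self.ba_col}")

    def population_curve(self, ca_grid, sex) -> pd.DataFrame:
        """Fixed-effect mean BA over an age grid for one sex (0/1).

        Rows outside the training age range are flagged as extrapolation
        (the natural spline continues linearly there).
        """
        ca_grid = np.asarray(ca_grid, dtype=float)
        B = self.basis_.transform(ca_grid)
        p = self.fe_params_
        mean = p[0] + B @ p[1:1 + self.basis_.df] + p[1 + self.basis_.df] * float(sex)
        if self.interaction_:
            mean = mean + (B * float(sex)) @ p[2 + self.basis_.df:]
        return pd.DataFrame({
            "ca": ca_grid, "sex": float(sex), "mean": mean,
            "extrapolated": self.basis_.is_extrapolating(ca_grid),
        })

    def to_json(self) -> str:
        return json.dumps({
            "ba_col": self.ba_col,
            "fe_params": self.fe_params_.tolist(),
            "fe_se": self.fe_se_.tolist(),
            "sigma2_pair": self.sigma2_pair_,
            "sigma2_individual": self.sigma2_individual_,
            "sigma2_resid": self.sigma2_resid_,
            "llf": self.llf_, "reml": self.reml,
            "basis": self.basis_.to_dict(),
            "n_obs": self.n_obs_, "n_individuals": self.n_individuals_,
            "n_pairs": self.n_pairs_,
        }, indent=2)


def sex_interaction_test(df: pd.DataFrame, ba_col: str, **kw) -> dict:
    """Likelihood-ratio test for a sex-by-age-spline interaction.

    Both the base model and the model adding sex x all spline columns are
    fitted by full maximum likelihood (REML likelihoods are not comparable
    across fixed-effect structures); the statistic 2*(llf1 - llf0) is
    referred to chi-square with df = spline df.
    """
    base = BATrajectoryModel(ba_col, reml=False, **kw).fit(df)
    full = BATrajectoryModel(ba_col, reml=False, **kw).fit(df, interaction=True)
    stat = max(0.0, 2.0 * (full.llf_ - base.llf_))
    dof = base.basis_.df
    return {"statistic": stat, "df": dof,
            "p_value": float(stats.chi2.sf(stat, dof)),
            "llf_base": base.llf_, "llf_interaction": full.llf_}


def fit_all_trajectories(cohort: pd.DataFrame, ba_cols: list[str],
                         **kw) -> dict[str, BATrajectoryModel]:
    """REML-fit one trajectory model per BA on its available rows."""
    return {c: BATrajectoryModel(c, **kw).fit(cohort) for c in ba_cols}


def add_residual_columns(cohort: pd.DataFrame,
                         models: dict[str, BATrajectoryModel],
                         kind: str = "eb") -> pd.DataFrame:
    """Join per-BA residual columns ``resid_<ba>`` onto the cohort table."""
    out = cohort.copy()
    for col, model in models.items():
        name = "resid_" + (col[3:] if col.startswith("ba_") else col)
        out[name] = model.transform(kind=kind)
    return out
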