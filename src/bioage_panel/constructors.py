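"""Construction of the nine biological-age measures from raw blocks.

Each constructor mirrors a standard recipe from the ageing-biomarker
literature:

* ``adjust_telomere`` — batch-mean centering of qPCR T/S ratios plus a
  single-pass mean +/- 4 SD outlier screen;
* ``EpigeneticClock`` — a frozen linear predictor over CpG beta values
  (weights + intercept, optional monotone output transform);
* ``KlemeraDoubalAge`` — the Klemera-Doubal biological-age estimator on
  principal components of screened, age-correlated biomarkers, calibrated
  per sex on a one-row-per-individual training subsample;
* ``CognitiveComposite`` — first principal component of four cognitive
  domain scores, anchored at wave 1 and T-scaled (mean 50, SD 10);
* ``FunctionalAgingIndex`` — sum of four wave-2-standardized functional
  indicators (sensory, pulmonary, grip, gait), oriented so higher = worse;
* ``frailty_index`` — deficit-accumulation ratio over 42 items.

All trained constructors are sklearn-style estimators (``fit`` freezes the
anchors; ``predict``/``transform`` apply them without refitting) and
serialize to JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "adjust_telomere",
    "EpigeneticClock",
    "screen_biomarkers",
    "KlemeraDoubalAge",
    "CognitiveComposite",
    "FunctionalAgingIndex",
    "frailty_index",
]


# ---------------------------------------------------------------------------
# telomere length

def adjust_telomere(ts, batches=None, n_sd: float = 4.0):
    """Batch-adjust T/S ratios and flag extreme outliers.

    Batch effects are removed by centering each batch on the grand mean of
    all non-missing values (one-way fixed-effect adjustment).  Outliers are
    flagged in a single pass: values beyond mean +/- ``n_sd`` * SD, both
    computed once on the batch-adjusted values.

    Returns
    -------
    adjusted : ndarray
        Batch-centered T/S ratios (outliers NOT removed; see ``excluded``).
    excluded : ndarray of bool
        True where the adjusted value falls outside the outlier band.
    """
    ts = np.asarray(ts, dtype=float)
    adjusted = ts.copy()
    ok = np.isfinite(ts)
    if batches is not None:
        batches = np.asarray(batches)
        grand = np.nanmean(ts[ok]) if ok.any() else np.nan
        ids = pd.unique(batches[ok])
        if len(ids) > 1:
            for b in ids:
                m = ok & (batches == b)
                adjusted[m] = ts[m] - np.nanmean(ts[m]) + grand
    mu = np.nanmean(adjusted[ok]) if ok.any() else np.nan
    sd = np.nanstd(adjusted[ok], ddof=1) if ok.sum() > 1 else 0.0
    excluded = np.zeros(ts.shape, dtype=bool)
    if sd > 0:
        excluded[ok] = np.abs(adjusted[ok] - mu) > n_sd * sd
    return adjusted, excluded


# ---------------------------------------------------------------------------
# epigenetic clocks

class EpigeneticClock:
    """Frozen linear DNA-methylation clock: age = f(intercept + w . betas).

    Parameters
    ----------
    name : str
    cpg_ids : sequence of str
        CpG identifiers, same length and order as ``weights``.
    weights : sequence of float
    intercept : float
    output_transform : callable, optional
        Monotone map applied to the linear predictor (identity default);
        hook for clocks calibrated on a transformed age scale.
    """

    def __init__(self, name, cpg_ids, weights, intercept=0.0, output_transform=None):
        cpg_ids = list(cpg_ids)
        weights = np.asarray(weights, dtype=float)
        if len(cpg_ids) != weights.size:
            raise ValueError("cpg_ids and weights must have equal length")
        self.name = name
        self.cpg_ids = cpg_ids
        self.weights = weights
        self.intercept = float(intercept)
        self.output_transform = output_transform

    def predict(self, betas: pd.DataFrame) -> np.ndarray:
        """Apply the clock to a table of beta values (columns = CpG ids)."""
        missing = [c for c in self.cpg_ids if c not in betas.columns]
        if missing:
            raise KeyError(f"clock {self.name!r}: missing CpGs {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))
        mat = betas[self.cpg_ids].to_numpy(dtype=float)
        finite = np.isfinite(mat)
        with np.errstate(invalid="ignore"):
            if np.any((mat[finite] < 0) | (mat[finite] > 1)):
                raise ValueError(f"clock {self.name!r}: beta values outside [0, 1]")
        pred = self.intercept + mat @ self.weights
        pred[~finite.all(axis=1)] = np.nan
        if self.output_transform is not None:
            pred = self.output_transform(pred)
        return pred

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "cpg_ids": self.cpg_ids,
                           "weights": self.weights.tolist(),
                           "intercept": self.intercept}, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "EpigeneticClock":
        d = json.loads(s)
        return cls(d["name"], d["cpg_ids"], d["weights"], d["intercept"])

    @classmethod
    def from_csv(cls, path, name=None, intercept=0.0) -> "EpigeneticClock":
        """Coefficients as CSV with columns (cpg_id, weight)."""
        tab = pd.read_csv(path)
        return cls(name or str(path), tab["cpg_id"].tolist(),
                   tab["weight"].to_numpy(), intercept)


# ---------------------------------------------------------------------------
# physiological age (PCA + Klemera-Doubal)

def screen_biomarkers(train: pd.DataFrame, age, candidates, threshold: float = 0.10,
                      signed: bool = False) -> list[str]:
    """Retain biomarkers whose Pearson correlation with age passes the screen.

    ``train`` must hold one row per individual (repeated measurements are
    subsampled upstream).  The default screen is |r| > threshold; a signed
    r > threshold variant is available since several biomarkers correlate
    negatively with age in the elderly.  Constant biomarkers are dropped.
    """
    age = np.asarray(age, dtype=float)
    kept = []
    for c in candidates:
        x = train[c].to_numpy(dtype=float)
        m = np.isfinite(x) & np.isfinite(age)
        if m.sum() < 3 or np.std(x[m]) == 0:
            continue
        r = np.corrcoef(x[m], age[m])[0, 1]
        stat = r if signed else abs(r)
        if stat > threshold:
            kept.append(c)
    return kept


class KlemeraDoubalAge(BaseEstimator):
    """Klemera-Doubal biological age over principal components of biomarkers.

    Training (per sex, on a one-row-per-individual subsample):

    1. standardize the screened biomarkers and extract principal components;
       retain PCs passing the same correlation-with-age screen;
    2. regress each retained PC on chronological age (OLS), giving intercept
       ``q_j``, slope ``k_j``, residual SD ``s_j`` and correlation ``r_j``;
    3. estimate the age-uncertainty variance ``s2_ba`` as
       ``max(eps, V - U)`` with ``V`` the sample variance of ``BA_E - CA``
       on the training data and ``U = ((1 - rchar2)/rchar2) * range(CA)^2 /
       (12 m)``, ``rchar2`` the mean squared PC-age correlation — the
       standard operationalization of the method's characteristic variance.

    Prediction combines markers and chronological age by inverse-variance
    weighting::

        BA_EC = [sum_j k_j (x_j - q_j) / s_j^2 + CA / s2_ba]
                / [sum_j k_j^2 / s_j^2 + 1 / s2_ba]

    ``predict(X, age=None)`` with ``age`` omitted returns the marker-only
    estimate ``BA_E`` (the ``s2_ba -> inf`` limit).
    """

    def __init__(self, pc_threshold: float = 0.10, signed_screen: bool = False,
                 eps_frac: float = 1e-6):
        self.pc_threshold = pc_threshold
        self.signed_screen = signed_screen
        self.eps_frac = eps_frac

    def fit(self, X: pd.DataFrame, age):
        age = np.asarray(age, dtype=float)
        X = pd.DataFrame(X)
        mask = np.isfinite(age) & X.notna().all(axis=1).to_numpy()
        Xv = X.loc[mask].to_numpy(dtype=float)
        agev = age[mask]
        if Xv.shape[0] < 30:
            raise ValueError("need at least 30 complete training rows per sex")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.center_ = Xv.mean(axis=0)
        self.scale_ = Xv.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            bad = self.feature_names_in_[self.scale_ == 0]
            raise ValueError(f"constant biomarkers in training data: {bad}")
        Z = (Xv - self.center_) / self.scale_

        # PCA on the correlation matrix via SVD; deterministic sign convention
        u, sing, vt = np.linalg.svd(Z, full_matrices=False)
        signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
        vt = vt * signs[:, None]
        scores = Z @ vt.T

        r_all = np.array([np.corrcoef(scores[:, j], agev)[0, 1]
                          for j in range(scores.shape[1])])
        keep = np.abs(r_all) > self.pc_threshold if not self.signed_screen \
            else r_all > self.pc_threshold
        if not keep.any():
            raise ValueError(
                "no principal component passes the age-correlation screen; "
                "review the threshold or the biomarker panel"
            )
        self.components_ = vt[keep]
        self.r_ = r_all[keep]
        m = int(keep.sum())

        # per-PC regression on age: x_j = q_j + k_j * CA + resid(s_j)
        S = scores[:, keep]
        q = np.empty(m); k = np.empty(m); s = np.empty(m)
        ca_c = agev - agev.mean()
        denom = np.sum(ca_c ** 2)
        for j in range(m):
            k[j] = np.sum(ca_c * (S[:, j] - S[:, j].mean())) / denom
            q[j] = S[:, j].mean() - k[j] * agev.mean()
            resid = S[:, j] - q[j] - k[j] * agev
            # floor keeps the noise-free calibration limit finite
            s[j] = max(np.sqrt(np.sum(resid ** 2) / max(1, len(agev) - 2)), 1e-8)
        if np.any(k == 0):
            raise ValueError("retained PC with zero age slope")
        self.q_, self.k_, self.s_ = q, k, s

        ba_e = self._ba_e(S)
        V = np.var(ba_e - agev, ddof=1)
        rchar2 = float(np.mean(self.r_ ** 2))
        rng_ca = float(agev.max() - agev.min())
        U = (1.0 - rchar2) / rchar2 * rng_ca ** 2 / (12.0 * m)
        eps = self.eps_frac * np.var(agev, ddof=1)
        self.s2_ba_ = max(eps, V - U)
        if V - U <= 0:
            import warnings
            warnings.warn("s2_ba estimate non-positive; floored", stacklevel=2)
        self.ca_range_ = (float(agev.min()), float(agev.max()))
        self.n_train_ = int(len(agev))
        return self

    def _project(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(dtype=float)
        Z = (X - self.center_) / self.scale_
        return Z @ self.components_.T

    def _ba_e(self, scores: np.ndarray) -> np.ndarray:
        w = self.k_ / self.s_ ** 2
        num = scores @ w - np.sum(self.q_ * w)
        den = np.sum(self.k_ ** 2 / self.s_ ** 2)
        return num / den

    def predict(self, X: pd.DataFrame, age=None) -> np.ndarray:
        """Physiological age; rows with any missing marker give NaN."""
        scores = self._project(X)
        ok = np.isfinite(scores).all(axis=1)
        out = np.full(scores.shape[0], np.nan)
        if age is None:
            out[ok] = self._ba_e(scores[ok])
            return out
        age = np.asarray(age, dtype=float)
        w = self.k_ / self.s_ ** 2
        num = scores[ok] @ w - np.sum(self.q_ * w) + age[ok] / self.s2_ba_
        den = np.sum(self.k_ ** 2 / self.s_ ** 2) + 1.0 / self.s2_ba_
        out[ok] = num / den
        return out

    def to_json(self) -> str:
        return json.dumps({
            "features": list(self.feature_names_in_),
            "center": self.center_.tolist(), "scale": self.scale_.tolist(),
            "components": self.components_.tolist(),
            "q": self.q_.tolist(), "k": self.k_.tolist(), "s": self.s_.tolist(),
            "r": self.r_.tolist(), "s2_ba": self.s2_ba_,
            "ca_range": list(self.ca_range_), "n_train": self.n_train_,
            "params": self.get_params(),
        }, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "KlemeraDoubalAge":
        d = json.loads(s)
        est = cls(**d["params"])
        est.feature_names_in_ = np.asarray(d["features"], dtype=object)
        est.center_ = np.asarray(d["center"])
        est.scale_ = np.asarray(d["scale"])
        est.components_ = np.asarray(d["components"])
        est.q_ = np.asarray(d["q"]); est.k_ = np.asarray(d["k"])
        est.s_ = np.asarray(d["s"]); est.r_ = np.asarray(d["r"])
        est.s2_ba_ = d["s2_ba"]; est.ca_range_ = tuple(d["ca_range"])
        est.n_train_ = d["n_train"]
        return est


# ---------------------------------------------------------------------------
# cognitive composite

class CognitiveComposite(BaseEstimator):
    """First-PC cognitive composite anchored at wave 1, on the T scale.

    ``fit`` freezes, from wave-1 rows: per-test mean/SD, first-principal-
    component scoring coefficients of the standardized tests, and the PC
    mean/SD used for T-scaling (mean 50, SD 10).  ``transform`` applies the
    frozen anchors to any rows; a row with any missing test gives NaN (PC
    scoring has no natural partial-missingness rule).
    """

    def __init__(self, t_mean: float = 50.0, t_sd: float = 10.0):
        self.t_mean = t_mean
        self.t_sd = t_sd

    def fit(self, tests: pd.DataFrame):
        tests = pd.DataFrame(tests)
        complete = tests.dropna()
        if len(complete) < 3:
            raise ValueError("need at least 3 complete anchor rows")
        self.feature_names_in_ = np.asarray(tests.columns, dtype=object)
        self.means_ = complete.mean().to_numpy()
        self.sds_ = complete.std(ddof=1).to_numpy()
        if np.any(self.sds_ == 0):
            raise ValueError("constant test score at the anchor wave")
        Z = (complete.to_numpy() - self.means_) / self.sds_
        cov = np.cov(Z, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        pc1 = vecs[:, -1]
        if pc1.sum() < 0:           # orient: higher composite = better scores
            pc1 = -pc1
        self.coef_ = pc1
        sc = Z @ pc1
        self.pc_mean_ = float(sc.mean())
        self.pc_sd_ = float(sc.std(ddof=1))
        return self

    def transform(self, tests: pd.DataFrame) -> np.ndarray:
        tests = pd.DataFrame(tests)[list(self.feature_names_in_)]
        Z = (tests.to_numpy(dtype=float) - self.means_) / self.sds_
        sc = Z @ self.coef_
        out = self.t_mean + self.t_sd * (sc - self.pc_mean_) / self.pc_sd_
        out[~np.isfinite(Z).all(axis=1)] = np.nan
        return out

    def to_json(self) -> str:
        return json.dumps({
            "features": list(self.feature_names_in_),
            "means": self.means_.tolist(), "sds": self.sds_.tolist(),
            "coef": self.coef_.tolist(), "pc_mean": self.pc_mean_,
            "pc_sd": self.pc_sd_, "params": self.get_params(),
        }, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "CognitiveComposite":
        d = json.loads(s)
        est = cls(**d["params"])
        est.feature_names_in_ = np.asarray(d["features"], dtype=object)
        est.means_ = np.asarray(d["means"]); est.sds_ = np.asarray(d["sds"])
        est.coef_ = np.asarray(d["coef"])
        est.pc_mean_ = d["pc_mean"]; est.pc_sd_ = d["pc_sd"]
        return est


# ---------------------------------------------------------------------------
# functional aging index

class FunctionalAgingIndex(BaseEstimator):
    """Sum of four standardized functional indicators, higher = worse.

    Vision and hearing (self-reported 1 = best .. 5 = worst) are first
    averaged into one sensory indicator.  The four indicators (sensory,
    pulmonary, grip, gait) are z-scored against wave-2 anchors and summed
    after orientation: indicators where larger raw values mean *better*
    functioning (pulmonary, grip strength, gait speed) enter with a minus
    sign.  A row missing any indicator gives NaN (the sum is undefined).
    """

    #: +1 keeps the indicator's direction, -1 flips "higher = better" scales
    DEFAULT_ORIENTATION = {"sensory": +1.0, "pulmonary": -1.0,
                           "grip": -1.0, "gait": -1.0}

    def __init__(self, orientation: dict | None = None):
        self.orientation = orientation

    def _indicators(self, df: pd.DataFrame) -> pd.DataFrame:
        sensory = df[["fn_vision", "fn_hearing"]].mean(axis=1, skipna=False)
        return pd.DataFrame({
            "sensory": sensory,
            "pulmonary": df["fn_pulmonary"],
            "grip": df["fn_grip"],
            "gait": df["fn_gait"],
        })

    def fit(self, df: pd.DataFrame):
        ind = self._indicators(pd.DataFrame(df)).dropna()
        if len(ind) < 3:
            raise ValueError("need at least 3 complete anchor rows")
        self.means_ = ind.mean()
        self.sds_ = ind.std(ddof=1)
        if (self.sds_ == 0).any():
            raise ValueError("constant functional indicator at the anchor wave")
        self.orientation_ = dict(self.DEFAULT_ORIENTATION)
        if self.orientation:
            self.orientation_.update(self.orientation)
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        ind = self._indicators(pd.DataFrame(df))
        z = (ind - self.means_) / self.sds_
        signs = pd.Series(self.orientation_)[z.columns]
        out = (z * signs).sum(axis=1, skipna=False)
        return out.to_numpy()

    def to_json(self) -> str:
        return json.dumps({
            "means": self.means_.to_dict(), "sds": self.sds_.to_dict(),
            "orientation": self.orientation_,
        }, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "FunctionalAgingIndex":
        d = json.loads(s)
        est = cls(orientation=d["orientation"])
        est.means_ = pd.Series(d["means"])
        est.sds_ = pd.Series(d["sds"])
        est.orientation_ = d["orientation"]
        return est


# ---------------------------------------------------------------------------
# frailty index

def frailty_index(deficits, min_fraction: float = 0.80) -> np.ndarray:
    """Deficit-accumulation frailty index on 42 items.

    FI = (number of deficits present) / (number of non-missing items),
    provided at least ``min_fraction`` of the 42 items are answered
    (>= 34 at the default); otherwise missing.
    """
    arr = np.asarray(deficits, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 42:
        raise ValueError(f"deficit vector must have 42 items, got {arr.shape[1]}")
    vals = arr[np.isfinite(arr)]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("deficit items must be 0, 1, or missing")
    answered = np.isfinite(arr).sum(axis=1)
    present = np.nansum(arr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = present / answered
    fi[answered < np.ceil(min_fraction * 42)] = np.nan
    return fi
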