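"""Seeded synthetic twin-cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: twin
pairs with pair- and individual-level random intercepts, birth years
1900-1948, nine possible in-person-testing waves spread over ~28 calendar
years, sex level-differences in every biological-age (BA) measure, curvature
(a change-point near age 70) in the three functional BAs and linear age
trends in the molecular/physiological BAs, BA-dependent Gompertz mortality
with staggered (left-truncated) entry, and administrative censoring at a
fixed calendar date.

Two layers are generated:

* **observed BA trajectories** ``ba_<name>``: fixed-effect curve + pair
  intercept + individual intercept + visit-level noise (always produced);
* **raw measurement blocks** (optional, ``include_raw=True``): CpG beta
  values with a stored invertible "true clock" per methylation BA,
  age-correlated blood/clinical biomarkers, percent-correct cognitive tests,
  functional indicators, 42 Bernoulli deficit items, and batch-offset
  telomere T/S ratios — so every constructor has a parameter-recovery test.

Mortality depends on the *latent* time-constant BA deviations (pair +
individual intercepts, standardized), never on noisy measured values, so
attenuation from measurement error is itself testable.  The truth ledger
records every latent value and parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import assign_birth_strata, validate_cohort

__all__ = [
    "BACurve",
    "SimulationTruth",
    "RawLayerSpec",
    "SimulatedCohort",
    "default_truth",
    "simulate_cohort",
    "make_missingness",
    "DEFAULT_WAVE_PATTERN",
    "BA_NAMES",
    "BLOCK_TO_BA",
]

BA_NAMES = [
    "telomere", "horvath", "hannum", "phenoage", "grimage",
    "physio", "cognitive", "fai", "fi",
]

#: calendar year of each in-person-testing wave (wave 4 was not an in-person visit)
WAVE_YEARS = {1: 1986.5, 2: 1989.5, 3: 1992.5, 5: 1998.5, 6: 2001.5,
              7: 2004.5, 8: 2007.5, 9: 2010.5, 10: 2013.5}

#: per-block wave availability mirroring the administrative design
DEFAULT_WAVE_PATTERN = {
    "telomere": {3, 5, 6, 8, 9},
    "methylation": {3, 5, 6, 8, 9},
    "biomarkers": {1, 2, 3, 5, 6, 7, 8, 9, 10},
    "cognitive": {1, 2, 3, 5, 6, 7, 8, 9},
    "functional": {2, 3, 5, 6, 7, 8, 9, 10},
    "deficits": {2, 3, 5, 6, 7, 8, 9, 10},
}

BLOCK_TO_BA = {
    "telomere": ["telomere"],
    "methylation": ["horvath", "hannum", "phenoage", "grimage"],
    "biomarkers": ["physio"],
    "cognitive": ["cognitive"],
    "functional": ["fai"],
    "deficits": ["fi"],
}

_REF_AGE = 65.0


@dataclass
class BACurve:
    """Fixed-effect age curve and variance components for one BA.

    ``level`` is the curve value for men at age 65; ``slope`` the yearly
    change; functional BAs get a linear-spline knot (``knot``) after which
    the slope increases by ``slope_increment``.  ``sex_shift`` is
    woman-minus-man.  ``log_hr_per_sd`` is the per-SD log hazard ratio of
    the time-constant latent deviation in the mortality model.
    """

    level: float
    slope: float
    sex_shift: float = 0.0
    knot: float | None = None
    slope_increment: float = 0.0
    sigma2_pair: float = 1.0
    sigma2_individual: float = 2.0
    sigma2_resid: float = 1.0
    log_hr_per_sd: float = 0.0
    log_hr_resid_per_sd: float = 0.0

    def mean(self, age, sex):
        age = np.asarray(age, dtype=float)
        out = self.level + self.slope * (age - _REF_AGE)
        if self.knot is not None:
            out = out + self.slope_increment * np.maximum(age - self.knot, 0.0)
        return out + self.sex_shift * np.asarray(sex, dtype=float)

    def latent_sd(self) -> float:
        return float(np.sqrt(self.sigma2_pair + self.sigma2_individual))


def _default_curves() -> dict[str, BACurve]:
    return {
        "telomere": BACurve(0.73, -0.004, sex_shift=+0.02,
                            sigma2_pair=0.004, sigma2_individual=0.008,
                            sigma2_resid=0.012, log_hr_per_sd=0.0),
        "horvath": BACurve(60.4, 0.85, sex_shift=-1.5,
                           sigma2_pair=8.0, sigma2_individual=16.0,
                           sigma2_resid=8.0, log_hr_per_sd=0.14),
        "hannum": BACurve(65.2, 0.85, sex_shift=-1.5,
                          sigma2_pair=8.0, sigma2_individual=16.0,
                          sigma2_resid=8.0, log_hr_per_sd=0.13),
        "phenoage": BACurve(63.8, 0.90, sex_shift=-1.0,
                            sigma2_pair=16.0, sigma2_individual=32.0,
                            sigma2_resid=16.0, log_hr_per_sd=0.20),
        "grimage": BACurve(69.4, 0.90, sex_shift=-2.0,
                           sigma2_pair=4.0, sigma2_individual=12.0,
                           sigma2_resid=4.0, log_hr_per_sd=0.33),
        "physio": BACurve(64.7, 1.00, sex_shift=0.0,
                          sigma2_pair=8.0, sigma2_individual=16.0,
                          sigma2_resid=10.0, log_hr_per_sd=0.12),
        "cognitive": BACurve(51.5, -0.35, sex_shift=0.0, knot=70.0,
                             slope_increment=-0.45,
                             sigma2_pair=20.0, sigma2_individual=40.0,
                             sigma2_resid=20.0, log_hr_per_sd=-0.17),
        "fai": BACurve(0.0, 0.08, sex_shift=+0.30, knot=70.0,
                       slope_increment=0.12,
                       sigma2_pair=0.5, sigma2_individual=1.0,
                       sigma2_resid=0.8, log_hr_per_sd=0.21),
        "fi": BACurve(0.10, 0.004, sex_shift=+0.01, knot=70.0,
                      slope_increment=0.004,
                      sigma2_pair=0.0008, sigma2_individual=0.0016,
                      sigma2_resid=0.0016, log_hr_per_sd=0.25),
    }


@dataclass
class SimulationTruth:
    """Scenario: cohort design, BA curves, and mortality model.

    Defaults mimic the scale of the motivating twin study: ~420 pairs born
    1900-1948, observed ages 50-90 across nine waves (1986-2014),
    administrative censoring in 2018, Gompertz baseline mortality hazard.
    """

    n_pairs: int = 420
    birth_year_range: tuple[int, int] = (1900, 1948)
    ca_range: tuple[float, float] = (50.0, 90.0)
    attendance: float = 0.75
    censor_year: float = 2018.62      # administrative cutoff (mid-August 2018)
    baseline_hazard: str = "gompertz"  # or "exponential" for closed-form checks
    gompertz_a: float = 0.013          # hazard at the 65-year reference age
    gompertz_b: float = 0.105          # log-hazard slope per year of age
    curves: dict[str, BACurve] = field(default_factory=_default_curves)
    #: optional blocks of BA names whose *visit-level* residuals are
    #: correlated (a shared time-varying factor beyond CA), as (names, rho)
    #: entries; this is the layer that survives mixed-model residualization
    residual_corr_blocks: list[tuple[list[str], float]] = field(default_factory=list)

    def validate(self) -> "SimulationTruth":
        for name, c in self.curves.items():
            if min(c.sigma2_pair, c.sigma2_individual, c.sigma2_resid) < 0:
                raise ValueError(f"negative variance component for {name}")
            if not (np.isfinite(c.log_hr_per_sd)
                    and np.isfinite(c.log_hr_resid_per_sd)):
                raise ValueError(f"non-finite hazard coefficient for {name}")
        if self.baseline_hazard not in ("gompertz", "exponential"):
            raise ValueError("baseline_hazard must be 'gompertz' or 'exponential'")
        return self

    def replace(self, **kw) -> "SimulationTruth":
        return dataclasses.replace(self, **kw)


def default_truth(**kw) -> SimulationTruth:
    return SimulationTruth(**kw).validate()


@dataclass
class RawLayerSpec:
    """Measurement layers linking raw blocks to the latent BA trajectories."""

    n_cpgs_per_clock: int = 25
    cpg_noise_sd: float = 0.008
    n_biomarkers: int = 10
    biomarker_noise_sd: float = 4.0
    cognitive_noise_sd: float = 6.0
    functional_noise_sd: float = 0.5
    telomere_batch_sd: float = 0.05
    deficit_steepness: float = 1.0

    def materialize(self, rng: np.random.Generator) -> dict:
        """Draw and freeze the layer coefficients (stored in the ledger)."""
        coef = {}
        clocks = {}
        cpg_index = 0
        for name in BLOCK_TO_BA["methylation"]:
            m = self.n_cpgs_per_clock
            ids = [f"cpg_{cpg_index + j:04d}" for j in range(m)]
            cpg_index += m
            slope = rng.uniform(0.15, 0.45, m) * rng.choice([-1, 1], m)
            # betas stay within [0,1] for latent ages in (0, 120)
            base = np.where(slope > 0, rng.uniform(0.05, 0.3, m),
                            rng.uniform(0.7, 0.95, m))
            # true linear clock inverting the noise-free layer
            w = 120.0 * slope / np.sum(slope ** 2)
            intercept = -float(w @ base)
            coef[name] = {"ids": ids, "base": base, "slope": slope}
            clocks[name] = {"cpg_ids": ids, "weights": w.tolist(),
                            "intercept": intercept}
        nb = self.n_biomarkers
        coef["biomarkers"] = {
            "names": [f"bm_{j:02d}" for j in range(nb)],
            "base": rng.uniform(20, 120, nb),
            # shared loading on the latent physiological age...
            "load": rng.uniform(0.3, 0.8, nb) * rng.choice([-1, 1], nb),
            # ...plus a heterogeneous direct age slope and a stable
            # marker-specific individual deviation (real panels are not
            # driven by a single common factor)
            "age_slope": rng.uniform(0.2, 0.8, nb) * rng.choice([-1, 1], nb),
            "idio_sd": rng.uniform(2.0, 4.0, nb),
        }
        coef["cognitive"] = {
            "names": ["cog_verbal", "cog_spatial", "cog_memory", "cog_speed"],
            "base": np.array([65.0, 55.0, 60.0, 50.0]),
            "load": np.array([0.9, 1.1, 1.0, 1.2]),
        }
        coef["deficits"] = {
            "offsets": rng.uniform(-0.06, 0.06, 42),
        }
        return {"coef": coef, "true_clocks": clocks}


@dataclass
class SimulatedCohort:
    cohort: pd.DataFrame
    survival: pd.DataFrame
    ledger: dict


class GenerationError(RuntimeError):
    pass


def _death_ages(truth: SimulationTruth, eta: np.ndarray, rng) -> np.ndarray:
    """Death age >= 50 from the scenario hazard h(t) = h0(t) * exp(eta).

    Survival to age 50 is assumed (the cohort design only observes ages
    50+); the Gompertz inverse transform is exact.
    """
    e = rng.exponential(1.0, size=eta.size)
    hr = np.exp(eta)
    if truth.baseline_hazard == "exponential":
        return 50.0 + e / (truth.gompertz_a * hr)
    a, b = truth.gompertz_a, truth.gompertz_b
    # H(t) = a/b [e^{b(t-65)} - e^{b(50-65)}] * hr  ->  invert at H = e
    return _REF_AGE + np.log(np.exp(b * (50.0 - _REF_AGE)) + b * e / (a * hr)) / b


def simulate_cohort(truth: SimulationTruth | None = None,
                    raw: RawLayerSpec | None = None,
                    seed: int = 0,
                    include_raw: bool = False) -> SimulatedCohort:
    """Generate one synthetic twin cohort.

    Returns the long-format cohort table, the per-individual survival table,
    and the truth ledger (all latent values and parameters).
    """
    truth = (truth or default_truth()).validate()
    rng = np.random.default_rng(seed)
    n_ind = 2 * truth.n_pairs
    names = list(truth.curves)

    pair_of_ind = np.repeat(np.arange(truth.n_pairs), 2)
    birth = rng.uniform(truth.birth_year_range[0], truth.birth_year_range[1] + 1,
                        truth.n_pairs)
    birth_of_ind = np.repeat(birth, 2)            # twins share a birth date
    sex = rng.integers(0, 2, n_ind).astype(float)

    # time-constant latent intercepts (independent across BAs)
    u_pair = {n: np.repeat(rng.normal(0.0, np.sqrt(truth.curves[n].sigma2_pair),
                                      truth.n_pairs), 2) for n in names}
    z = rng.standard_normal((n_ind, len(names)))
    u_ind = {n: z[:, j] * np.sqrt(truth.curves[n].sigma2_individual)
             for j, n in enumerate(names)}

    # optional cross-BA correlation of the visit-level residual layer
    corr = np.eye(len(names))
    for block, rho in truth.residual_corr_blocks:
        for a in block:
            for b in block:
                if a != b:
                    corr[names.index(a), names.index(b)] = rho
    noise_chol = np.linalg.cholesky(corr) if np.any(corr != np.eye(len(names))) \
        else None

    # candidate visit schedule: eligible, attended waves (death filter later)
    rows = []
    lo, hi = truth.ca_range
    attend_draw = rng.uniform(size=(n_ind, len(WAVE_YEARS)))
    for i in range(n_ind):
        for w_idx, (wave, year) in enumerate(sorted(WAVE_YEARS.items())):
            ca = year - birth_of_ind[i]
            if ca < lo or ca > hi or year > truth.censor_year:
                continue
            if attend_draw[i, w_idx] > truth.attendance:
                continue
            rows.append((i, wave, ca))
    if not rows:
        raise GenerationError(
            "infeasible scenario: no individual is ever eligible for a visit "
            f"(ca_range={truth.ca_range}, waves {min(WAVE_YEARS.values())}-"
            f"{max(WAVE_YEARS.values())})"
        )
    idx = np.array([r[0] for r in rows])
    wave = np.array([r[1] for r in rows])
    ca = np.array([r[2] for r in rows])

    # visit-level residual layer (optionally correlated across BAs)
    eps = rng.standard_normal((len(rows), len(names)))
    if noise_chol is not None:
        eps = eps @ noise_chol.T

    # mortality linear predictor: standardized time-constant deviations plus,
    # optionally, the standardized visit-level deviation at the first
    # (baseline) candidate visit
    eta = np.zeros(n_ind)
    for n in names:
        sd = truth.curves[n].latent_sd()
        if sd > 0 and truth.curves[n].log_hr_per_sd != 0.0:
            eta += truth.curves[n].log_hr_per_sd * (u_pair[n] + u_ind[n]) / sd
    resid_coefs = [(j, truth.curves[n].log_hr_resid_per_sd)
                   for j, n in enumerate(names)
                   if truth.curves[n].log_hr_resid_per_sd != 0.0]
    if resid_coefs:
        is_first = np.r_[True, idx[1:] != idx[:-1]]
        for j, coef in resid_coefs:
            eta[idx[is_first]] += coef * eps[is_first, j]

    death_age = _death_ages(truth, eta, rng)
    censor_age = truth.censor_year - birth_of_ind
    exit_age = np.minimum(death_age, censor_age)
    event = (death_age <= censor_age).astype(int)

    # visits after death are removed; individuals dead before their first
    # eligible visit never enter the cohort
    alive = ca < death_age[idx]
    if not alive.any():
        raise GenerationError("infeasible scenario: everyone dies before entry")
    idx, wave, ca, eps = idx[alive], wave[alive], ca[alive], eps[alive]

    df = pd.DataFrame({
        "pair_id": [f"P{pair_of_ind[i]:04d}" for i in idx],
        "individual_id": [f"I{i:04d}" for i in idx],
        "sex": sex[idx],
        "birth_year": np.floor(birth_of_ind[idx]).astype(int),
        "wave": wave,
        "ca": ca,
    })

    latent = {}
    for j, n in enumerate(names):
        c = truth.curves[n]
        mean = c.mean(ca, sex[idx])
        lat = mean + u_pair[n][idx] + u_ind[n][idx]
        df[f"ba_{n}"] = lat + np.sqrt(c.sigma2_resid) * eps[:, j]
        latent[f"latent_{n}"] = lat
    if "ba_fi" in df.columns:       # frailty index lives on [0, 1]
        df["ba_fi"] = df["ba_fi"].clip(0.0, 1.0)

    # covariates correlated with nothing by design (confounding is opt-in)
    edu = rng.choice(["primary", "lower secondary or vocational",
                      "upper secondary", "tertiary"], size=n_ind,
                     p=[0.58, 0.2, 0.12, 0.1])
    smoke = rng.choice(["non-smoker", "ex-smoker", "current smoker"],
                       size=n_ind, p=[0.75, 0.13, 0.12])
    bmi_base = rng.normal(25.7, 3.6, n_ind)
    df["education"] = edu[idx]
    df["smoking"] = smoke[idx]
    df["bmi"] = bmi_base[idx] + rng.normal(0, 0.8, len(df))
    df["exit_age"] = exit_age[idx]
    df["event"] = event[idx]

    if include_raw:
        missing = set(BA_NAMES) - set(names)
        if missing:
            raise ValueError(
                f"raw measurement layers need all nine BA curves; missing {missing}")
        raw = raw or RawLayerSpec()
        layers = raw.materialize(rng)
        raw_cols = _attach_raw_layers(df, latent, raw, layers, rng)
        df = pd.concat([df, pd.DataFrame(raw_cols, index=df.index)], axis=1)
    else:
        layers = None

    df = df.sort_values(["pair_id", "individual_id", "ca"], kind="mergesort")
    order = df.index.to_numpy()
    df = df.reset_index(drop=True)
    df = assign_birth_strata(df)
    validate_cohort(df)

    used = np.unique(idx)
    survival = pd.DataFrame({
        "individual_id": [f"I{i:04d}" for i in used],
        "pair_id": [f"P{pair_of_ind[i]:04d}" for i in used],
        "sex": sex[used],
        "birth_year": np.floor(birth_of_ind[used]).astype(int),
        "exit_age": exit_age[used],
        "event": event[used],
    })

    ledger = {
        "truth": truth,
        "raw_spec": raw,
        "raw_layers": layers,
        "seed": seed,
        "u_pair": {n: u_pair[n][::2].copy() for n in names},     # one per pair
        "u_individual": u_ind,
        "eta": eta,
        "death_age": death_age,
        "censor_age": censor_age,
        "n_excluded_dead_before_entry": int(
            n_ind - len(used)
        ),
        "latent": pd.DataFrame(
            {k: v[order] for k, v in latent.items()},
            index=df.index,
        ).assign(individual_id=df["individual_id"], wave=df["wave"]),
    }
    return SimulatedCohort(cohort=df, survival=survival, ledger=ledger)


def _attach_raw_layers(df, latent, raw: RawLayerSpec, layers: dict, rng) -> dict:
    coef = layers["coef"]
    n = len(df)
    new: dict[str, np.ndarray] = {}

    # telomere: latent T/S plus wave-batch offsets
    waves = sorted(WAVE_YEARS)
    batch_off = dict(zip(waves, rng.normal(0.0, raw.telomere_batch_sd, len(waves))))
    new["tl_ts"] = latent["latent_telomere"] + df["wave"].map(batch_off).to_numpy()
    new["tl_batch"] = df["wave"].astype(int).to_numpy()
    layers["telomere_batch_offsets"] = {int(k): float(v) for k, v in batch_off.items()}

    # methylation: per-clock CpG panels, betas linear in the latent age
    for name in BLOCK_TO_BA["methylation"]:
        c = coef[name]
        g = latent[f"latent_{name}"] / 120.0
        betas = (c["base"][None, :] + c["slope"][None, :] * g[:, None]
                 + rng.normal(0.0, raw.cpg_noise_sd, (n, len(c["ids"]))))
        betas = np.clip(betas, 0.0, 1.0)
        for j, cid in enumerate(c["ids"]):
            new[cid] = betas[:, j]

    # biomarkers: shared physiological-age loading + direct age slope +
    # stable marker-specific individual deviation + visit noise
    c = coef["biomarkers"]
    g = latent["latent_physio"]
    age = df["ca"].to_numpy(dtype=float)
    ind_codes, ind_inv = np.unique(df["individual_id"].to_numpy(), return_inverse=True)
    idio = rng.normal(0.0, 1.0, (len(ind_codes), len(c["names"])))
    for j, nm in enumerate(c["names"]):
        new[nm] = (c["base"][j] + c["load"][j] * (g - _REF_AGE)
                   + c["age_slope"][j] * (age - _REF_AGE)
                   + c["idio_sd"][j] * idio[ind_inv, j]
                   + rng.normal(0.0, raw.biomarker_noise_sd, n))

    # cognitive tests: percent-correct, loading on the latent composite
    c = coef["cognitive"]
    g = latent["latent_cognitive"]
    for j, nm in enumerate(c["names"]):
        new[nm] = np.clip(c["base"][j] + c["load"][j] * (g - 50.0)
                          + rng.normal(0.0, raw.cognitive_noise_sd, n), 0.0, 100.0)

    # functional indicators; orientation: vision/hearing 1(best)-5(worst),
    # pulmonary/grip/gait higher = better
    zf = (latent["latent_fai"]) / max(1e-12, np.std(latent["latent_fai"]))
    noise = lambda s: rng.normal(0.0, s, n)
    new["fn_vision"] = np.clip(np.round(2.5 + 0.6 * zf + noise(raw.functional_noise_sd)), 1, 5)
    new["fn_hearing"] = np.clip(np.round(2.5 + 0.6 * zf + noise(raw.functional_noise_sd)), 1, 5)
    new["fn_pulmonary"] = 3.0 - 0.4 * zf + noise(0.3)
    new["fn_grip"] = 30.0 - 3.5 * zf + noise(2.0)
    new["fn_gait"] = 1.2 - 0.15 * zf + noise(0.08)

    # deficits: 42 Bernoulli items with probability centred on the latent FI
    c = coef["deficits"]
    p = np.clip(latent["latent_fi"][:, None] + c["offsets"][None, :]
                * raw.deficit_steepness, 0.005, 0.95)
    items = (rng.uniform(size=(n, 42)) < p).astype(float)
    for j in range(42):
        new[f"def_{j + 1:02d}"] = items[:, j]

    return new


#: fraction of individuals in whom each block was assayed at all (sub-study
#: participation: methylation arrays were run on roughly half the cohort)
DEFAULT_INDIVIDUAL_AVAILABILITY = {
    "telomere": 0.75,
    "methylation": 0.46,
    "biomarkers": 0.95,
    "cognitive": 0.98,
    "functional": 0.87,
    "deficits": 0.89,
}


def make_missingness(cohort: pd.DataFrame,
                     pattern: dict[str, set] | None = None,
                     individual_availability: dict[str, float] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Blank measurement blocks outside their administratively available waves.

    ``pattern`` maps block names (see :data:`BLOCK_TO_BA`) to the set of
    waves where that block was collected; anything outside is set missing,
    both for raw columns and for the corresponding observed-BA columns.
    ``individual_availability`` additionally blanks a block for a seeded
    random subset of individuals, emulating sub-study participation.
    An empty pattern with availability 1.0 returns the cohort unchanged.
    """
    if pattern is None:
        pattern = DEFAULT_WAVE_PATTERN
    if individual_availability is None:
        individual_availability = DEFAULT_INDIVIDUAL_AVAILABILITY
    unknown = (set(pattern) | set(individual_availability)) - set(BLOCK_TO_BA)
    if unknown:
        raise KeyError(f"unknown measurement blocks in pattern: {sorted(unknown)}")
    df = cohort.copy()
    from .cohort import block_columns

    rng = np.random.default_rng(seed)
    individuals = np.sort(df["individual_id"].unique())

    def cols_for(block):
        cols = block_columns(df, block)
        cols += [f"ba_{n}" for n in BLOCK_TO_BA[block] if f"ba_{n}" in df.columns]
        if block == "telomere" and "tl_batch" in df.columns:
            cols.append("tl_batch")
        return cols

    for block, waves in pattern.items():
        mask = ~df["wave"].isin(list(waves))
        cols = cols_for(block)
        if cols:
            df.loc[mask, cols] = np.nan
    for block in sorted(individual_availability):
        p = individual_availability[block]
        if p >= 1.0:
            continue
        dropped = individuals[rng.uniform(size=individuals.size) >= p]
        cols = cols_for(block)
        if cols and dropped.size:
            df.loc[df["individual_id"].isin(dropped), cols] = np.nan
    return df


def complete_case_filter(cohort: pd.DataFrame, ba_cols: list[str]) -> pd.DataFrame:
    """Keep only visits at which every listed BA is observed."""
    mask = cohort[ba_cols].notna().all(axis=1)
    return cohort.loc[mask].copy()
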