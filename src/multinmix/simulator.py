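"""Generative simulator of community capture-history surveys.

Draws data from the full multispecies Poisson-lognormal N-mixture
model: per-survey residual vectors eps_i ~ MVN(0, Sigma), latent
abundances N_ik ~ Poisson(exp(mu_ik + eps_ik)), and, for each of the
N_ik individuals, a J-vector of Bernoulli(p_ik) detections.  Individuals
never detected are dropped from the observed layer but retained in the
truth record, exactly mirroring what a field survey can and cannot see.

The simulator doubles as the package's test oracle (its moments obey
the closed-form mean/variance/covariance identities of the mixture) and
as a stand-in for real survey data: ``write_fixture`` emits the same
three-file CSV layout the ingest module reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import CaptureRecord, DetectionFrequencyTable, build_frequency_table

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate", "write_fixture"]

TRUTH_FORMAT_VERSION = 1

_BLOCK_TIMES = {"early": "06:00", "middle": "07:30", "late": "09:00"}


@dataclass
class SimulationConfig:
    """True parameters and survey geometry for one synthetic community.

    Surveys are the cross product of ``n_locations`` survey points and
    ``n_dates`` visit dates (I = n_locations * n_dates), as in repeated
    point-count designs.  Abundance covariates are PC-score-like i.i.d.
    standard normals attached to locations; day of year is uniform over
    a 52-day breeding-season window and time block uniform over the
    three morning blocks.

    ``beta[k]`` / ``alpha[k]`` are intercept-first coefficient vectors on
    the log / logit scale; ``abundance_terms[k]`` / ``detection_terms[k]``
    name the covariate columns each non-intercept coefficient multiplies.
    """

    n_locations: int = 100
    n_dates: int = 3
    K: int = 1
    J: int = 4
    beta: list = field(default_factory=lambda: [np.array([0.0])])
    alpha: list = field(default_factory=lambda: [np.array([0.0])])
    Sigma: np.ndarray | None = None  # None => no extra-Poisson noise (eps = 0)
    abundance_terms: list = field(default_factory=list)  # per species
    detection_terms: list = field(default_factory=list)
    n_covariates: int = 8
    day_window: tuple = (141, 192)  # 21 May .. 11 Jul
    seed: int = 0
    observed_layer: bool = True  # False: truth only (moment studies at large I)

    @property
    def I(self) -> int:  # noqa: E743
        return self.n_locations * self.n_dates

    def __post_init__(self):
        self.beta = [np.atleast_1d(np.asarray(b, dtype=float)) for b in self.beta]
        self.alpha = [np.atleast_1d(np.asarray(a, dtype=float)) for a in self.alpha]
        if len(self.beta) != self.K or len(self.alpha) != self.K:
            raise ValueError("need one beta and one alpha vector per species")
        if not self.abundance_terms:
            self.abundance_terms = [[] for _ in range(self.K)]
        if not self.detection_terms:
            self.detection_terms = [[] for _ in range(self.K)]
        if self.Sigma is not None:
            self.Sigma = np.asarray(self.Sigma, dtype=float)
            if self.Sigma.shape != (self.K, self.K):
                raise ValueError("Sigma must be K x K")
            if not np.allclose(self.Sigma, self.Sigma.T):
                raise ValueError("Sigma must be symmetric")
            if np.linalg.eigvalsh(self.Sigma).min() <= 0:
                raise ValueError("Sigma must be positive definite")
        if min(self.n_locations, self.n_dates, self.K, self.J) < 1:
            raise ValueError("n_locations, n_dates, K, J must all be >= 1")


@dataclass
class SyntheticDataset:
    """Truth plus the observed layer of one simulated community survey."""

    config: SimulationConfig
    covariates: pd.DataFrame  # per survey: PC scores, day_of_year, time_block
    surveys: pd.DataFrame
    species: list
    mu: np.ndarray  # (I, K) linear predictors
    epsilon: np.ndarray  # (I, K) lognormal residuals
    N: np.ndarray  # (I, K) true abundances
    p: np.ndarray  # (I, K) per-interval detection probabilities
    records: list  # observed CaptureRecords (>= 1 detection each)
    frequency_table: DetectionFrequencyTable

    @property
    def truth(self) -> dict:
        return {
            "version": TRUTH_FORMAT_VERSION,
            "beta": [b.tolist() for b in self.config.beta],
            "alpha": [a.tolist() for a in self.config.alpha],
            "Sigma": None if self.config.Sigma is None else self.config.Sigma.tolist(),
            "N": self.N.tolist(),
            "epsilon": self.epsilon.tolist(),
            "seed": self.config.seed,
        }


def _species_codes(K: int) -> list:
    return [f"SP{k + 1:02d}" for k in range(K)]


def _design_from(cov: pd.DataFrame, terms, coef: np.ndarray) -> np.ndarray:
    """Linear predictor intercept + sum_t coef_t * cov[t] (time_block -> 2 dummies)."""
    from .single_species import build_design

    X = build_design(cov, terms)
    if X.shape[1] != len(coef):
        raise ValueError(
            f"coefficient vector length {len(coef)} does not match design "
            f"width {X.shape[1]} for terms {list(terms)}"
        )
    return X @ coef


def simulate(config: SimulationConfig, rng=None) -> SyntheticDataset:
    """Draw one synthetic community survey dataset from the model."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    I, K, J = config.I, config.K, config.J

    locs = [f"L{i + 1:03d}" for i in range(config.n_locations)]
    day0 = np.array(sorted(rng.choice(
        np.arange(config.day_window[0], config.day_window[1] + 1),
        size=config.n_dates, replace=False)))
    dates = [f"1983-{_doy_to_date(d)}" for d in day0]
    loc_scores = rng.standard_normal((config.n_locations, config.n_covariates))
    blocks = rng.choice(["early", "middle", "late"], size=I)

    rows = []
    for li, loc in enumerate(locs):
        for di, date in enumerate(dates):
            i = li * config.n_dates + di
            rows.append({"survey_id": f"{loc}:{date}", "location": loc,
                         "date": date, "day_of_year": int(day0[di]),
                         "time_block": blocks[i],
                         "time": _BLOCK_TIMES[blocks[i]], "has_history": True})
    surveys = pd.DataFrame(rows)
    cov = pd.DataFrame(
        np.repeat(loc_scores, config.n_dates, axis=0),
        columns=[f"X{m + 1}" for m in range(config.n_covariates)],
    )
    cov["day_of_year"] = surveys["day_of_year"].to_numpy(float)
    cov["day_of_year"] = (cov["day_of_year"] - cov["day_of_year"].mean())
    sd = cov["day_of_year"].std(ddof=1)
    if sd > 0:
        cov["day_of_year"] /= sd
    cov["time_block"] = surveys["time_block"].to_numpy()

    mu = np.column_stack([
        _design_from(cov, config.abundance_terms[k], config.beta[k])
        for k in range(K)
    ])
    logit_p = np.column_stack([
        _design_from(cov, config.detection_terms[k], config.alpha[k])
        for k in range(K)
    ])
    p = 1.0 / (1.0 + np.exp(-logit_p))

    if config.Sigma is None:
        eps = np.zeros((I, K))
    else:
        L = np.linalg.cholesky(config.Sigma)
        eps = rng.standard_normal((I, K)) @ L.T
    lam = np.exp(mu + eps)
    N = rng.poisson(lam)

    species = _species_codes(K)
    records = []
    if not config.observed_layer:
        freq = DetectionFrequencyTable(
            counts=np.zeros((I, K, J), dtype=np.int64), surveys=surveys,
            species=species)
        return SyntheticDataset(config=config, covariates=cov, surveys=surveys,
                                species=species, mu=mu, epsilon=eps, N=N, p=p,
                                records=records, frequency_table=freq)
    for i in range(I):
        srow = surveys.iloc[i]
        for k in range(K):
            if N[i, k] == 0:
                continue
            hist = rng.random((N[i, k], J)) < p[i, k]
            hist = hist[hist.any(axis=1)]
            for h in hist.astype(int):
                records.append(CaptureRecord(
                    location_id=srow["location"], survey_date=srow["date"],
                    species_code=species[k], history=tuple(int(v) for v in h),
                    time_block=srow["time_block"],
                    day_of_year=int(srow["day_of_year"])))

    freq = build_frequency_table(records, surveys, species, J)
    return SyntheticDataset(config=config, covariates=cov, surveys=surveys,
                            species=species, mu=mu, epsilon=eps, N=N, p=p,
                            records=records, frequency_table=freq)


def _doy_to_date(doy: int) -> str:
    import datetime as dt

    d = dt.date(1983, 1, 1) + dt.timedelta(days=int(doy) - 1)
    return f"{d.month:02d}-{d.day:02d}"


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict:
    """Emit the three-file CSV layout plus a truth JSON; returns the paths.

    The observations file holds one row per observed individual (with
    its interval history h1..hJ) and one species-blank marker row per
    survey with no detections, so the full survey grid round-trips.  The
    habitat file carries the per-location covariate scores; the species
    file the code list.  Fixed seed => byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    J = dataset.config.J
    hcols = [f"h{j + 1}" for j in range(J)]

    obs_rows = []
    seen = set()
    for rec in dataset.records:
        seen.add((rec.location_id, rec.survey_date))
        row = {"location": rec.location_id, "date": rec.survey_date,
               "time": _BLOCK_TIMES[rec.time_block], "species": rec.species_code}
        row.update({c: h for c, h in zip(hcols, rec.history)})
        obs_rows.append(row)
    # marker rows keep empty survey slots on the grid; a fully empty
    # community writes a header-only file
    for srow in (dataset.surveys.itertuples(index=False) if dataset.records else ()):
        if (srow.location, srow.date) not in seen:
            row = {"location": srow.location, "date": srow.date,
                   "time": srow.time, "species": ""}
            row.update({c: "" for c in hcols})
            obs_rows.append(row)
    obs = pd.DataFrame(obs_rows, columns=["location", "date", "time", "species"] + hcols)
    obs = obs.sort_values(["location", "date", "species"], kind="stable")

    per_loc = (dataset.covariates
               .assign(location=dataset.surveys["location"].to_numpy())
               .drop(columns=["day_of_year", "time_block"])
               .groupby("location", sort=True).first().reset_index())

    species = pd.DataFrame({"species": dataset.species,
                            "common_name": dataset.species})

    paths = {"observations": out / "observations.csv",
             "habitat": out / "habitat.csv",
             "species": out / "species.csv",
             "truth": out / "truth.json"}
    obs.to_csv(paths["observations"], index=False)
    per_loc.to_csv(paths["habitat"], index=False, float_format="%.10g")
    species.to_csv(paths["species"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
    return paths
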