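"""Survey-data ingest, detection-frequency tables, and PCA covariate scores.

Point-count surveys record, for every individual bird detected, a
"capture history": a binary vector saying in which of the J observation
intervals of the survey that individual was detected.  The sufficient
summary of these histories for the N-mixture likelihoods is the
detection-frequency table Y[i, k, j]: the number of individuals of
species k detected exactly j times (j = 1..J) in survey i.  The j = 0
cell is unobservable (undetected individuals leave no record).

Data arrive in a three-file layout: an observations file (one row per
detected individual, plus optional species-blank marker rows for surveys
where nothing was detected), a habitat file (one row per survey
location, raw landscape / vegetation measurements), and a species-code
list.  Column names are configurable through a schema mapping.

Abundance covariates are principal-component scores computed from the
correlation matrix of the habitat measurements (so they are invariant
to the units each measurement was taken in); detection covariates are
the day of year and a three-level time-of-day block.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ReferentialIntegrityError",
    "DataError",
    "DegenerateCovariateError",
    "CaptureRecord",
    "DetectionFrequencyTable",
    "CovariateScores",
    "DEFAULT_SCHEMA",
    "read_survey_files",
    "build_frequency_table",
    "pca_scores",
    "time_block",
    "standardize_day_of_year",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ReferentialIntegrityError(ValueError):
    """An observation refers to a species code absent from the species list."""


class DataError(ValueError):
    """A record violates a structural invariant (e.g. an all-zero history)."""


class DegenerateCovariateError(ValueError):
    """A covariate column is constant or contains missing values."""


#: Logical field -> column header expected in the delimited input files.
#: Override any entry via the ``schema`` argument of :func:`read_survey_files`.
DEFAULT_SCHEMA = {
    "location": "location",
    "date": "date",
    "time": "time",
    "species": "species",
    "history_prefix": "h",  # interval columns h1..hJ
}

TIME_BLOCKS = ("early", "middle", "late")


@dataclass(frozen=True)
class CaptureRecord:
    """One detected individual: where, when, what, and its capture history."""

    location_id: str
    survey_date: str
    species_code: str
    history: tuple  # 0/1 per interval, length J, at least one 1
    time_block: str
    day_of_year: int

    def __post_init__(self):
        if len(self.history) < 1:
            raise DataError("capture history must have length >= 1")
        if sum(self.history) == 0:
            raise DataError(
                "all-zero capture history: undetected individuals cannot be recorded"
            )


@dataclass
class DetectionFrequencyTable:
    """Y[i, k, j-1] = individuals of species k detected exactly j times in survey i."""

    counts: np.ndarray  # (I, K, J) non-negative ints
    surveys: pd.DataFrame  # one row per survey: survey_id, location, date, covariates
    species: list  # ordered species codes, length K

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (surveys, species, J) array")
        if (self.counts < 0).any():
            raise ValueError("detection-frequency counts must be non-negative")
        if len(self.surveys) != self.counts.shape[0]:
            raise ValueError("survey metadata length does not match counts")
        if len(self.species) != self.counts.shape[1]:
            raise ValueError("species list length does not match counts")

    @property
    def I(self) -> int:  # noqa: E743 - conventional symbol
        return self.counts.shape[0]

    @property
    def K(self) -> int:
        return self.counts.shape[1]

    @property
    def J(self) -> int:
        return self.counts.shape[2]

    def totals(self) -> np.ndarray:
        """D[i, k] = number of distinct individuals recorded for (i, k)."""
        return self.counts.sum(axis=2)

    def species_slice(self, code: str) -> np.ndarray:
        """The (I, J) frequency matrix of one species."""
        return self.counts[:, self.species.index(code), :]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long form: survey_id, species_code, j, count."""
        I, K, J = self.counts.shape
        sid = np.repeat(self.surveys["survey_id"].to_numpy(), K * J)
        sp = np.tile(np.repeat(np.asarray(self.species, dtype=object), J), I)
        j = np.tile(np.arange(1, J + 1), I * K)
        return pd.DataFrame(
            {"survey_id": sid, "species_code": sp, "j": j,
             "count": self.counts.reshape(-1)}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   surveys: pd.DataFrame | None = None) -> "DetectionFrequencyTable":
        """Rebuild from the tidy long form written by :meth:`write_csv`."""
        sids = list(dict.fromkeys(frame["survey_id"]))
        species = list(dict.fromkeys(frame["species_code"]))
        J = int(frame["j"].max())
        counts = np.zeros((len(sids), len(species), J), dtype=np.int64)
        si = {s: i for i, s in enumerate(sids)}
        ki = {s: k for k, s in enumerate(species)}
        for sid, sp, j, c in frame[["survey_id", "species_code", "j", "count"]].itertuples(index=False):
            counts[si[sid], ki[sp], int(j) - 1] = int(c)
        if surveys is None:
            surveys = pd.DataFrame({"survey_id": sids})
        return cls(counts=counts, surveys=surveys, species=species)

    @classmethod
    def read_csv(cls, path, surveys: pd.DataFrame | None = None):
        return cls.from_frame(pd.read_csv(path), surveys)


@dataclass
class CovariateScores:
    """Principal-component scores of a habitat-measurement matrix.

    The decomposition uses the correlation matrix, so scores do not
    depend on the units of the raw measurements.  ``variance_explained``
    covers *all* components (it sums to 1); ``scores``/``loadings`` keep
    only the requested leading components.
    """

    scores: pd.DataFrame  # rows = survey points, cols = <prefix>1..<prefix>m
    loadings: pd.DataFrame  # rows = measurements, cols = components
    variance_explained: np.ndarray  # all components, non-increasing, sums to 1
    prefix: str = "PC"

    def cumulative_explained(self, m: int) -> float:
        return float(self.variance_explained[:m].sum())


# ---------------------------------------------------------------------------
# Ingest
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols, filename: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{filename}: missing required column {c!r}")


def _day_of_year(date_str: str) -> int:
    return _dt.date.fromisoformat(str(date_str)).timetuple().tm_yday


def read_survey_files(observations_path, habitat_path, species_path,
                      schema: dict | None = None):
    """Read the three-file survey layout.

    Returns ``(records, surveys, habitat, species_table)`` where
    ``records`` is a list of :class:`CaptureRecord`, ``surveys`` is a
    DataFrame with one row per survey slot (location x date, flagged
    ``has_history`` where interval-level data exist), ``habitat`` is the
    raw per-location measurement table indexed by location, and
    ``species_table`` the species-code list.

    Rows with a blank species field are survey markers: they register
    the survey slot (and its time of day) without contributing a bird.
    Rows whose interval columns are all missing flag the survey as
    lacking capture histories; such surveys are retained in ``surveys``
    but excluded from likelihood-ready records.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)

    obs = pd.read_csv(observations_path, dtype=str, keep_default_na=False)
    hab = pd.read_csv(habitat_path)
    spt = pd.read_csv(species_path, dtype=str, keep_default_na=False)

    _require_columns(obs, [sch["location"], sch["date"], sch["species"]],
                     "observations")
    _require_columns(hab, [sch["location"]], "habitat")
    _require_columns(spt, [sch["species"]], "species list")

    hcols = sorted(
        (c for c in obs.columns if c.startswith(sch["history_prefix"])
         and c[len(sch["history_prefix"]):].isdigit()),
        key=lambda c: int(c[len(sch["history_prefix"]):]),
    )

    known_species = set(spt[sch["species"]])

    records: list[CaptureRecord] = []
    survey_meta: dict[tuple, dict] = {}
    no_history_surveys: set[tuple] = set()

    for row in obs.itertuples(index=False):
        rowd = row._asdict() if hasattr(row, "_asdict") else dict(zip(obs.columns, row))
        loc = str(rowd[sch["location"]])
        date = str(rowd[sch["date"]])
        key = (loc, date)
        meta = survey_meta.setdefault(
            key, {"location": loc, "date": date,
                  "time": rowd.get(sch["time"], ""), "day_of_year": _day_of_year(date)}
        )
        if not meta["time"] and rowd.get(sch["time"], ""):
            meta["time"] = rowd[sch["time"]]
        sp = str(rowd[sch["species"]]).strip()
        if sp == "":
            continue  # survey marker row
        if sp not in known_species:
            raise ReferentialIntegrityError(
                f"species code {sp!r} not present in the species list"
            )
        hvals = [str(rowd.get(c, "")).strip() for c in hcols]
        if all(v == "" for v in hvals):
            no_history_surveys.add(key)
            continue
        history = tuple(int(v) for v in hvals)
        records.append(
            CaptureRecord(
                location_id=loc,
                survey_date=date,
                species_code=sp,
                history=history,
                time_block=time_block(meta["time"]) if meta["time"] else "",
                day_of_year=meta["day_of_year"],
            )
        )

    # Survey slots = cross product of observed locations and dates, so that
    # surveys where no bird was detected still contribute all-zero rows.
    locs = sorted({k[0] for k in survey_meta} | set(hab[sch["location"]].astype(str)))
    dates = sorted({k[1] for k in survey_meta})
    rows = []
    for loc in locs:
        for date in dates:
            meta = survey_meta.get((loc, date),
                                   {"location": loc, "date": date, "time": "",
                                    "day_of_year": _day_of_year(date)})
            rows.append({
                "survey_id": f"{loc}:{date}",
                "location": loc,
                "date": date,
                "time": meta["time"],
                "day_of_year": meta["day_of_year"],
                "time_block": time_block(meta["time"]) if meta["time"] else "",
                "has_history": (loc, date) not in no_history_surveys,
            })
    surveys = pd.DataFrame(rows)

    hab = hab.copy()
    hab[sch["location"]] = hab[sch["location"]].astype(str)
    hab = hab.set_index(sch["location"])

    return records, surveys, hab, spt


def build_frequency_table(records, surveys: pd.DataFrame, species, J: int
                          ) -> DetectionFrequencyTable:
    """Aggregate capture records into the Y[i, k, j] frequency table.

    A survey with no record of species k yields an all-zero row — a
    legal observation, not missing data.  Every record's history must
    have length J and at least one detection.
    """
    species = list(species)
    sp_idx = {s: k for k, s in enumerate(species)}
    sid_idx = {
        (r.location, r.date): i for i, r in enumerate(surveys.itertuples(index=False))
    }
    counts = np.zeros((len(surveys), len(species), J), dtype=np.int64)
    for rec in records:
        if len(rec.history) != J:
            raise DataError(
                f"history length {len(rec.history)} != J={J} for record at "
                f"{rec.location_id}:{rec.survey_date}"
            )
        j = int(sum(rec.history))
        if j == 0:
            raise DataError("all-zero capture history in records")
        i = sid_idx[(rec.location_id, rec.survey_date)]
        k = sp_idx[rec.species_code]
        counts[i, k, j - 1] += 1
    return DetectionFrequencyTable(counts=counts, surveys=surveys.copy(),
                                   species=species)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def pca_scores(measurements: pd.DataFrame, n_components: int,
               prefix: str = "PC") -> CovariateScores:
    """Correlation-matrix PCA of a survey-point measurement table.

    Each column is standardized to zero mean and unit variance before
    the eigendecomposition, which makes the scores invariant to affine
    rescaling of any input column.  Components are oriented so that the
    largest-magnitude loading of each is positive (a deterministic sign
    convention; eigenvectors are otherwise sign-ambiguous).
    """
    X = measurements.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 survey points")
    if np.isnan(X).any():
        raise DegenerateCovariateError(
            "missing values in covariate measurements; imputation is refused"
        )
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = measurements.columns[np.where(sd == 0)[0]].tolist()
        raise DegenerateCovariateError(f"constant covariate column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for m in range(eigvec.shape[1]):
        imax = np.argmax(np.abs(eigvec[:, m]))
        if eigvec[imax, m] < 0:
            eigvec[:, m] = -eigvec[:, m]
    var_explained = eigval / eigval.sum()
    comp_names = [f"{prefix}{m + 1}" for m in range(n_components)]
    loadings = pd.DataFrame(eigvec[:, :n_components],
                            index=measurements.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec[:, :n_components],
                          index=measurements.index, columns=comp_names)
    return CovariateScores(scores=scores, loadings=loadings,
                           variance_explained=var_explained, prefix=prefix)


def abundance_covariates(habitat: pd.DataFrame, landscape_cols, vegetation_cols,
                         n_landscape: int = 2, n_vegetation: int = 6):
    """LPC and VPC score table from the raw habitat measurements.

    Separate correlation-matrix PCAs of the landscape and vegetation
    measurement sets; the leading ``n_landscape`` + ``n_vegetation``
    scores are the candidate abundance covariates.
    """
    lpc = pca_scores(habitat[list(landscape_cols)], n_landscape, prefix="LPC")
    vpc = pca_scores(habitat[list(vegetation_cols)], n_vegetation, prefix="VPC")
    return pd.concat([lpc.scores, vpc.scores], axis=1), lpc, vpc


_BLOCK_EDGES = (5.5, 7.0, 8.5, 10.0)  # hours; half-open [lo, hi), end inclusive


def _hours(clock) -> float:
    if isinstance(clock, _dt.time):
        return clock.hour + clock.minute / 60 + clock.second / 3600
    if isinstance(clock, str):
        h, m = clock.split(":")[:2]
        return int(h) + int(m) / 60
    return float(clock)


def time_block(clock) -> str:
    """Map a clock time to the early / middle / late survey block.

    Blocks are early 5:30-7:00, middle 7:00-8:30, late 8:30-10:00, with
    each boundary time assigned to the later block (half-open bins).
    Times outside the 5:30-10:00 survey window raise ``ValueError``.
    """
    h = _hours(clock)
    lo, b1, b2, hi = _BLOCK_EDGES
    if h < lo or h > hi:
        raise ValueError(f"clock time {clock!r} outside the 5:30-10:00 survey window")
    if h < b1:
        return "early"
    if h < b2:
        return "middle"
    return "late"


def standardize_day_of_year(day_of_year) -> np.ndarray:
    """Center and scale day-of-year to unit variance (sampler conditioning)."""
    d = np.asarray(day_of_year, dtype=float)
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    if sd == 0:
        return d - d.mean()
    return (d - d.mean()) / sd
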