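"""Data model for site-visit capture records.

The unit of observation is a *site visit*: a trapping session at a 0.25 ha
site in a given year, with ``effort = traps x nights`` trap-nights and the
number of distinct individuals captured in each response class (all
individuals, males, females, second-year females, and second-year females
with suckled teats).  Each trap-night is treated as a Bernoulli trial, so a
visit contributes a binomial observation ``y ~ Binomial(effort, p)``.

Covariates are a fixed, ordered set: the remotely sensed stand-condition
score, distance to floodwaters (km), fallen-timber volume (m3/ha),
previous-year rainfall (mm), orb-web counts, and two life-stage indicators
(trapping in the juvenile-dispersal period, January; or in the
post-juvenile-dispersal period, March-May; reference level is the
June-July breeding season).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONSE_CLASSES = ("total", "males", "females", "f2", "f2_teats")

#: canonical covariate order, used for design matrices and summary tables
COVARIATE_NAMES = ("Condition", "FloodDist", "Logs", "RainPrevYr", "Webs", "JD", "PostJD")

#: continuous covariates (standardized); the rest are 0/1 indicators
CONTINUOUS_COVARIATES = ("Condition", "FloodDist", "Logs", "RainPrevYr", "Webs")

#: CSV column name for each covariate
_COVARIATE_COLUMNS = {
    "Condition": "condition",
    "FloodDist": "flood_dist_km",
    "Logs": "logs_m3ha",
    "RainPrevYr": "rain_prev_yr_mm",
    "Webs": "webs",
}

_COUNT_COLUMNS = {
    "total": "y_total",
    "males": "y_male",
    "females": "y_female",
    "f2": "y_f2",
    "f2_teats": "y_f2teats",
}

SEASONS = ("JD", "postJD", "breeding")

REQUIRED_COLUMNS = (
    "site_id", "forest_id", "x_m", "y_m", "year", "traps", "nights",
    "y_total", "y_male", "y_female", "y_f2", "y_f2teats",
    "condition", "flood_dist_km", "logs_m3ha", "rain_prev_yr_mm", "webs",
    "season",
)


class SchemaError(ValueError):
    """The input table is missing required structure (columns, header)."""


class IntegrityError(ValueError):
    """A row violates a logical invariant of the capture data."""


class DegenerateCovariateError(ValueError):
    """A continuous covariate has zero variance and cannot be standardized."""


@dataclass
class SiteVisit:
    """One trapping session at one site in one year."""

    site_id: str
    forest_id: str
    x: float
    y: float
    year: int
    traps: int
    nights: int
    counts: dict[str, int]
    covariates: dict[str, float]  # NaN marks a not-collected value
    season: str = "breeding"

    @property
    def effort(self) -> int:
        """Trap-nights: the binomial denominator for this visit."""
        return self.traps * self.nights

    def validate(self, row_label: str | None = None) -> None:
        label = row_label if row_label is not None else f"visit {self.site_id}/{self.year}"
        if self.effort < 1:
            raise IntegrityError(f"{label}: effort must be >= 1, got {self.effort}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise IntegrityError(f"{label}: non-finite coordinates")
        if self.season not in SEASONS:
            raise IntegrityError(f"{label}: unknown season {self.season!r}")
        for cls in RESPONSE_CLASSES:
            y = self.counts[cls]
            if not (0 <= y <= self.effort):
                raise IntegrityError(
                    f"{label}: count {cls}={y} outside [0, effort={self.effort}]"
                )
        c = self.counts
        if c["males"] + c["females"] > c["total"]:
            raise IntegrityError(f"{label}: males + females > total")
        if not (c["f2_teats"] <= c["f2"] <= c["females"]):
            raise IntegrityError(f"{label}: need f2_teats <= f2 <= females")


@dataclass
class CaptureDataset:
    """An ordered collection of site visits plus covariate metadata.

    ``availability_mask[(covariate, year)]`` is False where a covariate was
    not collected in that year (orb-web counts exist only for 2011 surveys);
    such entries carry NaN in the visit records.
    """

    visits: list[SiteVisit]
    covariate_names: tuple[str, ...] = COVARIATE_NAMES
    availability_mask: dict[tuple[str, int], bool] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.visits)

    # -- array views used by the model ------------------------------------

    @property
    def years(self) -> np.ndarray:
        return np.array([v.year for v in self.visits])

    @property
    def efforts(self) -> np.ndarray:
        return np.array([v.effort for v in self.visits])

    def counts(self, response_class: str) -> np.ndarray:
        if response_class not in RESPONSE_CLASSES:
            raise KeyError(f"unknown response class {response_class!r}")
        return np.array([v.counts[response_class] for v in self.visits])

    @property
    def site_ids(self) -> np.ndarray:
        return np.array([v.site_id for v in self.visits])

    @property
    def forest_ids(self) -> np.ndarray:
        return np.array([v.forest_id for v in self.visits])

    def site_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique sites in first-appearance order and their coordinates.

        Returns ``(site_ids, coords)`` with ``coords`` of shape (n_sites, 2).
        """
        seen: dict[str, tuple[float, float]] = {}
        for v in self.visits:
            seen.setdefault(v.site_id, (v.x, v.y))
        ids = np.array(list(seen))
        coords = np.array([seen[s] for s in ids], dtype=float)
        return ids, coords

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if not self.visits:
            raise SchemaError("dataset has no visits")
        coords: dict[str, tuple[float, float]] = {}
        forests: set[str] = set()
        for i, v in enumerate(self.visits):
            v.validate(row_label=f"row {i}")
            forests.add(v.forest_id)
            prev = coords.setdefault(v.site_id, (v.x, v.y))
            if prev != (v.x, v.y):
                raise IntegrityError(
                    f"site {v.site_id}: coordinates differ across revisits"
                )
        _, xy = self.site_coordinates()
        if len(xy) > 1:
            d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
            iu = np.triu_indices(len(xy), k=1)
            dmin = float(np.sqrt(d2[iu].min()))
            if dmin <= 300.0:
                warnings.warn(
                    f"minimum inter-site distance {dmin:.1f} m <= 300 m",
                    stacklevel=2,
                )

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.visits:
            row = {
                "site_id": v.site_id, "forest_id": v.forest_id,
                "x_m": v.x, "y_m": v.y, "year": v.year,
                "traps": v.traps, "nights": v.nights,
            }
            for cls, col in _COUNT_COLUMNS.items():
                row[col] = v.counts[cls]
            for cov, col in _COVARIATE_COLUMNS.items():
                row[col] = v.covariates.get(cov, np.nan)
            row["season"] = v.season
            rows.append(row)
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _availability_from_visits(visits: list[SiteVisit]) -> dict[tuple[str, int], bool]:
    mask: dict[tuple[str, int], bool] = {}
    years = sorted({v.year for v in visits})
    for cov in CONTINUOUS_COVARIATES:
        for yr in years:
            vals = [v.covariates.get(cov, np.nan) for v in visits if v.year == yr]
            mask[(cov, yr)] = bool(np.isfinite(vals).any())
    return mask


def read_site_table(path) -> CaptureDataset:
    """Read a site-visit CSV and return a validated :class:`CaptureDataset`.

    Effort is recomputed as ``traps x nights``; if the file carries an
    ``effort`` column it is checked against the recomputed value.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "effort" in df.columns:
        recomputed = df["traps"] * df["nights"]
        bad = df.index[df["effort"].astype(int) != recomputed]
        if len(bad):
            raise IntegrityError(
                f"row {bad[0]}: effort column disagrees with traps x nights"
            )
    visits = []
    for i, r in df.iterrows():
        visits.append(SiteVisit(
            site_id=str(r["site_id"]), forest_id=str(r["forest_id"]),
            x=float(r["x_m"]), y=float(r["y_m"]), year=int(r["year"]),
            traps=int(r["traps"]), nights=int(r["nights"]),
            counts={cls: int(r[col]) for cls, col in _COUNT_COLUMNS.items()},
            covariates={cov: float(r[col]) if pd.notna(r[col]) else np.nan
                        for cov, col in _COVARIATE_COLUMNS.items()},
            season=str(r["season"]),
        ))
    ds = CaptureDataset(visits=visits,
                        availability_mask=_availability_from_visits(visits))
    ds.validate()
    return ds


@dataclass
class DesignMatrix:
    """Visit-aligned covariate matrix on the standardized scale.

    Continuous covariates are centered and scaled using all non-missing
    values; missing entries become 0 on the standardized scale (mean
    imputation), so a not-collected covariate contributes nothing to the
    linear predictor for those visits.  Life-stage indicators are 0/1 with
    breeding-season visits as the reference level.  The per-covariate
    (mean, sd) pairs are retained so standardized coefficients can be mapped
    back to the raw scale.
    """

    X: np.ndarray                      # (n_visits, n_covariates)
    covariate_names: tuple[str, ...]
    means: dict[str, float]            # continuous covariates only
    sds: dict[str, float]
    missing_mask: np.ndarray           # True where the raw value was missing

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.covariate_names.index(name)]

    def transform(self, dataset: "CaptureDataset") -> np.ndarray:
        """Standardize another dataset's covariates with the stored (mean, sd).

        Used for held-out data: test visits are scaled by the training
        standardization, with missing entries imputed to 0 as in fitting.
        """
        n = len(dataset)
        X = np.zeros((n, len(self.covariate_names)))
        for j, name in enumerate(self.covariate_names):
            if name == "JD":
                X[:, j] = [1.0 if v.season == "JD" else 0.0 for v in dataset.visits]
            elif name == "PostJD":
                X[:, j] = [1.0 if v.season == "postJD" else 0.0
                           for v in dataset.visits]
            else:
                raw = np.array([v.covariates.get(name, np.nan)
                                for v in dataset.visits], dtype=float)
                obs = np.isfinite(raw)
                col = np.zeros(n)
                col[obs] = (raw[obs] - self.means[name]) / self.sds[name]
                X[:, j] = col
        return X

    def raw_linear_predictor(self, beta_std: np.ndarray, intercept_std: float = 0.0):
        """Back-transform standardized coefficients to the raw scale.

        Returns ``(intercept_raw, beta_raw)`` such that
        ``intercept_raw + X_raw @ beta_raw`` equals
        ``intercept_std + X_std @ beta_std`` (missing entries at their mean).
        """
        beta_raw = np.asarray(beta_std, dtype=float).copy()
        intercept_raw = float(intercept_std)
        for j, name in enumerate(self.covariate_names):
            if name in self.sds:
                beta_raw[j] = beta_std[j] / self.sds[name]
                intercept_raw -= beta_std[j] * self.means[name] / self.sds[name]
        return intercept_raw, beta_raw


def build_design_matrix(dataset: CaptureDataset) -> DesignMatrix:
    """Standardize covariates and encode life-stage indicators for fitting."""
    n = len(dataset)
    names = dataset.covariate_names
    X = np.zeros((n, len(names)))
    missing = np.zeros((n, len(names)), dtype=bool)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for j, name in enumerate(names):
        if name == "JD":
            X[:, j] = [1.0 if v.season == "JD" else 0.0 for v in dataset.visits]
            continue
        if name == "PostJD":
            X[:, j] = [1.0 if v.season == "postJD" else 0.0 for v in dataset.visits]
            continue
        raw = np.array([v.covariates.get(name, np.nan) for v in dataset.visits],
                       dtype=float)
        obs = np.isfinite(raw)
        missing[:, j] = ~obs
        if not obs.any():
            # never collected: all-zero column, flagged missing throughout
            means[name], sds[name] = 0.0, 1.0
            continue
        mu = float(raw[obs].mean())
        sd = float(raw[obs].std(ddof=0))
        if sd == 0.0:
            raise DegenerateCovariateError(
                f"covariate {name!r} has zero variance among observed values"
            )
        means[name], sds[name] = mu, sd
        col = np.zeros(n)
        col[obs] = (raw[obs] - mu) / sd
        X[:, j] = col
    return DesignMatrix(X=X, covariate_names=tuple(names), means=means,
                        sds=sds, missing_mask=missing)
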