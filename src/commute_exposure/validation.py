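"""Validation of modelled routes and exposures against GPS data.

Two instruments:

* the 50 m intersection metric — the percentage of a modelled route's length
  lying within 50 m of the paired GPS route (denominator: the modelled
  route's length);
* a school-clustered random-intercept linear model regressing GPS-derived
  food-outlet exposure on the modelled weighted-network exposure (WNE), since
  participants are clustered within schools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError
from .routes import RouteRecord


@dataclass
class IntersectionResult:
    """Overlap of one modelled route with its GPS counterpart."""

    participant_id: str
    direction: str
    modelled_source: str
    modelled_length_km: float
    gps_length_km: float
    intersect_length_km: float
    intersect_pct: float


def intersection_pct(modelled: RouteRecord, gps: RouteRecord,
                     buffer: float = 50.0) -> IntersectionResult:
    """Length share of the modelled route inside the GPS route's buffer."""
    if modelled.geometry.length <= 0:
        raise DataError("zero-length modelled route")
    zone = gps.geometry.buffer(buffer)
    inter = modelled.geometry.intersection(zone).length
    return IntersectionResult(
        participant_id=modelled.participant_id,
        direction=modelled.direction,
        modelled_source=modelled.source,
        modelled_length_km=modelled.length_km,
        gps_length_km=gps.length_km,
        intersect_length_km=inter / 1000.0,
        intersect_pct=100.0 * inter / modelled.geometry.length,
    )


def score_routes(modelled: list[RouteRecord], gps: list[RouteRecord],
                 buffer: float = 50.0) -> pd.DataFrame:
    """Score every modelled route against each same-participant, same-direction
    GPS route; a participant with several GPS trips contributes the mean."""
    gps_by_key: dict[tuple[str, str], list[RouteRecord]] = {}
    for r in gps:
        gps_by_key.setdefault((r.participant_id, r.direction), []).append(r)
    rows = []
    for m in modelled:
        partners = gps_by_key.get((m.participant_id, m.direction), [])
        if not partners:
            continue
        results = [intersection_pct(m, g, buffer) for g in partners]
        rows.append({
            "participant_id": m.participant_id,
            "direction": m.direction,
            "source": m.source,
            "modelled_length_km": m.length_km,
            "gps_length_km": float(np.mean([r.gps_length_km for r in results])),
            "intersect_length_km": float(np.mean([r.intersect_length_km
                                                  for r in results])),
            "intersect_pct": float(np.mean([r.intersect_pct for r in results])),
        })
    return pd.DataFrame(rows)


def overlap_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Descriptive overlap table per (source, direction).

    mean/SD/median/min/max/range of modelled length and intersection
    percentage, the share of routes that intersect completely, and the mean
    intersection within length bands (< 1 km, < 3 km, > 4 km).
    """
    if results.empty:
        raise DataError("no intersection results to summarise")
    rows = []
    for (source, direction), g in results.groupby(["source", "direction"]):
        pct = g["intersect_pct"]
        length = g["modelled_length_km"]
        row = {"source": source, "direction": direction, "n": len(g)}
        for name, s in (("length_km", length), ("intersect_pct", pct)):
            row.update({f"{name}_mean": s.mean(), f"{name}_sd": s.std(ddof=1),
                        f"{name}_median": s.median(), f"{name}_min": s.min(),
                        f"{name}_max": s.max(),
                        f"{name}_range": s.max() - s.min()})
        row["pct_complete"] = 100.0 * (pct >= 100.0 - 1e-6).mean()
        for label, mask in (("lt1km", length < 1.0), ("lt3km", length < 3.0),
                            ("gt4km", length > 4.0)):
            row[f"mean_pct_{label}"] = pct[mask].mean() if mask.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# -- exposure agreement model ---------------------------------------------


class ExposureAgreementModel:
    """Random-intercept regression of GPS exposure on modelled exposure.

    gps_exposure_ij = b0 + b1 * wne_ij + u_j + e_ij, with u_j a school-level
    random intercept, fitted by REML.  With a single school the random
    intercept is unidentifiable and the model falls back to OLS with a
    prominent warning.
    """

    def __init__(self, gps_exposure, wne, school_ids):
        self.y = np.asarray(gps_exposure, dtype=float)
        self.x = np.asarray(wne, dtype=float)
        self.groups = np.asarray(school_ids)
        if not (len(self.y) == len(self.x) == len(self.groups)):
            raise DataError("exposure arrays must have equal length")
        if len(self.y) < 10:
            raise DataError("need at least 10 routes to fit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gps_col: str = "gps_exposure",
                       wne_col: str = "wne", school_col: str = "school_id"
                       ) -> "ExposureAgreementModel":
        return cls(df[gps_col], df[wne_col], df[school_col])

    def fit(self, reml: bool = True) -> "ExposureAgreementResults":
        exog = sm.add_constant(self.x)
        n_schools = len(np.unique(self.groups))
        if n_schools < 2:
            warnings.warn("only one school: random intercept unidentifiable; "
                          "falling back to ordinary least squares")
            ols = sm.OLS(self.y, exog).fit()
            return ExposureAgreementResults(
                params=np.asarray(ols.params), bse=np.asarray(ols.bse),
                tvalues=np.asarray(ols.tvalues),
                pvalues=np.asarray(ols.pvalues),
                school_var=0.0, resid_var=float(ols.scale),
                n_routes=len(self.y), n_schools=n_schools, method="OLS")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary variance warnings
            mlm = sm.MixedLM(self.y, exog, groups=self.groups).fit(reml=reml)
        params = np.asarray(mlm.fe_params)
        bse = np.asarray(mlm.bse_fe)
        t = params / bse
        p = 2 * stats.norm.sf(np.abs(t))   # normal approximation
        return ExposureAgreementResults(
            params=params, bse=bse, tvalues=t, pvalues=p,
            school_var=float(np.asarray(mlm.cov_re)[0, 0]),
            resid_var=float(mlm.scale),
            n_routes=len(self.y), n_schools=n_schools, method="REML")


@dataclass
class ExposureAgreementResults:
    """Fixed effects and variance components of the agreement model."""

    params: np.ndarray     # (intercept, slope)
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    school_var: float
    resid_var: float
    n_routes: int
    n_schools: int
    method: str

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    def summary(self, decimals: int = 2) -> pd.DataFrame:
        """Fixed-effect table: Value, SE, t-value, p-value."""
        return pd.DataFrame({
            "fixed_effect": ["intercept", "wne"],
            "value": np.round(self.params, decimals),
            "se": np.round(self.bse, decimals),
            "t_value": np.round(self.tvalues, decimals),
            "p_value": self.pvalues,
        })

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "intercept": self.intercept,
            "slope": self.slope,
            "se": [float(v) for v in self.bse],
            "t": [float(v) for v in self.tvalues],
            "p": [float(v) for v in self.pvalues],
            "school_var": self.school_var,
            "resid_var": self.resid_var,
            "n_routes": self.n_routes,
            "n_schools": self.n_schools,
        }
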