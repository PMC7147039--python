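"""Conditional logistic regression for matched route pairs.

Each stratum pairs the route a participant actually walked (GPS trace) with
the shortest network route they could have walked (SNR).  Conditioning on
the stratum removes the per-stratum intercept, so with a 1:1 match the
conditional likelihood reduces to intercept-free logistic regression on the
within-pair covariate differences d_i = x_GPS,i - x_SNR,i with the outcome
fixed at 1:

    log L(b) = - sum_i log(1 + exp(-d_i' b))

The model is fitted by Newton-Raphson on this likelihood; standard errors
come from the inverse observed information.  exp(b_j) is the odds ratio for
covariate j (reference group: shortest network routes), with 95% CI
exp(b_j +/- 1.96 SE_j).

Backward stepwise selection repeatedly removes the covariate with the
largest Wald p-value above alpha and refits, but never removes route length
(it is the matching scale of the pair and is always reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DataError, SeparationError
from .features import RouteFeatures

#: covariates offered to the model by default, as in the published tables
#: (length in meters; road-class percentages; counts) plus woodland and
#: accidents, which the selection step may remove.
DEFAULT_COVARIATES = ("length_m", "pct_bluespace", "n_traffic_lights",
                      "pct_main", "pct_residential", "pct_footpath",
                      "pct_minor", "n_outlets", "pct_woodland", "n_accidents")

#: covariates never removed by stepwise selection
PROTECTED = ("length_m",)


@dataclass
class MatchedPair:
    """One stratum: a GPS route's features matched to its SNR's features."""

    stratum_id: str
    gps_features: dict
    snr_features: dict
    direction: str


def _as_feature_dict(f) -> dict:
    if isinstance(f, RouteFeatures):
        d = {k: getattr(f, k) for k in f.NUMERIC}
    else:
        d = dict(f)
    if "length_km" in d and "length_m" not in d:
        d["length_m"] = d["length_km"] * 1000.0
    return d


def build_pairs(feature_frame: pd.DataFrame, direction: str) -> tuple[list[MatchedPair], list[str]]:
    """Pair GPS and SNR feature rows by participant for one direction.

    A participant's multiple GPS trips are averaged into one pair (one
    stratum per participant per direction).  Participants missing either
    route are skipped and returned in the log.
    """
    df = feature_frame[feature_frame["direction"] == direction]
    gps = df[df["source"] == "GPS"]
    snr = df[df["source"] == "SNR"]
    skipped: list[str] = []
    pairs: list[MatchedPair] = []
    num_cols = [c for c in df.columns if c not in
                ("participant_id", "direction", "source")]
    snr_by_pid = {pid: g[num_cols].mean() for pid, g in snr.groupby("participant_id")}
    for pid, g in gps.groupby("participant_id"):
        if pid not in snr_by_pid:
            skipped.append(f"{pid}: no SNR partner for direction {direction}")
            continue
        pairs.append(MatchedPair(
            stratum_id=str(pid),
            gps_features=_as_feature_dict(g[num_cols].mean().to_dict()),
            snr_features=_as_feature_dict(snr_by_pid[pid].to_dict()),
            direction=direction))
    return pairs, skipped


class RouteChoiceModel:
    """Conditional logit discriminating chosen routes from shortest routes.

    Parameters
    ----------
    diffs : (n_strata, k) array of within-pair covariate differences
        (GPS minus SNR).
    names : covariate names, length k.
    direction : which commute the strata describe (metadata only).

    Covariates whose differences are identically zero carry no information
    under the conditional likelihood; they are dropped with a warning.
    """

    def __init__(self, diffs: np.ndarray, names: list[str],
                 direction: str | None = None, screen_one_signed: bool = True):
        diffs = np.asarray(diffs, dtype=float)
        if diffs.ndim != 2 or diffs.shape[1] != len(names):
            raise DataError("diffs must be (n_strata, len(names))")
        zero = np.all(diffs == 0.0, axis=0)
        # one-signed nonzero differences admit no finite MLE (the matched
        # analogue of complete separation): screen them out up front unless
        # the caller will use the Firth fit, which stays finite
        one_signed = (~zero) & (np.all(diffs >= 0.0, axis=0) |
                                np.all(diffs <= 0.0, axis=0))
        if not screen_one_signed:
            one_signed &= False
        keep = ~(zero | one_signed)
        self.dropped = [n for n, k in zip(names, keep) if not k]
        #: sign of the (infinite-MLE) effect for screened one-signed covariates
        self.one_signed: dict[str, int] = {
            n: (1 if np.all(diffs[:, j] >= 0) else -1)
            for j, (n, s) in enumerate(zip(names, one_signed)) if s}
        if np.any(zero):
            warnings.warn("dropping all-zero-difference covariates: "
                          f"{[n for n, z in zip(names, zero) if z]}")
        if np.any(one_signed):
            warnings.warn(
                "dropping covariates with one-signed within-pair differences "
                f"(no finite MLE): {[n for n, s in zip(names, one_signed) if s]}")
        self.diffs = diffs[:, keep]
        self.names = [n for n, k in zip(names, keep) if k]
        self.direction = direction
        if self.diffs.shape[0] < 10:
            raise DataError("need at least 10 strata to fit")
        if not self.names:
            raise DataError("no informative covariates")

    @classmethod
    def from_pairs(cls, pairs: list[MatchedPair],
                   covariates: tuple[str, ...] = DEFAULT_COVARIATES
                   ) -> "RouteChoiceModel":
        rows = []
        for p in pairs:
            g, s = _as_feature_dict(p.gps_features), _as_feature_dict(p.snr_features)
            rows.append([g[c] - s[c] for c in covariates])
        direction = pairs[0].direction if pairs else None
        return cls(np.array(rows), list(covariates), direction)

    @classmethod
    def from_dataframe(cls, feature_frame: pd.DataFrame, direction: str,
                       covariates: tuple[str, ...] = DEFAULT_COVARIATES
                       ) -> "RouteChoiceModel":
        pairs, _ = build_pairs(feature_frame, direction)
        return cls.from_pairs(pairs, covariates)

    # -- likelihood --------------------------------------------------------

    def loglike(self, b: np.ndarray) -> float:
        eta = self.diffs @ b
        return float(-np.logaddexp(0.0, -eta).sum())

    def score(self, b: np.ndarray) -> np.ndarray:
        eta = self.diffs @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        return self.diffs.T @ (1.0 - p)

    def hessian(self, b: np.ndarray) -> np.ndarray:
        eta = self.diffs @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        return -(self.diffs * w[:, None]).T @ self.diffs

    def _firth_score(self, b: np.ndarray) -> np.ndarray:
        """Penalized score: U*(b) = U(b) + 0.5 tr(I^-1 dI/db_j).

        For logistic regression this is U + D' (h * (0.5 - p)) with h the
        leverages of the weighted design (Firth's bias-reduced score).
        """
        D = self.diffs
        eta = D @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        I = (D * w[:, None]).T @ D
        Iinv = np.linalg.pinv(I)
        h = w * np.einsum("ij,jk,ik->i", D, Iinv, D)
        return D.T @ ((1.0 - p) + h * (0.5 - p))

    def fit(self, max_iter: int = 200, tol: float = 1e-8,
            method: str = "newton") -> "RouteChoiceResults":
        """Maximise the conditional likelihood.

        ``newton``: Newton-Raphson with step-halving on the plain likelihood,
        converged when ||score|| < tol; raises SeparationError when the data
        are (quasi-)separated, i.e. the MLE is infinite.

        ``firth``: Firth's bias-reduced penalized likelihood, which always
        has a finite interior maximum and is the recommended fit when strata
        are highly discriminable (near-optimising route choice).
        """
        if method not in ("newton", "firth"):
            raise DataError(f"unknown fit method {method!r}")
        score = self.score if method == "newton" else self._firth_score
        k = len(self.names)
        n = self.diffs.shape[0]
        b = np.zeros(k)
        ll = self.loglike(b)
        trace = []
        for it in range(max_iter):
            g = score(b)
            trace.append((it, ll, float(np.linalg.norm(g))))
            if np.linalg.norm(g) < tol:
                break
            H = self.hessian(b)
            cond = np.linalg.cond(-H)
            if not np.isfinite(cond) or cond > 1e12:
                raise SeparationError(
                    "observed information is singular — likely complete "
                    "separation or collinear covariates (e.g. all four "
                    "road-class percentages); remove a covariate and refit")
            step = np.linalg.solve(-H, g)
            # damp large steps so Firth iterations stay in a stable region
            norm = np.linalg.norm(step)
            if norm > 5.0:
                step *= 5.0 / norm
            lam = 1.0
            b_new = b + step
            if method == "newton":
                while lam > 1e-8:
                    b_new = b + lam * step
                    ll_new = self.loglike(b_new)
                    if ll_new >= ll - 1e-12:
                        break
                    lam /= 2.0
                ll = ll_new
            else:
                ll = self.loglike(b_new)
            if method == "newton" and np.max(np.abs(b_new)) > 30:
                raise SeparationError(
                    "coefficients diverging — complete separation")
            b = b_new
        else:
            raise ConvergenceError(
                f"no convergence after {max_iter} iterations; trace={trace[-5:]}")
        eta = self.diffs @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        if method == "newton" and p.min() > 1.0 - 1e-6:
            # gradient vanishes on the separation plateau: the fit is not a
            # finite maximum even though ||score|| is small
            raise SeparationError(
                "all strata fitted perfectly — quasi-complete separation")
        H = self.hessian(b)
        cov = np.linalg.inv(-H)
        return RouteChoiceResults(model=self, params=b, cov_params=cov,
                                  llf=self.loglike(b), n_iter=it,
                                  method=method)

    def fit_stepwise(self, alpha: float = 0.05,
                     protected: tuple[str, ...] = PROTECTED,
                     criterion: str = "wald",
                     method: str = "newton") -> "RouteChoiceResults":
        """Backward stepwise selection.

        ``wald``: drop the covariate with the largest Wald p above alpha.
        ``aic``: drop the covariate whose removal lowers AIC most.
        """
        model = self
        path: list[str] = []
        while True:
            res = model.fit(method=method)
            removable = [n for n in model.names if n not in protected]
            if not removable:
                break
            if criterion == "wald":
                pvals = res.pvalues
                worst = max(removable, key=lambda n: pvals[n])
                if pvals[worst] <= alpha:
                    break
            elif criterion == "aic":
                base_aic = res.aic
                cand = []
                for n in removable:
                    sub = self._without(model, n)
                    cand.append((sub.fit(method=method).aic, n))
                best_aic, worst = min(cand)
                if best_aic >= base_aic:
                    break
            else:
                raise DataError(f"unknown stepwise criterion {criterion!r}")
            if len(model.names) <= 1:
                break  # never empty the model entirely
            path.append(worst)
            model = self._without(model, worst)
        res.selection_path = path
        return res

    @staticmethod
    def _without(model: "RouteChoiceModel", name: str) -> "RouteChoiceModel":
        idx = [i for i, n in enumerate(model.names) if n != name]
        return RouteChoiceModel(model.diffs[:, idx],
                                [model.names[i] for i in idx],
                                model.direction)


@dataclass
class RouteChoiceResults:
    """Fitted conditional logit: coefficients, ORs and Wald inference."""

    model: RouteChoiceModel
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    n_iter: int
    method: str = "newton"
    selection_path: list = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return self.model.names

    @property
    def n_strata(self) -> int:
        return self.model.diffs.shape[0]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def odds_ratios(self) -> pd.Series:
        return pd.Series(np.exp(self.params), index=self.names)

    def conf_int(self, z: float = 1.96) -> pd.DataFrame:
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"or_lower": lo, "or_upper": hi}, index=self.names)

    @property
    def zvalues(self) -> pd.Series:
        return pd.Series(self.params / self.bse, index=self.names)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.names)

    @property
    def aic(self) -> float:
        return 2 * len(self.params) - 2 * self.llf

    def summary(self, decimals: int = 2) -> pd.DataFrame:
        """Odds-ratio table in the published layout (OR with 95% CI bounds)."""
        ci = self.conf_int()
        out = pd.DataFrame({
            "covariate": self.names,
            "odds_ratio": np.round(np.exp(self.params), decimals),
            "ci_lower": np.round(ci["or_lower"].to_numpy(), decimals),
            "ci_upper": np.round(ci["or_upper"].to_numpy(), decimals),
        })
        return out

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "direction": self.model.direction,
            "n_strata": self.n_strata,
            "loglik": self.llf,
            "dropped": self.model.dropped,
            "selection_path": list(self.selection_path),
            "coefficients": {
                n: {"b": float(b), "se": float(se),
                    "or": float(np.exp(b)),
                    "or_lower": float(ci["or_lower"][n]),
                    "or_upper": float(ci["or_upper"][n]),
                    "p": float(self.pvalues[n])}
                for n, b, se in zip(self.names, self.params, self.bse)
            },
        }
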