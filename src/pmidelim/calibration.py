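"""Presence-probability calibration of degradation markers against ADD.

The analysis stage of the pipeline.  For each degradation product the data
are pairs (ADD_i, y_i) with y_i the binary presence call.  The stage runs,
per product and demographic subgroup:

1. Spearman rank correlation of presence with ADD, testing whether the
   product's appearance is random over the observed ADD range.  Exact
   permutation p-values are used for very small samples; otherwise the
   classical t approximation.
2. For products whose correlation passes the significance gate
   (p <= 0.01 by default), a binomial logistic regression

       P(y = 1 | ADD) = 1 / (1 + exp(-(beta0 + beta1 * ADD)))

   fitted by Newton/IRLS with step-halving (so the log-likelihood is
   non-decreasing across iterations).  Quasi-complete separation is
   detected and flagged, with an optional Firth (Jeffreys-prior) penalized
   refit instead of silently reporting runaway slopes.
3. Threshold extraction: the ADD at which presence probability reaches p,

       ADD(p) = (logit(p) - beta0) / beta1,

   in particular P50 = -beta0/beta1 (the inflection point: the product
   becomes more likely present than absent) and P95 (the product is
   "significantly present", i.e. expected in >= 95 % of cases).

The model/results pair follows the statsmodels idiom: ``MarkerLogit`` holds
the data, ``fit()`` returns a ``MarkerLogitResults`` carrying estimates,
standard errors, diagnostics and a ``summary()``; ``PanelCalibration``
orchestrates the product x subgroup table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "LogisticCurve",
    "CorrelationResult",
    "MarkerLogit",
    "MarkerLogitResults",
    "PanelCalibration",
    "PanelCalibrationResults",
    "spearman_presence_vs_add",
    "thresholds_from_fit",
    "subgroup_filter",
    "SUBGROUP_RULES",
    "ThresholdUndefinedError",
]

LN19 = math.log(19.0)  # logit(0.95)

#: subgroup restriction rules; boundaries strict on both sides
SUBGROUP_RULES = ("total", "age_corrected", "bmi_corrected", "female", "male")


class ThresholdUndefinedError(ValueError):
    """Raised when an ADD threshold is requested from a flat or unfitted curve."""


@dataclass(frozen=True)
class LogisticCurve:
    """A calibrated presence-probability curve P(add) = expit(b0 + b1*add)."""

    name: str
    beta0: float
    beta1: float

    @classmethod
    def from_thresholds(cls, name: str, p50: float, p95: float) -> "LogisticCurve":
        """The unique logistic curve through (p50, 0.5) and (p95, 0.95)."""
        if p95 <= p50:
            raise ValueError("need p95 > p50 for a rising curve")
        beta1 = LN19 / (p95 - p50)
        return cls(name, -beta1 * p50, beta1)

    def prob(self, add) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(add, dtype=float))

    def threshold(self, p: float) -> float:
        if not 0 < p < 1:
            raise ValueError("probability must be in (0, 1)")
        if self.beta1 == 0 or not math.isfinite(self.beta1):
            raise ThresholdUndefinedError(
                f"{self.name}: slope is zero/undefined, ADD threshold undefined"
            )
        return float((logit(p) - self.beta0) / self.beta1)

    @property
    def p50(self) -> float:
        return self.threshold(0.5)

    @property
    def p95(self) -> float:
        return self.threshold(0.95)


# ---------------------------------------------------------------------------
# Spearman correlation of binary presence with ADD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    n_absent: int
    n_present: int
    status: str = "ok"  # ok | few cases
    method: str = ""  # t-approx | exact-permutation


def _rank_rho(add: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho: Pearson correlation of average-tied ranks."""
    ra = stats.rankdata(add)
    rb = stats.rankdata(y)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = math.sqrt(float(ra @ ra) * float(rb @ rb))
    if denom == 0:
        return math.nan
    return float(ra @ rb) / denom


def _rho_all_assignments(add: np.ndarray, k: int) -> np.ndarray:
    """Spearman rho for every assignment of k present-labels over n cases.

    Each assignment (combination) corresponds to the same number of full
    label permutations, so the uniform distribution over combinations equals
    the permutation distribution.
    """
    n = len(add)
    ra = stats.rankdata(add)
    ra_c = ra - ra.mean()
    ss_a = float(ra_c @ ra_c)
    # binary ranks: zeros share rank (n-k+1)/2... compute via formula
    idx = np.array(list(combinations(range(n), k)), dtype=int)
    y = np.zeros((len(idx), n))
    np.put_along_axis(y, idx, 1.0, axis=1)
    ry = stats.rankdata(y, axis=1)
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    ss_b = np.einsum("ij,ij->i", ry_c, ry_c)
    num = ry_c @ ra_c
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / np.sqrt(ss_a * ss_b)


def spearman_presence_vs_add(
    add: Sequence[float],
    presence: Sequence[int],
    min_minority: int = 4,
    exact_below: int = 10,
) -> CorrelationResult:
    """Rank correlation between binary presence and ADD.

    Returns status ``"few cases"`` (and no rho) when fewer than
    ``min_minority`` cases fall in the rarer presence class — mirroring how
    near-constant products are reported rather than correlated.  For
    n < ``exact_below`` the p-value is an exact two-sided permutation test
    over presence-label assignments; otherwise the t approximation with
    n - 2 degrees of freedom.
    """
    add = np.asarray(add, dtype=float)
    y = np.asarray(presence, dtype=float)
    if add.shape != y.shape or add.ndim != 1:
        raise ValueError("add and presence must be equal-length 1-D sequences")
    n = len(add)
    n_present = int(y.sum())
    n_absent = n - n_present
    if n < 3 or min(n_present, n_absent) < min_minority:
        return CorrelationResult(
            math.nan, math.nan, n, n_absent, n_present, status="few cases"
        )
    rho = _rank_rho(add, y)
    if n < exact_below:
        rhos = _rho_all_assignments(add, n_present)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "exact-permutation"
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        method = "t-approx"
    return CorrelationResult(rho, p, n, n_absent, n_present, method=method)


# ---------------------------------------------------------------------------
# Logistic calibration model
# ---------------------------------------------------------------------------

def _detect_separation(add: np.ndarray, y: np.ndarray) -> bool:
    """Quasi-complete separation: the two classes split monotonically in ADD."""
    a0, a1 = add[y == 0], add[y == 1]
    if len(a0) == 0 or len(a1) == 0:
        return True
    return bool(a0.max() <= a1.min() or a1.max() <= a0.min())


class MarkerLogit:
    """Binomial logistic model of marker presence on ADD.

    Parameters
    ----------
    presence : array-like of {0, 1}
        Binary presence calls (missing calls must be dropped upstream).
    add : array-like
        Accumulated degree-days per case (°d).
    name : str
        Product identifier carried through to the results.
    """

    def __init__(self, presence, add, name: str = "product"):
        y = np.asarray(presence, dtype=float)
        x = np.asarray(add, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("presence and add must be equal-length 1-D arrays")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("presence must be binary 0/1 (drop missing first)")
        if len(y) < 6:
            raise ValueError("need at least 6 cases to fit a calibration")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("need both presence classes to fit")
        self.endog = y
        self.exog = np.column_stack([np.ones_like(x), x])
        self.add = x
        self.name = name

    # log-likelihood and derivatives -------------------------------------
    def loglike(self, params: np.ndarray) -> float:
        eta = self.exog @ params
        # log sigma(eta)*y + log sigma(-eta)*(1-y), numerically stable
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def score(self, params: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ params)
        return self.exog.T @ (self.endog - p)

    def hessian(self, params: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ params)
        w = p * (1 - p)
        return -(self.exog * w[:, None]).T @ self.exog

    def _hat_diag(self, params: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ params)
        w = p * (1 - p)
        xw = self.exog * np.sqrt(w)[:, None]
        xtx = xw.T @ xw
        return np.einsum("ij,jk,ik->i", xw, np.linalg.inv(xtx), xw)

    def fit(
        self,
        firth: bool = False,
        maxiter: int = 100,
        score_tol: float = 1e-8,
        param_tol: float = 1e-10,
    ) -> "MarkerLogitResults":
        """Maximum-likelihood (or Firth-penalized) fit by damped Newton/IRLS.

        Convergence is declared when the maximum absolute score drops below
        ``score_tol`` or the parameter update below ``param_tol``.  Data
        with quasi-complete separation are flagged; without ``firth`` the
        flagged result carries no usable estimates (the MLE diverges).
        """
        separated = _detect_separation(self.add, self.endog)
        if separated and not firth:
            return MarkerLogitResults(
                model=self,
                params=np.array([math.nan, math.nan]),
                bse=np.array([math.nan, math.nan]),
                llf=math.nan,
                niter=0,
                converged=False,
                separation=True,
                firth=False,
            )

        def objective(b):
            ll = self.loglike(b)
            if firth:
                h = -self.hessian(b)
                sign, logdet = np.linalg.slogdet(h)
                ll += 0.5 * logdet if sign > 0 else -np.inf
            return ll

        ybar = self.endog.mean()
        params = np.array([logit(min(max(ybar, 1e-6), 1 - 1e-6)), 0.0])
        ll = objective(params)
        llf_history = [ll]
        niter = 0
        converged = False
        for niter in range(1, maxiter + 1):
            if firth:
                h = self._hat_diag(params)
                p = expit(self.exog @ params)
                grad = self.exog.T @ (self.endog - p + h * (0.5 - p))
            else:
                grad = self.score(params)
            if np.max(np.abs(grad)) < score_tol:
                converged = True
                break
            hess = self.hessian(params)
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                break
            # step-halving keeps the (penalized) log-likelihood monotone
            scale = 1.0
            for _ in range(50):
                candidate = params + scale * step
                ll_new = objective(candidate)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            else:
                converged = True  # no improving step left: at the optimum
                break
            if np.max(np.abs(scale * step)) < param_tol:
                params, ll = candidate, ll_new
                llf_history.append(ll)
                converged = True
                break
            params, ll = candidate, ll_new
            llf_history.append(ll)

        cov = np.linalg.inv(-self.hessian(params))
        bse = np.sqrt(np.diag(cov))
        return MarkerLogitResults(
            model=self,
            params=params,
            bse=bse,
            llf=self.loglike(params),
            niter=niter,
            converged=converged,
            separation=separated,
            firth=firth,
            llf_history=tuple(llf_history),
        )


@dataclass
class MarkerLogitResults:
    """Fitted logistic calibration for one product (and subgroup).

    Attributes
    ----------
    params : ndarray
        ``[beta0, beta1]`` on the logit scale (beta1 per °d).
    bse : ndarray
        Asymptotic standard errors from the observed information.
    separation : bool
        Quasi-complete separation was detected in the data.
    wide : bool
        The slope is not significantly different from 0 at ~5 %; threshold
        estimates are unstable and should be read as orders of magnitude.
    """

    model: MarkerLogit
    params: np.ndarray
    bse: np.ndarray
    llf: float
    niter: int
    converged: bool
    separation: bool
    firth: bool
    subgroup: str = "total"
    #: (penalized) log-likelihood after each accepted Newton step
    llf_history: tuple[float, ...] = ()

    @property
    def name(self) -> str:
        return self.model.name

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def n_present(self) -> int:
        return int(self.model.endog.sum())

    @property
    def n_absent(self) -> int:
        return self.nobs - self.n_present

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta1(self) -> float:
        return float(self.params[1])

    @property
    def wide(self) -> bool:
        if not np.all(np.isfinite(self.params)) or not np.isfinite(self.bse[1]):
            return True
        return bool(abs(self.beta1) < 1.96 * self.bse[1])

    @property
    def curve(self) -> LogisticCurve:
        return LogisticCurve(self.name, self.beta0, self.beta1)

    def predict(self, add) -> np.ndarray:
        return self.curve.prob(add)

    def threshold(self, p: float) -> float:
        """ADD (°d) at which presence probability reaches ``p``."""
        if self.separation and not self.firth:
            raise ThresholdUndefinedError(
                f"{self.name}: separation flagged, no usable estimates"
            )
        return self.curve.threshold(p)

    @property
    def p50_add(self) -> float:
        """Inflection point: product more likely present than absent beyond."""
        try:
            return self.threshold(0.5)
        except ThresholdUndefinedError:
            return math.nan

    @property
    def p95_add(self) -> float:
        """ADD from which the product is expected in >= 95 % of cases."""
        try:
            return self.threshold(0.95)
        except ThresholdUndefinedError:
            return math.nan

    def se_p50(self) -> float:
        """Delta-method standard error of the P50 threshold."""
        if self.beta1 == 0 or not np.all(np.isfinite(self.params)):
            return math.nan
        cov = np.linalg.inv(-self.model.hessian(self.params))
        g = np.array([-1.0 / self.beta1, self.beta0 / self.beta1**2])
        return float(np.sqrt(g @ cov @ g))

    def summary(self) -> str:
        lines = [
            f"Logistic presence calibration: {self.name} [{self.subgroup}]",
            f"  n = {self.nobs} (absent {self.n_absent} / present {self.n_present})",
            f"  beta0 = {self.beta0:+.4f} (se {self.bse[0]:.4f})",
            f"  beta1 = {self.beta1:+.5f} per °d (se {self.bse[1]:.5f})",
            f"  P50  = {self.p50_add:.1f} °d",
            f"  P95  = {self.p95_add:.1f} °d",
            f"  log-likelihood = {self.llf:.3f}, iterations = {self.niter}, "
            f"converged = {self.converged}",
        ]
        if self.separation:
            lines.append("  WARNING: quasi-complete separation" +
                         (" (Firth-penalized fit)" if self.firth else
                          " — estimates unavailable"))
        if not self.separation and self.wide:
            lines.append("  WARNING: slope not significant; thresholds unstable (wide)")
        return "\n".join(lines)

    def plot(self, ax=None, add_range=None, **kwargs):
        """Plot the fitted presence-probability curve with P50/P95 markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if add_range is None:
            add_range = (self.model.add.min(), self.model.add.max())
        grid = np.linspace(*add_range, 300)
        ax.plot(grid, self.predict(grid), **kwargs)
        ax.axhline(0.95, ls=":", color="grey", lw=0.8)
        ax.set_xlabel("ADD (°d)")
        ax.set_ylabel("presence probability")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(self.name)
        return ax


def thresholds_from_fit(cal, p: float) -> float:
    """ADD at which a calibration's presence probability equals ``p``.

    Accepts a :class:`MarkerLogitResults` or a :class:`LogisticCurve`.
    """
    return cal.threshold(p)


# ---------------------------------------------------------------------------
# Subgroups and the panel-level calibration table
# ---------------------------------------------------------------------------

def subgroup_filter(cases: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Restrict a case table to a demographic subgroup.

    Rules (boundaries strict): ``age_corrected`` keeps 18 < age < 80
    (excludes possible developmental isoforms in the young and severe
    sarcopenia in the very old); ``bmi_corrected`` keeps 19 < BMI < 30
    (excludes underweight/cachectic and obese); ``female``/``male`` filter
    on sex; ``total`` is the identity.
    """
    if rule == "total":
        return cases
    if rule == "age_corrected":
        return cases[(cases["age"] > 18) & (cases["age"] < 80)]
    if rule == "bmi_corrected":
        return cases[(cases["bmi"] > 19) & (cases["bmi"] < 30)]
    if rule == "female":
        return cases[cases["sex"] == "F"]
    if rule == "male":
        return cases[cases["sex"] == "M"]
    raise ValueError(f"unknown subgroup rule {rule!r}; valid: {SUBGROUP_RULES}")


GROUP_LABELS = {
    "total": "Total",
    "age_corrected": "Age <80 and >18",
    "bmi_corrected": "BMI <30 and >19",
    "female": "Female",
    "male": "Male",
}


def _format_p(p: float, floor: float = 5e-4) -> str:
    """Display form of a p-value: three decimals, printing below-floor
    values as 0.000 (stored values keep full precision)."""
    if not math.isfinite(p):
        return ""
    return "0.000" if p < floor else f"{p:.3f}"


class PanelCalibration:
    """Product x subgroup calibration of a whole marker panel.

    Parameters
    ----------
    data : DataFrame
        One row per case with an ``add`` column (°d), one binary column per
        product (0/1; NaN or "missing" entries are dropped per product), and
        the demographic columns ``age``, ``bmi``, ``sex`` used by subgroup
        rules.
    products : sequence of str
        Degradation-product columns to calibrate.
    alpha : float
        Significance gate: logistic regressions are fitted only for products
        whose Spearman correlation has p <= alpha (default 0.01).
    min_minority : int
        Below this many cases in the rarer class the product is reported as
        "few cases" and not correlated.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        products: Sequence[str],
        add_col: str = "add",
        alpha: float = 0.01,
        min_minority: int = 4,
    ):
        missing = [c for c in (add_col, *products) if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns: {missing}")
        self.data = data
        self.products = tuple(products)
        self.add_col = add_col
        self.alpha = alpha
        self.min_minority = min_minority

    @classmethod
    def from_cohort(
        cls, cases: pd.DataFrame, panel=None, **kwargs
    ) -> "PanelCalibration":
        """Build from a cohort frame, taking products from a Panel (or all
        ``*_dp*`` columns when none is given)."""
        if panel is not None:
            products = [p for p in panel.degradation_products if p in cases.columns]
        else:
            products = [c for c in cases.columns if "_dp" in c]
        return cls(cases, products, **kwargs)

    def fit(
        self, subgroups: Sequence[str] = ("total",), firth: bool = False
    ) -> "PanelCalibrationResults":
        rows = []
        fits: dict[tuple[str, str], MarkerLogitResults] = {}
        correlations: dict[tuple[str, str], CorrelationResult] = {}
        for product in self.products:
            for rule in subgroups:
                sub = subgroup_filter(self.data, rule)
                mask = pd.to_numeric(sub[product], errors="coerce").isin([0, 1])
                sub = sub[mask]
                y = pd.to_numeric(sub[product]).to_numpy(dtype=float)
                add = sub[self.add_col].to_numpy(dtype=float)
                row = {
                    "product": product,
                    "group": GROUP_LABELS.get(rule, rule),
                    "rule": rule,
                    "n": len(y),
                    "n_absent": int(len(y) - y.sum()),
                    "n_present": int(y.sum()),
                    "rho": math.nan,
                    "p_value": math.nan,
                    "p_display": "",
                    "p50_add": math.nan,
                    "p95_add": math.nan,
                    "status": "",
                }
                if len(y) == 0:
                    row["status"] = "empty"
                    rows.append(row)
                    continue
                corr = spearman_presence_vs_add(
                    add, y, min_minority=self.min_minority
                )
                correlations[(product, rule)] = corr
                if corr.status == "few cases":
                    row["status"] = "few cases"
                    rows.append(row)
                    continue
                row.update(
                    rho=corr.rho,
                    p_value=corr.p_value,
                    p_display=_format_p(corr.p_value),
                )
                if corr.p_value > self.alpha:
                    row["status"] = "no significant correlation"
                    rows.append(row)
                    continue
                res = MarkerLogit(y, add, name=product).fit(firth=firth)
                res.subgroup = rule
                fits[(product, rule)] = res
                if res.separation and not res.firth:
                    row["status"] = "separation"
                else:
                    row.update(
                        p50_add=res.p50_add, p95_add=res.p95_add, status="ok"
                    )
                    if res.wide:
                        row["status"] = "ok (wide)"
                rows.append(row)
        table = pd.DataFrame(rows)
        return PanelCalibrationResults(self, table, fits, correlations)


@dataclass
class PanelCalibrationResults:
    """Calibration table plus the per-cell fit objects."""

    model: PanelCalibration
    table: pd.DataFrame
    fits: dict[tuple[str, str], MarkerLogitResults]
    correlations: dict[tuple[str, str], CorrelationResult] = field(
        default_factory=dict
    )

    def get(self, product: str, subgroup: str = "total") -> MarkerLogitResults | None:
        return self.fits.get((product, subgroup))

    def curves(self, subgroup: str = "total") -> dict[str, LogisticCurve]:
        """Converged, non-separated curves of one subgroup, keyed by product."""
        out = {}
        for (product, rule), res in self.fits.items():
            if rule == subgroup and res.converged and not (
                res.separation and not res.firth
            ):
                out[product] = res.curve
        return out

    def summary(self) -> str:
        cols = ["product", "group", "n", "n_absent", "n_present"]
        lines = ["Marker calibration table (presence vs ADD)", ""]
        hdr = (
            f"{'product':<14}{'group':<18}{'n':>4}{'abs':>5}{'pres':>5}"
            f"{'rho':>8}{'p':>8}{'P50':>7}{'P95':>7}  status"
        )
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for _, r in self.table.iterrows():
            rho = f"{r['rho']:.3f}" if math.isfinite(r["rho"]) else "-"
            p50 = f"{r['p50_add']:.1f}" if math.isfinite(r["p50_add"]) else "n.d."
            p95 = f"{r['p95_add']:.1f}" if math.isfinite(r["p95_add"]) else "n.d."
            lines.append(
                f"{r['product']:<14}{r['group']:<18}{r['n']:>4}{r['n_absent']:>5}"
                f"{r['n_present']:>5}{rho:>8}{r['p_display'] or '-':>8}"
                f"{p50:>7}{p95:>7}  {r['status']}"
            )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "alpha": self.model.alpha,
            "calibrations": [
                {
                    "product": product,
                    "subgroup": rule,
                    "beta0": res.beta0,
                    "beta1": res.beta1,
                    "p50_add": res.p50_add,
                    "p95_add": res.p95_add,
                    "n": res.nobs,
                    "converged": bool(res.converged),
                    "separation": bool(res.separation),
                    "firth": bool(res.firth),
                }
                for (product, rule), res in self.fits.items()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot_curves(self, product: str, ax=None, add_range=(0.0, 40.0)):
        """Overlay one product's fitted curves across subgroups (solid total,
        dashed age-corrected, dotted BMI-corrected)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        styles = {"total": "-", "age_corrected": "--", "bmi_corrected": ":"}
        grid = np.linspace(*add_range, 300)
        for (prod, rule), res in self.fits.items():
            if prod != product or (res.separation and not res.firth):
                continue
            ax.plot(grid, res.predict(grid), styles.get(rule, "-."),
                    label=GROUP_LABELS.get(rule, rule))
        ax.axhline(0.95, ls=":", color="grey", lw=0.8)
        ax.set_xlabel("ADD (°d)")
        ax.set_ylabel("presence probability")
        ax.set_title(product)
        ax.legend()
        return ax


def load_curves(path) -> dict[tuple[str, str], LogisticCurve]:
    """Load a calibration JSON artifact back into curves keyed by
    (product, subgroup)."""
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for c in payload["calibrations"]:
        if c.get("separation") and not c.get("firth"):
            continue
        out[(c["product"], c["subgroup"])] = LogisticCurve(
            c["product"], c["beta0"], c["beta1"]
        )
    return out
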