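"""Propensity-score matching and signal statistics.

Pipeline per drug: logistic propensity model of exposure on four confounders
(age, sex, admission time, main diagnosis), greedy 1:4 nearest-neighbor
matching without replacement inside a caliper (default 0.1 on the raw
propensity scale), unconditional logistic regression of the outcome on
exposure (optionally adjusted for the same four covariates), Wald 95% CI and
two-sided p, Benjamini-Hochberg adjustment across the analyzed drugs, and
the signal rule: positive iff the CI lower bound exceeds 1.

Admission time enters the models as fractional years since a fixed epoch;
the main diagnosis as a categorical grouped by code prefix (default 3
characters) to control cardinality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "DEFAULT_CALIPER",
    "DEFAULT_MATCH_RATIO",
    "SeparationError",
    "MatchedCohort",
    "SignalRow",
    "design_matrix",
    "fit_propensity",
    "match_1to4",
    "estimate_or",
    "adjust_bh",
    "classify_signal",
    "standardized_mean_differences",
    "analyze_drug",
]

logger = logging.getLogger(__name__)

DEFAULT_CALIPER = 0.1
DEFAULT_MATCH_RATIO = 4
EPOCH = pd.Timestamp("2009-01-01")


class SeparationError(RuntimeError):
    """Logistic fit failed because a covariate (nearly) separates the groups."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(
            f"propensity/outcome model degenerate: covariate {covariate!r} "
            "separates the groups"
        )


def design_matrix(
    members: pd.DataFrame, diag_prefix_len: int = 3, epoch: pd.Timestamp = EPOCH
) -> pd.DataFrame:
    """Covariate encoding shared by the propensity and adjusted outcome models."""
    X = pd.DataFrame(index=members.index)
    X["age"] = members["age"].astype(float)
    X["sex_male"] = (members["sex"] == "male").astype(float)
    admit = pd.to_datetime(members["admission_time"])
    X["admit_years"] = (admit - epoch).dt.total_seconds() / (365.25 * 86400.0)
    diag = members["main_diagnosis"].astype(str).str[:diag_prefix_len]
    dummies = pd.get_dummies(diag, prefix="dx", drop_first=True, dtype=float)
    return pd.concat([X, dummies], axis=1)


def _diagnose_separation(y: np.ndarray, X: pd.DataFrame) -> str | None:
    """Name a covariate that fully separates y, if one exists."""
    y = y.astype(bool)
    if y.all() or (~y).all():
        return "(outcome constant)"
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        uniq = np.unique(v)
        if len(uniq) == 2:
            m1 = v == uniq.max()
            if (len(np.unique(y[m1])) == 1 and len(np.unique(y[~m1])) == 1
                    and bool(y[m1][0]) != bool(y[~m1][0])):
                return col
        elif len(uniq) > 2:
            if v[y].min() > v[~y].max() or v[y].max() < v[~y].min():
                return col
    return None


def _fit_logit(y: np.ndarray, X: pd.DataFrame, context: str):
    # zero-variance covariates carry no information and break the Hessian
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X[keep]
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.astype(float), Xc).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        cov = _diagnose_separation(y, X)
        if cov is not None:
            raise SeparationError(cov) from exc
        raise
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 50:
        cov = _diagnose_separation(y, X)
        if cov is not None:
            raise SeparationError(cov)
        logger.warning("%s: logistic fit did not fully converge", context)
    return res


def fit_propensity(members: pd.DataFrame, diag_prefix_len: int = 3) -> np.ndarray:
    """Propensity scores P(exposed | covariates) in (0, 1), one per member row."""
    if members["exposed"].all() or (~members["exposed"]).all():
        raise ValueError("propensity model needs both exposed and unexposed members")
    X = design_matrix(members, diag_prefix_len)
    res = _fit_logit(members["exposed"].to_numpy(), X, "propensity")
    scores = np.asarray(res.predict())
    eps = 1e-12
    return np.clip(scores, eps, 1 - eps)


@dataclass
class MatchedCohort:
    """Result of greedy 1:k caliper matching (indices refer to the member table)."""

    pairs: pd.DataFrame          # columns: set_id, exposed_index, unexposed_index
    matched_exposed: np.ndarray  # member-table indices of matched exposed rows
    dropped_exposed: np.ndarray  # exposed rows with no within-caliper candidate
    scores: np.ndarray
    caliper: float
    ratio: int
    seed: int

    @property
    def member_indices(self) -> np.ndarray:
        return np.concatenate([self.matched_exposed, self.pairs["unexposed_index"].to_numpy()])


def match_1to4(
    scores: np.ndarray,
    exposed: np.ndarray,
    caliper: float = DEFAULT_CALIPER,
    ratio: int = DEFAULT_MATCH_RATIO,
    seed: int = 0,
) -> MatchedCohort:
    """Greedy nearest-neighbor matching without replacement.

    Exposed members are processed in a seeded random order; each receives up
    to `ratio` distinct unexposed neighbors whose propensity score lies
    within `caliper`.  Exposed members with no candidate inside the caliper
    are dropped (and reported).  Deterministic given (scores, seed); ties in
    distance break toward the lower score.
    """
    scores = np.asarray(scores, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    exp_idx = np.flatnonzero(exposed)
    une_idx = np.flatnonzero(~exposed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(exp_idx))

    s_order = np.argsort(scores[une_idx], kind="stable")
    pool_scores = scores[une_idx][s_order]
    pool_member = une_idx[s_order]
    n = len(pool_scores)
    # doubly linked free-list over the sorted pool for O(1) removal
    left = np.arange(n) - 1
    right = np.arange(n) + 1
    alive = np.ones(n, dtype=bool)

    def first_alive_at_or_after(pos: int) -> int:
        while pos < n and not alive[pos]:
            pos = right[pos]
        return pos  # n when exhausted

    def first_alive_before(pos: int) -> int:
        pos = pos - 1
        while pos >= 0 and not alive[pos]:
            pos = left[pos]
        return pos  # -1 when exhausted

    def remove(pos: int) -> None:
        alive[pos] = False
        l, r = left[pos], right[pos]
        if l >= 0:
            right[l] = r
        if r < n:
            left[r] = l

    rows = []
    matched_exposed = []
    dropped = []
    for set_id, oi in enumerate(order):
        e_member = exp_idx[oi]
        p = scores[e_member]
        start = int(np.searchsorted(pool_scores, p))
        got = []
        r = first_alive_at_or_after(start)
        l = first_alive_before(start)
        while len(got) < ratio:
            dl = p - pool_scores[l] if l >= 0 else np.inf
            dr = pool_scores[r] - p if r < n else np.inf
            d = min(dl, dr)
            if d > caliper or not np.isfinite(d):
                break
            if dl <= dr:
                got.append(l)
                nl = left[l]
                remove(l)
                l = nl
                while l >= 0 and not alive[l]:
                    l = left[l]
            else:
                got.append(r)
                nr = right[r]
                remove(r)
                r = nr
                while r < n and not alive[r]:
                    r = right[r]
        if got:
            matched_exposed.append(e_member)
            for g in got:
                rows.append({"set_id": set_id, "exposed_index": e_member,
                             "unexposed_index": pool_member[g]})
        else:
            dropped.append(e_member)

    pairs = pd.DataFrame(rows, columns=["set_id", "exposed_index", "unexposed_index"])
    if dropped:
        logger.info("matching: %d exposed member(s) had no within-caliper candidate", len(dropped))
    return MatchedCohort(
        pairs=pairs,
        matched_exposed=np.array(matched_exposed, dtype=int),
        dropped_exposed=np.array(dropped, dtype=int),
        scores=scores,
        caliper=caliper,
        ratio=ratio,
        seed=seed,
    )


@dataclass
class SignalRow:
    """Per-drug stage-2 result mirroring the signal table."""

    drug_id: str
    n_exposed_with: int
    n_exposed_without: int
    n_unexposed_with: int
    n_unexposed_without: int
    or_estimate: float
    ci_lo: float
    ci_hi: float
    p: float
    p_adj: float | None = None
    signal: str | None = None
    matched_fraction: float = float("nan")

    def classify(self) -> "SignalRow":
        self.signal = classify_signal(self.or_estimate, (self.ci_lo, self.ci_hi))
        return self


def _counts(members: pd.DataFrame) -> tuple[int, int, int, int]:
    e = members["exposed"].astype(bool)
    o = members["outcome"].astype(bool)
    return (
        int((e & o).sum()), int((e & ~o).sum()),
        int((~e & o).sum()), int((~e & ~o).sum()),
    )


def estimate_or(
    members: pd.DataFrame,
    adjusted: bool = True,
    diag_prefix_len: int = 3,
    drug_id: str = "",
) -> SignalRow:
    """Unconditional logistic OR with Wald 95% CI and two-sided p.

    adjusted=True regresses outcome on exposure plus the four covariates;
    adjusted=False on exposure alone (equivalent to the 2x2 cross-product
    ratio).  A zero cell in the unadjusted 2x2 falls back to the
    Haldane-Anscombe 0.5 correction with a warning.
    """
    if len(members) == 0:
        raise ValueError("empty matched cohort")
    a, b, c, d = _counts(members)
    if (a + c == 0) or (b + d == 0):
        raise ValueError("both outcome levels must be present to estimate an OR")

    if not adjusted and min(a, b, c, d) == 0:
        logger.warning("zero cell in 2x2 for %s; applying Haldane-Anscombe correction", drug_id)
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = np.log(aa * dd / (bb * cc))
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    else:
        y = members["outcome"].to_numpy(dtype=float)
        X = pd.DataFrame({"exposed": members["exposed"].to_numpy(dtype=float)},
                         index=members.index)
        if adjusted:
            X = pd.concat([X, design_matrix(members, diag_prefix_len)], axis=1)
        res = _fit_logit(y, X, f"outcome model ({drug_id})")
        log_or = float(res.params["exposed"])
        se = float(res.bse["exposed"])
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (np.exp(log_or - 1.959963984540054 * se), np.exp(log_or + 1.959963984540054 * se))
    return SignalRow(
        drug_id=drug_id,
        n_exposed_with=a, n_exposed_without=b,
        n_unexposed_with=c, n_unexposed_without=d,
        or_estimate=float(np.exp(log_or)), ci_lo=float(ci[0]), ci_hi=float(ci[1]),
        p=float(p),
    ).classify()


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("adjust_bh needs at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_signal(or_estimate: float, ci: tuple[float, float]) -> str:
    """'positive' iff the 95% CI lower bound strictly exceeds 1, else 'negative'."""
    lo, hi = ci
    if not (lo <= or_estimate <= hi):
        raise ValueError(f"inconsistent CI {ci} for OR {or_estimate}")
    return "positive" if lo > 1.0 else "negative"


def standardized_mean_differences(
    members: pd.DataFrame, diag_prefix_len: int = 3
) -> pd.Series:
    """SMD per covariate between exposed and unexposed (pooled-SD denominator)."""
    X = design_matrix(members, diag_prefix_len)
    e = members["exposed"].astype(bool).to_numpy()
    smd = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        m1, m0 = v[e].mean(), v[~e].mean()
        s = np.sqrt((v[e].var(ddof=1) + v[~e].var(ddof=1)) / 2.0)
        smd[col] = 0.0 if s == 0 else (m1 - m0) / s
    return pd.Series(smd, name="smd")


@dataclass
class DrugAnalysis:
    drug_id: str
    row: SignalRow
    matched: MatchedCohort
    smd_pre: pd.Series
    smd_post: pd.Series
    members_matched: pd.DataFrame = field(repr=False, default=None)


def analyze_drug(
    members: pd.DataFrame,
    drug_id: str,
    caliper: float = DEFAULT_CALIPER,
    ratio: int = DEFAULT_MATCH_RATIO,
    adjusted: bool = True,
    diag_prefix_len: int = 3,
    seed: int = 0,
) -> DrugAnalysis:
    """Propensity fit -> matching -> OR for one drug's stacked cohorts."""
    members = members.reset_index(drop=True)
    scores = fit_propensity(members, diag_prefix_len)
    matched = match_1to4(scores, members["exposed"].to_numpy(dtype=bool),
                         caliper, ratio, seed)
    if len(matched.pairs) == 0:
        raise ValueError(f"no matches within caliper for drug {drug_id}")
    sub = members.loc[matched.member_indices]
    row = estimate_or(sub, adjusted=adjusted, diag_prefix_len=diag_prefix_len,
                      drug_id=drug_id)
    n_exposed = int(members["exposed"].sum())
    row.matched_fraction = len(matched.matched_exposed) / n_exposed if n_exposed else float("nan")
    return DrugAnalysis(
        drug_id=drug_id,
        row=row,
        matched=matched,
        smd_pre=standardized_mean_differences(members, diag_prefix_len),
        smd_post=standardized_mean_differences(sub, diag_prefix_len),
        members_matched=sub,
    )
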