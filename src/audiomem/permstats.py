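"""Permutation-based inference cascade.

Implements, from scratch:

* Welch's t statistic and a two-sided permutation t-test (exhaustive
  relabeling when feasible, Monte-Carlo with the add-one correction
  otherwise), with Cohen's d attached;
* a two-factor mixed-design (between x within) permutation ANOVA with
  classical repeated-measures error terms and partial eta-squared;
* a distance-based multivariate permutation test (pseudo-F from the
  partition of a Gower-centered distance matrix, sequential Type-I sums
  of squares) with an optional covariate and optional strata-restricted
  permutations;
* Bonferroni correction.

Monte-Carlo p-values use ``p = (b + 1) / (n_perm + 1)`` so a reported p
is never zero; exhaustive mode reports the exact enumeration proportion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StatResult",
    "welch_t",
    "cohens_d",
    "perm_t_test",
    "perm_anova",
    "dist_perm_manova",
    "bonferroni",
    "validate_model_table",
]

_TIE_TOL = 1e-12


class DegenerateSamplesError(ValueError):
    """Both samples are constant with different means: t is infinite."""


@dataclass(frozen=True)
class StatResult:
    """Outcome of one permutation test term."""

    statistic: float
    p_perm: float
    n_perm: int
    effect_size: float
    effect_size_kind: str  # "cohens_d" or "partial_eta_sq"
    exhaustive: bool
    seed: Optional[int]
    term: Optional[str] = None
    df: Optional[tuple[float, float]] = None


# ---------------------------------------------------------------------------
# two-sample statistics


def welch_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Welch's t: (mean x - mean y) / sqrt(s2x/nx + s2y/ny), ddof=1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    num = x.mean() - y.mean()
    den = math.sqrt(vx / x.size + vy / y.size)
    if den == 0.0:
        if num == 0.0:
            return 0.0
        raise DegenerateSamplesError(
            "both samples are constant with different means (infinite t)"
        )
    return float(num / den)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference with the pooled SD (ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0
        raise DegenerateSamplesError("zero pooled variance with unequal means")
    return float(diff / math.sqrt(sp2))


def _welch_t_batch(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Welch t for X (B, nx) against Y (B, ny)."""
    vx = X.var(axis=1, ddof=1)
    vy = Y.var(axis=1, ddof=1)
    num = X.mean(axis=1) - Y.mean(axis=1)
    den = np.sqrt(vx / X.shape[1] + vy / Y.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    t[(den == 0) & (num == 0)] = 0.0
    return t


def perm_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 5000,
    seed: int = 0,
    alternative: str = "two_sided",
    enumeration_threshold: int = 20_000,
) -> StatResult:
    """Two-sided permutation test of the Welch t over pooled relabelings.

    All ``C(nx + ny, nx)`` relabelings are enumerated when their number
    is at most ``enumeration_threshold``; otherwise ``n_perm``
    Monte-Carlo relabelings are drawn and the add-one correction
    applied.
    """
    if alternative != "two_sided":
        raise ValueError("only the two_sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t_obs = welch_t(x, y)
    d = cohens_d(x, y)
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size

    n_comb = math.comb(n, nx)
    if n_comb <= enumeration_threshold:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), nx)),
            dtype=np.intp,
        ).reshape(n_comb, nx)
        mask = np.zeros((n_comb, n), dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        Xs = pooled[idx]
        Ys = np.broadcast_to(pooled, (n_comb, n))[~mask].reshape(n_comb, n - nx)
        t_star = _welch_t_batch(Xs, Ys)
        p = float(np.mean(np.abs(t_star) >= abs(t_obs) - _TIE_TOL))
        return StatResult(t_obs, p, n_comb, d, "cohens_d", True, seed)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
    )
    shuffled = pooled[perms]
    t_star = _welch_t_batch(shuffled[:, :nx], shuffled[:, nx:])
    b = int(np.sum(np.abs(t_star) >= abs(t_obs) - _TIE_TOL))
    p = (b + 1) / (n_perm + 1)
    return StatResult(t_obs, p, n_perm, d, "cohens_d", False, seed)


# ---------------------------------------------------------------------------
# mixed-design (between x within) ANOVA


def validate_model_table(
    table: pd.DataFrame, responses: Sequence[str]
) -> None:
    """Check the subject/group/difficulty table is complete and balanced."""
    required = {"subject_id", "group", "difficulty"} | set(responses)
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"model table missing columns: {sorted(missing)}")
    if table[list(responses)].isna().any().any():
        raise ValueError("model table contains missing responses")
    levels = sorted(table["difficulty"].unique())
    per_subject = table.groupby("subject_id")["difficulty"].agg(
        lambda s: sorted(s.tolist())
    )
    if not all(v == levels for v in per_subject):
        raise ValueError(
            "unbalanced design: every subject needs exactly one row per "
            "difficulty level"
        )
    groups_per_subject = table.groupby("subject_id")["group"].nunique()
    if (groups_per_subject != 1).any():
        raise ValueError("a subject cannot belong to two groups")
    n_per_group = table.drop_duplicates("subject_id").groupby("group").size()
    if len(n_per_group) < 2 or (n_per_group < 2).any():
        raise ValueError("need at least 2 groups with >= 2 subjects each")


class _MixedDesign:
    """Precomputed index structure of a balanced mixed design."""

    def __init__(self, table: pd.DataFrame):
        subjects = table["subject_id"].astype(str).to_numpy()
        subj_labels, self.subj = np.unique(subjects, return_inverse=True)
        group_labels, grp_rows = np.unique(
            table["group"].astype(str).to_numpy(), return_inverse=True
        )
        lvl_labels, self.level = np.unique(
            table["difficulty"].astype(str).to_numpy(), return_inverse=True
        )
        self.n = len(table)
        self.N = len(subj_labels)  # subjects
        self.a = len(group_labels)  # groups
        self.b = len(lvl_labels)  # within levels
        # group of each subject
        self.gsub = np.zeros(self.N, dtype=np.intp)
        self.gsub[self.subj] = grp_rows
        self.n_g = np.bincount(self.gsub, minlength=self.a)
        # row indicator matrices
        self.S = np.zeros((self.n, self.N))
        self.S[np.arange(self.n), self.subj] = 1.0
        self.L = np.zeros((self.n, self.b))
        self.L[np.arange(self.n), self.level] = 1.0
        cell = grp_rows * self.b + self.level
        self.C = np.zeros((self.n, self.a * self.b))
        self.C[np.arange(self.n), cell] = 1.0
        self.cell_n = self.C.sum(axis=0)
        self.grp_rows = grp_rows
        self.row_n_group = np.bincount(grp_rows, minlength=self.a)

    def f_stats(self, Y: np.ndarray, return_ss: bool = False):
        """F statistics (group, difficulty, interaction) for rows of Y.

        Y has shape (B, n); returns three (B,) arrays (plus the SS/df
        decomposition when ``return_ss``).
        """
        grand = Y.mean(axis=1, keepdims=True)
        Yc = Y - grand
        ss_total = np.sum(Yc**2, axis=1)

        subj_means = (Y @ self.S) / self.b  # (B, N)
        ss_between_subj = self.b * np.sum(
            (subj_means - grand) ** 2, axis=1
        )
        group_means = (Y @ self.S @ _group_agg(self.gsub, self.a)) / (
            self.b * self.n_g
        )
        ss_A = self.b * np.sum(
            self.n_g * (group_means - grand) ** 2, axis=1
        )
        level_means = (Y @ self.L) / self.N
        ss_B = self.N * np.sum((level_means - grand) ** 2, axis=1)
        cell_means = (Y @ self.C) / self.cell_n
        ss_cells = np.sum(self.cell_n * (cell_means - grand) ** 2, axis=1)
        ss_AB = ss_cells - ss_A - ss_B
        ss_subj = ss_between_subj - ss_A
        ss_err = ss_total - ss_between_subj - ss_B - ss_AB

        df_A = self.a - 1
        df_subj = self.N - self.a
        df_B = self.b - 1
        df_AB = df_A * df_B
        df_err = df_subj * df_B

        f_A = _safe_f(ss_A, df_A, ss_subj, df_subj)
        f_B = _safe_f(ss_B, df_B, ss_err, df_err)
        f_AB = _safe_f(ss_AB, df_AB, ss_err, df_err)
        if not return_ss:
            return f_A, f_B, f_AB
        ss = {
            "group": (ss_A, df_A, ss_subj, df_subj),
            "difficulty": (ss_B, df_B, ss_err, df_err),
            "group:difficulty": (ss_AB, df_AB, ss_err, df_err),
        }
        return (f_A, f_B, f_AB), ss

    def reduced_fit(self, y: np.ndarray, term: str) -> np.ndarray:
        """Fitted values of the fixed-effects model without ``term``."""
        if term == "group":
            X = self.L
        elif term == "difficulty":
            X = np.column_stack([np.ones(self.n), _dummies(self.grp_rows, self.a)])
        elif term == "group:difficulty":
            X = np.column_stack(
                [
                    np.ones(self.n),
                    _dummies(self.grp_rows, self.a),
                    _dummies(self.level, self.b),
                ]
            )
        else:  # pragma: no cover - internal
            raise ValueError(term)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ beta


def _group_agg(gsub: np.ndarray, a: int) -> np.ndarray:
    M = np.zeros((len(gsub), a))
    M[np.arange(len(gsub)), gsub] = 1.0
    return M


def _dummies(codes: np.ndarray, k: int) -> np.ndarray:
    """Treatment (drop-first) dummy columns for integer codes."""
    M = np.zeros((len(codes), k - 1))
    for j in range(1, k):
        M[codes == j, j - 1] = 1.0
    return M


def _safe_f(ss_eff, df_eff, ss_err, df_err):
    ss_eff = np.atleast_1d(np.asarray(ss_eff, dtype=float))
    ss_err = np.atleast_1d(np.asarray(ss_err, dtype=float))
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_eff / ms_err
    f[np.isclose(ss_eff, 0.0, atol=1e-300)] = 0.0
    return f


def _partial_eta_sq(ss_eff: float, ss_err: float) -> float:
    tot = ss_eff + ss_err
    return float(ss_eff / tot) if tot > 0 else 0.0


def perm_anova(
    table: pd.DataFrame,
    response: str,
    n_perm: int = 5000,
    seed: int = 0,
    scheme: str = "raw",
    enumeration_threshold: int = 40_320,
) -> dict[str, StatResult]:
    """Two-factor mixed-design permutation ANOVA of one response column.

    The F statistics use the classical repeated-measures decomposition
    (the between factor is tested against subject-within-group error;
    the within factor and the interaction against the residual
    difficulty-by-subject error).  Only the reference distribution is
    obtained by permutation:

    ``raw``
        unrestricted permutation of the response values across all rows
        (exhaustively enumerated when ``n!`` is small enough);
    ``residual``
        Freedman-Lane permutation of the residuals of the reduced model
        for each term.

    Returns a mapping of term name (``group``, ``difficulty``,
    ``group:difficulty``) to :class:`StatResult` with partial
    eta-squared effect sizes.
    """
    if scheme not in ("raw", "residual"):
        raise ValueError("scheme must be 'raw' or 'residual'")
    validate_model_table(table, [response])
    design = _MixedDesign(table)
    y = table[response].to_numpy(dtype=float)
    (f_obs, ss) = _observed_anova(design, y)

    terms = ("group", "difficulty", "group:difficulty")
    exhaustive = (
        scheme == "raw" and math.factorial(design.n) <= enumeration_threshold
    )
    if exhaustive:
        perms = np.array(
            list(itertools.permutations(range(design.n))), dtype=np.intp
        )
        f_star = design.f_stats(y[perms])
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(
            np.broadcast_to(np.arange(design.n), (n_perm, design.n)).copy(),
            axis=1,
        )
        n_used = n_perm
        if scheme == "raw":
            f_star = design.f_stats(y[perms])
        else:
            f_star = _freedman_lane(design, y, perms, terms)

    results: dict[str, StatResult] = {}
    for k, term in enumerate(terms):
        stars = f_star[k]
        hits = np.sum(stars >= f_obs[k] - _TIE_TOL)
        if exhaustive:
            p = float(hits / n_used)
        else:
            p = float((hits + 1) / (n_used + 1))
        ss_eff, df_eff, ss_err, df_err = ss[term]
        results[term] = StatResult(
            statistic=float(f_obs[k]),
            p_perm=p,
            n_perm=n_used,
            effect_size=_partial_eta_sq(float(ss_eff), float(ss_err)),
            effect_size_kind="partial_eta_sq",
            exhaustive=exhaustive,
            seed=seed,
            term=term,
            df=(float(df_eff), float(df_err)),
        )
    return results


def _observed_anova(design: _MixedDesign, y: np.ndarray):
    (fa, fb, fab), ss = design.f_stats(y[None, :], return_ss=True)
    ss = {
        term: (v[0][0], v[1], v[2][0], v[3]) for term, v in ss.items()
    }
    return (float(fa[0]), float(fb[0]), float(fab[0])), ss


def _freedman_lane(design, y, perms, terms):
    out = []
    for k, term in enumerate(terms):
        fit = design.reduced_fit(y, term)
        resid = y - fit
        y_star = fit[None, :] + resid[perms]
        out.append(design.f_stats(y_star)[k])
    return out


# ---------------------------------------------------------------------------
# distance-based multivariate permutation test


def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ (-0.5 * D2) @ J


def _term_columns(
    table: pd.DataFrame, term: str
) -> np.ndarray:
    """Design columns of one formula term (treatment coding, centered age)."""
    parts = term.split(":")
    cols = None
    for part in parts:
        if part not in table.columns:
            raise ValueError(f"unknown term component {part!r}")
        v = table[part]
        if np.issubdtype(v.dtype, np.number):
            block = (v.to_numpy(dtype=float) - v.to_numpy(dtype=float).mean())[
                :, None
            ]
        else:
            labels, codes = np.unique(v.astype(str).to_numpy(), return_inverse=True)
            if len(labels) < 2:
                raise ValueError(f"term {part!r} has no variation")
            block = _dummies(codes, len(labels))
        cols = block if cols is None else _interact(cols, block)
    return cols


def _interact(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [A[:, i : i + 1] * B for i in range(A.shape[1])], axis=1
    )


def dist_perm_manova(
    table: pd.DataFrame,
    responses: Sequence[str],
    terms: Sequence[str] = ("group", "difficulty", "age", "group:difficulty"),
    distance: str = "euclidean_standardized",
    n_perm: int = 5000,
    seed: int = 0,
    strata: Optional[str] = None,
    enumeration_threshold: int = 40_320,
) -> dict[str, StatResult]:
    """Distance-matrix partition test with sequential (Type-I) pseudo-F.

    Response columns are z-standardized, pairwise Euclidean distances
    Gower-centered, and the centered matrix partitioned along the model
    sequence given by ``terms``.  Each term's pseudo-F is
    ``(SS_term / df_term) / (SS_residual / df_residual)`` and its
    p-value comes from permuting rows of the distance matrix (free by
    default; restricted within the levels of ``strata`` if given).
    Effect sizes are multivariate partial eta-squared,
    ``SS_term / (SS_term + SS_residual)``.
    """
    if distance not in ("euclidean_standardized", "euclidean"):
        raise ValueError(f"unsupported distance {distance!r}")
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    Y = table[list(responses)].to_numpy(dtype=float)
    if distance == "euclidean_standardized":
        sd = Y.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [responses[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant response column(s): {const}")
        Y = (Y - Y.mean(axis=0)) / sd
    sq = np.sum(Y**2, axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T), 0.0)
    G = _gower_center(D2)
    n = len(table)
    ss_total = float(np.trace(G))
    if ss_total <= 0:
        raise ValueError("zero total sum of squares")

    # sequential hat matrices
    X = np.ones((n, 1))
    hats = []
    ranks = [1]
    for term in terms:
        X = np.column_stack([X, _term_columns(table, term)])
        Q, R = np.linalg.qr(X)
        rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(n, X.shape[1])))
        keep = Q[:, : X.shape[1]]
        hats.append(keep @ keep.T)
        ranks.append(rank)
    dfs = np.diff(ranks)
    if np.any(dfs == 0):
        bad = [t for t, d in zip(terms, dfs) if d == 0]
        raise ValueError(f"singular term(s) with no added variation: {bad}")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    def term_ss(Gp: np.ndarray) -> np.ndarray:
        # tr(H G H) = tr(H G) for idempotent symmetric H
        traces = np.array([np.sum(H * Gp) for H in hats])
        ss = np.diff(np.concatenate([[0.0], traces]))
        ss_res = float(np.trace(Gp)) - traces[-1]
        return ss, ss_res

    ss_obs, ss_res_obs = term_ss(G)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_obs / dfs) / (ss_res_obs / df_res)

    perms = _row_permutations(
        table, n, n_perm, seed, strata, enumeration_threshold
    )
    exhaustive = isinstance(perms, tuple)
    if exhaustive:
        perms = perms[0]
    hits = np.zeros(len(terms))
    for pi in perms:
        Gp = G[np.ix_(pi, pi)]
        ss_p, ss_res_p = term_ss(Gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ss_p / dfs) / (ss_res_p / df_res)
        hits += f_p >= f_obs - _TIE_TOL
    n_used = len(perms)
    if exhaustive:
        p_vals = hits / n_used
    else:
        p_vals = (hits + 1) / (n_used + 1)

    results = {}
    for k, term in enumerate(terms):
        results[term] = StatResult(
            statistic=float(f_obs[k]),
            p_perm=float(p_vals[k]),
            n_perm=n_used,
            effect_size=_partial_eta_sq(float(ss_obs[k]), ss_res_obs),
            effect_size_kind="partial_eta_sq",
            exhaustive=exhaustive,
            seed=seed,
            term=term,
            df=(float(dfs[k]), float(df_res)),
        )
    return results


def _row_permutations(table, n, n_perm, seed, strata, enumeration_threshold):
    if strata is None:
        if math.factorial(n) <= enumeration_threshold:
            return (np.array(list(itertools.permutations(range(n))), dtype=np.intp),)
        rng = np.random.default_rng(seed)
        return rng.permuted(
            np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
        )
    codes = table[strata].astype(str).to_numpy()
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(codes == g) for g in np.unique(codes)]
    perms = np.broadcast_to(np.arange(n), (n_perm, n)).copy()
    for idx in groups:
        sub = rng.permuted(np.broadcast_to(idx, (n_perm, len(idx))).copy(), axis=1)
        perms[:, idx] = sub
    return perms


def bonferroni(
    p_values: Iterable[float], family_size: Optional[int] = None
) -> list[float]:
    """Multiply each p-value by the family size, capping at 1."""
    ps = list(p_values)
    if not ps:
        raise ValueError("empty p-value list")
    m = family_size if family_size is not None else len(ps)
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    return [min(1.0, p * m) for p in ps]
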