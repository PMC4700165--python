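"""Stepwise multilinear-regression feature filter.

Features are screened by forward/backward stepwise regression of a numeric
response on the feature columns: at each step the excluded feature with the
smallest partial-F p-value is added if it clears the entrance tolerance,
then included terms whose p-value has drifted above the (larger) exit
tolerance are removed.  The procedure starts from an intercept-only model
and stops at a fixed point; with ``p_remove > p_enter`` a term can never be
re-added at the step it was removed, so the iteration terminates.

Class labels enter through indicator responses: a binary problem is a
single 0/1 regression, a multiclass problem runs one one-vs-rest indicator
regression per class and takes the union of the per-class selections.

The partial F-test is scale-invariant, so features are used raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["SelectionResult", "stepwise_select", "encode_response", "select_features"]

P_ENTER_DEFAULT = 0.01
P_REMOVE_DEFAULT = 0.02

#: Relative tolerance below which a residualized candidate column is
#: considered collinear with the current model and skipped.
_COLLINEAR_RTOL = 1e-10


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one stepwise run: ordered selected column indices, the
    final per-term p-values, and the add/remove history."""

    selected: tuple[int, ...]
    p_values: dict[int, float]
    history: tuple[tuple[str, int, float], ...]  # ("add"|"remove", index, p)


def _term_p_values(X: np.ndarray, y: np.ndarray, idx: list[int]) -> np.ndarray:
    """Partial-F p-values of each term in the model [intercept, X[:, idx]].

    For a single added/kept column the partial F equals the squared
    t-statistic of its coefficient, so p-values come from the coefficient
    standard errors of one least-squares fit.
    """
    n = X.shape[0]
    D = np.column_stack([np.ones(n), X[:, idx]])
    p = D.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    dof = n - p
    if dof <= 0 or rank < p:
        return np.full(len(idx), np.nan)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    f_stat = t[1:] ** 2  # drop the intercept term
    return stats.f.sf(f_stat, 1, dof)


def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
    max_steps: int = 1000,
) -> SelectionResult:
    """Forward/backward stepwise selection by partial-F p-values.

    Deterministic: candidates tied on p-value are resolved toward the
    lowest column index.  Collinear candidates (residual norm ~ 0 against
    the current model) are skipped, and no term is added once the model
    size reaches the sample size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, m) and y must be (n,)")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    if not p_remove > p_enter:
        raise ValueError("p_remove must exceed p_enter to prevent cycling")

    n, m = X.shape
    included: list[int] = []
    history: list[tuple[str, int, float]] = []
    col_sq = (X * X).sum(axis=0)

    for _ in range(max_steps):
        changed = False

        # --- forward step: residualize all excluded candidates at once
        if len(included) + 1 < n - 1:
            D = np.column_stack([np.ones(n), X[:, included]])
            Q, _ = np.linalg.qr(D)
            r_y = y - Q @ (Q.T @ y)
            rss0 = float(r_y @ r_y)
            excluded = [j for j in range(m) if j not in included]
            if excluded and rss0 > 0:
                Xc = X[:, excluded]
                R = Xc - Q @ (Q.T @ Xc)
                rnorm2 = (R * R).sum(axis=0)
                ok = rnorm2 > _COLLINEAR_RTOL * np.maximum(col_sq[excluded], 1.0)
                proj = R.T @ r_y
                dof = n - len(included) - 2
                with np.errstate(divide="ignore", invalid="ignore"):
                    rss_drop = np.where(ok, proj**2 / rnorm2, 0.0)
                    rss1 = np.maximum(rss0 - rss_drop, 0.0)
                    f_stat = np.where(
                        ok & (rss1 > 0), rss_drop / (rss1 / max(dof, 1)), 0.0
                    )
                pvals = np.where(ok & (dof > 0), stats.f.sf(f_stat, 1, max(dof, 1)), np.inf)
                best = int(np.argmin(pvals))  # argmin takes the lowest index on ties
                if pvals[best] < p_enter:
                    j = excluded[best]
                    included.append(j)
                    history.append(("add", j, float(pvals[best])))
                    changed = True

        # --- backward step: drop the worst term above the exit tolerance
        if included:
            pv = _term_p_values(X, y, included)
            worst = int(np.nanargmax(pv)) if not np.all(np.isnan(pv)) else None
            if worst is not None and pv[worst] > p_remove:
                j = included.pop(worst)
                history.append(("remove", j, float(pv[worst])))
                changed = True

        if not changed:
            break

    final_p = {}
    if included:
        pv = _term_p_values(X, y, included)
        final_p = {j: float(p) for j, p in zip(included, pv)}
    return SelectionResult(
        selected=tuple(included), p_values=final_p, history=tuple(history)
    )


def encode_response(labels: np.ndarray, classes: list | None = None) -> dict[object, np.ndarray]:
    """Numeric indicator responses for a label vector.

    Two classes give a single 0/1 vector (keyed by the positive class,
    the second in sorted order); more classes give one one-vs-rest 0/1
    indicator per class.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes in the fold")
    if len(classes) == 2:
        pos = classes[1]
        return {pos: (labels == pos).astype(float)}
    return {c: (labels == c).astype(float) for c in classes}


def select_features(
    X: np.ndarray,
    labels: np.ndarray,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
) -> tuple[int, ...]:
    """Stepwise selection against class labels.

    Runs one stepwise regression per indicator response and returns the
    sorted union of the selected column indices.
    """
    chosen: set[int] = set()
    for _, y in encode_response(labels).items():
        res = stepwise_select(X, y, p_enter=p_enter, p_remove=p_remove)
        chosen.update(res.selected)
    return tuple(sorted(chosen))
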