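"""Mixed-model group comparison and blocked cross-validation.

Per-trial metrics (LRV, %REC, Lmax) are compared between groups
(professional vs amateur) with a linear mixed model: group as the fixed
effect and crossed random intercepts for participant and trial index.
The group effect is tested with a Type-3 Wald chi-square; effect size is
a partial eta squared computed on participant-level residual degrees of
freedom.  Robustness to the small sample is probed with repeated blocked
k-fold cross-validation in which all trials of a participant travel into
the same fold, comparing an intercept-only regression against an
intercept + group regression on held-out prediction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sci_stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMMResult",
    "BlockedCVResult",
    "fit_group_lmm",
    "partial_eta_squared",
    "blocked_cv_compare",
    "outlier_sensitivity",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = ("participant", "group", "trial")
GROUPS = ("amateur", "professional")


@dataclass(frozen=True)
class LMMResult:
    """Group fixed effect from the mixed model."""

    response: str
    beta: float            # professional minus amateur, response units
    se: float
    wald_chisq: float
    df: int
    p_value: float
    partial_eta_sq: float
    ci95: tuple[float, float]
    n_obs: int
    n_participants: int
    converged: bool
    singular: bool         # a variance component collapsed to ~0


@dataclass(frozen=True)
class BlockedCVResult:
    """Repeated blocked k-fold model comparison."""

    response: str
    reps: int
    folds: int
    model2_wins: int       # reps where intercept+group beat intercept-only
    mean_err_model1: float
    mean_err_model2: float
    seed: int


def _validate_table(table: pd.DataFrame, response: str) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, response) if c not in table.columns]
    if missing:
        raise ValueError(f"observation table lacks columns: {missing}")
    if table[response].isna().any():
        raise ValueError(f"missing values in response '{response}'")
    bad = set(table["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    gp = table.groupby("group")["participant"].nunique()
    if len(gp) < 2 or (gp < 2).any():
        raise ValueError("need at least 2 participants per group")
    multi = table.groupby("participant")["group"].nunique()
    if (multi > 1).any():
        raise ValueError("a participant appears in more than one group")


def partial_eta_squared(wald_chisq: float, n_participants: int,
                        n_fixed: int = 2) -> float:
    """Partial eta squared from a Wald chi-square.

    ``eta_p^2 = chi^2 / (chi^2 + df_resid)`` with the residual degrees of
    freedom taken at the level of the independent units:
    ``df_resid = n_participants - n_fixed`` (group comparisons are
    between-participant contrasts, so the repeated trials do not add
    independent information).
    """
    if wald_chisq < 0:
        raise ValueError("chi-square must be non-negative")
    df_resid = n_participants - n_fixed
    if df_resid <= 0:
        raise ValueError("too few participants for the fixed-effect count")
    return wald_chisq / (wald_chisq + df_resid)


def fit_group_lmm(table: pd.DataFrame, response: str,
                  reml: bool = True) -> LMMResult:
    """Mixed model: response ~ group + (1|participant) + (1|trial).

    Crossed random intercepts for participant and trial index; the group
    effect (professional minus amateur) is tested with a Wald chi-square
    on 1 df.  Singular fits (a variance component at the zero boundary)
    are flagged but estimates are still returned.
    """
    _validate_table(table, response)
    n_pp = table["participant"].nunique()
    if table[response].nunique() == 1:
        # degenerate: no variance anywhere, group effect exactly zero
        return LMMResult(response=response, beta=0.0, se=0.0, wald_chisq=0.0,
                         df=1, p_value=1.0,
                         partial_eta_sq=partial_eta_squared(0.0, n_pp),
                         ci95=(0.0, 0.0), n_obs=len(table),
                         n_participants=n_pp, converged=True, singular=True)
    df = table.copy()
    df["_one"] = 1
    formula = f"{response} ~ C(group, Treatment('amateur'))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        md = smf.mixedlm(formula, data=df, groups="_one",
                         vc_formula={"participant": "0 + C(participant)",
                                     "trial": "0 + C(trial)"})
        res = md.fit(reml=reml)
    term = "C(group, Treatment('amateur'))[T.professional]"
    beta = float(res.fe_params[term])
    se = float(res.bse_fe[term])
    chisq = (beta / se) ** 2 if se > 0 else float("inf")
    p = float(sci_stats.chi2.sf(chisq, df=1))
    ci = (beta - 1.959963984540054 * se, beta + 1.959963984540054 * se)
    vcs = np.asarray(res.vcomp, dtype=float)
    scale = float(res.scale)
    singular = bool(np.any(vcs < 1e-8 * max(scale, 1e-12)))
    return LMMResult(
        response=response, beta=beta, se=se, wald_chisq=float(chisq), df=1,
        p_value=p, partial_eta_sq=partial_eta_squared(chisq, n_pp),
        ci95=ci, n_obs=len(table), n_participants=n_pp,
        converged=bool(res.converged), singular=singular,
    )


def _fold_assignment(participants: np.ndarray, k: int,
                     rng: np.random.Generator) -> dict[str, int]:
    order = rng.permutation(participants)
    folds = np.arange(len(order)) % k
    return dict(zip(order, folds))


def blocked_cv_compare(table: pd.DataFrame, response: str, k: int = 5,
                       reps: int = 2000, seed: int = 0) -> BlockedCVResult:
    """Repeated blocked k-fold comparison of two regression models.

    Model 1 predicts with the training-fold mean (intercept only);
    Model 2 predicts with training-fold group means (intercept + group).
    All trials of a participant are confined to one fold, so held-out
    prediction is always for unseen participants.  A repetition is a
    Model-2 win iff its total squared prediction error is strictly lower.
    """
    _validate_table(table, response)
    participants = np.sort(table["participant"].unique())
    if k > len(participants):
        raise ValueError(f"k={k} exceeds the {len(participants)} participants")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    y = table[response].to_numpy(dtype=float)
    pid = table["participant"].to_numpy()
    is_pro = (table["group"] == "professional").to_numpy()
    wins = 0
    tot1 = 0.0
    tot2 = 0.0
    for _ in range(reps):
        assign = _fold_assignment(participants, k, rng)
        fold_of_row = np.array([assign[p] for p in pid])
        err1 = 0.0
        err2 = 0.0
        for f in range(k):
            test = fold_of_row == f
            train = ~test
            if not test.any():
                continue
            mu = y[train].mean()
            err1 += float(np.sum((y[test] - mu) ** 2))
            pred = np.full(test.sum(), mu)
            for grp_mask in (is_pro, ~is_pro):
                tr = train & grp_mask
                if tr.any():
                    pred[grp_mask[test]] = y[tr].mean()
            err2 += float(np.sum((y[test] - pred) ** 2))
        tot1 += err1
        tot2 += err2
        if err2 < err1:
            wins += 1
    return BlockedCVResult(response=response, reps=reps, folds=k,
                           model2_wins=wins, mean_err_model1=tot1 / reps,
                           mean_err_model2=tot2 / reps, seed=seed)


def outlier_sensitivity(table: pd.DataFrame, response: str,
                        exclude: str, reml: bool = True) -> LMMResult:
    """Refit the group mixed model after dropping one participant."""
    if exclude not in set(table["participant"]):
        raise ValueError(f"participant '{exclude}' not in table")
    sub = table[table["participant"] != exclude]
    if sub["group"].nunique() < 2:
        raise ValueError("exclusion empties a group")
    return fit_group_lmm(sub, response, reml=reml)
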