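"""Population- and individual-level inference.

Implements the classical toolkit used to relate capacity to trade-off
ability: paired t-tests with Cohen's d (d = mean(diff)/sd(diff)), the
JZS default Bayes factor for the paired contrast, a mixed-design ANOVA
(one two-level within-subject factor crossed with categorical
between-subject factors, balanced designs only) with eta-squared, and
one-tailed Pearson correlations.

The JZS Bayes factor places a Cauchy(0, r) prior on the standardised
effect (default scale r = sqrt(2)/2, the common one-sample default) and
evaluates the marginal-likelihood ratio by adaptive quadrature over the
Zellner-Siow mixing variable g:

    BF10 = int_0^inf (1+Ng)^(-1/2) [1 + t^2/((1+Ng) v)]^(-(v+1)/2) pi(g) dg
           / [1 + t^2/v]^(-(v+1)/2)

with v = N - 1 and pi(g) an inverse-gamma(1/2, r^2/2) density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import DesignError, EstimationError

__all__ = [
    "PairedTestResult",
    "AnovaEffect",
    "CorrelationResult",
    "paired_t",
    "jzs_bf10",
    "mixed_anova",
    "pearson_one_tailed",
]

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    bf10: float

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "cohens_d": self.cohens_d,
            "bf10": self.bf10,
        }


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    f: float
    df1: int
    df2: int
    p: float
    eta_sq: float
    eta_sq_partial: float

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.f,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "eta_sq": self.eta_sq,
            "eta_sq_partial": self.eta_sq_partial,
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    direction: str

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n, "direction": self.direction}


def paired_t(x, y, prior_scale: float = DEFAULT_PRIOR_SCALE) -> PairedTestResult:
    """Paired two-tailed t-test with Cohen's d and the JZS Bayes factor.

    Cohen's d is the standardised mean difference mean(diff)/sd(diff).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):
            # identical samples: no evidence of any difference
            return PairedTestResult(
                t=0.0, df=n - 1, p=1.0, cohens_d=0.0,
                bf10=jzs_bf10(0.0, n, prior_scale),
            )
        raise EstimationError("paired t undefined: differences have zero variance")
    t = float(diff.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    d = float(diff.mean() / sd)
    return PairedTestResult(t=t, df=df, p=p, cohens_d=d, bf10=jzs_bf10(t, n, prior_scale))


def _jzs_integrand(g: np.ndarray, t: float, n: int, r: float) -> np.ndarray:
    v = n - 1
    # inverse-gamma(1/2, r^2/2) density on g
    prior = (
        (r**2 / 2.0) ** 0.5 / math.gamma(0.5) * g ** (-1.5) * np.exp(-(r**2) / (2.0 * g))
    )
    like = (1.0 + n * g) ** -0.5 * (1.0 + t**2 / ((1.0 + n * g) * v)) ** (
        -(v + 1) / 2.0
    )
    return like * prior


def jzs_bf10(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS default Bayes factor BF10 for a one-sample/paired t statistic.

    Values above 1 favour the alternative, below 1 the null. Evaluated by
    adaptive quadrature; raises on quadrature failure.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be > 0")
    v = n - 1
    null_like = (1.0 + t**2 / v) ** (-(v + 1) / 2.0)
    with np.errstate(over="ignore", under="ignore"):
        alt_like, err = integrate.quad(
            _jzs_integrand,
            0.0,
            np.inf,
            args=(float(t), int(n), float(prior_scale)),
            epsabs=0.0,
            epsrel=1e-10,
            limit=200,
        )
    if not np.isfinite(alt_like) or alt_like <= 0:
        raise ArithmeticError(
            f"JZS quadrature failed (value {alt_like}, abs err {err})"
        )
    if err > 1e-6 * alt_like:
        raise ArithmeticError(
            f"JZS quadrature did not converge (rel err {err / alt_like:.2e})"
        )
    return float(alt_like / null_like)


def pearson_one_tailed(x, y, direction: str = "positive") -> CorrelationResult:
    """Pearson correlation with a one-tailed p in the stated direction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("need paired 1-D samples with n >= 3")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    if x.std() == 0.0 or y.std() == 0.0:
        raise EstimationError("correlation undefined: zero variance input")
    alternative = "greater" if direction == "positive" else "less"
    res = stats.pearsonr(x, y, alternative=alternative)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=int(x.shape[0]), direction=direction
    )


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: list[str] | str,
) -> list[AnovaEffect]:
    """Mixed-design ANOVA: one two-level within factor x between factors.

    Requires a balanced design (every subject observed at both within
    levels; equal cell sizes across between-factor cells). Sums of
    squares are computed by stratum: between-subject effects from the
    subject means, the within effect and its interactions from the
    subject difference scores — exact for two-level within factors, and
    identical to Type III SS on balanced data. ``eta_sq`` is classical
    (SS_effect / SS_total); a partial variant is also reported.
    """
    if isinstance(between, str):
        between = [between]
    for col in [dv, within, subject, *between]:
        if col not in table.columns:
            raise DesignError(f"column {col!r} missing from table")
    levels = sorted(table[within].unique())
    if len(levels) != 2:
        raise DesignError(f"within factor must have exactly 2 levels, got {levels}")
    wide = table.pivot_table(
        index=[subject, *between], columns=within, values=dv, aggfunc="mean"
    )
    if wide.isna().any().any():
        raise DesignError("missing cells: every subject needs both within levels")
    wide = wide.reset_index()
    n_subj = len(wide)
    if between:
        cells = wide.groupby(between, observed=True).size()
        if cells.nunique() != 1:
            raise DesignError(
                f"unbalanced between-subject design (cell sizes {sorted(set(cells))})"
            )
        n_cells = len(cells)
    else:
        n_cells = 1
    y1 = wide[levels[0]].to_numpy(dtype=float)
    y2 = wide[levels[1]].to_numpy(dtype=float)
    means = (y1 + y2) / 2.0
    diffs = y1 - y2
    grand = float(np.concatenate([y1, y2]).mean())
    ss_total = float(((y1 - grand) ** 2).sum() + ((y2 - grand) ** 2).sum())

    factors = [wide[b].astype("category") for b in between]

    # --- between-subject stratum: ANOVA on subject means (SS doubled,
    # each mean standing for two observations)
    between_ss = _factorial_ss(means, factors)
    ss_between_err = 2.0 * between_ss.pop("__resid__")
    df_between_err = n_subj - n_cells

    # --- within-subject stratum: ANOVA on difference scores (SS halved)
    within_ss = _factorial_ss(diffs, factors)
    ss_within_err = within_ss.pop("__resid__") / 2.0
    ss_within_main = n_subj * float(np.mean(diffs)) ** 2 / 2.0
    df_within_err = n_subj - n_cells

    effects: list[AnovaEffect] = []

    def add(name: str, ss: float, df1: int, ss_err: float, df_err: int):
        ms = ss / df1
        ms_err = ss_err / df_err
        if ms_err > 0:
            f = ms / ms_err
        else:
            f = 0.0 if ms == 0 else np.inf
        p = float(stats.f.sf(f, df1, df_err))
        effects.append(
            AnovaEffect(
                effect=name,
                f=float(f),
                df1=df1,
                df2=df_err,
                p=p,
                eta_sq=float(ss / ss_total) if ss_total > 0 else 0.0,
                eta_sq_partial=float(ss / (ss + ss_err)) if (ss + ss_err) > 0 else 0.0,
            )
        )

    for name, (ss, df1) in between_ss.items():
        add(name, 2.0 * ss, df1, ss_between_err, df_between_err)
    add(within, ss_within_main, 1, ss_within_err, df_within_err)
    for name, (ss, df1) in within_ss.items():
        add(f"{within} * {name}", ss / 2.0, df1, ss_within_err, df_within_err)
    return effects


def _factorial_ss(y: np.ndarray, factors: list[pd.Series]):
    """Full-factorial sums of squares for a balanced design.

    Returns {effect_name: (SS, df)} for all main effects and
    interactions among ``factors``, plus the residual SS under
    '__resid__'. Computed by Yates-style marginal means, valid because
    the design is balanced.
    """
    import itertools

    n = y.shape[0]
    grand = float(y.mean())
    names = [f.name for f in factors]
    codes = pd.DataFrame({f.name: f.to_numpy() for f in factors})
    results: dict = {}
    ss_model = 0.0
    # cell-mean based SS via inclusion-exclusion over factor subsets
    subset_ss: dict[frozenset, float] = {}
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(range(len(factors)), k):
            cols = [names[i] for i in combo]
            cell_means = pd.Series(y).groupby(
                [codes[c] for c in cols], observed=True
            ).transform("mean").to_numpy()
            ss_cells = float(((cell_means - grand) ** 2).sum())
            ss = ss_cells - sum(
                subset_ss[s]
                for s in subset_ss
                if s < frozenset(combo)
            )
            subset_ss[frozenset(combo)] = ss
            df = 1
            for i in combo:
                df *= factors[i].nunique() - 1
            results[" * ".join(cols)] = (ss, df)
            ss_model += ss
    if factors:
        full_cols = [codes[c] for c in names]
        full_means = pd.Series(y).groupby(full_cols, observed=True).transform("mean").to_numpy()
        resid = float(((y - full_means) ** 2).sum())
    else:
        resid = float(((y - grand) ** 2).sum())
    results["__resid__"] = resid
    return results
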