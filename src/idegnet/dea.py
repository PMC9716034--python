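"""Two-group moderated-t differential expression.

Per gene a two-group linear model gives the log-fold-change (case minus
control mean on log2-scale data) and the pooled residual variance s^2 on
d = n1 + n2 - 2 degrees of freedom.  Gene-wise variances are shrunk
toward a common prior by empirical Bayes:

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

with the prior degrees of freedom d0 and prior variance s0^2 estimated by
moment-matching on log s^2 (digamma/trigamma method).  The moderated
statistic t = logFC / (s_tilde * sqrt(1/n1 + 1/n2)) is referred to a t
distribution on d0 + d degrees of freedom.

DEG selection is a strict raw-p threshold (default p < 0.05) with no
multiple-testing adjustment; an adjusted-p mode exists but is off by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .study import ExpressionStudy
from .synthetic import DOWN, UP


@dataclass
class ModeratedFit:
    table: pd.DataFrame   # gene-indexed: logFC, s2, t, p, direction
    df_residual: float
    df_prior: float       # may be +inf (no-shrinkage limit)
    s2_prior: float


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < tol:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed variances.

    Returns ``(df_prior, s2_prior)``; ``df_prior`` is ``inf`` when the
    log-variances show no excess spread beyond sampling noise.  Zero or
    non-finite variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = ((e - e_mean) ** 2).sum() / (ok.sum() - 1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # no between-gene variance heterogeneity: infinite prior df and the
        # arithmetic-mean variance as the common value
        return np.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def moderated_t_table(study: ExpressionStudy, df_prior: float | None = None
                      ) -> ModeratedFit:
    """Empirical-Bayes moderated t-test, case vs control, per gene.

    ``df_prior`` overrides the estimated prior degrees of freedom (0 gives
    the ordinary pooled-variance t-test).  All-constant genes get p = 1
    with a warning.
    """
    case = study.case_mask()
    n1, n2 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    y = study.values()
    mean1 = y[:, case].mean(axis=1)
    mean2 = y[:, ~case].mean(axis=1)
    logfc = mean1 - mean2
    ss1 = ((y[:, case] - mean1[:, None]) ** 2).sum(axis=1)
    ss2 = ((y[:, ~case] - mean2[:, None]) ** 2).sum(axis=1)
    df = float(n1 + n2 - 2)
    s2 = (ss1 + ss2) / df

    constant = s2 <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} all-constant gene(s); p set to 1"
        )

    if df_prior is None:
        d0, s0 = fit_f_dist(s2[~constant], df)
    else:
        d0 = float(df_prior)
        _, s0 = fit_f_dist(s2[~constant], df)
        if d0 == 0:
            s0 = 0.0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(constant, 1.0, p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "t": np.where(constant, 0.0, t),
            "p": p,
            "direction": np.where(logfc > 0, UP, DOWN),
        },
        index=study.genes,
    )
    return ModeratedFit(table=table, df_residual=df, df_prior=d0, s2_prior=s0)


def select_degs(fit: ModeratedFit, alpha: float = 0.05,
                adjust: bool = False) -> pd.DataFrame:
    """Genes with p strictly below ``alpha``, partitioned up/down by logFC.

    ``adjust=True`` applies Benjamini-Hochberg before thresholding (off by
    default: the selection rule is a raw-p cut).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    tab = fit.table.copy()
    if adjust:
        tab["p_adj"] = stats.false_discovery_control(tab["p"].to_numpy())
        keep = tab["p_adj"] < alpha
    else:
        keep = tab["p"] < alpha
    return tab.loc[keep, [c for c in tab.columns if c != "s2"]].sort_values("p")
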