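"""Model selection for the latent class mixed model ladder.

Fits G = 1..G_max models, tabulates fit criteria (log-likelihood, AIC,
BIC), the relative entropy of the posterior classification, class sizes,
and the posterior classification table (mean posterior probability of
each class among subjects modally assigned to each class).  No automatic
winner is declared: selection in practice also weighs the substantive
relevance of the trajectories; the report flags the BIC-minimizing G and
exposes everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lcmm import ConvergenceError, LCMMFit, LCMMSpec, fit as _fit

__all__ = ["SelectionReport", "entropy", "classification_table", "select"]


def entropy(posterior: np.ndarray) -> float:
    """Relative entropy of a posterior classification, in [0, 1].

    E = 1 - sum_i sum_g (-p_ig ln p_ig) / (N ln G): 1 for perfectly crisp
    one-hot assignment, 0 for uniform rows.  Undefined (NaN) for G = 1.
    """
    P = np.asarray(posterior, dtype=float)
    if P.ndim != 2:
        raise ValueError("posterior must be an N x G matrix")
    N, G = P.shape
    if G < 2:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0.0, P * np.log(P), 0.0)
    e = float(1.0 + plogp.sum() / (N * np.log(G)))
    # snap the exact endpoints (one-hot / uniform rows) through rounding noise
    if abs(e) < 1e-12:
        return 0.0
    if abs(e - 1.0) < 1e-12:
        return 1.0
    return e


def classification_table(posterior: np.ndarray) -> pd.DataFrame:
    """G x G posterior classification table.

    Row g holds the mean posterior probability of membership in each class
    among subjects modally assigned to class g; rows sum to 1.  Diagonal
    dominance indicates good discrimination.  Rows for empty modal classes
    are NaN (flagged by the 'n' column being 0).
    """
    P = np.asarray(posterior, dtype=float)
    N, G = P.shape
    if G < 2:
        raise ValueError("classification table needs G >= 2")
    modal = P.argmax(axis=1)
    rows = np.full((G, G), np.nan)
    counts = np.zeros(G, dtype=int)
    for g in range(G):
        mask = modal == g
        counts[g] = mask.sum()
        if counts[g]:
            rows[g] = P[mask].mean(axis=0)
    out = pd.DataFrame(
        rows,
        index=[f"modal_{g + 1}" for g in range(G)],
        columns=[f"mean_p_{g + 1}" for g in range(G)],
    )
    out.insert(0, "n", counts)
    return out


@dataclass
class SelectionReport:
    """Per-G fit summaries, classification tables, fitted models, and the
    BIC-minimizing G among converged fits."""

    table: pd.DataFrame
    classification_tables: dict[int, pd.DataFrame]
    fits: dict[int, LCMMFit]
    errors: dict[int, str]
    bic_optimal_g: int | None


def select(data, spec_base: LCMMSpec, g_max: int = 6) -> SelectionReport:
    """Fit the G = 1..g_max ladder and tabulate selection evidence.

    Fit failures for individual G are recorded and the ladder continues.
    Each G > 1 additionally seeds one start from the previous G's solution
    with its largest class split, which keeps the maximized log-likelihood
    non-decreasing in G.
    """
    if g_max < 1:
        raise ValueError("g_max must be >= 1")
    rows = []
    fits: dict[int, LCMMFit] = {}
    ctabs: dict[int, pd.DataFrame] = {}
    errors: dict[int, str] = {}
    prev: LCMMFit | None = None
    for G in range(1, g_max + 1):
        spec = LCMMSpec(
            n_classes=G,
            time_basis=spec_base.time_basis,
            link_knots=spec_base.link_knots,
            link_order=spec_base.link_order,
            random_intercept=spec_base.random_intercept,
            n_starts=spec_base.n_starts,
            seed=spec_base.seed + G,
            control=spec_base.control,
        )
        extra = [_split_largest(prev.params)] if prev is not None else None
        try:
            f = fits[G] = _fit(data, spec, extra_starts=extra)
        except ConvergenceError as err:
            errors[G] = str(err)
            if err.best_fit is not None:
                prev = err.best_fit
            continue
        prev = f
        P = f.posterior
        props = P.mean(axis=0)
        modal_counts = np.bincount(f.modal_class, minlength=G)
        rows.append(
            {
                "G": G,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "AIC": f.aic,
                "BIC": f.bic,
                "entropy": entropy(P) if G > 1 else float("nan"),
                "min_class_size": int(modal_counts.min()),
                "pct_per_class": "/".join(f"{100 * p:.1f}" for p in props),
                "converged": f.converged,
            }
        )
        if G > 1:
            ctabs[G] = classification_table(P)
    table = pd.DataFrame(rows)
    bic_opt = None
    if len(table):
        conv = table[table["converged"]]
        pool = conv if len(conv) else table
        bic_opt = int(pool.loc[pool["BIC"].idxmin(), "G"])
    return SelectionReport(table, ctabs, fits, errors, bic_opt)


def _split_largest(params):
    """Seed start for G+1: duplicate the largest class with nudged level."""
    from .lcmm import LCMMParams

    pi = params.class_probs
    g = int(np.argmax(pi))
    beta = np.vstack([params.beta, params.beta[g]])
    beta[g, 0] -= 0.5
    beta[-1, 0] += 0.5
    pi_new = np.append(pi, pi[g] / 2.0)
    pi_new[g] /= 2.0
    pi_new /= pi_new.sum()
    xi = np.log(pi_new[:-1]) - np.log(pi_new[-1])
    sigma = np.append(params.sigma, params.sigma[g])
    return LCMMParams(
        xi, beta, sigma, params.link_weights.copy(), params.x_scale.copy()
    )
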