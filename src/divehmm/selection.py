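"""Choosing the number of dive states by information criteria."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import DiveHMM
from .spec import HmmSpec

log = logging.getLogger(__name__)


def select_n_dive_states(
    records: pd.DataFrame,
    candidate_counts=(2, 3, 4),
    criterion: str = "bic",
    covariate_design: str = "intercept",
    initial: str = "stationary",
    n_starts: int = 5,
    seed: int = 0,
    **fit_kwargs,
):
    """Fit one model per candidate dive-state count and rank by criterion.

    The two known non-diving states are always present, so a candidate count
    of k dive states yields a (k+2)-state model.  Returns a table of
    (n_dive_states, loglik, aic, bic, converged_starts) plus the chosen
    count (argmin of the criterion, BIC by default).  Candidates whose fit
    fails are skipped with a log entry.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    rows = []
    fits = {}
    for k in candidate_counts:
        if not 1 <= k <= 6:
            raise ValueError("candidate dive-state counts must lie in 1..6")
        names = ("haulout", "surface") + tuple(f"dive{i + 1}" for i in range(k))
        spec = HmmSpec(
            state_names=names, covariate_design=covariate_design, initial=initial
        )
        try:
            fit = DiveHMM(records, spec).fit(
                n_starts=n_starts, seed=seed, **fit_kwargs
            )
        except Exception as err:  # noqa: BLE001 - candidate-level isolation
            log.warning("fit with %d dive states failed: %s", k, err)
            continue
        fits[k] = fit
        rows.append(
            {
                "n_dive_states": k,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "bic": fit.bic,
                "converged_starts": fit.converged_starts,
            }
        )
    if not rows:
        raise RuntimeError("no candidate state count could be fitted")
    table = pd.DataFrame(rows).set_index("n_dive_states")
    chosen = int(table[criterion].idxmin())
    return table, chosen, fits
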