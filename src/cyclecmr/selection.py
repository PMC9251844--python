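"""AICc model selection with the simplest-adequate-model rule.

Among all candidate models within 2 AICc units of the best, the selected
model is the one with the fewest parameters (avoiding uninformative ones);
remaining ties go to the lower AICc.
"""

from __future__ import annotations

import numpy as np

__all__ = ["aicc", "select_simplest", "selection_table"]


def aicc(loglik: float, n_params: int, n_eff: int) -> float:
    """Small-sample-corrected AIC; infinite when n_eff <= n_params + 1."""
    k = n_params
    if n_eff - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_eff - k - 1)


def select_simplest(models, delta: float = 2.0):
    """Index of the selected model: fewest parameters among those with dAICc < delta."""
    aiccs = np.array([m.aicc for m in models], dtype=float)
    if not np.any(np.isfinite(aiccs)):
        raise ValueError("no candidate model has a finite AICc")
    best = np.nanmin(aiccs)
    cands = [i for i, a in enumerate(aiccs) if a - best < delta]
    cands.sort(key=lambda i: (models[i].n_params, aiccs[i]))
    return cands[0]


def selection_table(models, names=None):
    import pandas as pd

    aiccs = np.array([m.aicc for m in models], dtype=float)
    best = np.nanmin(aiccs)
    sel = select_simplest(models)
    return pd.DataFrame(dict(
        model=[names[i] if names else getattr(m, "name", str(i)) for i, m in enumerate(models)],
        n_params=[m.n_params for m in models],
        loglik=[getattr(m, "loglik", np.nan) for m in models],
        AICc=aiccs, dAICc=aiccs - best,
        selected=[i == sel for i in range(len(models))],
    )).sort_values("AICc").reset_index(drop=True)
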