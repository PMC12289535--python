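"""Independent naive implementations used as test oracles.

These deliberately bypass the fold-plan machinery: they refit the backend
explicitly per held-out sample with plain loops, so agreement with the
package's cross-validation is a genuine two-route check.
"""

import numpy as np

from icolike.backends import fit_regressor


def naive_loo_predictions(dataset, backend_config):
    """Leave-one-out by explicit per-sample refit; returns id -> prediction."""
    n = dataset.n_samples
    out = {}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        handle = fit_regressor(dataset.X[mask], dataset.y[mask], backend_config)
        out[dataset.ids[i]] = float(handle.predict(dataset.X[i:i + 1])[0])
    return out


def naive_ico_likeness(dataset, candidate_id, backend_config):
    """Brute-force leave-one-out ICO-likeness for one candidate."""
    cand = str(candidate_id)
    preds_full = naive_loo_predictions(dataset, backend_config)
    reduced = dataset.drop(cand)
    preds_reduced = naive_loo_predictions(reduced, backend_config)
    others = [s for s in dataset.ids if s != cand]
    err_full = [abs(dataset.y_of(s) - preds_full[s]) for s in others]
    err_red = [abs(reduced.y_of(s) - preds_reduced[s]) for s in others]
    mae_wos = float(np.mean(err_full))
    mae_woos = float(np.mean(err_red))
    return mae_wos, mae_woos, mae_wos - mae_woos
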