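"""Independent brute-force reference for weighted kNN (test oracle only)."""

import numpy as np


def brute_force_fwknn(X_tr, y_tr, X_te, w, k):
    """Exhaustive neighbor search with explicit tie rules.

    Majority vote over the k nearest under weighted Euclidean distance on
    z-scored features; ties broken by the smaller summed distance, then by
    the lower class id.
    """
    X_tr = np.asarray(X_tr, float)
    X_te = np.asarray(X_te, float)
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z_tr = (X_tr - mu) / sd
    Z_te = (X_te - mu) / sd
    classes = list(np.unique(y_tr))
    preds = []
    for z in Z_te:
        d = np.array([np.sqrt(np.sum(w * (z - row) ** 2)) for row in Z_tr])
        nn = np.argsort(d, kind="stable")[:k]
        best, best_key = None, None
        for c in classes:
            members = [i for i in nn if y_tr[i] == c]
            if not members:
                continue
            key = (-len(members), float(sum(d[i] for i in members)),
                   classes.index(c))
            if best_key is None or key < best_key:
                best, best_key = c, key
        preds.append(best)
    return np.array(preds)
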