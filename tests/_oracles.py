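"""Independent brute-force oracles used to check the fast implementations."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pair_counts_bruteforce(labels_a, labels_b):
    """Enumerate all N(N-1)/2 unordered cell pairs and tally agreements."""
    a = list(labels_a)
    b = list(labels_b)
    tp = fp = fn = tn = 0
    for i, j in combinations(range(len(a)), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            tp += 1
        elif same_a:
            fp += 1
        elif same_b:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def ari_bruteforce(labels_a, labels_b) -> float:
    tp, fp, fn, tn = pair_counts_bruteforce(labels_a, labels_b)
    total = tp + fp + fn + tn
    sum_c = tp
    sum_p = tp + fp
    sum_q = tp + fn
    if total == 0:
        return 1.0
    expected = sum_p * sum_q / total
    maximum = 0.5 * (sum_p + sum_q)
    if maximum == expected:
        return 1.0 if list(labels_to_canon(labels_a)) == list(labels_to_canon(labels_b)) else 0.0
    return (sum_c - expected) / (maximum - expected)


def fmi_bruteforce(labels_a, labels_b) -> float:
    tp, fp, fn, _ = pair_counts_bruteforce(labels_a, labels_b)
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    return tp / np.sqrt((tp + fp) * (tp + fn))


def labels_to_canon(labels):
    """Map labels to first-appearance integer codes (rename-invariant form)."""
    seen = {}
    return [seen.setdefault(l, len(seen)) for l in labels]


def loss_scalar_bruteforce(params, mats, acts, recons, cfg):
    """Entry-by-entry scalar re-derivation of the training objective."""
    n = mats[0].shape[0]
    total = 0.0
    for lam, x, r in zip(cfg.lambdas, mats, recons):
        for ij in np.ndindex(*x.shape):
            total += lam * (x[ij] - r[ij]) ** 2 / n
    for h in list(acts.h2) + [acts.h3] + list(acts.h4):
        for ij in np.ndindex(*h.shape):
            total += cfg.alpha * abs(h[ij]) / n
    for w in list(params.W2) + list(params.W3) + list(params.W4):
        for ij in np.ndindex(*w.shape):
            total += cfg.beta * w[ij] ** 2
    return total


def activation_pattern(params, mats):
    """Concatenated ReLU on/off pattern of a forward pass (kink detector)."""
    a2 = [x @ W + b for x, W, b in zip(mats, params.W1, params.b1)]
    h2 = [np.maximum(a, 0.0) for a in a2]
    a3 = sum(h @ W for h, W in zip(h2, params.W2)) + params.b2
    h3 = np.maximum(a3, 0.0)
    a4 = [h3 @ W + b for W, b in zip(params.W3, params.b3)]
    return np.concatenate([(a > 0).ravel() for a in a2 + [a3] + a4])


def finite_difference_gradient_check(params, mats, cfg, rng,
                                     samples_per_array=4, eps=1e-6,
                                     max_tries=40):
    """Worst relative error of analytic vs central-difference gradients.

    Samples entries from every parameter array. A perturbation that flips
    any ReLU activation pattern lands on a kink where the objective is not
    differentiable and central differences are meaningless; such draws are
    rejected and resampled. Returns (worst_relative_error, n_checked).
    """
    from umint.core import loss_and_gradients

    _, grads = loss_and_gradients(params, mats, cfg)
    worst = 0.0
    checked = 0
    for arr, g in zip(params.arrays(), grads.arrays()):
        done = tries = 0
        while done < samples_per_array and tries < max_tries:
            tries += 1
            idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            pat_p = activation_pattern(params, mats)
            lp, _ = loss_and_gradients(params, mats, cfg)
            arr[idx] = orig - eps
            pat_m = activation_pattern(params, mats)
            lm, _ = loss_and_gradients(params, mats, cfg)
            arr[idx] = orig
            if not np.array_equal(pat_p, pat_m):
                continue  # kink crossed: non-differentiable point
            numeric = (lp.total - lm.total) / (2 * eps)
            denom = max(abs(numeric), abs(g[idx]), 1e-8)
            worst = max(worst, abs(numeric - g[idx]) / denom)
            done += 1
            checked += 1
    return worst, checked
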