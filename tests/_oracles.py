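"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the defining equations and
first principles — scalar loops, explicit per-gate matrices, exhaustive
threshold/permutation enumeration — and never calls the implementation
code paths it is checking.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# recurrent-cell equation oracles (per-gate matrices, vector arguments)


def simple_step_oracle(x, h_prev, Wh, Wx, b):
    return np.tanh(Wh.T @ h_prev + Wx.T @ x + b)


def lstm_step_oracle(x, h_prev, c_prev, g):
    """g: dict with per-gate matrices Whf, Wxf, bf, Whi, ... Whg, Wxg, bg."""
    f = sigmoid(g["Whf"].T @ h_prev + g["Wxf"].T @ x + g["bf"])
    i = sigmoid(g["Whi"].T @ h_prev + g["Wxi"].T @ x + g["bi"])
    o = sigmoid(g["Who"].T @ h_prev + g["Wxo"].T @ x + g["bo"])
    gg = np.tanh(g["Whg"].T @ h_prev + g["Wxg"].T @ x + g["bg"])
    c = f * c_prev + i * gg
    h = o * np.tanh(c)
    return h, c


def gru_step_oracle(x, h_prev, g):
    z = sigmoid(g["Whz"].T @ h_prev + g["Wxz"].T @ x + g["bz"])
    r = sigmoid(g["Whr"].T @ h_prev + g["Wxr"].T @ x + g["br"])
    n = np.tanh(g["Whh"].T @ (r * h_prev) + g["Wxh"].T @ x + g["bh"])
    return (1.0 - z) * h_prev + z * n


# ---------------------------------------------------------------------------
# classification metric oracles (exhaustive threshold enumeration)


def threshold_metrics_oracle(labels, scores, threshold=0.5):
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    tp = fp = fn = tn = 0
    for yi, si in zip(y, s):
        call = 1 if si >= threshold else 0
        if call and yi:
            tp += 1
        elif call and not yi:
            fp += 1
        elif not call and yi:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / len(y)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "accuracy": accuracy, "f1": f1}


def roc_auc_oracle(labels, scores):
    """Trapezoid area over the ROC curve, thresholds at every unique score
    in descending order with ties grouped."""
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    P, N = int(y.sum()), int((1 - y).sum())
    pts = [(0.0, 0.0)]
    for thr in sorted(set(s), reverse=True):
        calls = s >= thr
        tpr = (calls & (y == 1)).sum() / P
        fpr = (calls & (y == 0)).sum() / N
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return auc


def pr_auc_oracle(labels, scores):
    """Average precision: sum of (R_n - R_{n-1}) * P_n over descending
    unique thresholds (step-wise interpolation)."""
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    P = int(y.sum())
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(s), reverse=True):
        calls = s >= thr
        tp = (calls & (y == 1)).sum()
        fp = (calls & (y == 0)).sum()
        precision = tp / (tp + fp)
        recall = tp / P
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


# ---------------------------------------------------------------------------
# rank-sum oracle (full enumeration over group assignments)


def u_of(x, y):
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def ranksum_oracle(x, y):
    """Two-sided exact p: enumerate every assignment of the pooled values
    into groups of the observed sizes; double the smaller tail."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)
    u_obs = u_of(x, y)
    total = le = ge = 0
    for pick in combinations(range(len(pooled)), n1):
        pick = set(pick)
        gx = [pooled[i] for i in pick]
        gy = [pooled[i] for i in range(len(pooled)) if i not in pick]
        u = u_of(gx, gy)
        total += 1
        le += u <= u_obs
        ge += u >= u_obs
    return u_obs, min(1.0, 2.0 * min(le / total, ge / total))
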