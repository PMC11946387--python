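import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def brute_force_mask(exam, voi, thr):
    """Independent per-voxel reference for the FTV segmentation: a literal
    loop applying the PE/SER definitions and strict thresholds."""
    nx, ny, nz = exam.shape
    mask = np.zeros(exam.shape, dtype=bool)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not (
                    voi.lo[0] <= i < voi.hi[0]
                    and voi.lo[1] <= j < voi.hi[1]
                    and voi.lo[2] <= k < voi.hi[2]
                ):
                    continue
                s0 = exam.s0[i, j, k]
                s1 = exam.s1[i, j, k]
                s2 = exam.s2[i, j, k]
                if s0 <= 0 or s2 == s0:
                    continue
                pe = (s1 - s0) / s0 * 100.0
                ser = (s1 - s0) / (s2 - s0)
                if pe > thr.pe_min and ser > thr.ser_min:
                    mask[i, j, k] = True
    return mask


def brute_force_auc(scores, labels):
    """All-pairs AUC: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_select(probs, labels, level):
    """Reference threshold selection: scan every candidate cutoff and keep
    the one maximizing sensitivity subject to PPV >= level."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    candidates = sorted(set(probs) | {0.0})
    best = None  # (threshold, sensitivity, ppv)
    for t in candidates:
        pred = probs >= t
        tp = int((pred & labels).sum())
        npred = int(pred.sum())
        if npred == 0:
            continue
        ppv = tp / npred * 100.0
        sens = tp / labels.sum() * 100.0
        if ppv >= level and (best is None or sens > best[1]):
            best = (t, sens, ppv)
    return best  # None when unattainable
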