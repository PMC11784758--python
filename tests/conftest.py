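"""Shared fixtures: tiny UCI-dialect text fixtures and a literal,
loop-based reference implementation of plain MVO used as the oracle for
the hybrid optimizer's reduction property."""

from __future__ import annotations

import numpy as np
import pytest

_ROULETTE_SHIFT = 1e-12


def literal_mvo(objective, lb, ub, n, d, max_iter, p_min, p_max, chi, seed):
    """Plain multi-verse optimizer written as literal nested loops.

    Follows the published update rules directly — normalize fitness to
    unit norm, per-object white/black-hole exchange with roulette donor
    selection, per-object wormhole jump with the r3 sign branch — under
    the same draw-order contract as the package (row-major blocks), but
    with scalar draws and explicit loops so it is an independent code
    path.  Returns (best_position, best_fitness, history).
    """
    lb = np.full(d, float(lb)) if np.isscalar(lb) else np.asarray(lb, float)
    ub = np.full(d, float(ub)) if np.isscalar(ub) else np.asarray(ub, float)
    rng = np.random.default_rng(seed)

    X = np.empty((n, d))
    for i in range(n):
        for j in range(d):
            X[i, j] = lb[j] + rng.random() * (ub[j] - lb[j])
    fitness = np.array([float(objective(x)) for x in X])
    best_idx = int(np.argmin(fitness))
    best = X[best_idx].copy()
    best_f = float(fitness[best_idx])

    history = []
    for m in range(1, max_iter + 1):
        pw = p_min + m * (p_max - p_min) / max_iter
        vt = 1.0 - (m / max_iter) ** (1.0 / chi)

        order = np.argsort(fitness, kind="stable")
        sorted_X = X[order].copy()
        norm = np.linalg.norm(fitness)
        f_norm = fitness / norm if norm > 0 else fitness.copy()
        f_norm_sorted = f_norm[order]

        # roulette mass on -f_norm_sorted, shifted positive
        w = -f_norm_sorted
        w = w - w.min() + _ROULETTE_SHIFT
        cum = np.cumsum(w) / np.sum(w)

        # exchange: r1 block first, then one roulette draw per firing cell
        r1 = np.empty((n, d))
        for i in range(n):
            for j in range(d):
                r1[i, j] = rng.random()
        newX = X.copy()
        for i in range(n):
            for j in range(d):
                if r1[i, j] < f_norm[i]:
                    u = rng.random()
                    k = int(np.searchsorted(cum, u, side="right"))
                    newX[i, j] = sorted_X[k, j]
        X = newX

        # wormhole: r2 block, then (r3, r4) per firing cell
        r2 = np.empty((n, d))
        for i in range(n):
            for j in range(d):
                r2[i, j] = rng.random()
        for i in range(n):
            for j in range(d):
                if r2[i, j] < pw:
                    r3 = rng.random()
                    r4 = rng.random()
                    step = vt * ((ub[j] - lb[j]) * r4 + lb[j])
                    val = best[j] + step if r3 < 0.5 else best[j] - step
                    X[i, j] = min(max(val, lb[j]), ub[j])

        fitness = np.array([float(objective(x)) for x in X])
        cur = int(np.argmin(fitness))
        if fitness[cur] < best_f:
            best_f = float(fitness[cur])
            best = X[cur].copy()
        history.append(best_f)

    return best, best_f, np.array(history)


@pytest.fixture
def mvo_reference():
    return literal_mvo


WBCD_FIXTURE = """\
1000025,5,1,1,1,2,1,3,1,1,2
1002945,5,4,4,5,7,10,3,2,1,2
1015425,3,1,1,1,2,2,3,1,1,2
1016277,6,8,8,1,3,4,3,7,1,2
1017023,4,1,1,3,2,1,3,1,1,2
1017122,8,10,10,8,7,10,9,7,1,4
1018099,1,1,1,1,2,10,3,1,1,4
1018561,2,1,2,1,2,1,3,1,1,4
"""

WBCD_MISSING_FIXTURE = """\
1000025,5,1,1,1,2,1,3,1,1,2
1002945,5,4,4,5,7,?,3,2,1,2
1015425,3,1,1,1,2,3,3,1,1,4
"""


@pytest.fixture
def wbcd_file(tmp_path):
    path = tmp_path / "breast-cancer-wisconsin.data"
    path.write_text(WBCD_FIXTURE)
    return path


@pytest.fixture
def wbcd_missing_file(tmp_path):
    path = tmp_path / "wbcd_missing.data"
    path.write_text(WBCD_MISSING_FIXTURE)
    return path


@pytest.fixture
def wdbc_file(tmp_path):
    """Synthetic rows in the 32-field diagnostic dialect (fake values)."""
    rng = np.random.default_rng(7)
    lines = []
    for i in range(8):
        label = "M" if i % 2 else "B"
        feats = np.round(rng.random(30) * 10 + (3 if label == "M" else 0), 4)
        lines.append(",".join([str(842300 + i), label] + [str(v) for v in feats]))
    path = tmp_path / "wdbc.data"
    path.write_text("\n".join(lines) + "\n")
    return path
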