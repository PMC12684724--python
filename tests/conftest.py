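"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import isocontext as ic


@pytest.fixture(scope="session")
def benchmark_run():
    """One full benchmark simulation + detection + MID estimation (seed 0)."""
    cfg = ic.benchmark_config(0)
    features, samples, truth = ic.simulate_experiment(cfg)
    params = ic.DetectionParams()
    groups = ic.detect_groups(features, samples, ic.TracerDef.from_name("13C"),
                              params, "cond1")
    estimates = ic.estimate_mids(groups, features, samples)
    return {"config": cfg, "features": features, "samples": samples,
            "truth": truth, "groups": groups, "estimates": estimates}


@pytest.fixture()
def small_feature_table():
    """Two-compound toy table: base + M1 features, 3+3 samples."""
    df = pd.DataFrame({
        "mz": [181.0707, 182.0740, 300.1000],
        "rt": [120.0, 120.5, 240.0],
        "L1": [600.0, 400.0, 1000.0],
        "L2": [620.0, 410.0, 990.0],
        "L3": [590.0, 395.0, 1010.0],
        "U1": [990.0, 10.0, 1005.0],
        "U2": [985.0, 11.0, 998.0],
        "U3": [995.0, 9.0, 1002.0],
    }, index=pd.Index(["F1", "F1_M1", "F2"], name="feature_id"))
    return ic.FeatureTable(df)


@pytest.fixture()
def small_sample_sheet():
    return ic.SampleSheet(pd.DataFrame({
        "sample_id": ["L1", "L2", "L3", "U1", "U2", "U3"],
        "experiment": "exp1",
        "condition": "cond1",
        "tracer_state": ["labeled"] * 3 + ["unlabeled"] * 3,
        "replicate": [1, 2, 3, 1, 2, 3],
    }))


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def simplex_grid(length: int, step: float) -> np.ndarray:
    """All vectors on the probability simplex with entries on a step grid."""
    n = round(1.0 / step)
    pts = []
    for combo in itertools.combinations_with_replacement(range(n + 1),
                                                         length - 1):
        # stars and bars: cut points -> composition
        prev = 0
        comp = []
        for c in combo:
            comp.append(c - prev)
            prev = c
        comp.append(n - prev)
        pts.append(comp)
    return np.asarray(pts, dtype=float) * step


def _ray_objective(c: np.ndarray, m: np.ndarray,
                   directions: np.ndarray) -> np.ndarray:
    """min over s >= 0 of ||C (s f) - m|| for each simplex direction f."""
    proj = directions @ c.T
    num = proj @ m
    den = np.einsum("ij,ij->i", proj, proj)
    s = np.where(den > 0, np.maximum(num, 0.0) / np.where(den > 0, den, 1.0), 0.0)
    resid2 = (m @ m) - 2.0 * s * num + s ** 2 * den
    return np.sqrt(np.maximum(resid2, 0.0))


def grid_search_objective(c: np.ndarray, m: np.ndarray,
                          coarse: float = 0.01, fine: float = 0.001,
                          box: int = 15) -> float:
    """Best ||C f - m|| with the *direction* of f on a simplex grid and the
    scale minimized in closed form along each ray (1-D least squares).

    Exhaustive at the coarse step, then exhaustive at the fine step inside
    a +/- ``box``-fine-steps cube around the coarse optimum; exact for the
    convex objective. Independent of the NNLS path under test.
    """
    length = len(m)
    candidates = simplex_grid(length, coarse)
    obj = _ray_objective(c, m, candidates)
    i = int(np.argmin(obj))
    best, best_f = float(obj[i]), candidates[i]
    # fine pass: integer compositions of 1/fine within the box
    n = round(1.0 / fine)
    center = np.round(best_f * n).astype(int)
    ranges = [range(max(0, center[i] - box), min(n, center[i] + box) + 1)
              for i in range(length - 1)]
    fine_pts = []
    for combo in itertools.product(*ranges):
        last = n - sum(combo)
        if abs(last - center[-1]) <= box and last >= 0:
            fine_pts.append(list(combo) + [last])
    if fine_pts:
        candidates = np.asarray(fine_pts, dtype=float) * fine
        obj = _ray_objective(c, m, candidates)
        best = min(best, float(obj.min()))
    return best


def brute_force_network(mids: "ic.MIDTable", threshold: float, metric: str,
                        combine: str):
    """All-pairs reference computation for build_network."""
    by_node = mids.by_node()
    ids = sorted(by_node)
    edges = {}
    for a, b in itertools.combinations(ids, 2):
        scopes_a = {(r.experiment, r.condition): r for r in by_node[a]}
        scopes_b = {(r.experiment, r.condition): r for r in by_node[b]}
        shared = sorted(set(scopes_a) & set(scopes_b))
        if not shared:
            continue
        sims = []
        for s in shared:
            fa, fb = scopes_a[s].fractions, scopes_b[s].fractions
            L = max(len(fa), len(fb))
            fa = np.pad(fa, (0, L - len(fa)))
            fb = np.pad(fb, (0, L - len(fb)))
            if metric == "cosine":
                sims.append(fa @ fb / (np.linalg.norm(fa) * np.linalg.norm(fb)))
            else:
                sims.append(1.0 - np.linalg.norm(fa - fb) / np.sqrt(2.0))
        sim = float(np.mean(sims)) if combine == "mean" else float(min(sims))
        if sim >= threshold:
            edges[(a, b)] = sim
    return edges
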