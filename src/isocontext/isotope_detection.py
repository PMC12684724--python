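"""Non-targeted isotopologue-group detection.

The detector scans a feature table for sets of features spaced by the
tracer mass difference (e.g. 13C-12C = 1.0033548 Da) at a shared
retention time, then asks whether the *relative* intensity pattern over
those candidate isotopologues differs between labeled and unlabeled
samples. Working on per-sample relative intensities makes detection
invariant to total-intensity rescaling of any single sample; the
labeled-vs-unlabeled comparison at each isotopologue position n >= 1
uses a two-sided Welch t-test (no equal-variance assumption, small
replicate numbers).

Base features are visited in descending mean unlabeled intensity and
greedily consume their group members, so no feature can belong to two
groups and the scan order is deterministic. Multiplicity across all
base x position tests in a run is controlled by Benjamini-Hochberg by
default (``fdr=True``): under a complete null this also bounds the
probability of any detected group at alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .io_tables import FeatureTable, SampleSheet

logger = logging.getLogger(__name__)

#: Per-heavy-atom mass differences in Da for common tracers.
TRACER_DELTAS = {
    "13C": 1.0033548,
    "15N": 0.9970349,
    "2H": 1.0062767,
}


@dataclass(frozen=True)
class TracerDef:
    """A stable-isotope tracer: name and mass shift per incorporated atom."""

    name: str
    delta_mass: float

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ConfigurationError("tracer delta_mass must be positive")

    @classmethod
    def from_name(cls, name: str) -> "TracerDef":
        if name not in TRACER_DELTAS:
            raise ConfigurationError(
                f"unknown tracer '{name}'; known: {sorted(TRACER_DELTAS)}"
            )
        return cls(name, TRACER_DELTAS[name])


@dataclass
class DetectionParams:
    """Knobs of the isotopologue scan.

    ppm_tol          mass window for member matching (ppm of target m/z)
    rt_window        max |rt - base rt| in seconds
    n_max            highest isotopologue index searched
    charge           assumed charge state (single value per run)
    alpha            significance level on the labeled-vs-unlabeled test
    noise_floor      minimum mean unlabeled base intensity to seed a group
    min_replicates   minimum usable samples per tracer state
    require_enrichment_direction
                     additionally require labeled mean relative intensity
                     to exceed unlabeled at some n >= 1
    fdr              Benjamini-Hochberg correction across the whole run
    pair_tol_factor  multiplier on ppm_tol when comparing two *measured*
                     m/z values: if each feature is accurate within
                     ppm_tol, their difference can be off by twice that,
                     so member matching uses pair_tol_factor * ppm_tol
    """

    ppm_tol: float = 5.0
    rt_window: float = 10.0
    n_max: int = 10
    charge: int = 1
    alpha: float = 0.05
    noise_floor: float = 0.0
    min_replicates: int = 2
    require_enrichment_direction: bool = True
    fdr: bool = True
    pair_tol_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0 or self.rt_window <= 0:
            raise ConfigurationError("ppm_tol and rt_window must be positive")
        if self.n_max < 1 or self.charge < 1:
            raise ConfigurationError("n_max and charge must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.min_replicates < 2:
            raise ConfigurationError("min_replicates must be >= 2")


@dataclass
class IsotopologueGroup:
    """A base feature plus its detected isotopologues at n * delta offsets."""

    group_id: str
    base_feature_id: str
    rt: float
    condition: str
    members: list[tuple[int, str, float]]  # (n, feature_id, mz)
    p_values: dict[int, float] = field(default_factory=dict)

    @property
    def max_n(self) -> int:
        return max(n for n, _, _ in self.members)

    @property
    def member_ids(self) -> list[str]:
        return [fid for _, fid, _ in self.members]

    def min_p(self) -> float:
        return min(self.p_values.values()) if self.p_values else 1.0


def candidate_members(features: FeatureTable, base_id: str, tracer: TracerDef,
                      params: DetectionParams) -> list[tuple[int, str, float]]:
    """Collect features at base m/z + n*delta/charge within rt/ppm windows.

    The m/z window is ``pair_tol_factor * ppm_tol`` of the target: the
    comparison is between two *measured* m/z values, so it carries both
    features' mass errors. Each target is extrapolated from the nearest
    already-matched member (ladder-chain matching) rather than always
    from the base, so the base's own mass error cannot offset the whole
    ladder. n = 0 is the base itself; if several features fall in one
    n's window the closest in m/z is kept and the ambiguity logged.
    """
    base_mz = float(features.data.loc[base_id, "mz"])
    base_rt = float(features.data.loc[base_id, "rt"])
    mz = features.data["mz"].to_numpy(dtype=float)
    rt = features.data["rt"].to_numpy(dtype=float)
    fids = features.feature_ids
    members: list[tuple[int, str, float]] = [(0, base_id, base_mz)]
    rt_ok = np.abs(rt - base_rt) <= params.rt_window
    ref_n, ref_mz = 0, base_mz
    for n in range(1, params.n_max + 1):
        target = ref_mz + (n - ref_n) * tracer.delta_mass / params.charge
        tol = params.pair_tol_factor * params.ppm_tol * target * 1e-6
        ok = rt_ok & (np.abs(mz - target) <= tol)
        idx = [i for i in np.flatnonzero(ok) if fids[i] != base_id]
        if not idx:
            continue
        if len(idx) > 1:
            logger.debug("base %s: %d candidates for n=%d; keeping closest m/z",
                         base_id, len(idx), n)
        best = min(idx, key=lambda i: (abs(mz[i] - target), fids[i]))
        members.append((n, fids[best], float(mz[best])))
        ref_n, ref_mz = n, float(mz[best])
    return members


def per_sample_relative_intensities(
        members: list[tuple[int, str, float]], features: FeatureTable,
        sample_ids: list[str]) -> dict[str, np.ndarray]:
    """Normalize member intensities to fractions within each sample.

    Vectors are indexed by isotopologue index n (length max_n + 1); an n
    with no member feature contributes 0, so an interior gap does not
    truncate or shift the distribution. Absent intensities count as 0; a
    sample in which every member is absent is dropped. Each returned
    vector sums to 1.
    """
    if not members:
        raise ConfigurationError("group has no members")
    if not sample_ids:
        raise ConfigurationError("no samples given")
    length = max(n for n, _, _ in members) + 1
    out: dict[str, np.ndarray] = {}
    mat = features.data.loc[[fid for _, fid, _ in members],
                            sample_ids].to_numpy(dtype=float)
    for j, sid in enumerate(sample_ids):
        col = mat[:, j]
        if np.all(np.isnan(col)):
            continue
        col = np.nan_to_num(col, nan=0.0)
        total = col.sum()
        if total <= 0:
            continue
        vec = np.zeros(length)
        for row, (n, _, _) in enumerate(members):
            vec[n] = col[row]
        out[sid] = vec / total
    return out


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Two-sided Welch t-test: (t, Welch-Satterthwaite df, p).

    Degenerate inputs (zero variance in both groups) return p = 1 for
    equal means and the p -> 0 limit for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("Welch test needs >= 2 observations per group")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf if diff > 0 else -np.inf), \
            float(len(a) + len(b) - 2), 0.0
    se2 = va / len(a) + vb / len(b)
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def adjust_pvalues_bh(p) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # monotone from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out.tolist()


def detect_groups(features: FeatureTable, samples: SampleSheet,
                  tracer: TracerDef, params: DetectionParams,
                  condition: str) -> list[IsotopologueGroup]:
    """Detect isotopologue groups for one labeled condition.

    Requires at least ``min_replicates`` labeled and unlabeled samples
    for the condition (the unlabeled set is the condition's own if
    present, otherwise all unlabeled samples). Returns retained groups
    with per-position p-values (BH-adjusted when ``params.fdr``).
    """
    labeled = samples.samples_for(condition, "labeled")
    unlabeled = samples.samples_for(condition, "unlabeled")
    if not unlabeled:
        unlabeled = list(samples.data.loc[
            samples.data["tracer_state"] == "unlabeled", "sample_id"])
    if len(labeled) < params.min_replicates or len(unlabeled) < params.min_replicates:
        raise ConfigurationError(
            f"condition '{condition}' needs >= {params.min_replicates} labeled "
            f"and unlabeled samples (got {len(labeled)} labeled, "
            f"{len(unlabeled)} unlabeled)"
        )
    mean_unlabeled = features.data[unlabeled].mean(axis=1, skipna=True)
    order = sorted(features.feature_ids,
                   key=lambda fid: (-np.nan_to_num(mean_unlabeled[fid], nan=0.0), fid))
    consumed: set[str] = set()
    candidates: list[IsotopologueGroup] = []
    directions: list[bool] = []
    for base_id in order:
        if base_id in consumed:
            continue
        base_mean = mean_unlabeled[base_id]
        if np.isnan(base_mean) or base_mean < params.noise_floor:
            continue
        members = candidate_members(features, base_id, tracer, params)
        members = [m for m in members if m[1] == base_id or m[1] not in consumed]
        if len(members) < 2:
            continue
        rel_lab = per_sample_relative_intensities(members, features, labeled)
        rel_unl = per_sample_relative_intensities(members, features, unlabeled)
        if len(rel_lab) < params.min_replicates or len(rel_unl) < params.min_replicates:
            continue
        lab_mat = np.vstack(list(rel_lab.values()))
        unl_mat = np.vstack(list(rel_unl.values()))
        p_values: dict[int, float] = {}
        direction_ok = False
        for n, _, _ in members:
            if n == 0:
                continue
            _, _, p = welch_t_test(lab_mat[:, n], unl_mat[:, n])
            p_values[n] = p
            if lab_mat[:, n].mean() > unl_mat[:, n].mean():
                direction_ok = True
        if not p_values:
            continue
        group = IsotopologueGroup(
            group_id=f"G{len(candidates):04d}_{condition}",
            base_feature_id=base_id,
            rt=float(features.data.loc[base_id, "rt"]),
            condition=condition,
            members=members,
            p_values=p_values,
        )
        keep_raw = group.min_p() <= params.alpha
        if params.require_enrichment_direction:
            keep_raw = keep_raw and direction_ok
        candidates.append(group)
        directions.append(keep_raw)
        if keep_raw:
            # only retained groups consume their members; BH below can
            # still drop a group but never add one
            consumed.update(group.member_ids)
    if params.fdr and candidates:
        # adjust over every test performed, not just the significant ones
        flat = [(gi, n) for gi, g in enumerate(candidates)
                for n in sorted(g.p_values)]
        adj = adjust_pvalues_bh([candidates[gi].p_values[n] for gi, n in flat])
        for (gi, n), q in zip(flat, adj):
            candidates[gi].p_values[n] = q
    return [g for g, keep_raw in zip(candidates, directions)
            if keep_raw and g.min_p() <= params.alpha]


def detect_all_conditions(features: FeatureTable, samples: SampleSheet,
                          tracer: TracerDef,
                          params: DetectionParams) -> list[IsotopologueGroup]:
    """Run detection independently for every labeled condition."""
    groups: list[IsotopologueGroup] = []
    for condition in samples.labeled_conditions():
        groups.extend(detect_groups(features, samples, tracer, params, condition))
    return groups


def groups_to_frame(groups: list[IsotopologueGroup]):
    """Long-format groups table (one row per member) for CSV export."""
    import pandas as pd

    rows = []
    for g in groups:
        for n, fid, mz in g.members:
            rows.append({
                "group_id": g.group_id,
                "base_feature_id": g.base_feature_id,
                "condition": g.condition,
                "n": n,
                "feature_id": fid,
                "mz": mz,
                "rt": g.rt,
                "p_value": g.p_values.get(n, np.nan),
            })
    return pd.DataFrame(rows, columns=["group_id", "base_feature_id", "condition",
                                       "n", "feature_id", "mz", "rt", "p_value"])


def groups_from_frame(df) -> list[IsotopologueGroup]:
    """Rebuild groups from the long-format CSV written by groups_to_frame."""
    groups = []
    for gid, sub in df.groupby("group_id", sort=True):
        sub = sub.sort_values("n")
        members = [(int(r["n"]), str(r["feature_id"]), float(r["mz"]))
                   for _, r in sub.iterrows()]
        p_values = {int(r["n"]): float(r["p_value"]) for _, r in sub.iterrows()
                    if r["n"] > 0 and np.isfinite(r["p_value"])}
        first = sub.iloc[0]
        groups.append(IsotopologueGroup(
            group_id=str(gid),
            base_feature_id=str(first["base_feature_id"]),
            rt=float(first["rt"]),
            condition=str(first["condition"]),
            members=members,
            p_values=p_values,
        ))
    return groups
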