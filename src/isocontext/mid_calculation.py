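"""Mass isotopomer distributions with unlabeled-condition correction.

The measured MID of a labeled sample is the tracer-incorporation
distribution *convolved* with the isotope pattern the compound shows
without tracer (natural abundance plus any instrument bias). Writing
that background as the unlabeled condition's measured MID ``u``, the
forward model for a labeled measurement ``m`` is

    m = C(u) . f,      C[i, j] = u[i - j]  (0 for i < j)

where ``f`` is the tracer-incorporation ("label") distribution to
recover and C is the shifted-kernel (lower-triangular Toeplitz) matrix.
Correction inverts this by non-negative least squares; truncated
columns are deliberately *not* renormalized, so any mass the model
cannot place shows up in the reported residual instead of being hidden.

This is the standard non-targeted tracer-fate reading of "correction
with the unlabeled samples": the kernel is measured, never theoretical,
so instrument effects common to both tracer states cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .errors import ConfigurationError, DegenerateSolutionError, ValidationError
from .io_tables import FeatureTable, SampleSheet
from .isotope_detection import IsotopologueGroup, per_sample_relative_intensities

#: Natural heavy-isotope fraction per tracer element.
NATURAL_HEAVY_FRACTION = {"13C": 0.0107, "15N": 0.00364, "2H": 0.000115}

TRACER_ELEMENT = {"13C": "C", "15N": "N", "2H": "H"}


@dataclass
class MidEstimate:
    """Corrected MID of one isotopologue group in one condition."""

    group_id: str
    condition: str
    raw_labeled: np.ndarray
    raw_unlabeled: np.ndarray
    corrected: np.ndarray
    corrected_sd: np.ndarray
    residual: float
    enrichment: float
    quantification: float
    quantification_sd: float
    labeled_replicate_fraction: float = 1.0
    base_feature_id: str = ""

    def __post_init__(self) -> None:
        for name in ("raw_labeled", "raw_unlabeled", "corrected"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-6:
                raise ValidationError(
                    f"group '{self.group_id}': {name} not on the simplex"
                )
        self.corrected_sd = np.asarray(self.corrected_sd, dtype=float)
        assert abs(self.enrichment - (1.0 - self.corrected[0])) < 1e-9


@dataclass
class MidFilterParams:
    """Labeling filters applied to MID estimates.

    min_labeled_enrichment   keep only groups with 1 - M0 at least this
    max_unlabeled_labeling   reject if the unlabeled samples themselves
                             look labeled beyond this (plus an optional
                             natural-abundance tail allowance when the
                             compound's formula is known)
    min_quantification       intensity floor on the labeled total
    min_replicate_fraction   minimum fraction of labeled replicates with
                             usable data
    max_residual             reconstruction-error ceiling from correction
    """

    min_labeled_enrichment: float = 0.05
    max_unlabeled_labeling: float = 0.05
    min_quantification: float = 0.0
    min_replicate_fraction: float = 0.5
    max_residual: float = 0.05
    natural_tail_allowance: bool = True

    def __post_init__(self) -> None:
        for name in ("min_labeled_enrichment", "max_unlabeled_labeling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.0 < self.min_replicate_fraction <= 1.0:
            raise ConfigurationError("min_replicate_fraction must be in (0, 1]")


def pooled_mid(per_sample_vectors) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean (renormalized) and sample sd of fraction vectors.

    Normalize-then-average: each replicate contributes equally regardless
    of its total intensity.
    """
    vectors = [np.asarray(v, dtype=float) for v in per_sample_vectors]
    if not vectors:
        raise ConfigurationError("pooled_mid needs at least one vector")
    length = len(vectors[0])
    if any(len(v) != length for v in vectors):
        raise ValidationError("fraction vectors have mismatched lengths")
    mat = np.vstack(vectors)
    mean = mat.mean(axis=0)
    mean = mean / mean.sum()
    sd = mat.std(axis=0, ddof=1) if len(vectors) > 1 else np.zeros(length)
    return mean, sd


def correction_matrix(unlabeled_mid) -> np.ndarray:
    """Shifted-kernel matrix C with C[:, j] = unlabeled_mid shifted down by j.

    Truncated columns are not renormalized: lost tail mass belongs in the
    residual, not hidden by rescaling.
    """
    u = np.asarray(unlabeled_mid, dtype=float)
    if (u < 0).any():
        raise ValidationError("unlabeled MID has negative entries")
    if abs(u.sum() - 1.0) > 1e-6:
        raise ValidationError("unlabeled MID must sum to 1")
    length = len(u)
    c = np.zeros((length, length))
    for j in range(length):
        c[j:, j] = u[: length - j]
    return c


def correct_mid(labeled_mid, unlabeled_mid) -> tuple[np.ndarray, float]:
    """Deconvolve the unlabeled kernel out of a labeled MID.

    Solves min ||C f - m||_2 with f >= 0, then renormalizes f to the
    simplex. Vectors of unequal length are zero-padded to the longer.
    Returns (corrected distribution, pre-normalization residual norm).
    """
    m = np.asarray(labeled_mid, dtype=float)
    u = np.asarray(unlabeled_mid, dtype=float)
    length = max(len(m), len(u))
    m = np.pad(m, (0, length - len(m)))
    u = np.pad(u, (0, length - len(u)))
    c = correction_matrix(u)
    f, residual = nnls(c, m)
    total = f.sum()
    if total <= 1e-12:
        raise DegenerateSolutionError("correction produced an all-zero solution")
    return f / total, float(residual)


def estimate_mids(groups: list[IsotopologueGroup], features: FeatureTable,
                  samples: SampleSheet,
                  min_replicates: int = 2) -> list[MidEstimate]:
    """Pool per-replicate MIDs and correct each group against its unlabeled set.

    The per-element sd of the corrected MID comes from correcting each
    labeled replicate separately (assumption-light, approximate);
    quantification is the mean (and sd) over labeled replicates of the
    summed member intensities.
    """
    estimates = []
    for group in groups:
        missing = [fid for fid in group.member_ids
                   if fid not in features.data.index]
        if missing:
            raise ValidationError(
                f"group '{group.group_id}' references absent features: {missing}"
            )
        labeled = samples.samples_for(group.condition, "labeled")
        unlabeled = samples.samples_for(group.condition, "unlabeled")
        if not unlabeled:
            unlabeled = list(samples.data.loc[
                samples.data["tracer_state"] == "unlabeled", "sample_id"])
        if len(labeled) < 1 or len(unlabeled) < 1:
            raise ConfigurationError(
                f"condition '{group.condition}' lacks labeled or unlabeled samples"
            )
        rel_lab = per_sample_relative_intensities(group.members, features, labeled)
        rel_unl = per_sample_relative_intensities(group.members, features, unlabeled)
        if not rel_lab or not rel_unl:
            continue
        raw_labeled, _ = pooled_mid(list(rel_lab.values()))
        raw_unlabeled, _ = pooled_mid(list(rel_unl.values()))
        corrected, residual = correct_mid(raw_labeled, raw_unlabeled)
        per_rep = []
        for vec in rel_lab.values():
            try:
                fi, _ = correct_mid(vec, raw_unlabeled)
                per_rep.append(fi)
            except DegenerateSolutionError:
                continue
        if len(per_rep) > 1:
            corrected_sd = np.vstack(per_rep).std(axis=0, ddof=1)
        else:
            corrected_sd = np.zeros_like(corrected)
        member_mat = features.data.loc[group.member_ids, list(rel_lab)] \
            .to_numpy(dtype=float)
        totals = np.nansum(member_mat, axis=0)
        quant = float(totals.mean())
        quant_sd = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
        estimates.append(MidEstimate(
            group_id=group.group_id,
            condition=group.condition,
            raw_labeled=raw_labeled,
            raw_unlabeled=raw_unlabeled,
            corrected=corrected,
            corrected_sd=corrected_sd,
            residual=residual,
            enrichment=1.0 - float(corrected[0]),
            quantification=quant,
            quantification_sd=quant_sd,
            labeled_replicate_fraction=len(rel_lab) / len(labeled),
            base_feature_id=group.base_feature_id,
        ))
    return estimates


def natural_labeling_allowance(n_tracer_atoms: int, tracer: str = "13C") -> float:
    """Expected apparent labeling (1 - M0) from natural abundance alone."""
    p = NATURAL_HEAVY_FRACTION[tracer]
    return float(1.0 - binom.pmf(0, n_tracer_atoms, p))


def filter_mids(estimates: list[MidEstimate], params: MidFilterParams,
                n_tracer_atoms: dict[str, int] | None = None,
                tracer: str = "13C") -> tuple[list[MidEstimate],
                                              list[tuple[MidEstimate, str]]]:
    """Apply the labeling filters; rejections carry the first failing rule.

    ``n_tracer_atoms`` optionally maps group_id to the tracer-element
    atom count of an annotated formula; with ``natural_tail_allowance``
    the expected natural 1 - M0 for that count is added to
    ``max_unlabeled_labeling`` so large molecules are not rejected for
    their own natural isotope envelope.
    """
    kept: list[MidEstimate] = []
    rejected: list[tuple[MidEstimate, str]] = []
    for est in estimates:
        reason = None
        if est.enrichment < params.min_labeled_enrichment:
            reason = "min_labeled_enrichment"
        if reason is None:
            allowance = 0.0
            if params.natural_tail_allowance and n_tracer_atoms \
                    and est.group_id in n_tracer_atoms:
                allowance = natural_labeling_allowance(
                    n_tracer_atoms[est.group_id], tracer)
            unlabeled_labeling = 1.0 - float(est.raw_unlabeled[0])
            if unlabeled_labeling > params.max_unlabeled_labeling + allowance:
                reason = "max_unlabeled_labeling"
        if reason is None and est.quantification < params.min_quantification:
            reason = "min_quantification"
        if reason is None and est.residual > params.max_residual:
            reason = "max_residual"
        if reason is None \
                and est.labeled_replicate_fraction < params.min_replicate_fraction:
            reason = "min_replicate_fraction"
        if reason is None:
            kept.append(est)
        else:
            rejected.append((est, reason))
    return kept, rejected


def estimates_to_mid_table(estimates: list[MidEstimate], experiment: str = "exp1",
                           display_names: dict[str, str] | None = None):
    """Convert estimates to the MIDTable consumed by contextualization."""
    from .io_tables import MidRecord, MIDTable

    display_names = display_names or {}
    records = []
    for est in estimates:
        name = display_names.get(est.group_id, "")
        records.append(MidRecord(
            node_id=est.group_id,
            display_name=name,
            condition=est.condition,
            experiment=experiment,
            fractions=est.corrected,
            fraction_sds=est.corrected_sd,
            quantification=est.quantification,
            quantification_sd=est.quantification_sd,
            residual=est.residual,
            annotated=bool(name),
        ))
    return MIDTable(records)
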