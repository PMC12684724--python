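"""Forward simulation of stable-isotope labeling experiments.

Generates feature tables, sample sheets and ground truth so the whole
pipeline is testable without instrument data. Each simulated compound
has a *tracer-incorporation distribution* (the "label distribution" over
heavy-atom counts 0..k); its measured MID in a labeled sample is that
distribution convolved with the compound's natural isotope pattern,
truncated at the tracer-atom count and renormalized — exactly the
shifted-kernel model the correction step inverts, so in the noise-free
limit the pipeline must recover every label distribution to numerical
precision.

What the simulator emulates: accurate-mass isotopologue features with
ppm-level m/z jitter, shared retention time with jitter, multiplicative
(lognormal) intensity noise, intensity-threshold dropout, and decoy
features with no isotopologue partners. What it does not: chromatographic
peak shapes, adduct cross-talk, natural isotopes of non-tracer elements
(the correction only ever sees the simulated unlabeled measurement, so
the pipeline round trip stays self-consistent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binom

from .annotation import AdductDef, DEFAULT_ADDUCTS, adduct_mz, monoisotopic_mass, \
    parse_formula
from .errors import ConfigurationError, ValidationError
from .io_tables import FeatureTable, SampleSheet
from .isotope_detection import TRACER_DELTAS
from .mid_calculation import NATURAL_HEAVY_FRACTION, TRACER_ELEMENT

#: Components of an expected MID below this fraction produce no feature.
MIN_EXPECTED_FRACTION = 1e-8


def natural_mid(formula: dict[str, int], tracer: str = "13C",
                n_max: int | None = None) -> np.ndarray:
    """Binomial natural-abundance MID over the tracer element's atoms.

    Only the tracer element contributes (no fine structure of O/S/...);
    truncation at ``n_max`` renormalizes.
    """
    element = TRACER_ELEMENT[tracer]
    n_atoms = formula.get(element, 0)
    if n_atoms == 0:
        raise ConfigurationError(
            f"formula lacks tracer element '{element}'"
        )
    p = NATURAL_HEAVY_FRACTION[tracer]
    k = np.arange(n_atoms + 1)
    mid = binom.pmf(k, n_atoms, p)
    if n_max is not None and n_max < n_atoms:
        mid = mid[: n_max + 1]
    return mid / mid.sum()


@dataclass
class SimCompound:
    """A simulated metabolite with a known tracer-incorporation pattern."""

    name: str
    formula: str
    rt: float
    base_abundance: float
    true_label_dist: np.ndarray
    pathway_group: str = ""
    adduct: AdductDef = field(default_factory=lambda: DEFAULT_ADDUCTS[0])

    def __post_init__(self) -> None:
        self.true_label_dist = np.asarray(self.true_label_dist, dtype=float)
        d = self.true_label_dist
        if (d < 0).any() or abs(d.sum() - 1.0) > 1e-9:
            raise ValidationError(f"compound '{self.name}': label dist off simplex")
        comp = parse_formula(self.formula)
        n_c = comp.get("C", 0)
        if len(d) - 1 > n_c:
            raise ValidationError(
                f"compound '{self.name}': more heavy positions than tracer atoms"
            )

    @property
    def composition(self) -> dict[str, int]:
        return parse_formula(self.formula)


@dataclass
class SimConfig:
    """Study conditions of one simulated labeling experiment."""

    compounds: list[SimCompound]
    n_replicates: int = 3
    intensity_cv: float = 0.05
    dropout_intensity: float = 0.0
    mz_jitter_ppm: float = 2.0
    rt_jitter_s: float = 1.0
    n_decoys: int = 50
    seed: int = 0
    tracer: str = "13C"
    condition: str = "cond1"
    experiment: str = "exp1"

    def __post_init__(self) -> None:
        if self.intensity_cv < 0:
            raise ConfigurationError("intensity_cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


def true_measured_mid(compound: SimCompound, tracer: str = "13C",
                      labeled: bool = True) -> np.ndarray:
    """Expected measured MID: label dist (*) natural pattern, truncated.

    The unlabeled state uses the delta distribution e0, so its measured
    MID is exactly the natural pattern. Truncation at tracer-atom count
    plus renormalization matches the physics (a molecule cannot hold
    more heavy atoms than tracer-element positions).
    """
    natural = natural_mid(compound.composition, tracer)
    n_atoms = len(natural) - 1
    dist = compound.true_label_dist if labeled else np.array([1.0])
    conv = np.convolve(dist, natural)[: n_atoms + 1]
    return conv / conv.sum()


@dataclass
class GroundTruth:
    """Compound <-> feature mapping and true distributions of a simulation."""

    feature_map: dict[str, dict[int, str]]       # compound -> n -> feature_id
    label_dists: dict[str, np.ndarray]
    measured_labeled: dict[str, np.ndarray]
    measured_unlabeled: dict[str, np.ndarray]
    pathway_groups: dict[str, str]
    base_features: dict[str, str]                # compound -> n=0 feature_id
    decoy_feature_ids: list[str]

    def frame(self) -> pd.DataFrame:
        rows = []
        for name, nmap in self.feature_map.items():
            for n, fid in sorted(nmap.items()):
                rows.append({"compound": name, "n": n, "feature_id": fid,
                             "pathway_group": self.pathway_groups.get(name, ""),
                             "true_fraction": float(self.label_dists[name][n])
                             if n < len(self.label_dists[name]) else 0.0})
        for fid in self.decoy_feature_ids:
            rows.append({"compound": "", "n": -1, "feature_id": fid,
                         "pathway_group": "", "true_fraction": 0.0})
        return pd.DataFrame(rows, columns=["compound", "n", "feature_id",
                                           "pathway_group", "true_fraction"])


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and relative sd ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


def simulate_experiment(config: SimConfig) -> tuple[FeatureTable, SampleSheet,
                                                    GroundTruth]:
    """Simulate one labeled-vs-unlabeled experiment from the config seed.

    Pure function of the config: the same seed reproduces every jitter,
    intensity and decoy byte-for-byte.
    """
    rng = np.random.default_rng(config.seed)
    delta = TRACER_DELTAS[config.tracer]
    lab_samples = [f"L{i + 1}" for i in range(config.n_replicates)]
    unl_samples = [f"U{i + 1}" for i in range(config.n_replicates)]
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": lab_samples + unl_samples,
        "experiment": config.experiment,
        "condition": config.condition,
        "tracer_state": ["labeled"] * len(lab_samples)
        + ["unlabeled"] * len(unl_samples),
        "replicate": list(range(1, len(lab_samples) + 1)) * 2,
    }))

    rows: list[dict] = []
    feature_map: dict[str, dict[int, str]] = {}
    label_dists: dict[str, np.ndarray] = {}
    measured_lab: dict[str, np.ndarray] = {}
    measured_unl: dict[str, np.ndarray] = {}
    pathway_groups: dict[str, str] = {}
    base_features: dict[str, str] = {}

    for ci, comp in enumerate(config.compounds):
        v_lab = true_measured_mid(comp, config.tracer, labeled=True)
        v_unl = true_measured_mid(comp, config.tracer, labeled=False)
        label_dists[comp.name] = comp.true_label_dist.copy()
        measured_lab[comp.name] = v_lab
        measured_unl[comp.name] = v_unl
        pathway_groups[comp.name] = comp.pathway_group
        feature_map[comp.name] = {}
        base_mz = adduct_mz(monoisotopic_mass(comp.composition), comp.adduct)
        charge = abs(comp.adduct.charge)
        length = max(len(v_lab), len(v_unl))
        for n in range(length):
            f_lab = v_lab[n] if n < len(v_lab) else 0.0
            f_unl = v_unl[n] if n < len(v_unl) else 0.0
            if max(f_lab, f_unl) <= MIN_EXPECTED_FRACTION:
                continue
            fid = f"F{ci:03d}_M{n}"
            center = base_mz + n * delta / charge
            mz = center * (1.0 + rng.normal(0.0, config.mz_jitter_ppm) * 1e-6)
            rt = comp.rt + rng.normal(0.0, config.rt_jitter_s)
            row: dict = {"feature_id": fid, "mz": mz, "rt": max(rt, 0.0)}
            lab_noise = _lognormal_noise(rng, config.intensity_cv,
                                         len(lab_samples))
            unl_noise = _lognormal_noise(rng, config.intensity_cv,
                                         len(unl_samples))
            for sid, eps in zip(lab_samples, lab_noise):
                row[sid] = comp.base_abundance * f_lab * eps
            for sid, eps in zip(unl_samples, unl_noise):
                row[sid] = comp.base_abundance * f_unl * eps
            rows.append(row)
            feature_map[comp.name][n] = fid
            if n == 0:
                base_features[comp.name] = fid

    decoy_ids = []
    if config.compounds:
        mz_lo = min(r["mz"] for r in rows) * 0.8
        mz_hi = max(r["mz"] for r in rows) * 1.2
        rt_lo = min(c.rt for c in config.compounds) * 0.5
        rt_hi = max(c.rt for c in config.compounds) * 1.5
    else:
        mz_lo, mz_hi, rt_lo, rt_hi = 100.0, 900.0, 30.0, 600.0
    for d in range(config.n_decoys):
        fid = f"D{d:03d}"
        row = {"feature_id": fid,
               "mz": float(rng.uniform(mz_lo, mz_hi)),
               "rt": float(rng.uniform(rt_lo, rt_hi))}
        abundance = float(10 ** rng.uniform(4.0, 6.0))
        noise = _lognormal_noise(rng, config.intensity_cv,
                                 len(lab_samples) + len(unl_samples))
        for sid, eps in zip(lab_samples + unl_samples, noise):
            row[sid] = abundance * eps
        rows.append(row)
        decoy_ids.append(fid)

    df = pd.DataFrame(rows).set_index("feature_id")
    sample_cols = lab_samples + unl_samples
    if config.dropout_intensity > 0:
        vals = df[sample_cols].to_numpy(dtype=float)
        vals[vals < config.dropout_intensity] = np.nan
        df[sample_cols] = vals
    features = FeatureTable(df[["mz", "rt"] + sample_cols])
    truth = GroundTruth(feature_map, label_dists, measured_lab, measured_unl,
                        pathway_groups, base_features, decoy_ids)
    return features, sheet, truth


# ---------------------------------------------------------------------------
# Canonical study configurations
# ---------------------------------------------------------------------------

#: Base tracer-incorporation patterns of the four pathway groups. Chosen so
#: within-group cosine stays >= 0.95 after per-compound perturbation while
#: every cross-group cosine stays < 0.8 (asserted at generation time).
PATHWAY_GROUP_PATTERNS = {
    "glycolysis": np.array([0.70, 0.20, 0.10, 0.00, 0.00]),
    "ppp": np.array([0.10, 0.60, 0.20, 0.10, 0.00]),
    "tca": np.array([0.10, 0.10, 0.20, 0.60, 0.00]),
    "lipid": np.array([0.05, 0.10, 0.15, 0.20, 0.50]),
}

_BENCHMARK_FORMULAS = [
    "C6H12O6", "C6H13O9P", "C6H8O7", "C7H14O7", "C9H11NO3",
    "C6H14N4O2", "C10H13N5O4", "C8H15NO6", "C12H22O11", "C9H16O4",
    "C7H12O6", "C10H17N3O6", "C11H12N2O2", "C6H13NO2", "C8H14O7",
    "C12H24O2", "C9H14N3O8P", "C10H16N2O3S", "C7H11NO5", "C11H19NO9",
]


def _perturbed_dist(base: np.ndarray, rng: np.random.Generator,
                    scale: float = 0.05) -> np.ndarray:
    """Multiplicative perturbation of a label pattern (zeros stay zero)."""
    d = base * (1.0 + rng.uniform(-scale, scale, size=len(base)))
    return d / d.sum()


def check_pathway_structure(compounds: list[SimCompound],
                            within_min: float = 0.95,
                            cross_max: float = 0.8) -> None:
    """Assert the group structure the contextualization tests rely on."""
    from .contextualization import mid_similarity

    for i, a in enumerate(compounds):
        for b in compounds[i + 1:]:
            if not a.pathway_group or not b.pathway_group:
                continue
            sim = mid_similarity(a.true_label_dist, b.true_label_dist, "cosine")
            if a.pathway_group == b.pathway_group and sim < within_min:
                raise ValidationError(
                    f"within-group cosine {sim:.3f} < {within_min} "
                    f"({a.name}, {b.name})"
                )
            if a.pathway_group != b.pathway_group and sim >= cross_max:
                raise ValidationError(
                    f"cross-group cosine {sim:.3f} >= {cross_max} "
                    f"({a.name}, {b.name})"
                )


def benchmark_compounds(seed: int = 0) -> list[SimCompound]:
    """The 20-compound, 4-pathway-group benchmark panel."""
    rng = np.random.default_rng(seed)
    groups = list(PATHWAY_GROUP_PATTERNS)
    compounds = []
    for i, formula in enumerate(_BENCHMARK_FORMULAS):
        group = groups[i % len(groups)]
        dist = _perturbed_dist(PATHWAY_GROUP_PATTERNS[group], rng)
        compounds.append(SimCompound(
            name=f"cmpd{i:02d}",
            formula=formula,
            rt=60.0 + 18.0 * i,
            base_abundance=float(10 ** (5.0 + (i % 5) * 0.4)),
            true_label_dist=dist,
            pathway_group=group,
        ))
    check_pathway_structure(compounds)
    return compounds


def benchmark_config(seed: int = 0) -> SimConfig:
    """The canonical benchmark: 20 compounds, 3+3 replicates, cv 5%, 50 decoys."""
    return SimConfig(
        compounds=benchmark_compounds(seed),
        n_replicates=3,
        intensity_cv=0.05,
        mz_jitter_ppm=2.0,
        rt_jitter_s=1.0,
        n_decoys=50,
        seed=seed,
    )


def null_config(seed: int = 0, n_compounds: int = 5,
                n_decoys: int = 0) -> SimConfig:
    """A no-labeling control: labeled samples drawn from the unlabeled model."""
    compounds = []
    for i, formula in enumerate(_BENCHMARK_FORMULAS[:n_compounds]):
        compounds.append(SimCompound(
            name=f"null{i:02d}",
            formula=formula,
            rt=60.0 + 20.0 * i,
            base_abundance=1e6,
            true_label_dist=np.array([1.0]),
            pathway_group="",
        ))
    return SimConfig(compounds=compounds, n_replicates=3, intensity_cv=0.05,
                     mz_jitter_ppm=2.0, rt_jitter_s=1.0, n_decoys=n_decoys,
                     seed=seed)


def noise_free_config(seed: int = 0, n_compounds: int = 10) -> SimConfig:
    """Noise-free identifiability setting: cv 0, no jitter, no decoys."""
    cfg = benchmark_config(seed)
    return replace(cfg, compounds=cfg.compounds[:n_compounds],
                   intensity_cv=0.0, mz_jitter_ppm=0.0, rt_jitter_s=0.0,
                   n_decoys=0)
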