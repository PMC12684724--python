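"""Annotate features by accurate mass, reference standards and MS2 spectra.

MS1 annotation matches each feature m/z against compound x adduct
theoretical m/z within a ppm window; standards additionally require a
retention-time match; MS2 annotation scores fragmentation spectra with
a square-root-intensity greedy cosine.
"""

import pandas as pd

import isocontext as ic

config = ic.benchmark_config(seed=1)
features, _, truth = ic.simulate_experiment(config)
compounds = pd.DataFrame([{"name": c.name, "formula": c.formula}
                          for c in config.compounds])

annotations = ic.annotate_ms1(features, compounds, ppm_tol=5.0)
print(f"MS1: {len(annotations)} candidate annotations on "
      f"{annotations['feature_id'].nunique()} of {len(features)} features")
row = annotations.iloc[0]
print(f"  e.g. {row['feature_id']} -> {row['compound_name']} "
      f"{row['adduct']} at {row['ppm_error']:+.2f} ppm")

# reference standard: m/z AND retention time must match
std = ic.ReferenceStandard("glucose", "C6H12O6", rt=120.0, mz=181.0707)
feat = ic.FeatureTable(pd.DataFrame(
    {"mz": [181.0706], "rt": [118.0], "S1": [1.0]},
    index=pd.Index(["F_glc"], name="feature_id")))
matches = ic.match_reference_standards(feat, [std], ppm_tol=5.0, rt_tol=10.0)
print(f"standards: matched {list(matches['compound_name'])} "
      f"(0.55 ppm, 2 s inside the windows)")

# MS2: identical spectrum scores 1.0, half-overlapping ~0.71
a = ic.Ms2Spectrum(181.0707, 120.0, [(100.0, 1.0), (200.0, 1.0)])
b = ic.Ms2Spectrum(181.0707, 120.0, [(100.0, 1.0)])
print(f"MS2 similarity, 1-of-2 shared peaks: "
      f"{ic.spectral_similarity(a, b):.4f} (cosine of (1,1) vs (1,0))")
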