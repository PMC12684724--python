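# isocontext

Non-targeted analysis of stable-isotope labeling metabolomics
experiments: isotopologue detection from labeled/unlabeled feature
tables, mass isotopomer distribution (MID) calculation with
unlabeled-condition correction, MS1/standard/MS2 annotation, and
MID-similarity networks that place unknown metabolites next to
annotated ones, with pathway overlay in Cytoscape JSON.

**Who it is for.** Anyone with LC-MS (or other preprocessed) feature
intensity tables from a tracer experiment — e.g. U-13C-glucose fed to
cells alongside unlabeled controls — who wants corrected labeling
patterns and biological context for unannotated features without a
predefined target list. The library is instrument-agnostic: it starts
from CSV tables (features x samples, sample metadata), or directly
from a MID table for contextualization-only runs.

## The method

A tracer shifts part of each downstream metabolite's isotopologue
envelope by multiples of the heavy-isotope mass difference
(Δ(13C) = 1.0033548 Da). For each base feature, `isocontext` collects
candidate isotopologues at m/z + nΔ/z within ppm and retention-time
windows and tests, per position n, whether the *relative* intensity
pattern differs between labeled and unlabeled samples (two-sided Welch
t-test, Benjamini–Hochberg across the run).

The measured MID **m** of a labeled sample is the tracer-incorporation
distribution **f** convolved with the compound's natural isotope
pattern. Writing the unlabeled condition's measured MID as the kernel
**u**, the forward model is

    m = C(u) · f,    C[i, j] = u[i − j]  (0 for i < j)

and correction inverts it by non-negative least squares, reporting the
reconstruction residual. Enrichment is 1 − f₀, the fraction of
molecules carrying any label. Because MIDs of metabolites in the same
pathway are closely related, cosine similarity between corrected MIDs
(combined across experiments/conditions) yields a network in which the
nearest unannotated neighbors of an annotated metabolite are candidates
for pathway membership. See `docs/methods.md` for the full model,
parameter and design documentation.

## Worked example

```python
import isocontext as ic

config = ic.benchmark_config(seed=1)          # 20 compounds, 4 pathway groups
features, samples, truth = ic.simulate_experiment(config)
groups = ic.detect_groups(features, samples,
                          tracer=ic.TracerDef.from_name("13C"),
                          params=ic.DetectionParams(ppm_tol=5.0, alpha=0.05),
                          condition="cond1")
estimates = ic.estimate_mids(groups, features, samples)
net = ic.build_network(ic.estimates_to_mid_table(estimates), threshold=0.9)
```

Running `python examples/01_simulate_and_detect.py` (then 02 and 04)
prints:

```
simulated 210 features (20 compounds + 50 decoys), 6 samples
detected 20 isotopologue groups
20/20 true compounds recovered, 0 false groups
example group G0000_cond1: base F014_M0, members n=[0, 1, 2, 3, 4, 5, 6, 7],
  min adjusted p = 5.69e-04
G0000_cond1: enrichment 0.901, corrected MID [0.099 0.101 0.209 0.59 0.],
  residual 2.54e-03
network: 20 nodes, 40 edges at cosine >= 0.9
100% of edges connect same-pathway compounds
median similarity: 1.000 within pathway groups vs 0.356 across
```

Reading: all 20 simulated compounds were found with no false groups
among 50 decoys; the first group's corrected MID says ~90% of that
metabolite's molecules carry label, mostly three 13C atoms (M3 = 0.59);
and at a 0.9 cosine threshold every network edge connects metabolites
that truly share a precursor labeling pattern.

The same stages are available as a CLI for shell use:

```sh
isocontext simulate --preset benchmark --seed 1 --out-dir demo/
isocontext pipeline --features demo/features.csv --samples demo/samples.csv \
    --compounds demo/compounds.csv --out-dir demo/run/
```

Each stage writes its outputs plus a JSON run manifest (parameters,
input digests, output list, seed).

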