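"""The whole analysis end to end on a synthetic 38-landscape study.

Generates a complete study bundle (sites, covariates, dung pats,
communities, traits) with a known diversity -> removal effect, then runs
removal rates, community metrics, the two PCAs, the spatial
random-effects meta-analysis and the piecewise SEM, exactly as one would
on field data read from CSVs.
"""

import tempfile

from dungbef.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as out:
    report = run_pipeline(RunConfig(out_dir=out, synthetic=True, seed=5))
    meta = report["meta"]
    print("stages completed:", " -> ".join(report["stages"]))
    print(f"\nclimate PCA axis 1: "
          f"{100 * report['pca_climate_variance_fraction']:.1f}% of variance; "
          f"diversity-difference PCA axis 1: "
          f"{100 * report['pca_diversity_variance_fraction']:.1f}%")
    p = meta["pooled"]
    print(f"pooled Hedges' g = {p['mu']:+.3f} (t = {p['t']:.2f}, "
          f"p = {p['p']:.3f}), structure = {meta['selected_structure']}")
    h = meta["heterogeneity"]
    print(f"T^2 = {h['tau2']:.2f}, Q = {h['Q']:.1f} (df {h['df']}), "
          f"I^2 = {h['I2']:.3f}")
    mr = meta["meta_regression"]
    print(f"meta-regression: F({mr['F_df'][0]},{mr['F_df'][1]}) = "
          f"{mr['F']:.2f}, p = {mr['F_p']:.3f}, "
          f"pseudo-R^2 = {mr['pseudo_R2']:.3f}")
    sem = report["sem"]
    print(f"piecewise SEM: Fisher's C = {sem['fishers_C']:.1f} "
          f"(df {sem['df']}, p = {sem['p']:.2g})")
    if sem["suggested_path"]:
        a, b, pv = sem["suggested_path"]
        print(f"  most significant violated claim: {a} -> {b} (p = {pv:.2g}) "
              "— the paired design induces within-landscape dependence the "
              "between-site DAG does not encode.")
print("\nNo overall regime effect, but ~88% of effect-size variance is "
      "between sites: the signature the analysis is built to dissect.")
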