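"""Quantify the change of tabletability with RP and CoTr.

Runs the pipeline on a small zero-noise synthetic library and contrasts
the legacy reworking potential (a per-material ratio of areas) with the
relative change of tabletability (an absolute area change normalised by
the library-wide envelope).  A weak material can post a dramatic RP while
its absolute tabletability change is negligible — the situation CoTr was
designed to de-dramatise.
"""

import warnings

from tabletability.config import RunConfig
from tabletability.pipeline import run_pipeline
from tabletability.simulate import library_tables, make_library

lib = make_library(n_materials=12, seed=5, noise_sd=0.0)
materials, tablets, truth = library_tables(lib)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(materials, tablets, RunConfig())

env = result.envelope
print(f"library envelope: AUCmax = {env.auc_max:.0f} MPa², AUCmin = {env.auc_min:.0f} MPa², "
      f"Amax = {env.a_max:.0f} MPa²")
print()
print(f"{'material':10s} {'AUCp':>8s} {'AUCg':>8s} {'RP %':>7s} {'CoTr %':>8s}  type")
merged = result.indices.merge(result.classification, on="material_id")
for _, row in merged.iterrows():
    print(f"{row['material_id']:10s} {row['AUCp']:8.0f} {row['AUCg']:8.0f} "
          f"{row['RP_percent']:7.1f} {row['CoTr_percent_x']:8.2f}  {row['tccs_type']}")
print()
weak = merged.loc[(merged["AUCp"] < 300) & (merged["RP_percent"] < 90)]
if len(weak):
    row = weak.iloc[0]
    print(f"note: {row['material_id']} loses {100 - row['RP_percent']:.0f}% of its area by RP,")
    print(f"yet its CoTr is only {row['CoTr_percent_x']:.2f}% of the library envelope —")
    print("RP amplifies changes in weak materials; CoTr keeps them comparable.")
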