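"""Generate a synthetic two-subtype cohort and inspect its planted structure.

Builds a 154-sample cohort of per-cell morphometric tables plus clinical
outcomes (survival with a planted subtype hazard ratio of 1.893, metastasis
loading on biomarkers 13 and 249) and prints what was planted.
"""

import numpy as np

import morphoctx as m

cfg = m.trp53_preset(seed=0, cells_per_slide=100)
cohort = m.generate_cohort(cfg)

clin = cohort.clinical
print(f"samples: {len(clin)}  subtype counts: "
      f"{np.bincount(clin['subtype_true'])[1:].tolist()}")
print(f"events: {int(clin['event'].sum())}  "
      f"censored fraction: {1 - clin['event'].mean():.2f}")
print(f"metastasis prevalence: {clin['metastasis'].mean():.2f}")

cells = sum(len(t) for t in cohort.features.values())
print(f"cells total: {cells} (Poisson around {cfg.cells_per_slide}/slide)")

# the planted morphometric difference downstream stages must rediscover
for g in (1, 2):
    sids = clin.loc[clin["subtype_true"] == g, "sample_id"]
    major = np.concatenate(
        [cohort.features[s]["major_axis_length"].to_numpy() for s in sids]
    )
    print(f"subtype {g}: mean major axis {major.mean():.1f} px")
# Subtype 2 nuclei are larger/brighter/more irregular; its hazard is 1.893x.
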