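#!/usr/bin/env python
"""Push one synthetic subject through the full imaging chain.

Phantom (two-shell DWI at SNR 40 + Dixon pair + muscle mask) -> MP-PCA
denoising -> isotropic 2 mm upsampling -> Bayesian compartment fitting ->
Dixon FF map -> per-muscle VOI means, compared against the generator's
ground truth. Writes results/phantom_metrics.json.
"""

import json
from pathlib import Path

import pandas as pd

from myodmi.dixon import fat_fraction_from_echoes
from myodmi.dmi_fit import PriorConfig, fit_fractions_bayes
from myodmi.model import TissueParams
from myodmi.preprocess import mppca_denoise, upsample_iso
from myodmi.synthetic import (
    default_scheme,
    generate_cohort,
    generate_subject_phantom,
    make_phantom_mask,
    subject_truth_from_row,
)
from myodmi.voi import voi_mean

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

row = generate_cohort(seed=7).iloc[0]  # first male subject
truth = subject_truth_from_row(row)
scheme = default_scheme()
tissue = TissueParams()

phantom = generate_subject_phantom(truth, scheme, snr=40.0, seed=11)
dwi, _ = mppca_denoise(phantom.dwi)
dwi = upsample_iso(dwi, 2.0)
mask = make_phantom_mask(dwi.data.shape[:3])

cmap = fit_fractions_bayes(dwi, tissue, PriorConfig(), seed=12)
ff = fat_fraction_from_echoes(
    phantom.dixon_in_phase.data, phantom.dixon_opposed_phase.data
)

records = []
for label, name in mask.muscles().items():
    rec = {"muscle": name}
    for metric in ("v_intra", "v_extra", "v_iso"):
        rec[metric] = voi_mean(getattr(cmap, metric), mask, label)
        rec[f"{metric}_true"] = truth[name][metric]
    rec["ff"] = voi_mean(ff.ff, phantom.mask, label)
    rec["ff_true"] = truth[name]["ff"]
    records.append(rec)

df = pd.DataFrame(records).set_index("muscle")
(OUT / "phantom_metrics.json").write_text(json.dumps(records, indent=2))
print("subject", row["subject_id"], "(male), SNR 40, denoised + upsampled to 2 mm iso")
print(df.round(3))
err = max(
    abs(r[m] - r[f"{m}_true"]) for r in records for m in ("v_intra", "v_extra", "v_iso")
)
print(f"\nmax VOI-mean fraction error vs ground truth: {err:.3f}")
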