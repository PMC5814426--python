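"""Generate a small labeled EEG cohort and inspect the planted effect.

Builds 20 synthetic 2-minute resting-state recordings (47% male), writes
them to EDF with a manifest, and compares female vs male beta-band power
on the planted fronto-central/centro-parietal channels.  The printed
ratio should sit clearly above 1: females carry the planted fast-beta
amplitude gain (1.4 on those channels) on top of a small broadband gain.
"""

import numpy as np

import eegsex as e

spec = e.CohortSpec(n_subjects=20, male_fraction=0.47, duration_s=120.0,
                    seed=42)
cohort = e.generate_cohort(spec)
manifest = e.write_cohort_edf(cohort, "scratch/example_cohort")
print(f"wrote {len(manifest)} EDF files; "
      f"{manifest['sex'].sum()} male / {(1 - manifest['sex']).sum()} female")

planted = np.where(e.default_spatial_profile() == 1.0)[0]
by_sex = {0: [], 1: []}
for rec in cohort:
    f, psd = e.welch_psd(rec)
    beta = e.band_power(psd, f, (12.0, 25.0))
    by_sex[rec.sex].append(beta[planted].mean())

ratio = np.mean(by_sex[0]) / np.mean(by_sex[1])
print(f"female/male beta power on planted channels: {ratio:.2f} "
      "(>1 means the planted sex difference is present)")
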