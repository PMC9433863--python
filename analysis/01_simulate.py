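#!/usr/bin/env python
"""Generate the study inputs: a pelvic PET/CT phantom with known ground
truth, the deterministic 41-patient fixture cohort, and a freshly sampled
cohort from the reference distributions.

Small text artifacts (cohort tables, blood counts, phantom truth) go under
results/; the NIfTI volumes themselves are bulky and land in scratch/.
"""

from pathlib import Path

import pandas as pd

from pelvimarrow import image_io, synthetic_data as sd

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sim"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    phantom = sd.generate_phantom(sd.PhantomConfig(active_fraction=0.312, seed=1))
    image_io.write_volume(phantom["ct"], SCRATCH / "phantom_ct.nii.gz")
    image_io.write_volume(phantom["pet"], SCRATCH / "phantom_pet.nii.gz")
    image_io.write_mask(phantom["interference"], SCRATCH / "phantom_interference.nii.gz")
    sd.truth_to_json(phantom["truth"], RESULTS / "phantom_truth.json")
    print(f"phantom: {phantom['truth']['n_bone_voxels']} bone voxels, "
          f"true BM_ACT% {phantom['truth']['bm_act_pct']:.2f}, "
          f"lesion peak {phantom['truth']['suvmax']}, "
          f"analytic MTV {phantom['truth']['mtv_cm3_analytic']:.2f} cm^3")

    fixture, series = sd.realize_table3_cohort()
    fixture.to_csv(RESULTS / "fixture_cohort.csv", index=False)
    blood = pd.concat(
        [s.records.assign(patient_id=pid) for pid, s in series.items()], ignore_index=True
    )
    blood.round(3).to_csv(RESULTS / "fixture_blood.csv", index=False)
    print(f"fixture cohort: {len(fixture)} patients, "
          f"{(fixture['ht_group'] == 'G3plus').sum()} severe (G3+), "
          f"group counts {fixture['bm_group'].value_counts().to_dict()}")

    sampled, _ = sd.generate_cohort(sd.CohortConfig(n=41, seed=1), include_series=False)
    sampled.round(4).to_csv(RESULTS / "sampled_cohort.csv", index=False)
    print(f"sampled cohort: {len(sampled)} patients, "
          f"{(sampled['ht_group'] == 'G3plus').mean():.1%} severe")


if __name__ == "__main__":
    main()
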