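#!/usr/bin/env python
"""Determine the two calibration factors.

Sphere-CF: a 65.4 ml sphere at 3.04 MBq/ml inside the non-radioactive water
cylinder, delineated at its physical dimensions.  Cylinder-CF: the cylinder
uniformly filled at 3.04 MBq/ml with a central VOI (half radius, half
height) excluding edge effects.  The sphere-CF comes out below the
cylinder-CF because spill-out counts leave the physical sphere VOI.
"""

import json
from pathlib import Path

from luquant.study import desk_config, run_calibration_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cal = run_calibration_study(desk_config(), seed=1)
    payload = {
        "sphere_cf_cps_per_mbq": cal.sphere_cf.value_cps_per_mbq,
        "cylinder_cf_cps_per_mbq": cal.cylinder_cf.value_cps_per_mbq,
        "percent_difference_ref_cylinder": cal.percent_difference,
    }
    (OUT / "calibration.json").write_text(json.dumps(payload, indent=1))
    print(f"sphere-CF   : {payload['sphere_cf_cps_per_mbq']:.2f} cps/MBq")
    print(f"cylinder-CF : {payload['cylinder_cf_cps_per_mbq']:.2f} cps/MBq")
    print(f"difference  : {payload['percent_difference_ref_cylinder']:+.1f}% "
          "(reference: cylinder-CF)")
    print(f"written to {OUT / 'calibration.json'}")


if __name__ == "__main__":
    main()
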