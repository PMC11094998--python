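"""Build a small synthetic cohort and print severity-grouped summary tables.

Patients are classified from their largest Cobb angle (mild < 20°,
strong > 40°, medium in between) and per-level / regional mean ± SD of the
spinous-tip distance L12 and skin distance L13 are tabulated, pooling
regional rows over all (patient, level) values.
"""

import numpy as np

from vertemetry import PatientRecord, aggregate_levels, findings_report, regional_means
from vertemetry.morphometry import VERTEBRAL_LEVELS, AspectPair, QuadrantAreas, VertebraMeasurement

rng = np.random.default_rng(0)


def measurement(level, L12, L13):
    q = QuadrantAreas(250.0, 250.0, 250.0, 250.0, 1000.0)
    return VertebraMeasurement(level, L12, L13, None, q, AspectPair(0.5, 0.5))


records = []
for i in range(8):
    cobb = float(rng.uniform(8, 55))
    ms = []
    for lv in VERTEBRAL_LEVELS[2:]:  # T2..L5
        L12 = float(rng.normal(58, 4))
        # skin distance varies more between patients than the spinous distance
        L13 = L12 + float(rng.normal(18, 6))
        ms.append(measurement(lv, L12, L13))
    records.append(PatientRecord(f"P{i:02d}", "female" if i % 2 else "male",
                                 ((cobb, "T8"),), tuple(ms)))

table = regional_means(aggregate_levels(records, grouping="severity"))
regional = table.table[table.table["level"].isin(["T2...T11", "T12/L1", "L2...L5", "all"])]
print(regional.to_string(index=False, float_format=lambda x: f"{x:.1f}"))

report = findings_report({"severity": aggregate_levels(records, "severity")})
for group, entry in report["severity"]["sd_L13_gt_sd_L12"].items():
    print(f"{group}: SD(L13)={entry['sd_L13']:.1f} > SD(L12)={entry['sd_L12']:.1f}? "
          f"{entry['holds']}")
print("With independent per-level noise on the skin distance, SD(L13) exceeds")
print("SD(L12) in every severity group, as the aggregation is built to expose.")
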