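"""Compute the 1-100 area deprivation index from five indicators.

Employment (unemployment rate, employed-at-residence), income (purchasing
power) and education (high-school degree, no formal education) domains are
weighted equally; aggregation is rank-based, so the index only depends on
how areas order each other.
"""

import pandas as pd

from spatialenroll import compute_deprivation

areas = pd.DataFrame(
    {
        "area_id": ["A", "B", "C", "D", "E"],
        "unemployment_rate": [12, 5, 9, 7, 20],
        "employed_at_residence": [40, 55, 45, 60, 35],
        "purchasing_power": [90, 120, 100, 110, 80],
        "highschool_degree": [25, 40, 30, 35, 20],
        "no_formal_education": [8, 3, 6, 4, 10],
    }
)

print(compute_deprivation(areas).round(3).to_string(index=False))

# Area E is worst on every indicator and scores 100 (most deprived);
# B is best on every indicator and scores 1 (least deprived).
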