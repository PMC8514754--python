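"""Published per-patient measurements for a seven-patient repaired
tetralogy-of-Fallot cohort, used as pipeline inputs.

These are the printed cohort tables (demographics and flow splits, branch
diameters and velocities, geometric analysis, and dimensionless numbers)
that the aggregation stages reproduce. The raw images and meshes behind
them are not public, so the tables are the canonical cohort input of this
package.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

# demographics and hemodynamics; flow split percentages of net forward
# volume (patient 7's split is radius-estimated, flagged in `split_estimated`)
_DEMOGRAPHICS = """\
patient,sex,age_years,pa_rf_pct,grade,split_rpa_pct,split_lpa_pct,split_estimated
1,M,5,45,Severe,55.3,44.7,0
2,M,12,41,Severe,64.8,35.2,0
3,M,19,30,Severe,55.5,44.4,0
4,M,23,40,Moderate,63.9,36.1,0
5,M,30,48,Severe,75.4,24.6,0
6,F,41,50,Moderate,76.6,23.4,0
7,F,54,50,Severe,45.7,54.3,1
"""

# branch diameters (m), mean flow rate (ml/s), mean and max velocities (m/s)
_FLOW = """\
model,D_mpa_m,D_rpa_m,D_lpa_m,Q_mean_mls,U_mean_mpa,U_mean_rpa,U_mean_lpa,U_max_mpa,U_max_rpa,U_max_lpa
1,0.017,0.010,0.013,33.9,0.086,0.133,0.148,0.696,1.076,0.534
2,0.022,0.013,0.013,47.2,0.086,0.154,0.087,0.699,1.252,0.703
3,0.050,0.016,0.015,114.4,0.131,0.696,0.676,0.346,1.843,1.797
4,0.018,0.009,0.015,69.6,0.148,0.391,0.071,1.210,3.302,1.260
5,0.024,0.017,0.022,103.0,0.048,0.066,0.020,1.043,1.454,0.308
6,0.025,0.019,0.019,85.0,0.158,0.201,0.063,0.685,0.982,0.312
7,0.028,0.017,0.028,54.4,0.069,0.134,0.119,0.508,1.581,0.648
"""

# geometric analysis: curvature (1/mm) mean/max, tortuosity, minimum
# inscribed-sphere radius (mm), in-plane and signed out-of-plane angles (deg)
_GEOMETRY = """\
model,kappa_mean_rpa,kappa_max_rpa,kappa_mean_lpa,kappa_max_lpa,tortuosity_rpa,tortuosity_lpa,r_min_rpa_mm,r_min_lpa_mm,inplane_rpa_deg,inplane_lpa_deg,outplane_rpa_deg,outplane_lpa_deg
1,0.021,0.066,0.036,0.103,0.017,0.115,4.8,5.8,132.1,118.7,1.3,27.0
2,0.015,0.036,0.029,0.110,0.017,0.132,4.5,4.8,142.6,119.9,9.4,-21.4
3,0.014,0.087,0.012,0.068,0.044,0.091,5.7,4.8,163.8,168.2,7.1,-3.8
4,0.018,0.035,0.036,0.105,0.013,0.121,3.5,4.1,142.2,110.1,-15.4,11.2
5,0.014,0.053,0.032,0.131,0.011,0.258,7.0,6.5,135.9,118.6,-35.1,58.9
6,0.016,0.034,0.042,0.094,0.003,0.182,6.3,5.3,160.3,126.7,-26.1,31.5
7,0.019,0.046,0.015,0.058,0.103,0.111,6.7,10.8,124.4,160.1,-12.5,16.9
"""

# dimensionless numbers per model: Reynolds mean (max) per branch, inlet
# Womersley, and daughter-branch maximum Dean numbers
_DIMENSIONLESS = """\
model,re_mean_mpa,re_max_mpa,re_mean_rpa,re_max_rpa,re_mean_lpa,re_max_lpa,wo,de_max_rpa,de_max_lpa
1,397,3199,367,2958,520,1873,13.6,1034,1178
2,504,4093,542,4408,300,2434,17.3,1302,1215
3,1722,4561,2962,7846,2615,6925,40.3,2115,1450
4,696,5694,905,7638,290,5127,13.6,1412,1844
5,297,6529,305,6695,116,1760,16.3,3180,1851
6,1023,4450,1011,4936,315,1537,17.7,1934,972
7,521,3823,718,6918,886,4807,18.3,1085,1854
"""


def demographics() -> pd.DataFrame:
    return pd.read_csv(StringIO(_DEMOGRAPHICS))


def flow_table() -> pd.DataFrame:
    return pd.read_csv(StringIO(_FLOW))


def geometry_table() -> pd.DataFrame:
    return pd.read_csv(StringIO(_GEOMETRY))


def dimensionless_table() -> pd.DataFrame:
    return pd.read_csv(StringIO(_DIMENSIONLESS))


def measured_flow_splits() -> pd.DataFrame:
    """Per-patient splits excluding the radius-estimated patient."""
    df = demographics()
    return df[df["split_estimated"] == 0].reset_index(drop=True)
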