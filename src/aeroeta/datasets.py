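"""Published reference summary of a 22-variety winter-wheat trial.

Variety-mean table from a two-season, two-water-regime (full irrigation at
100% of crop ET vs rainfed) field trial of 22 commercial winter wheat
varieties in a Mediterranean climate: mean leaf area index, cumulative
actual evapotranspiration over the season and its vegetative/grain-filling
split (mm), grain yield (kg·ha⁻¹) and water productivity (kg·m⁻³), plus
the two treatment-level means.  Used as a worked example and as the fixed
input for recomputing the trial's derived statistics (treatment
reductions, trait correlations, WP unit identity).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["reference_variety_trial", "reference_treatment_means"]

_VARIETY_ROWS = """\
variety	LAI	ETa	GY	ETa_GF	ETa_VEG	WP
Variety 1	6.32	232.0	9951.1	68.9	163.1	4.2
Variety 2	6.63	241.4	9356.9	67.0	174.4	3.8
Variety 3	5.93	248.1	9330.4	86.7	161.4	3.7
Variety 4	6.93	270.5	9238.3	83.3	187.2	3.4
Variety 5	6.32	234.4	9215.6	66.5	167.9	3.9
Variety 6	6.76	257.9	9154.2	78.2	179.7	3.5
Variety 7	6.10	234.8	9109.3	71.4	163.4	3.8
Variety 8	6.50	246.1	9108.7	61.5	184.6	3.6
Variety 9	6.84	255.7	9105.8	84.6	171.1	3.5
Variety 10	5.66	230.3	9011.5	80.5	149.8	3.8
Variety 11	6.50	236.8	9002.6	64.0	172.8	3.7
Variety 12	6.91	252.0	8919.5	72.7	179.3	3.4
Variety 13	6.16	242.4	8875.9	71.7	170.7	3.6
Variety 14	7.22	252.9	8862.2	79.1	173.8	3.4
Variety 15	7.15	250.2	8783.7	54.9	195.3	3.4
Variety 16	6.63	263.8	8762.3	52.9	180.9	3.7
Variety 17	5.60	236.7	8730.9	82.5	154.2	3.6
Variety 18	6.51	220.4	8718.9	62.7	157.7	3.9
Variety 19	6.38	240.8	8336.9	84.4	156.4	3.4
Variety 20	6.99	255.4	8122.2	79.0	176.4	3.2
Variety 21	7.23	256.2	7983.2	43.4	197.8	3.2
Variety 22	6.06	236.9	7869.9	83.7	153.2	3.3
"""

_TREATMENT_ROWS = """\
treatment	LAI	ETa	GY	ETa_GF	ETa_VEG	WP
full_irrigation	7.22	268.3	10323.9	97.2	171.1	3.8
rainfed	5.81	218.1	7453.3	46.4	171.7	3.3
"""


def reference_variety_trial() -> pd.DataFrame:
    """22 variety-mean rows (LAI, ETa, GY, ETa_GF, ETa_VEG, WP)."""
    return pd.read_csv(StringIO(_VARIETY_ROWS), sep="\t")


def reference_treatment_means() -> pd.DataFrame:
    """Treatment-level means (full irrigation vs rainfed), same columns."""
    return pd.read_csv(StringIO(_TREATMENT_ROWS), sep="\t", index_col="treatment")
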