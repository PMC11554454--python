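"""Reference clinical cohort summaries for the post-stroke depression study.

Published demographic and clinical summary statistics (mean +/- sd, n)
of the study cohorts: healthy controls (HC, n=40), post-stroke
depression patients at baseline (PSD, n=70), the same patients after
the six-week acupuncture course (MA, n=60), and the treated cohort
split into remission-predicted (RP, n=40) and non-remission-predicted
(NRP, n=20) subgroups by the HAMD-24 reduction-rate rule.

These summaries are inputs to the desk-level statistical layer: every
group test statistic they support (pooled t, chi-square on sex counts,
mean HAMD-24 change) can be recomputed from them without access to the
raw recordings.
"""
from __future__ import annotations

from .stats import SummaryStat

# mean +/- sd summaries per group
HC_AGE = SummaryStat(58.90, 4.91, 40)
PSD_AGE = SummaryStat(56.93, 6.65, 70)
RP_AGE = SummaryStat(58.03, 6.36, 40)
NRP_AGE = SummaryStat(58.15, 6.46, 20)

HC_EDUCATION = SummaryStat(7.10, 2.31, 40)
PSD_EDUCATION = SummaryStat(7.16, 2.57, 70)
RP_EDUCATION = SummaryStat(7.65, 2.72, 40)
NRP_EDUCATION = SummaryStat(6.20, 2.33, 20)

RP_PSD_DURATION_DAYS = SummaryStat(69.25, 4.20, 40)
NRP_PSD_DURATION_DAYS = SummaryStat(73.15, 5.10, 20)

HC_HAMD = SummaryStat(2.63, 1.03, 40)
PSD_HAMD = SummaryStat(19.89, 1.81, 70)
MA_HAMD = SummaryStat(10.87, 3.93, 60)

# sex counts as (male, female) rows per group
SEX_HC_PSD = [[21, 19], [34, 36]]
SEX_RP_NRP = [[20, 20], [7, 13]]


def hamd_mean_change() -> float:
    """Mean HAMD-24 change from baseline (PSD) to post-treatment (MA)."""
    return MA_HAMD.mean - PSD_HAMD.mean
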