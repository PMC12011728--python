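"""Published group-level summary statistics of the two-group MI-NF study.

Per-participant raw data of the study this pipeline models are not publicly
deposited; what is published are block-wise summary statistics of the
contralateral MI-interval ERD (%): the paired training-vs-neurofeedback
comparison within the quiet-rest group (t statistic, group means and SDs,
n = 17) and the per-block group means/SDs of both groups (17 participants
each). These summaries are sufficient inputs for the effect-size and
independent-test recomputations in :mod:`minf.stats`.

The per-subject paired differences were not published, so the paired t
itself is not recomputable from data — only d = t / sqrt(n) is.
"""

import pandas as pd

N_PER_GROUP = 17

#: Paired comparison T-MI-ERD vs NF-MI-ERD within the quiet-rest group.
PAIRED_SUMMARY = pd.DataFrame(
    [
        # block, t,     n,  mean_T,  sd_T,   mean_NF, sd_NF
        (1, 5.185, 17, -8.176, 18.510, -29.285, 9.589),
        (2, 4.041, 17, -14.168, 8.428, -25.939, 11.003),
        (3, 3.932, 17, -8.087, 16.656, -24.731, 10.582),
    ],
    columns=["block", "t", "n", "mean_T", "sd_T", "mean_NF", "sd_NF"],
)

#: Between-group NF-MI-ERD summaries (quiet rest vs documentaries);
#: ``p`` is the published two-sided p-value as printed (3 decimals).
GROUP_SUMMARY = pd.DataFrame(
    [
        # block, mean_qr, sd_qr,  mean_doc, sd_doc, n_per_group, p
        (1, -29.285, 9.589, -25.289, 14.490, 17, 0.350),
        (2, -25.939, 11.003, -32.005, 20.773, 17, 0.295),
        (3, -24.731, 10.582, -25.966, 19.851, 17, 0.822),
    ],
    columns=["block", "mean_qr", "sd_qr", "mean_doc", "sd_doc", "n", "p"],
)
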