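#!/usr/bin/env python
"""Statistical comparisons of the two onset responses.

Runs, per stimulus condition, the paired t-max permutation test on the
per-subject TFRs (NB1 vs NB2 onset response, family-wise alpha 0.05);
per response group, the per-sample Wilcoxon rank-sum comparison of the
pooled filtered waveforms with FDR correction (alpha 0.01); and the
two-way ANOVA of the time-domain parameters on NB1 duration x gap
duration.  Prints a compact summary table.
"""

from pathlib import Path

import pandas as pd

from abrgap import (
    anova_time_domain,
    assign_group,
    choi_williams,
    extract_onset_epochs,
    filter_recording,
    gap_nb1_ratio,
    paired_permutation_tfr,
    read_recordings,
    wilcoxon_fdr_waveforms,
)
from abrgap.io import write_table

IN = Path("scratch/recordings.h5")
TIME_DOMAIN = Path("results/time_domain.tsv")
OUT = Path("results/stats_summary.tsv")


def main() -> None:
    by_cond = {}
    by_group = {}
    for rec in read_recordings(IN):
        e1, e2 = extract_onset_epochs(filter_recording(rec))
        by_cond.setdefault(rec.condition.label(), ([], []))
        t1 = choi_williams(e1)
        t2 = choi_williams(e2)
        keep = (t1.freq_axis_hz >= 350) & (t1.freq_axis_hz <= 1200)
        by_cond[rec.condition.label()][0].append(t1.power[:, keep])
        by_cond[rec.condition.label()][1].append(t2.power[:, keep])
        group = assign_group(gap_nb1_ratio(rec.condition)).value
        by_group.setdefault(group, ([], []))
        by_group[group][0].append(e1)
        by_group[group][1].append(e2)

    rows = []
    for label, (tfr1, tfr2) in sorted(by_cond.items()):
        tfr_mask = paired_permutation_tfr(tfr1, tfr2, seed=1)
        rows.append(
            {
                "condition": label,
                "tfr_significant_fraction": tfr_mask.mask.mean(),
            }
        )
        print(f"{label:28s} TFR sig {tfr_mask.mask.mean():5.1%}")

    for group, (a, b) in sorted(by_group.items()):
        wave_mask = wilcoxon_fdr_waveforms(a, b)
        print(f"{group:18s} pooled waveform samples significant: "
              f"{wave_mask.mask.mean():5.1%}")

    td = pd.read_csv(TIME_DOMAIN, sep="\t", comment="#")
    for param in ("rms_ratio", "peak3_ratio"):
        res = anova_time_domain(td[param], td["nb1_ms"], td["gap_ms"])
        print(f"ANOVA {param}: p(nb1)={res.p_value('nb1'):.2e} "
              f"p(gap)={res.p_value('gap'):.2e} "
              f"p(interaction)={res.p_value('nb1:gap'):.2e}")

    write_table(pd.DataFrame(rows), OUT)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
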