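#!/usr/bin/env python
"""Control-cohort descriptive statistics motivating the KDE approach.

For each modality: median [Q1, Q3] of the voxel-wise CoV of baseline
values (CS reference) and of longitudinal changes (LNG reference), the
median longitudinal percent change, and the fraction of voxels
rejecting normality (Shapiro-Wilk, BH at FDR 0.05).  Output:
results/control_summaries.tsv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import MODALITIES, RESULTS, get_cohort  # noqa: E402

from voxnorm.core_io import Group, Session  # noqa: E402
from voxnorm.abnormality import longitudinal_change  # noqa: E402
from voxnorm.summaries import normality_qc, percent_change, voxelwise_cov  # noqa: E402


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for modality in MODALITIES:
        cohort = get_cohort(modality)
        base = cohort.stack(Group.CONTROL, Session.BASELINE)
        post = cohort.stack(Group.CONTROL, Session.POSTSEASON)
        change = longitudinal_change(post, base)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for analysis, stack in (("CS", base), ("LNG", change)):
                cov = voxelwise_cov(stack)
                qc = normality_qc(stack)
                rows.append(dict(
                    modality=modality.value, analysis=analysis,
                    cov_median=round(cov.median, 4),
                    cov_q1=round(cov.q1, 4), cov_q3=round(cov.q3, 4),
                    nonnormal_fraction=round(qc.rejected_fraction, 4)))
            chg = percent_change(base, post)
        rows[-2]["chg_pct_median"] = ""
        rows[-1]["chg_pct_median"] = round(chg.median, 3)
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "control_summaries.tsv", sep="\t", index=False)
    print("Control normative summaries (44 simulated controls):")
    print(table.to_string(index=False))
    print("\nNote the longitudinal-change CoV dwarfs the baseline CoV: "
          "stable between-subject differences dominate baseline variance.")


if __name__ == "__main__":
    main()
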