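#!/usr/bin/env python
"""Per-subject abnormality maps: CS and LNG pipelines at FDR 0.05.

Fits the per-voxel normative KDE models (cached under scratch/), scores
every concussed subject at SYM and RTP, thresholds (BH q = 0.05 +
minimum cluster size 3), and writes:
  results/extent_table.tsv        percent abnormal voxels, median [Q1, Q3]
  results/direction_table.tsv     positive-abnormality fraction
  results/representative_slices.tsv  per-subject display slice
  scratch/maps_<mod>.npz          retained probability and binary maps
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, MODALITIES, RESULTS, SCRATCH, get_cohort, get_model  # noqa: E402

from voxnorm.core_io import Group, Session  # noqa: E402
from voxnorm.abnormality import (  # noqa: E402
    analyze_stack, longitudinal_change, representative_slice, summarize_extent,
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    extent_tables, slice_rows = [], []
    for modality in MODALITIES:
        cohort = get_cohort(modality)
        conc_base = cohort.stack(Group.CONCUSSED, Session.BASELINE)
        results, pmaps, binaries = [], {}, {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for analysis in ("CS", "LNG"):
                model = get_model(modality, analysis)
                for tp in (Session.SYM, Session.RTP):
                    stack = cohort.stack(Group.CONCUSSED, tp)
                    if analysis == "LNG":
                        stack = longitudinal_change(stack, conc_base)
                    res = analyze_stack(model, stack, analysis, tp, CONFIG)
                    results.extend(res)
                    for r in res:
                        key = f"{r.subject_id}|{analysis}|{tp.value}"
                        pmaps[key] = r.p_two
                        binaries[key] = r.abnormal
        np.savez_compressed(SCRATCH / f"maps_{modality.value}.npz",
                            mask=cohort.mask, **{f"p|{k}": v for k, v in pmaps.items()},
                            **{f"b|{k}": v for k, v in binaries.items()})
        table = summarize_extent(results)
        extent_tables.append(table)
        # representative axial slice per subject from the 4 binary maps
        for sid in cohort.stack(Group.CONCUSSED, Session.SYM).subject_ids:
            maps = []
            for analysis in ("CS", "LNG"):
                for tp in ("SYM", "RTP"):
                    vec = binaries.get(f"{sid}|{analysis}|{tp}")
                    if vec is None:
                        maps.append(None)
                        continue
                    vol = np.zeros(cohort.mask.shape, dtype=bool)
                    vol[cohort.mask] = vec
                    maps.append(vol)
            slice_rows.append(dict(modality=modality.value, subject_id=sid,
                                   axial_slice=representative_slice(maps)))

    extent = pd.concat(extent_tables, ignore_index=True)
    ext_cols = ["modality", "analysis", "timepoint", "n_subjects",
                "abnormal_pct_median", "abnormal_pct_q1", "abnormal_pct_q3"]
    dir_cols = ["modality", "analysis", "timepoint", "n_subjects",
                "positive_fraction_median", "positive_fraction_q1",
                "positive_fraction_q3"]
    extent[ext_cols].round(3).to_csv(RESULTS / "extent_table.tsv",
                                     sep="\t", index=False)
    extent[dir_cols].round(3).to_csv(RESULTS / "direction_table.tsv",
                                     sep="\t", index=False)
    pd.DataFrame(slice_rows).to_csv(RESULTS / "representative_slices.tsv",
                                    sep="\t", index=False)
    print("Percent abnormal voxels, median [Q1, Q3]:")
    print(extent[ext_cols].round(3).to_string(index=False))
    print("\nPositive-abnormality fraction:")
    print(extent[dir_cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
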