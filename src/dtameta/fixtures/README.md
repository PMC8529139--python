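# Packaged study tables

## `liu2021_mir21`

Thirty diagnostic trials from 26 published articles (2008-2020)
evaluating exosomal microRNA-21 as a cancer biomarker, each summarised
by its 2x2 confusion table (TP, FN, FP, TN) against a gold-standard
diagnosis, as collected in a 2021 meta-analysis of the marker.  Trials
that share an article (the three Goto cohorts, the two Kawamura blood
compartments, the two Liu-2020 serum cohorts) carry the same
`article_id` but are pooled as independent units, which is how the
source's 30-trial forest plots treat them.

Every row satisfies `tp + fn + fp + tn == sample_size`.

### Count-column orientation

The source's printed table labels its middle count columns "FN, FP",
but the values in those columns are transposed: the printed layout is
actually TP, FP, FN, TN.  Two independent checks establish this:

1. The bivariate random-effects fit of the printed reading gives pooled
   sensitivity 0.88 / specificity 0.73, irreconcilable with the
   source's reported 0.76 / 0.82; the transposed reading gives
   0.75 / 0.82 (and matching PLR, NLR, DOR and AUC).
2. The source states that the positive predictive value TP/(TP+FP)
   exceeds 75% in 23 of its 30 trials.  Under the transposed reading
   the count is exactly 23; under the printed header it is 14.

This file stores the corrected assignment (`fn` and `fp` as analysed,
not as printed).

### Subgroup labels

The source does not enumerate subgroup membership, so the labels are
materialised here as columns rather than recomputed:

- `ethnicity_group`: `caucasian` for US/Canada/Spain/Germany trials,
  `asian` for Japan/China.
- `sample_group`: `plasma` / `serum` per the specimen column; `other`
  for urine, CSF, pancreatic juice, peritoneal-lavage fluid,
  portal-vein and peripheral blood.  The table contains 6 plasma and
  15 serum trials (the source's prose counts specimens per article,
  not per trial, and cannot be reconciled exactly).
- `cancer_group`: `digestive` for PC/PDAC/CRC/GC/ESCC, `breast`,
  `lung`, and `other` for CC (colon), OC, HCC, glioma, RCC, IPMN,
  UC, LSCC and lymphoma, following the source's own enumeration of
  "other types".  This yields 14 digestive trials at the trial level
  (13 at the article level); the source's 13/11 split is not uniquely
  reconstructible and this mapping is one defensible choice.
- `pancreatic`: true for PC, PDAC and IPMN trials (8 trials).  The
  pancreatic-cancer summary row of the source corresponds most closely
  to the PC/PDAC-labelled subset (7 trials, IPMN excluded).
- `cut-off` values are free text in the source and are not used by any
  computation, so they are not carried.
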