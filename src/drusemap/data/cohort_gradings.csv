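# 33-eye intermediate-AMD cohort: expert change grading vs two automated
# methods (mspr = multispectral pattern recognition; cirrus = OCT-based
# RPE-elevation change analysis). The categorical columns reproduce the
# observed per-subgroup classification counts of the reference cohort
# (11 progression / 11 stable / 11 regression eyes). The *_pct columns are
# SYNTHETIC illustrative percent changes consistent with the categories
# (per-eye percent values are not part of the reported counts; stable-eye
# false positives for mspr use the reported 23-33% range).
eye_id,expert,mspr_pct,mspr_cat,cirrus_pct,cirrus_cat
E01,progression,12.0,progression,10.5,progression
E02,progression,18.5,progression,20.0,progression
E03,progression,25.0,progression,30.0,progression
E04,progression,31.0,progression,28.0,progression
E05,progression,40.0,progression,35.0,progression
E06,progression,8.5,progression,2.0,stable
E07,progression,55.0,progression,48.0,progression
E08,progression,22.0,progression,18.0,progression
E09,progression,15.5,progression,12.0,progression
E10,progression,70.0,progression,60.0,progression
E11,progression,9.0,progression,-1.5,stable
E12,stable,23.0,progression,4.0,stable
E13,stable,28.0,progression,1.0,stable
E14,stable,33.0,progression,-2.0,stable
E15,stable,-2.0,stable,7.5,progression
E16,stable,1.5,stable,10.0,progression
E17,stable,4.0,stable,0.0,stable
E18,stable,-3.5,stable,-1.0,stable
E19,stable,0.5,stable,2.0,stable
E20,stable,2.5,stable,-3.0,stable
E21,stable,-4.5,stable,1.5,stable
E22,stable,3.0,stable,-0.5,stable
E23,regression,-12.0,regression,-10.0,regression
E24,regression,-20.0,regression,-18.0,regression
E25,regression,-8.0,regression,-6.5,regression
E26,regression,-30.0,regression,-25.0,regression
E27,regression,-45.0,regression,-40.0,regression
E28,regression,-15.0,regression,8.0,progression
E29,regression,-25.0,regression,12.0,progression
E30,regression,-10.0,regression,6.5,progression
E31,regression,-60.0,regression,2.0,stable
E32,regression,-18.0,regression,-3.0,stable
E33,regression,-35.0,regression,1.0,stable
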