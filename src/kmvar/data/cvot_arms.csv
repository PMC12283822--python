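trial_id,arm,drug_class,deaths,n,median_follow_up,year,mean_age,pct_male,mean_bmi,mean_hba1c,mean_hba1c_mmol_mol,mean_duration,mean_egfr,mean_sbp,mean_chol,mean_trig
CANVAS,placebo,SGLT2,289,4347,28.1,2017,63.4,63.3,32.0,8.2,66.1,13.7,76.2,136.9,170.2,177.0
CARMELINA,placebo,DPP-4,373,3485,26.5,2018,65.6,64.3,31.3,8.0,63.9,14.5,54.5,140.6,171.0,187.0
CREDENCE,placebo,SGLT2,200,2199,31.3,2019,63.2,66.7,31.3,8.3,67.2,16.0,56.0,140.2,179.8,197.0
DECLARE-TIMI 58,placebo,SGLT2,489,8578,47.3,2019,64.0,62.1,32.0,8.3,67.2,10.0,85.1,134.8,,
EMPA-REG Outcome,placebo,SGLT2,194,2333,37.5,2015,63.2,72.0,30.7,8.1,64.8,,73.8,135.8,161.9,170.7
EXAMINE,placebo,DPP-4,166,2679,19.4,2013,61.0,67.7,28.7,8.0,63.9,7.1,71.1,,154.8,166.4
EXSCEL,placebo,GLP-1,564,7396,39.8,2017,62.0,62.0,31.7,8.0,63.9,12.0,76.0,,,
LEADER,placebo,GLP-1,445,4672,46.5,2016,64.4,64.0,32.5,8.7,71.6,12.9,80.6,135.9,,
REWIND,placebo,GLP-1,585,4952,65.4,2019,66.2,53.9,32.3,7.4,57.4,10.6,76.6,137.3,174.8,141.6
TECOS,placebo,DPP-4,518,7339,36.1,2015,65.5,70.5,30.2,7.2,55.2,11.6,74.9,135.0,165.4,164.8
CANVAS,verum,SGLT2,412,5795,33.9,2017,63.2,64.9,31.9,8.2,66.1,13.5,76.7,136.4,170.2,177.0
CARMELINA,verum,DPP-4,366,3494,26.8,2018,66.1,61.5,31.4,7.9,62.8,15.0,54.7,140.4,173.0,190.0
CREDENCE,verum,SGLT2,166,2202,31.6,2019,62.9,65.4,31.4,8.3,67.2,15.5,56.3,139.8,180.9,198.8
DECLARE-TIMI 58,verum,SGLT2,465,8582,47.3,2019,63.9,63.1,32.1,8.3,67.2,11.0,85.4,135.1,,
EMPA-REG Outcome,verum,SGLT2,267,4687,37.9,2015,63.1,71.2,30.6,8.1,64.7,,74.2,135.3,163.5,170.5
EXAMINE,verum,DPP-4,150,2701,19.5,2013,61.0,68.0,28.7,8.0,63.9,7.3,71.2,,153.9,162.7
EXSCEL,verum,GLP-1,487,7356,40.1,2017,62.0,62.0,31.8,8.0,63.9,12.0,76.6,,,
LEADER,verum,GLP-1,379,4668,46.7,2016,64.2,64.5,32.5,8.7,71.6,12.8,80.2,135.9,,
REWIND,verum,GLP-1,524,4949,65.3,2019,66.2,53.4,32.3,7.3,56.3,10.5,77.2,137.1,174.8,141.6
TECOS,verum,DPP-4,524,7332,36.4,2015,65.4,70.9,30.2,7.2,55.2,11.6,74.9,135.0,166.1,166.0
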