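# prospective (TTP) cohort, individual patient imaging data, rows ordered by hours after stroke onset
# volumes in ml as printed (whole-ml precision); inconsistent_flag marks rows irreconcilable with the mismatch rules at that precision
patient_id,hours_after_onset,dwi_vol_ml,perf_vol_ml,perf_modality,mismatch_vol_ml,mismatch_pct,inconsistent_flag
P01,0.5,11,57,TTP,46,417,0
P02,1.6,3,18,TTP,20,649,1
P03,1.7,18,106,TTP,88,502,0
P04,2.5,16,52,TTP,36,229,0
P05,2.7,99,208,TTP,109,109,0
P06,3.0,88,186,TTP,97,110,0
P07,3.0,17,37,TTP,21,121,0
P08,3.1,60,180,TTP,120,200,0
P09,4.1,23,54,TTP,31,132,0
P10,4.2,69,250,TTP,181,263,0
P11,4.5,8,206,TTP,199,2556,0
P12,4.5,15,92,TTP,76,497,0
P13,4.7,0,3,TTP,3,615,0
P14,4.7,34,82,TTP,48,142,0
P15,4.8,154,242,TTP,88,57,0
P16,5.0,121,205,TTP,84,69,0
P17,5.0,116,151,TTP,36,31,0
P18,5.1,8,19,TTP,10,120,0
P19,5.2,118,260,TTP,143,121,0
P20,5.2,158,200,TTP,41,26,0
P21,5.3,7,26,TTP,18,254,0
P22,5.3,24,50,TTP,26,110,0
P23,5.5,18,68,TTP,50,277,0
P24,5.5,20,93,TTP,73,367,0
P25,5.7,11,59,TTP,49,460,0
P26,5.7,101,153,TTP,53,52,0
P27,5.7,244,286,TTP,42,17,0
P28,5.9,12,84,TTP,72,578,0
P29,5.9,13,35,TTP,22,177,0
P30,6.1,5,30,TTP,25,491,0
P31,6.2,1,37,TTP,37,5883,0
P32,6.2,2,66,TTP,64,3490,0
P33,6.2,29,84,TTP,56,195,0
P34,6.3,192,270,TTP,78,41,0
P35,6.4,8,145,TTP,138,1832,0
P36,6.5,18,82,TTP,64,347,0
P37,6.6,4,51,TTP,47,1261,0
P38,6.6,304,354,TTP,51,17,0
P39,6.6,37,160,TTP,123,332,0
P40,6.6,39,178,TTP,139,355,0
P41,7.7,43,105,TTP,63,148,0
P42,9.0,16,49,TTP,32,196,0
P43,10.8,150,243,TTP,93,62,0
P44,12.3,58,129,TTP,72,125,0
P45,12.7,2,43,TTP,41,1719,0
P46,12.8,2,28,TTP,26,1211,0
P47,13.4,130,246,TTP,117,90,0
P48,14.4,6,49,TTP,43,684,0
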