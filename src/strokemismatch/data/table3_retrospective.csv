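# retrospective (MTT) cohort, individual patient imaging data, rows ordered by hours after stroke onset
# volumes in ml as printed (whole-ml precision); inconsistent_flag marks rows irreconcilable with the mismatch rules at that precision
patient_id,hours_after_onset,dwi_vol_ml,perf_vol_ml,perf_modality,mismatch_vol_ml,mismatch_pct,inconsistent_flag
R01,1.4,1,85,MTT,83,7049,0
R02,1.5,90,209,MTT,118,131,0
R03,1.6,277,348,MTT,71,26,0
R04,1.7,2,37,MTT,35,1508,0
R05,1.9,85,148,MTT,63,75,0
R06,2.0,150,290,MTT,140,93,0
R07,2.0,72,168,MTT,96,134,0
R08,2.0,161,228,MTT,67,42,0
R09,2.0,170,14,MTT,0,0,0
R10,2.0,0,49,MTT,49,52239,0
R11,2.2,24,84,MTT,60,252,0
R12,2.3,30,245,MTT,215,723,0
R13,2.4,11,217,MTT,206,1898,0
R14,2.5,17,170,MTT,152,871,0
R15,2.8,252,484,MTT,232,92,0
R16,2.9,232,289,MTT,57,25,0
R17,3.0,17,174,MTT,157,912,0
R18,3.3,7,126,MTT,120,1782,0
R19,3.4,3,216,MTT,213,8290,0
R20,3.4,5,86,MTT,81,1663,0
R21,3.5,308,315,MTT,7,2,0
R22,3.6,27,122,MTT,95,349,0
R23,4.4,2,38,MTT,37,2249,0
R24,4.4,43,128,MTT,86,201,0
R25,4.4,65,204,MTT,139,216,0
R26,4.4,8,177,MTT,169,2083,0
R27,4.5,12,174,MTT,162,1321,0
R28,4.6,29,128,MTT,99,347,0
R29,4.8,115,170,MTT,55,48,0
R30,4.9,0,68,MTT,68,49547,0
R31,5.0,182,299,MTT,117,64,0
R32,5.3,10,147,MTT,137,1439,0
R33,5.6,2,53,MTT,51,2780,0
R34,5.6,25,93,MTT,68,276,0
R35,5.7,20,86,MTT,66,326,0
R36,5.9,89,247,MTT,158,178,0
R37,6.0,8,85,MTT,77,976,0
R38,6.4,67,152,MTT,85,126,0
R39,6.5,14,251,MTT,237,1667,0
R40,6.6,166,283,MTT,117,70,0
R41,6.7,1,140,MTT,138,12810,0
R42,6.7,4,52,MTT,49,1356,0
R43,6.8,11,257,MTT,246,2261,0
R44,7.6,31,125,MTT,94,301,0
R45,7.9,203,218,MTT,15,7,0
R46,8.1,23,92,MTT,69,301,0
R47,8.1,3,52,MTT,50,1983,0
R48,8.2,44,180,MTT,136,313,0
R49,9.0,23,317,MTT,295,1307,0
R50,9.4,149,161,MTT,12,8,0
R51,10.3,91,11,MTT,0,0,0
R52,10.5,65,272,MTT,207,319,0
R53,11.0,58,248,MTT,191,330,0
R54,11.2,232,181,MTT,0,0,0
R55,11.2,18,75,MTT,93,513,1
R56,12.7,12,203,MTT,190,1529,0
R57,13.0,3,87,MTT,84,2475,0
R58,14.0,60,176,MTT,116,195,0
R59,15.2,26,206,MTT,180,691,0
R60,15.8,9,166,MTT,158,1818,0
R61,16.8,19,216,MTT,198,1055,0
R62,17.4,3,14,MTT,11,406,0
R63,18.0,6,191,MTT,186,3234,0
R64,19.5,62,157,MTT,95,153,0
R65,21.1,79,167,MTT,87,110,0
R66,21.2,1,123,MTT,122,12052,0
R67,22.3,50,127,MTT,77,153,0
R68,22.7,11,85,MTT,74,658,0
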