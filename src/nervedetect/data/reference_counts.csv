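slide_id,n_annotations,cf_tp_m,cf_tpr_printed,cnn_tp_m,cnn_tpr_printed,cf_additional,cf_est_tp_a,cf_est_fp,cnn_additional,cnn_tp_a,cnn_fp,cf_tp_printed,cf_ppv_printed,cnn_tp_printed,cnn_ppv_printed
10012,10,9,0.9,9,0.9,847,45,802,50,34,16,54,0.06,43,0.73
10023,12,12,1,11,0.92,2658,89,2569,63,39,24,101,0.04,50,0.68
10029,11,11,1,8,0.73,3390,0,3390,21,11,10,11,0,19,0.66
10036,9,8,0.89,9,1,4316,432,3884,385,304,81,440,0.1,313,0.79
10039,35,35,1,31,0.89,6591,712,5879,419,316,103,747,0.11,347,0.77
10049,15,15,1,12,0.8,7185,48,7137,26,15,11,63,0.01,27,0.71
10064,28,28,1,25,0.89,1922,26,1896,33,21,12,54,0.03,46,0.79
10067,27,27,1,25,0.93,815,244,571,146,126,20,271,0.32,151,0.88
10071,21,20,0.95,18,0.86,3113,197,2916,40,29,11,217,0.07,47,0.81
10072,15,14,0.93,14,0.93,492,77,415,45,37,8,91,0.18,51,0.86
10073,2,2,1,1,0.5,8348,167,8181,25,17,8,169,0.02,18,0.69
10078,15,15,1,13,0.87,9884,659,9225,99,70,29,674,0.07,83,0.74
10087,0,0,,0,,877,9,868,11,10,1,9,0.01,10,0.91
10088,8,8,1,8,1,1689,146,1543,100,70,30,154,0.09,78,0.72
10093,11,11,1,11,1,2773,55,2718,17,11,6,66,0.02,22,0.79
10096,1,1,1,1,1,1019,27,992,32,18,14,28,0.03,19,0.58
10097,19,18,0.95,18,0.95,6907,1036,5871,511,395,116,1054,0.15,413,0.78
10102,25,25,1,24,0.96,4799,720,4079,405,285,120,745,0.15,309,0.72
10113,16,15,0.94,14,0.88,1504,140,1364,245,185,60,155,0.1,199,0.77
10114,14,14,1,13,0.93,6529,1372,5157,1059,806,253,1386,0.21,819,0.76
10116,16,16,1,15,0.94,5005,233,4772,318,222,96,249,0.05,237,0.71
10121,8,8,1,7,0.88,4278,399,3879,296,198,98,407,0.09,205,0.68
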