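t_start_h,t_end_h,t_mid_h,n,mean_fraction,sd_fraction,cv_pct
0.17,0.32,0.24,1,0.096,,
0.50,0.65,0.58,3,0.167,0.014,8.4
0.67,0.82,0.74,4,0.215,0.063,29.2
0.83,0.98,0.91,1,0.300,,
1.17,1.32,1.24,2,0.193,0.071,37.1
1.67,1.82,1.74,1,0.434,,
1.83,1.98,1.91,1,0.321,,
2.17,2.32,2.24,2,0.283,0.002,0.8
2.33,2.48,2.41,2,0.317,0.027,8.5
2.50,2.65,2.58,9,0.335,0.028,8.4
2.67,2.82,2.74,14,0.320,0.066,20.7
2.83,2.98,2.91,17,0.294,0.065,22.3
3.00,3.15,3.08,22,0.326,0.065,20.0
3.17,3.32,3.24,5,0.283,0.086,30.3
3.33,3.48,3.41,2,0.336,0.046,13.7
3.50,3.65,3.58,1,0.353,,
3.67,3.82,3.74,1,0.244,,
3.83,3.98,3.91,1,0.433,,
4.00,4.15,4.08,1,0.341,,
4.17,4.32,4.24,3,0.366,0.058,15.7
4.33,4.48,4.41,1,0.344,,
4.67,4.82,4.74,2,0.395,,
5.67,5.82,5.74,1,0.474,,
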